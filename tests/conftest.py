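import numpy as np
import pytest

from painrank import nn, pspi, ranker, synth


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Default synthetic corpus: 2 subjects x 5 levels x 12 frames at 64x64."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = synth.simulate_corpus(synth.ProtocolParams(seed=0),
                                     synth.FaceRenderParams(), out)
    frames = ranker.load_frames(manifest, out)
    return {"dir": out, "manifest": manifest, "frames": frames}


@pytest.fixture(scope="session")
def trained(corpus):
    """One 3-layer triplet model trained at the default hyperparameters
    (lr 0.1, batch 64, 30 epochs) on the minority-balanced corpus."""
    balanced = pspi.balance_by_minority(corpus["manifest"], seed=1)
    model, info = ranker.train(
        balanced, nn.BranchSpec(n_conv_layers=3),
        ranker.TrainConfig(loss_kind="triplet", seed=1, n_samples=512),
        frames=corpus["frames"])
    return {"model": model, "info": info}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
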