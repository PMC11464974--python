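"""Siamese/Triplet metric learning with exponential losses.

Training units are pairs or triplets of frames carrying ordinal pain
relations.  With g(.) the shared branch embedding and ||.|| the Euclidean
norm, the losses are

    L_siamese = sum over same-state pairs      exp(||g(x0) - g(x1)||)
    L_triplet = sum over (anchor, pos, neg)    exp(||g(x0) - g(x1)||)
                                             - exp(||g(x0) - g(x2)||)

The Siamese form only pulls same-pain-state pairs together (the contrastive
reading of a similarity loss); the triplet form additionally pushes the
anchor away from a frame of a different pain state.  Because exp of a
distance is unbounded, branches use tanh-squashed embeddings by default,
which bounds both losses (see ``nn``).

Optimization is plain SGD at the printed defaults (learning rate 0.1, batch
size 64, 30 epochs), using the batch-mean loss with global gradient-norm
clipping for stability at that step size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .nn import BranchSpec, RankerModel

__all__ = [
    "PairSample", "TripletSample", "TrainConfig", "TrainingDiverged",
    "siamese_loss", "triplet_loss", "siamese_loss_grad", "triplet_loss_grad",
    "make_pairs", "make_triplets", "load_frames", "train",
    "triplet_ordering_accuracy",
]

_DIST_EPS = 1e-12


@dataclass(frozen=True)
class PairSample:
    """Two frames (manifest indices) plus the ordinal sign of PSPI(x1)-PSPI(x0)."""

    x0: int
    x1: int
    relation: int  # -1, 0, +1

    def __post_init__(self):
        if self.relation not in (-1, 0, 1):
            raise ValueError(f"relation must be -1, 0 or +1, got {self.relation}")


@dataclass(frozen=True)
class TripletSample:
    """Anchor, positive (same pain state) and negative (different state) frames."""

    anchor: int
    positive: int
    negative: int


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    batch_size: int = 64
    epochs: int = 30
    optimizer: str = "sgd"
    seed: int = 0
    loss_kind: str = "triplet"
    n_samples: int = 512          # pairs or triplets drawn for training
    holdout_fraction: float = 0.2  # frame-level, stratified by pain state
    grad_clip: float = 5.0         # global gradient-norm ceiling

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("hyperparameters must be positive (epochs >= 0)")
        if self.loss_kind not in ("siamese", "triplet"):
            raise ValueError(f"loss_kind must be 'siamese' or 'triplet', got {self.loss_kind!r}")
        if self.optimizer != "sgd":
            raise ValueError("only sgd is supported")


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------- losses

def _dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.atleast_2d(a) - np.atleast_2d(b), axis=-1)


def siamese_loss(e0: np.ndarray, e1: np.ndarray) -> float:
    """Sum of exp(Euclidean distance) over embedded same-state pairs."""
    e0, e1 = np.atleast_2d(e0), np.atleast_2d(e1)
    if e0.shape[0] == 0:
        raise ValueError("siamese_loss requires at least one pair")
    return float(np.exp(_dists(e0, e1)).sum())


def triplet_loss(e0: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> float:
    """Sum of exp(d(anchor, pos)) - exp(d(anchor, neg)) over embedded triplets."""
    e0 = np.atleast_2d(e0)
    if e0.shape[0] == 0:
        raise ValueError("triplet_loss requires at least one triplet")
    return float((np.exp(_dists(e0, e1)) - np.exp(_dists(e0, e2))).sum())


def _exp_dist_grad(e0: np.ndarray, e1: np.ndarray):
    """d/de of exp(||e0-e1||): value, grad_e0 (grad_e1 is its negative)."""
    diff = e0 - e1
    d = np.linalg.norm(diff, axis=-1, keepdims=True)
    val = np.exp(d[..., 0])
    unit = np.where(d > _DIST_EPS, diff / np.maximum(d, _DIST_EPS), 0.0)
    return val, val[..., None] * unit


def siamese_loss_grad(e0: np.ndarray, e1: np.ndarray):
    """(loss, dL/de0, dL/de1) for the Siamese exponential loss."""
    e0, e1 = np.atleast_2d(e0), np.atleast_2d(e1)
    if e0.shape[0] == 0:
        raise ValueError("siamese_loss requires at least one pair")
    val, g0 = _exp_dist_grad(e0, e1)
    return float(val.sum()), g0, -g0


def triplet_loss_grad(e0: np.ndarray, e1: np.ndarray, e2: np.ndarray):
    """(loss, dL/de0, dL/de1, dL/de2) for the Triplet exponential loss."""
    e0, e1, e2 = np.atleast_2d(e0), np.atleast_2d(e1), np.atleast_2d(e2)
    if e0.shape[0] == 0:
        raise ValueError("triplet_loss requires at least one triplet")
    vp, gp = _exp_dist_grad(e0, e1)
    vn, gn = _exp_dist_grad(e0, e2)
    return float((vp - vn).sum()), gp - gn, -gp, gn


# ---------------------------------------------------------------- sampling

def make_pairs(manifest: pd.DataFrame, n_pairs: int, seed: int = 0) -> list[PairSample]:
    """Draw same-pain-state pairs uniformly (with replacement) under ``seed``.

    The relation field records sign(PSPI(x1) - PSPI(x0)), which may be
    nonzero within a state whose bin spans several PSPI values.
    """
    rng = np.random.default_rng(seed)
    by_state = {s: manifest.index[manifest["pain_state"] == s].to_numpy()
                for s in sorted(manifest["pain_state"].unique())}
    states = [s for s, idx in by_state.items() if len(idx) >= 2]
    if not states:
        raise ValueError("no pain state has >= 2 frames; cannot form pairs")
    pspi = manifest["pspi"]
    out = []
    for _ in range(n_pairs):
        s = states[rng.integers(len(states))]
        i, j = rng.choice(by_state[s], size=2, replace=False)
        out.append(PairSample(int(i), int(j), int(np.sign(pspi[j] - pspi[i]))))
    return out


def make_triplets(manifest: pd.DataFrame, n_triplets: int, seed: int = 0) -> list[TripletSample]:
    """Draw (anchor, positive, negative) triplets under ``seed``.

    Positive shares the anchor's pain state; negative is drawn uniformly from
    the other states.  Requires at least two states, one of which has >= 2
    frames.
    """
    rng = np.random.default_rng(seed)
    by_state = {s: manifest.index[manifest["pain_state"] == s].to_numpy()
                for s in sorted(manifest["pain_state"].unique())}
    if len(by_state) < 2:
        raise ValueError("triplet sampling needs at least two pain-state classes")
    anchor_states = [s for s, idx in by_state.items() if len(idx) >= 2]
    if not anchor_states:
        raise ValueError("no pain state has >= 2 frames; cannot form triplets")
    out = []
    for _ in range(n_triplets):
        s = anchor_states[rng.integers(len(anchor_states))]
        a, p = rng.choice(by_state[s], size=2, replace=False)
        others = [t for t in by_state if t != s]
        t = others[rng.integers(len(others))]
        n = rng.choice(by_state[t])
        out.append(TripletSample(int(a), int(p), int(n)))
    return out


# ---------------------------------------------------------------- training

def load_frames(manifest: pd.DataFrame, root: str | Path) -> dict[int, np.ndarray]:
    """Load the manifest's frames as float [0, 1] arrays keyed by manifest index."""
    root = Path(root)
    frames = {}
    for idx, rel in manifest["frame_path"].items():
        path = root / rel
        try:
            with Image.open(path) as im:
                frames[idx] = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        except OSError as e:
            raise OSError(f"cannot read frame {path}: {e}") from e
    return frames


def _stratified_split(manifest: pd.DataFrame, fraction: float, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    test_idx = []
    for s in sorted(manifest["pain_state"].unique()):
        idx = manifest.index[manifest["pain_state"] == s].to_numpy()
        n_test = max(1, int(round(fraction * len(idx)))) if fraction > 0 and len(idx) > 1 else 0
        test_idx.extend(rng.choice(idx, size=n_test, replace=False))
    test_mask = manifest.index.isin(test_idx)
    return manifest.loc[~test_mask], manifest.loc[test_mask]


def _clip_grads(grads: dict, ceiling: float) -> dict:
    norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if norm > ceiling:
        scale = ceiling / norm
        grads = {k: g * scale for k, g in grads.items()}
    return grads


def train(manifest: pd.DataFrame, spec: BranchSpec | None = None,
          config: TrainConfig | None = None, root: str | Path = ".",
          frames: dict[int, np.ndarray] | None = None) -> tuple[RankerModel, dict]:
    """Train a ranker on a labeled manifest.

    Returns ``(model, info)`` where ``info`` carries the per-epoch loss
    history, the held-out manifest split, and the training samples used.
    With ``epochs=0`` the initialized model is returned unchanged.  All
    randomness (init, split, sampling, shuffling) derives from
    ``config.seed``.  Raises :class:`TrainingDiverged` if the loss becomes
    non-finite.
    """
    spec = spec or BranchSpec()
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    model = nn.init_model(spec, seed=config.seed)
    model.meta.update({"config": config.__dict__.copy(), "channel_plan": spec.channel_plan})

    if frames is None:
        frames = load_frames(manifest, root)
    train_m, test_m = _stratified_split(manifest, config.holdout_fraction, rng)
    sample_seed = int(rng.integers(2**31 - 1))
    if config.loss_kind == "siamese":
        samples = make_pairs(train_m, config.n_samples, seed=sample_seed)
        cols = [[s.x0 for s in samples], [s.x1 for s in samples]]
    else:
        samples = make_triplets(train_m, config.n_samples, seed=sample_seed)
        cols = [[s.anchor for s in samples], [s.positive for s in samples],
                [s.negative for s in samples]]
    idx_mat = np.array(cols)                      # (branches, n_samples)
    n_branches, n_samples = idx_mat.shape

    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_samples)
        epoch_loss = 0.0
        for start in range(0, n_samples, config.batch_size):
            batch = idx_mat[:, order[start:start + config.batch_size]]
            nb = batch.shape[1]
            stack = np.stack([frames[i] for i in batch.T.ravel()])  # (nb*branches,H,W)
            emb, cache = nn.forward(model, stack, keep_cache=True)
            e = emb.reshape(nb, n_branches, -1)
            if config.loss_kind == "siamese":
                loss, g0, g1 = siamese_loss_grad(e[:, 0], e[:, 1])
                demb = np.stack([g0, g1], axis=1).reshape(emb.shape)
            else:
                loss, g0, g1, g2 = triplet_loss_grad(e[:, 0], e[:, 1], e[:, 2])
                demb = np.stack([g0, g1, g2], axis=1).reshape(emb.shape)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            grads = nn.backward(model, cache, demb / nb)
            grads = _clip_grads(grads, config.grad_clip)
            for k, g in grads.items():
                model.params[k] -= config.learning_rate * g
            epoch_loss += loss
        history.append(epoch_loss / n_samples)
    model.meta["loss_history"] = history
    model.meta["final_loss"] = history[-1] if history else None
    info = {"history": history, "train_manifest": train_m, "test_manifest": test_m,
            "samples": samples, "frames": frames}
    return model, info


def triplet_ordering_accuracy(model: RankerModel, triplets: list[TripletSample],
                              frames: dict[int, np.ndarray]) -> float:
    """Fraction of triplets with the anchor embedded closer to the positive."""
    if not triplets:
        raise ValueError("no triplets to evaluate")
    idx = sorted({i for t in triplets for i in (t.anchor, t.positive, t.negative)})
    emb = nn.embed(model, np.stack([frames[i] for i in idx]))
    pos = {i: k for k, i in enumerate(idx)}
    correct = 0
    for t in triplets:
        dp = np.linalg.norm(emb[pos[t.anchor]] - emb[pos[t.positive]])
        dn = np.linalg.norm(emb[pos[t.anchor]] - emb[pos[t.negative]])
        correct += dp < dn
    return correct / len(triplets)
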