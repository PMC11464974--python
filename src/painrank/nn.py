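"""Minimal convolutional branch network with manual backprop.

The Siamese/Triplet ranker uses two or three "sister" branches that are
literally one parameter set applied to each input; a branch is a small stack
of 3x3 stride-2 convolutions with ReLU, flattened into a fully connected
embedding layer of 48 units.  The final embedding is optionally squashed
through tanh so every component lies in (-1, 1), which bounds the pairwise
distances the exponential losses see.

Implemented directly on numpy (im2col convolutions, explicit backward pass);
the networks involved are tiny, so this stays fast on one CPU and keeps the
forward/backward arithmetic fully transparent for gradient checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["BranchSpec", "RankerModel", "init_model", "embed", "save_model", "load_model"]

_KERNEL = 3
_STRIDE = 2
_PAD = 1


@dataclass(frozen=True)
class BranchSpec:
    """Architecture of one branch: conv depth, channel plan, embedding width."""

    n_conv_layers: int = 3
    embedding_dim: int = 48
    input_size: int = 64
    channel_plan: tuple = ()
    activation: str = "relu"
    embedding_squash: bool = True

    def __post_init__(self) -> None:
        if self.n_conv_layers not in (3, 4, 5):
            raise ValueError(f"n_conv_layers must be 3, 4 or 5, got {self.n_conv_layers}")
        if self.activation != "relu":
            raise ValueError("only relu is supported")
        plan = self.channel_plan or tuple(16 * 2**i for i in range(self.n_conv_layers))
        if len(plan) != self.n_conv_layers:
            raise ValueError("channel_plan length must equal n_conv_layers")
        object.__setattr__(self, "channel_plan", tuple(int(c) for c in plan))
        if self.input_size % 2**self.n_conv_layers:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.n_conv_layers}"
            )

    @property
    def flat_dim(self) -> int:
        side = self.input_size // 2**self.n_conv_layers
        return self.channel_plan[-1] * side * side


@dataclass
class RankerModel:
    """Branch spec + one shared weight set + training metadata."""

    spec: BranchSpec
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def init_model(spec: BranchSpec, seed: int = 0) -> RankerModel:
    """He-initialized weights; biases zero.  Deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    c_in = 1
    for i, c_out in enumerate(spec.channel_plan):
        fan_in = c_in * _KERNEL * _KERNEL
        params[f"conv{i}_w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        params[f"conv{i}_b"] = np.zeros(c_out)
        c_in = c_out
    params["fc_w"] = rng.normal(0.0, np.sqrt(2.0 / spec.flat_dim), (spec.flat_dim, spec.embedding_dim))
    params["fc_b"] = np.zeros(spec.embedding_dim)
    return RankerModel(spec=spec, params=params, meta={"init_seed": seed})


def _im2col(x: np.ndarray) -> tuple[np.ndarray, int]:
    """(N, C, H, W) -> (N, Ho*Wo, C*9) patch matrix for 3x3/stride-2/pad-1."""
    xp = np.pad(x, ((0, 0), (0, 0), (_PAD, _PAD), (_PAD, _PAD)))
    n, c, hp, wp = xp.shape
    ho = (hp - _KERNEL) // _STRIDE + 1
    s = xp.strides
    shape = (n, c, ho, ho, _KERNEL, _KERNEL)
    strides = (s[0], s[1], s[2] * _STRIDE, s[3] * _STRIDE, s[2], s[3])
    patches = np.lib.stride_tricks.as_strided(xp, shape, strides)
    cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * ho, c * _KERNEL * _KERNEL)
    return cols, ho


def _col2im(dcols: np.ndarray, xshape: tuple, ho: int) -> np.ndarray:
    """Adjoint of _im2col: scatter patch gradients back to the input."""
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * _PAD, w + 2 * _PAD))
    dpatch = dcols.reshape(n, ho, ho, c, _KERNEL, _KERNEL).transpose(0, 3, 1, 2, 4, 5)
    for i in range(_KERNEL):
        for j in range(_KERNEL):
            dxp[:, :, i:i + _STRIDE * ho:_STRIDE, j:j + _STRIDE * ho:_STRIDE] += dpatch[:, :, :, :, i, j]
    return dxp[:, :, _PAD:_PAD + h, _PAD:_PAD + w]


def _as_batch(spec: BranchSpec, images: np.ndarray) -> tuple[np.ndarray, bool]:
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 2
    if single:
        images = images[None]
    if images.ndim != 3 or images.shape[1:] != (spec.input_size, spec.input_size):
        raise ValueError(
            f"expected images of shape (n, {spec.input_size}, {spec.input_size}), "
            f"got {tuple(images.shape)}"
        )
    return images[:, None, :, :], single


def forward(model: RankerModel, images: np.ndarray, keep_cache: bool = False):
    """Embed a batch of grayscale images; optionally keep the backward cache."""
    x, _ = _as_batch(model.spec, images)
    cache = []
    for i in range(model.spec.n_conv_layers):
        cols, ho = _im2col(x)
        w, b = model.params[f"conv{i}_w"], model.params[f"conv{i}_b"]
        pre = cols @ w.T + b                      # (N, Ho*Wo, F)
        act = np.maximum(pre, 0.0)
        if keep_cache:
            cache.append((x.shape, cols, ho, pre > 0))
        x = act.transpose(0, 2, 1).reshape(x.shape[0], w.shape[0], ho, ho)
    flat = x.reshape(x.shape[0], -1)
    z = flat @ model.params["fc_w"] + model.params["fc_b"]
    emb = np.tanh(z) if model.spec.embedding_squash else z
    if keep_cache:
        return emb, (cache, flat, emb, x.shape)
    return emb


def backward(model: RankerModel, cache, demb: np.ndarray) -> dict:
    """Gradients of a scalar loss w.r.t. all parameters, given d(loss)/d(embedding)."""
    conv_cache, flat, emb, last_shape = cache
    dz = demb * (1.0 - emb**2) if model.spec.embedding_squash else demb
    grads = {
        "fc_w": flat.T @ dz,
        "fc_b": dz.sum(axis=0),
    }
    dx = (dz @ model.params["fc_w"].T).reshape(last_shape)
    for i in reversed(range(model.spec.n_conv_layers)):
        xshape, cols, ho, relu_mask = conv_cache[i]
        w = model.params[f"conv{i}_w"]
        dact = dx.reshape(dx.shape[0], dx.shape[1], -1).transpose(0, 2, 1)  # (N, Ho*Wo, F)
        dpre = dact * relu_mask
        grads[f"conv{i}_w"] = np.einsum("npf,npk->fk", dpre, cols)
        grads[f"conv{i}_b"] = dpre.sum(axis=(0, 1))
        dcols = dpre @ w
        dx = _col2im(dcols, xshape, ho)
    return grads


def embed(model: RankerModel, images: np.ndarray) -> np.ndarray:
    """Branch output g(x): one 48-vector per image, order-preserving over a batch.

    Accepts a single (H, W) image or a stack (n, H, W); with
    ``embedding_squash`` every component lies in (-1, 1).
    """
    x = forward(model, images)
    _, single = _as_batch(model.spec, images)
    return x[0] if single else x


def save_model(model: RankerModel, path) -> None:
    """Single-file checkpoint: spec+meta JSON plus raw weight arrays (npz)."""
    payload = {"spec": asdict(model.spec), "meta": model.meta}
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    with open(path, "wb") as fh:
        np.savez(fh, header=np.frombuffer(json.dumps(payload).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> RankerModel:
    with np.load(path) as z:
        payload = json.loads(bytes(z["header"]).decode())
        spec_d = payload["spec"]
        spec_d["channel_plan"] = tuple(spec_d["channel_plan"])
        spec = BranchSpec(**spec_d)
        params = {k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")}
    return RankerModel(spec=spec, params=params, meta=payload["meta"])
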