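"""Convolutional sequence encoder, implemented in NumPy.

The encoder maps a one-hot encoded aligned sequence (4 channels x L sites)
to a d-dimensional real vector through three 1-D convolutional layers with
kernel sizes 1, 5 and 5, an additive skip connection from the second layer's
output into the third (a residual block), and a final fully-connected layer.
A rectifying nonlinearity between blocks is on by default and configurable.
Composed with an exponential map (:mod:`hyperplace.geometry`) the encoder
becomes a map from sequences into hyperbolic space.

Forward and backward passes are hand-written: convolutions are evaluated as
matrix products over an im2col view, and :func:`encoder_backward` returns
exact gradients for every parameter given the gradient at the output.  All
arithmetic is in double precision and fully deterministic given the
initialisation seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alignio import Alignment, _BASE_INDEX, _UNINFORMATIVE
from .geometry import GeometryMode, embed_tangent

__all__ = [
    "EncoderSpec",
    "EmbeddingModel",
    "encode_one_hot",
    "encoder_init",
    "encoder_forward",
    "encoder_backward",
    "embed_sequences",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1

_GAP_COLUMN = np.full(4, 0.25)


def encode_one_hot(seq: str) -> np.ndarray:
    """One-hot encode an aligned sequence into a (4, L) matrix.

    A/C/G/T map to standard basis columns; gaps and ambiguity codes map to
    the uninformative column (1/4, 1/4, 1/4, 1/4).  Every column sums to 1.
    """
    seq = seq.upper()
    out = np.zeros((4, len(seq)), dtype=float)
    for j, ch in enumerate(seq):
        if ch in _BASE_INDEX:
            out[_BASE_INDEX[ch], j] = 1.0
        elif ch in _UNINFORMATIVE:
            out[:, j] = _GAP_COLUMN
        else:
            raise ValueError(f"illegal character {ch!r} at position {j}")
    return out


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture hyper-parameters of the convolutional encoder.

    ``channels`` are the widths of the three convolutional layers; the
    second and third must match because of the additive skip connection.
    Kernel sizes are fixed at (1, 5, 5).  ``activation`` toggles the ReLU
    between blocks (the convolutions themselves are linear).
    """

    input_length: int
    embed_dim: int = 128
    channels: tuple[int, int, int] = (16, 16, 16)
    kernel_sizes: tuple[int, int, int] = (1, 5, 5)
    activation: bool = True
    residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_length < 1:
            raise ValueError("input_length must be >= 1")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if tuple(self.kernel_sizes) != (1, 5, 5):
            raise ValueError("kernel sizes are fixed at (1, 5, 5)")
        if len(self.channels) != 3 or any(c < 1 for c in self.channels):
            raise ValueError("channels must be three positive integers")
        if self.residual and self.channels[1] != self.channels[2]:
            raise ValueError("residual skip requires channels[1] == channels[2]")


@dataclass
class EmbeddingModel:
    """Encoder parameters plus the geometry they embed into.

    ``params`` holds the trainable arrays (conv and dense weights/biases).
    ``geometry.scale`` is the learned scale s (curvature C = -1/s^2);
    ``normalization_factor`` is the maximum tree distance absorbed during
    training, used to de-normalise reported distances.
    """

    spec: EncoderSpec
    geometry: GeometryMode
    params: dict[str, np.ndarray]
    normalization_factor: float = 1.0
    backbone_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.geometry.dimension != self.spec.embed_dim:
            raise ValueError("geometry.dimension must equal spec.embed_dim")

    def copy(self) -> "EmbeddingModel":
        return EmbeddingModel(
            spec=self.spec,
            geometry=self.geometry,
            params={k: v.copy() for k, v in self.params.items()},
            normalization_factor=self.normalization_factor,
            backbone_ids=list(self.backbone_ids),
        )


def encoder_init(spec: EncoderSpec, mode: str = "loid") -> EmbeddingModel:
    """Deterministically initialise an untrained model from ``spec.seed``.

    Weights are drawn from a fan-in-scaled normal distribution; biases start
    at zero.
    """
    rng = np.random.default_rng(spec.seed)
    c1, c2, c3 = spec.channels
    k1, k2, k3 = spec.kernel_sizes
    L, d = spec.input_length, spec.embed_dim

    def draw(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

    params = {
        "W1": draw((c1, 4, k1), 4 * k1),
        "b1": np.zeros(c1),
        "W2": draw((c2, c1, k2), c1 * k2),
        "b2": np.zeros(c2),
        "W3": draw((c3, c2, k3), c2 * k3),
        "b3": np.zeros(c3),
        "Wd": draw((d, c3 * L), c3 * L),
        "bd": np.zeros(d),
    }
    geometry = GeometryMode(mode=mode, scale=1.0, dimension=d)
    return EmbeddingModel(spec=spec, geometry=geometry, params=params)


# ---------------------------------------------------------------------------
# convolution primitives (im2col)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, L, C*k) patches with zero 'same' padding."""
    if k == 1:
        B, C, L = x.shape
        return x.transpose(0, 2, 1)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)  # (B, C, L, k)
    B, C, L, _ = win.shape
    return win.transpose(0, 2, 1, 3).reshape(B, L, C * k)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-D 'same' convolution; returns output (B, Cout, L) and the im2col cache."""
    cout, cin, k = W.shape
    cols = _im2col(x, k)  # (B, L, cin*k)
    y = cols @ W.reshape(cout, cin * k).T + b  # (B, L, cout)
    return y.transpose(0, 2, 1), cols


def _conv_backward(
    dy: np.ndarray, cols: np.ndarray, W: np.ndarray, input_shape: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a 'same' conv: returns (dx, dW, db)."""
    cout, cin, k = W.shape
    B, C, L = input_shape
    dyt = dy.transpose(0, 2, 1)  # (B, L, cout)
    dW = np.einsum("blo,blp->op", dyt, cols).reshape(cout, cin, k)
    db = dyt.sum(axis=(0, 1))
    dcols = dyt @ W.reshape(cout, cin * k)  # (B, L, cin*k)
    if k == 1:
        dx = dcols.transpose(0, 2, 1)
        return dx, dW, db
    pad = k // 2
    dxp = np.zeros((B, C, L + 2 * pad))
    dwin = dcols.reshape(B, L, C, k)
    for j in range(k):
        dxp[:, :, j : j + L] += dwin[:, :, :, j].transpose(0, 2, 1)
    return dxp[:, :, pad : pad + L], dW, db


def encoder_forward(
    model: EmbeddingModel, onehot: np.ndarray, want_cache: bool = False
):
    """Forward pass: (B, 4, L) or (4, L) one-hot input -> (B, d) tangent vectors.

    Architecture: conv(k=1) -> conv(k=5) -> conv(k=5) with additive skip from
    the second layer's output into the third, then flatten and a dense layer.
    """
    single = onehot.ndim == 2
    x = onehot[None] if single else onehot
    spec, p = model.spec, model.params
    if x.shape[1] != 4 or x.shape[2] != spec.input_length:
        raise ValueError(
            f"input shape {x.shape[1:]} incompatible with (4, {spec.input_length})"
        )
    act = spec.activation

    a1, cols1 = _conv_forward(x, p["W1"], p["b1"])
    z1 = np.maximum(a1, 0.0) if act else a1
    a2, cols2 = _conv_forward(z1, p["W2"], p["b2"])
    z2 = np.maximum(a2, 0.0) if act else a2
    a3, cols3 = _conv_forward(z2, p["W3"], p["b3"])
    if spec.residual:
        a3 = a3 + a2
    z3 = np.maximum(a3, 0.0) if act else a3
    flat = z3.reshape(z3.shape[0], -1)
    v = flat @ p["Wd"].T + p["bd"]

    if not want_cache:
        return v[0] if single else v
    cache = {
        "x": x, "a1": a1, "z1": z1, "a2": a2, "z2": z2, "a3": a3, "z3": z3,
        "flat": flat, "cols1": cols1, "cols2": cols2, "cols3": cols3,
    }
    return (v[0] if single else v), cache


def encoder_backward(
    model: EmbeddingModel, cache: dict, dv: np.ndarray
) -> dict[str, np.ndarray]:
    """Exact parameter gradients given dLoss/dOutput of shape (B, d)."""
    spec, p = model.spec, model.params
    act = spec.activation
    grads: dict[str, np.ndarray] = {}

    grads["Wd"] = dv.T @ cache["flat"]
    grads["bd"] = dv.sum(axis=0)
    dflat = dv @ p["Wd"]
    dz3 = dflat.reshape(cache["z3"].shape)
    da3 = dz3 * (cache["a3"] > 0) if act else dz3
    dz2, grads["W3"], grads["b3"] = _conv_backward(
        da3, cache["cols3"], p["W3"], cache["z2"].shape
    )
    # conv path reaches a2 through z2 = act(a2); the skip (a3 = conv3(z2) + a2)
    # routes da3 to a2 directly, bypassing the activation mask
    da2 = dz2 * (cache["a2"] > 0) if act else dz2
    if spec.residual:
        da2 = da2 + da3
    dz1, grads["W2"], grads["b2"] = _conv_backward(
        da2, cache["cols2"], p["W2"], cache["z1"].shape
    )
    da1 = dz1 * (cache["a1"] > 0) if act else dz1
    _, grads["W1"], grads["b1"] = _conv_backward(
        da1, cache["cols1"], p["W1"], cache["x"].shape
    )
    return grads


def embed_sequences(model: EmbeddingModel, aln: Alignment) -> np.ndarray:
    """Embed every alignment row, in order, into the model's geometry.

    Returns manifold points: (N, d+1) in loid mode, (N, d) otherwise.
    """
    V = encoder_forward(model, aln.one_hot())
    return embed_tangent(V, model.geometry.mode)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: EmbeddingModel, path: str) -> None:
    """Write a versioned, round-trip-stable model archive (.npz)."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "spec": asdict(model.spec),
        "geometry": {
            "mode": model.geometry.mode,
            "scale": model.geometry.scale,
            "dimension": model.geometry.dimension,
        },
        "normalization_factor": model.normalization_factor,
        "backbone_ids": model.backbone_ids,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path: str) -> EmbeddingModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        spec_d = meta["spec"]
        spec_d["channels"] = tuple(spec_d["channels"])
        spec_d["kernel_sizes"] = tuple(spec_d["kernel_sizes"])
        spec = EncoderSpec(**spec_d)
        params = {k: data[k] for k in data.files if k != "meta"}
    return EmbeddingModel(
        spec=spec,
        geometry=GeometryMode(**meta["geometry"]),
        params=params,
        normalization_factor=meta["normalization_factor"],
        backbone_ids=list(meta["backbone_ids"]),
    )
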