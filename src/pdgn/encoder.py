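"""Attention-based spatial feature encoder.

Maps a patch-grid image — a P×P grid of regions, each carrying a
c-channel feature vector — to a fixed-size latent state. The pipeline is

    conv layers (same padding)  →  per-region multi-scale hiddens
    →  additive attention over regions  →  weighted aggregation
    →  linear projection to the latent dimension d_z.

Region attention follows the additive form
``e_j = v^T tanh(W_a h_j + b_a)``, ``alpha = softmax(e)``, and the latent
is the attention-weighted sum of region hiddens. Everything is built on
the package's autodiff tensors, so the encoder is differentiable end to
end; plain numpy inputs work too and give plain numpy outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "PatchImage",
    "ConvLayerParams",
    "AttentionParams",
    "EncoderParams",
    "conv_feature_maps",
    "attention_scores",
    "attend_aggregate",
    "encode",
    "encode_batch",
    "init_encoder",
]

REGION_TYPES = ("leaf", "stem", "background")

_ACTIVATIONS = {
    "identity": lambda x: x,
    "relu": ad.relu,
    "tanh": ad.tanh,
}


@dataclass
class PatchImage:
    """P×P grid of c-channel region feature vectors.

    ``values`` has shape (P, P, c). ``layout``, when present, assigns each
    region a type in {"leaf", "stem", "background"}; the simulator fills it
    in and tests use it as attention ground truth.
    """

    values: np.ndarray
    layout: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PatchImage values must have shape (P, P, c)")
        if self.values.shape[0] != self.values.shape[1] or self.values.shape[0] < 1:
            raise ValueError("patch grid must be square with P >= 1")
        if self.layout is not None:
            self.layout = np.asarray(self.layout)
            if self.layout.shape != self.values.shape[:2]:
                raise ValueError("layout shape must match the patch grid")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


@dataclass
class ConvLayerParams:
    """One convolutional layer: f^l = sigma(W^l * f^{l-1} + b^l)."""

    weight: Tensor | np.ndarray  # (kh, kw, c_in, c_out)
    bias: Tensor | np.ndarray    # (c_out,)
    activation: str = "relu"
    layer_index: int = 0

    def __post_init__(self):
        w = self.weight.data if isinstance(self.weight, Tensor) else np.asarray(self.weight)
        b = self.bias.data if isinstance(self.bias, Tensor) else np.asarray(self.bias)
        if w.ndim != 4:
            raise ValueError("conv weight must have shape (kh, kw, c_in, c_out)")
        if b.shape != (w.shape[3],):
            raise ValueError("conv bias must have shape (c_out,)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class AttentionParams:
    """Additive attention parameters: projection W_a, bias b_a, scorer v."""

    W_a: Tensor | np.ndarray  # (m, h)
    b_a: Tensor | np.ndarray  # (m,)
    v: Tensor | np.ndarray    # (m,)


@dataclass
class EncoderParams:
    """Full encoder parameter bundle."""

    layers: list[ConvLayerParams]
    attention: AttentionParams
    W_out: Tensor | np.ndarray  # (d_z, h)
    b_out: Tensor | np.ndarray  # (d_z,)

    def parameters(self) -> list[Tensor]:
        out = []
        for lyr in self.layers:
            out += [lyr.weight, lyr.bias]
        out += [self.attention.W_a, self.attention.b_a, self.attention.v,
                self.W_out, self.b_out]
        return [p for p in out if isinstance(p, Tensor)]


# ----------------------------------------------------------------------
def _zeros_like_frame(x, shape):
    return Tensor(np.zeros(shape)) if isinstance(x, Tensor) else np.zeros(shape)


def _pad_same(x, ph: int, pw: int):
    """Zero-pad the two spatial axes of (N, P, P, c)."""
    if ph == 0 and pw == 0:
        return x
    n, p, q, c = x.shape
    rows = _zeros_like_frame(x, (n, ph, q, c))
    x = ad.concatenate([rows, x, rows], axis=1)
    cols = _zeros_like_frame(x, (n, p + 2 * ph, pw, c))
    return ad.concatenate([cols, x, cols], axis=2)


def _conv2d_same(x, weight, bias):
    """Stride-1 same-padding 2D convolution on (N, P, P, c_in).

    Implemented as a sum of shifted slices times kernel taps, which keeps
    the whole operation inside the autodiff graph.
    """
    w_arr = weight.data if isinstance(weight, Tensor) else np.asarray(weight)
    kh, kw = w_arr.shape[:2]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("same-padding convolution requires odd kernel sizes")
    p = x.shape[1]
    xp = _pad_same(x, kh // 2, kw // 2)
    out = None
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, di:di + p, dj:dj + p, :]  # (N, P, P, c_in)
            term = patch @ weight[di, dj] if isinstance(weight, Tensor) else patch @ w_arr[di, dj]
            out = term if out is None else out + term
    return out + bias


def conv_feature_maps(image: PatchImage, layers: Sequence[ConvLayerParams]):
    """Apply the conv chain and return every intermediate feature map.

    Returns a list of maps of shape (P, P, c_out_l), one per layer, for
    multi-scale aggregation downstream.
    """
    maps = _conv_feature_maps_batch(image.values[None], layers)
    return [m[0] for m in maps]


def _conv_feature_maps_batch(x, layers: Sequence[ConvLayerParams]):
    if isinstance(x, np.ndarray) and any(isinstance(l.weight, Tensor) for l in layers):
        x = Tensor(x)
    maps = []
    f = x
    for lyr in layers:
        f = _conv2d_same(f, lyr.weight, lyr.bias)
        f = _ACTIVATIONS[lyr.activation](f)
        maps.append(f)
    return maps


# ----------------------------------------------------------------------
def attention_scores(region_hiddens, params: AttentionParams):
    """Additive attention weights over regions.

    ``region_hiddens`` has shape (J, h) (or (N, J, h) batched); returns
    softmax weights of shape (J,) (or (N, J)) that are non-negative and
    sum to one. Softmax is computed max-subtracted for stability.
    """
    h = region_hiddens
    n_regions = h.shape[-2]
    if n_regions == 0:
        raise ValueError("attention requires at least one region")
    if isinstance(h, np.ndarray) and any(
        isinstance(p, Tensor) for p in (params.W_a, params.b_a, params.v)
    ):
        h = Tensor(h)
    W_a, b_a, v = params.W_a, params.b_a, params.v
    if isinstance(h, Tensor):
        W_a, b_a, v = map(ad.as_tensor, (W_a, b_a, v))
        scores = ad.tanh(h @ W_a.transpose() + b_a) @ v
    else:
        W_a = W_a.data if isinstance(W_a, Tensor) else np.asarray(W_a)
        b_a = b_a.data if isinstance(b_a, Tensor) else np.asarray(b_a)
        v = v.data if isinstance(v, Tensor) else np.asarray(v)
        scores = np.tanh(h @ W_a.T + b_a) @ v
    return ad.softmax(scores, axis=-1)


def attend_aggregate(region_hiddens, weights):
    """Weighted sum of region hiddens: z = sum_j alpha_j h_j."""
    h, w = region_hiddens, weights
    if h.shape[-2] != w.shape[-1]:
        raise ValueError(
            f"weights length {w.shape[-1]} does not match region count {h.shape[-2]}"
        )
    if isinstance(h, Tensor) or isinstance(w, Tensor):
        h, w = ad.as_tensor(h), ad.as_tensor(w)
        return (w.reshape(w.shape + (1,)) * h).sum(axis=-2)
    return (np.expand_dims(w, -1) * h).sum(axis=-2)


# ----------------------------------------------------------------------
def _region_hiddens_batch(x, params: EncoderParams):
    """Per-region multi-scale hiddens: every layer's map, already at the
    patch-grid resolution, concatenated along channels, then flattened to
    (N, J, h) with J = P*P."""
    maps = _conv_feature_maps_batch(x, params.layers)
    feats = ad.concatenate(maps, axis=3)
    n, p, q, c = feats.shape
    return feats.reshape(n, p * q, c)


def encode_batch(images, params: EncoderParams, return_attention: bool = False):
    """Encode a batch of images (N, P, P, c) to latents (N, d_z)."""
    x = images.values[None] if isinstance(images, PatchImage) else images
    if isinstance(x, np.ndarray) and params.parameters():
        x = Tensor(x)
    h = _region_hiddens_batch(x, params)
    alpha = attention_scores(h, params.attention)
    z_raw = attend_aggregate(h, alpha)
    W_out, b_out = params.W_out, params.b_out
    if isinstance(z_raw, Tensor):
        z = z_raw @ ad.as_tensor(W_out).transpose() + ad.as_tensor(b_out)
    else:
        W = W_out.data if isinstance(W_out, Tensor) else np.asarray(W_out)
        b = b_out.data if isinstance(b_out, Tensor) else np.asarray(b_out)
        z = z_raw @ W.T + b
    return (z, alpha) if return_attention else z


def encode(image: PatchImage, params: EncoderParams, return_attention: bool = False):
    """Encode a single PatchImage to a latent vector of dimension d_z."""
    out = encode_batch(image.values[None], params, return_attention=return_attention)
    if return_attention:
        z, alpha = out
        return z[0], alpha[0]
    return out[0]


# ----------------------------------------------------------------------
def init_encoder(
    rng: np.random.Generator,
    n_channels: int,
    conv_channels: Sequence[int] = (8, 8),
    kernel_size: int = 3,
    attention_dim: int = 16,
    d_z: int = 16,
    activation: str = "tanh",
) -> EncoderParams:
    """Small random initialization (scaled-Gaussian) of all encoder weights."""
    layers = []
    c_in = n_channels
    for i, c_out in enumerate(conv_channels):
        scale = 1.0 / np.sqrt(kernel_size * kernel_size * c_in)
        layers.append(
            ConvLayerParams(
                weight=Tensor(
                    rng.normal(0.0, scale, size=(kernel_size, kernel_size, c_in, c_out)),
                    requires_grad=True,
                ),
                bias=Tensor(np.zeros(c_out), requires_grad=True),
                activation=activation,
                layer_index=i,
            )
        )
        c_in = c_out
    h_dim = int(np.sum(conv_channels))
    att = AttentionParams(
        W_a=Tensor(rng.normal(0.0, 1.0 / np.sqrt(h_dim), size=(attention_dim, h_dim)),
                   requires_grad=True),
        b_a=Tensor(np.zeros(attention_dim), requires_grad=True),
        v=Tensor(rng.normal(0.0, 1.0 / np.sqrt(attention_dim), size=attention_dim),
                 requires_grad=True),
    )
    return EncoderParams(
        layers=layers,
        attention=att,
        W_out=Tensor(rng.normal(0.0, 1.0 / np.sqrt(h_dim), size=(d_z, h_dim)),
                     requires_grad=True),
        b_out=Tensor(np.zeros(d_z), requires_grad=True),
    )
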