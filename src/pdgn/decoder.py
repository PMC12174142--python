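"""Biologically-constrained decoding of latent states to trait vectors.

The decoder is a small feed-forward map from a latent state (optionally
concatenated with the environment vector) to d named trait outputs.
Alongside it live the decoder-side penalties:

* correlation loss — squared deviation of realized batch Pearson
  correlations from target values on a trait dependency graph;
* hierarchy loss — hinge penalty on ordered trait inequalities (e.g.
  leaf area must not exceed canopy area), in physical units;
* reconstruction loss — mean squared error per observation;
* the composite objective L = L_recon + l1 L_cor + l2 L_struct + l3 L_env.

Traits are predicted in normalized space; callers de-normalize through a
stored per-column affine before hierarchy/bounds penalties, which are
physical-unit statements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .constraints import HierarchyPair, TraitDependencyGraph

__all__ = [
    "DecoderParams",
    "LossWeights",
    "decode",
    "correlation_loss",
    "hierarchy_loss",
    "reconstruction_loss",
    "total_loss",
    "pearson",
    "init_decoder",
]


@dataclass
class LossWeights:
    """Relative weights of the loss components; all must be >= 0."""

    lambda_cor: float = 0.0    # trait correlation
    lambda_struct: float = 0.0  # structural hierarchy
    lambda_env: float = 0.0     # environment-perturbation robustness
    growth: float = 0.0
    smooth: float = 0.0
    consistency: float = 0.0
    classification: float = 0.0

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"loss weight {name} must be non-negative, got {v}")


@dataclass
class DecoderParams:
    """Two-layer feed-forward decoder; input is z or [z; e]."""

    W1: Tensor | np.ndarray  # (h, d_in)
    b1: Tensor | np.ndarray
    W2: Tensor | np.ndarray  # (d_out, h)
    b2: Tensor | np.ndarray
    env_conditioned: bool = True
    activation: str = "tanh"

    def parameters(self) -> list[Tensor]:
        return [p for p in (self.W1, self.b1, self.W2, self.b2)
                if isinstance(p, Tensor)]

    @property
    def d_in(self) -> int:
        w = self.W1.data if isinstance(self.W1, Tensor) else np.asarray(self.W1)
        return w.shape[1]


def init_decoder(rng: np.random.Generator, d_z: int, n_env: int, d_out: int,
                 hidden: int = 32, env_conditioned: bool = True) -> DecoderParams:
    d_in = d_z + (n_env if env_conditioned else 0)
    return DecoderParams(
        W1=Tensor(rng.normal(0, 1 / np.sqrt(d_in), size=(hidden, d_in)), requires_grad=True),
        b1=Tensor(np.zeros(hidden), requires_grad=True),
        W2=Tensor(rng.normal(0, 1 / np.sqrt(hidden), size=(d_out, hidden)), requires_grad=True),
        b2=Tensor(np.zeros(d_out), requires_grad=True),
        env_conditioned=env_conditioned,
    )


def decode(z, e=None, params: DecoderParams | None = None):
    """Map latent (and environment, if the model is conditioned) to traits.

    ``z`` is (d_z,) or (..., d_z); for a conditioned model ``e`` of
    matching leading shape is required and is concatenated onto z. An
    unconditioned model ignores any supplied ``e``.
    """
    if params is None:
        raise ValueError("decoder parameters are required")
    if params.env_conditioned:
        if e is None:
            raise ValueError("this decoder is environment-conditioned; pass e")
        x_in = ad.concatenate([z, e], axis=-1) if _any_t(z, e) else \
            np.concatenate([np.asarray(z, float), np.asarray(e, float)], axis=-1)
    else:
        x_in = z
    tensor_path = isinstance(x_in, Tensor) or params.parameters()
    if tensor_path and not isinstance(x_in, Tensor):
        x_in = Tensor(np.asarray(x_in, dtype=float))
    W1, b1, W2, b2 = (ad.as_tensor(p) if tensor_path else _np(p)
                      for p in (params.W1, params.b1, params.W2, params.b2))
    act = {"tanh": ad.tanh, "relu": ad.relu, "identity": lambda v: v}[params.activation]
    h = act(x_in @ (W1.transpose() if tensor_path else W1.T) + b1)
    return h @ (W2.transpose() if tensor_path else W2.T) + b2


def _any_t(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def _np(p):
    return p.data if isinstance(p, Tensor) else np.asarray(p, dtype=float)


# ----------------------------------------------------------------------
def _resolve(x, columns):
    """Accept a DataFrame or (array-like, columns) and return (x, names)."""
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    if columns is None:
        raise ValueError("column names are required for array inputs")
    return x, list(columns)


def pearson(x, y):
    """Batch Pearson correlation of two columns (autodiff-compatible)."""
    xc = x - x.mean()
    yc = y - y.mean()
    num = (xc * yc).sum()
    den = ad.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return num / den


def correlation_loss(x, graph: TraitDependencyGraph, columns=None,
                     diagnostics: dict | None = None):
    """sum over edges of (Pearson(x_i, x_j) - rho_ij)^2.

    Requires n >= 3 rows. Edges touching a constant column are skipped
    with a warning (Pearson undefined) and recorded in ``diagnostics``
    under "skipped_edges" when a dict is supplied.
    """
    x, names = _resolve(x, columns)
    if x.shape[0] < 3:
        raise ValueError("correlation loss requires at least 3 rows")
    total = 0.0
    for edge in graph:
        i, j = names.index(edge.trait_i), names.index(edge.trait_j)
        xi, xj = x[:, i], x[:, j]
        if _is_constant(xi) or _is_constant(xj):
            warnings.warn(
                f"edge ({edge.trait_i}, {edge.trait_j}) skipped: constant column",
                RuntimeWarning, stacklevel=2,
            )
            if diagnostics is not None:
                diagnostics.setdefault("skipped_edges", []).append(
                    (edge.trait_i, edge.trait_j)
                )
            continue
        total = total + (pearson(xi, xj) - edge.rho) ** 2
    return total


def _is_constant(col) -> bool:
    arr = col.data if isinstance(col, Tensor) else np.asarray(col)
    return float(np.ptp(arr)) == 0.0


def hierarchy_loss(x, pairs: list[HierarchyPair], columns=None):
    """Hinge penalty sum_rows sum_pairs max(0, x_smaller - x_larger).

    Covers both the generic ordered-pair form and the leaf/canopy
    instance through the pair set. Inputs are physical-unit traits.
    """
    x, names = _resolve(x, columns)
    total = 0.0
    for pair in pairs:
        if pair.smaller not in names or pair.larger not in names:
            raise ValueError(
                f"hierarchy pair ({pair.smaller}, {pair.larger}) references "
                f"unknown traits; available: {names}"
            )
        i, j = names.index(pair.smaller), names.index(pair.larger)
        total = total + ad.relu(x[:, i] - x[:, j]).sum()
    return total


def reconstruction_loss(x_hat, x):
    """Mean over rows of the squared error ||x_hat - x||^2."""
    shape_hat = x_hat.shape if hasattr(x_hat, "shape") else np.shape(x_hat)
    shape_x = x.shape if hasattr(x, "shape") else np.shape(x)
    if tuple(shape_hat) != tuple(shape_x):
        raise ValueError(f"shape mismatch: {shape_hat} vs {shape_x}")
    if not isinstance(x_hat, Tensor) and not isinstance(x, Tensor):
        x_hat, x = np.asarray(x_hat, float), np.asarray(x, float)
    diff = (x_hat - x) ** 2
    if len(shape_hat) <= 1:
        return diff.sum()
    n_rows = shape_hat[0]
    return diff.sum() / n_rows


def total_loss(recon, cor, struct, env, weights: LossWeights):
    """Composite objective L = L_recon + l1 L_cor + l2 L_struct + l3 L_env."""
    return (recon + weights.lambda_cor * cor + weights.lambda_struct * struct
            + weights.lambda_env * env)
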