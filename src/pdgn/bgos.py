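"""Biologically-guided optimization losses.

These regularizers push model predictions toward agronomically plausible
configurations:

* hinge hierarchy loss — one-sided penalty when a realized batch Pearson
  correlation exceeds its biologically determined threshold;
* bounds loss — linear penalty for trait predictions outside their
  physiological ranges [l_j, u_j];
* multi-scale loss — weighted sum of squared errors at the organ (local)
  and plant (global) scales;
* consistency loss — squared mismatch between predicted global traits
  and a linear aggregation T of predicted local traits;
* environment-perturbation loss — Monte-Carlo estimate of the decoder's
  output sensitivity to small Gaussian perturbations of the environment
  vector, penalizing unstable predictions.

All losses are non-negative, zero exactly on feasible/target
configurations, and differentiable through the package's autodiff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .constraints import AggregationMap, TraitDependencyGraph
from .decoder import _resolve, pearson
from .simulate import ENV_CHANNELS, EnvironmentSeries

__all__ = [
    "ScaleWeights",
    "PerturbationSpec",
    "hier_threshold_loss",
    "bounds_loss",
    "multiscale_loss",
    "consistency_loss",
    "env_perturbation_loss",
]


@dataclass(frozen=True)
class ScaleWeights:
    """Local/global weighting factors alpha and beta (not both zero)."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("scale weights must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("at least one scale weight must be positive")


@dataclass
class PerturbationSpec:
    """Gaussian perturbation of the environment: per-channel scale sigma
    (channel units), M Monte-Carlo samples, and a seed."""

    sigma: np.ndarray | float = 0.05
    n_samples: int = 8
    seed: int = 0

    def __post_init__(self):
        sig = np.asarray(self.sigma, dtype=float)
        if np.any(sig < 0):
            raise ValueError("perturbation scales must be non-negative")
        if self.n_samples < 1:
            raise ValueError("need at least one perturbation sample")

    @classmethod
    def from_series(cls, env: EnvironmentSeries | np.ndarray, frac: float = 0.05,
                    n_samples: int = 8, seed: int = 0) -> "PerturbationSpec":
        """Scales set to ``frac`` of each channel's observed standard
        deviation — the default operating point during training."""
        data = env.data if isinstance(env, EnvironmentSeries) else np.asarray(env)
        return cls(sigma=frac * data.std(axis=0), n_samples=n_samples, seed=seed)

    def draw(self, n_env: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        sig = np.broadcast_to(np.asarray(self.sigma, dtype=float), (n_env,))
        return rng.normal(0.0, 1.0, size=(self.n_samples, n_env)) * sig


# ----------------------------------------------------------------------
def hier_threshold_loss(x, graph: TraitDependencyGraph, columns=None):
    """One-sided hinge on realized dependencies:
    sum over edges of max(0, Pearson(x_i, x_j) - rho_ij)."""
    x, names = _resolve(x, columns)
    if x.shape[0] < 3:
        raise ValueError("hinge correlation loss requires at least 3 rows")
    total = 0.0
    for edge in graph:
        i, j = names.index(edge.trait_i), names.index(edge.trait_j)
        h_ij = pearson(x[:, i], x[:, j])
        total = total + ad.relu(h_ij - edge.hinge_threshold)
    return total


def bounds_loss(x, bounds: dict[str, tuple[float, float]], columns=None):
    """Linear out-of-range penalty
    sum_rows sum_traits max(0, x - u_j) + max(0, l_j - x).

    Traits without a declared bound contribute nothing."""
    x, names = _resolve(x, columns)
    total = 0.0
    for name, (lo, hi) in bounds.items():
        if lo >= hi:
            raise ValueError(f"bound for {name!r}: lower {lo} >= upper {hi}")
        if name not in names:
            continue
        col = x[:, names.index(name)] if getattr(x, "ndim", 2) > 1 else x
        total = total + ad.relu(col - hi).sum() + ad.relu(lo - col).sum()
    return total


def multiscale_loss(local_pred, local_true, global_pred, global_true,
                    weights: ScaleWeights = ScaleWeights()):
    """alpha * sum ||local_pred - local_true||^2
    + beta * sum ||global_pred - global_true||^2."""
    for a, b, scale in ((local_pred, local_true, "local"),
                        (global_pred, global_true, "global")):
        if tuple(np.shape(a.data if isinstance(a, Tensor) else a)) != \
           tuple(np.shape(b.data if isinstance(b, Tensor) else b)):
            raise ValueError(f"shape mismatch at the {scale} scale")
    loc = ((local_pred - local_true) ** 2).sum()
    glo = ((global_pred - global_true) ** 2).sum()
    return weights.alpha * loc + weights.beta * glo


def consistency_loss(global_pred, local_pred, agg: AggregationMap | np.ndarray | Tensor):
    """Cross-scale consistency sum_rows ||x_global - T x_local||^2."""
    T = agg.matrix if isinstance(agg, AggregationMap) else agg
    mapped = local_pred @ (T.transpose() if isinstance(T, Tensor) else np.asarray(T).T)
    return ((global_pred - mapped) ** 2).sum()


def env_perturbation_loss(decode_fn, z, e, spec: PerturbationSpec):
    """Monte-Carlo robustness penalty
    (1/M) sum_m || phi(z, e + delta_m) - phi(z, e) ||^2,
    with delta_m ~ N(0, diag(sigma^2)) drawn deterministically from the
    spec's seed. ``decode_fn(z, e)`` must accept the environment; an
    unconditioned model is a usage error (the penalty would be trivially
    zero by construction rather than by learned robustness).
    """
    if getattr(decode_fn, "env_conditioned", True) is False:
        raise ValueError(
            "env_perturbation_loss requires an environment-conditioned model"
        )
    e_arr = e.data if isinstance(e, Tensor) else np.asarray(e, dtype=float)
    n_env = e_arr.shape[-1]
    deltas = spec.draw(n_env)
    base = decode_fn(z, e)
    total = 0.0
    for m in range(spec.n_samples):
        pert = decode_fn(z, e + deltas[m])
        total = total + ((pert - base) ** 2).sum()
    return total / spec.n_samples
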