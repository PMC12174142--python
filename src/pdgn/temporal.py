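"""Latent temporal dynamics with growth constraints.

The latent state of a plant evolves Markovianly: the next state depends
only on the current state and the current environment vector,

    z^{t+1} = cell(z^t, e^t) + eta ⊙ (W_e e^t),

where the cell is a single gated recurrent unit (update gate + candidate)
and ``eta`` is a per-latent-dimension environmental-sensitivity
coefficient on a linear projection of the environment.

Two regularizers act on latent trajectories:

* a growth residual that penalizes deviation from the discrete logistic
  (or Gompertz) update z_{t+1} = z_t + r(t) z_t (1 - z_t/K) dt, with an
  optional seasonal growth rate r(t) = r0 (1 + alpha sin(2 pi t/T_season));
* a smoothness term sum_t ||z^{t+1} - z^t||^2 encouraging gradual change.

The growth equation is scalar; it is applied element-wise across latent
dimensions, with either shared (r, K) or per-dimension values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .simulate import EnvironmentSeries, GrowthParams, TimeGrid, seasonal_growth_rate

__all__ = [
    "TemporalParams",
    "transition",
    "rollout",
    "growth_residual_loss",
    "gompertz_rate",
    "smoothness_loss",
    "init_temporal",
]

GOMPERTZ_ZMIN_FRAC = 1e-6  # clamp floor inside gompertz_rate, as a fraction of K


@dataclass
class TemporalParams:
    """Gated-cell weights, environment projection, and sensitivity eta.

    The cell input weights are kept split between the latent part (``_z``)
    and the environment part (``_e``) so environmental influence can be
    ablated exactly by zeroing ``W_ue``, ``W_ce``, ``W_env`` and ``eta``.
    """

    W_uz: Tensor | np.ndarray  # (d, d) update gate, latent part
    W_ue: Tensor | np.ndarray  # (d, k) update gate, environment part
    b_u: Tensor | np.ndarray   # (d,)
    W_cz: Tensor | np.ndarray  # (d, d) candidate, latent part
    W_ce: Tensor | np.ndarray  # (d, k)
    b_c: Tensor | np.ndarray   # (d,)
    W_env: Tensor | np.ndarray  # (d, k) additive environment projection
    eta: Tensor | np.ndarray    # (d,) environmental sensitivity
    growth: GrowthParams | None = None  # prior used by the growth regularizer

    def parameters(self) -> list[Tensor]:
        cand = [self.W_uz, self.W_ue, self.b_u, self.W_cz, self.W_ce, self.b_c,
                self.W_env, self.eta]
        return [p for p in cand if isinstance(p, Tensor)]


def init_temporal(rng: np.random.Generator, d_z: int, n_env: int,
                  growth: GrowthParams | None = None) -> TemporalParams:
    def mat(rows, cols, scale):
        return Tensor(rng.normal(0.0, scale, size=(rows, cols)), requires_grad=True)

    s_z, s_e = 1.0 / np.sqrt(d_z), 1.0 / np.sqrt(n_env)
    return TemporalParams(
        W_uz=mat(d_z, d_z, s_z), W_ue=mat(d_z, n_env, s_e),
        b_u=Tensor(np.zeros(d_z), requires_grad=True),
        W_cz=mat(d_z, d_z, s_z), W_ce=mat(d_z, n_env, s_e),
        b_c=Tensor(np.zeros(d_z), requires_grad=True),
        W_env=mat(d_z, n_env, 0.1 * s_e),
        eta=Tensor(np.zeros(d_z), requires_grad=True),
        growth=growth,
    )


def _maybe_tensorize(x, params: TemporalParams):
    if isinstance(x, np.ndarray) and params.parameters():
        return Tensor(x)
    return x


def transition(z, e, params: TemporalParams):
    """One Markov step: gated cell plus eta-scaled environment projection.

    ``z`` is (d,) or (N, d); ``e`` is (k,) or (N, k) correspondingly.
    """
    z = _maybe_tensorize(np.asarray(z, dtype=float) if not isinstance(z, Tensor) else z, params)
    e = _maybe_tensorize(np.asarray(e, dtype=float) if not isinstance(e, Tensor) else e, params)
    if z.shape[-1] != _dim(params.W_uz, 0):
        raise ValueError("latent dimension mismatch in transition")
    if e.shape[-1] != _dim(params.W_ue, 1):
        raise ValueError("environment dimension mismatch in transition")
    tensor_path = isinstance(z, Tensor) or isinstance(e, Tensor)
    P = {k: _as(v, tensor_path) for k, v in vars(params).items() if k != "growth"}
    u = ad.sigmoid(_affine(z, P["W_uz"]) + _affine(e, P["W_ue"]) + P["b_u"])
    cand = ad.tanh(_affine(z, P["W_cz"]) + _affine(e, P["W_ce"]) + P["b_c"])
    return (1.0 - u) * z + u * cand + P["eta"] * _affine(e, P["W_env"])


def _dim(w, axis):
    return (w.data if isinstance(w, Tensor) else np.asarray(w)).shape[axis]


def _as(w, tensor_path):
    if tensor_path:
        return ad.as_tensor(w)
    return w.data if isinstance(w, Tensor) else np.asarray(w, dtype=float)


def _affine(x, W):
    return x @ (W.transpose() if isinstance(W, Tensor) else W.T)


def rollout(z1, env, params: TemporalParams):
    """Iterate the transition over an environment series.

    Returns a trajectory of shape (T, d) for single inputs or (N, T, d)
    for batched ``z1`` (N, d) with env (T, k) shared or (N, T, k).
    """
    if isinstance(env, EnvironmentSeries):
        e = env.data
    elif isinstance(env, Tensor):
        e = env
    else:
        e = np.asarray(env, dtype=float)
    T = e.shape[-2]
    states = [z1 if isinstance(z1, Tensor) else np.asarray(z1, dtype=float)]
    for t in range(T - 1):
        e_t = e[:, t, :] if e.ndim == 3 else e[t]
        states.append(transition(states[-1], e_t, params))
    batched = states[0].ndim == 2
    axis = 1 if batched else 0
    return ad.stack(states, axis=axis)


# ----------------------------------------------------------------------
def _growth_increment(z, r_t, K, model: str, dt: float):
    if model == "logistic":
        return r_t * z * (1.0 - z / K) * dt
    if model == "gompertz":
        zmin = GOMPERTZ_ZMIN_FRAC * (K if np.isscalar(K) else np.min(np.asarray(K)))
        zc = ad.clip(z, zmin, K if np.isscalar(K) else np.max(np.asarray(K)))
        return r_t * zc * ad.log(K / zc) * dt
    raise ValueError(f"unknown growth model {model!r}")


def growth_residual_loss(traj, growth: GrowthParams | None, grid: TimeGrid,
                         r=None, K=None, model: str | None = None,
                         seasonal: bool | None = None):
    """Squared residual against the discrete growth update.

    sum_t || z^{t+1} - (z^t + r(t) z^t (1 - z^t/K) dt) ||^2 (logistic), or
    the Gompertz increment when the model says so. ``traj`` is (T, d) or
    (N, T, d). (r, K) default to the GrowthParams prior (shared across
    latent dimensions); pass arrays or autodiff tensors of shape (d,) for
    per-dimension or learnable values. Seasonal r(t) is used when the
    growth prior has a non-zero seasonal amplitude (or ``seasonal=True``).
    """
    if r is None or K is None:
        if growth is None:
            raise ValueError("either a GrowthParams prior or explicit (r, K) is required")
        r = growth.r0 if r is None else r
        K = growth.K if K is None else K
    K_arr = K.data if isinstance(K, Tensor) else np.asarray(K)
    if np.any(K_arr <= 0):
        raise ValueError("carrying capacity K must be positive")
    model = model or (growth.model if growth is not None else "logistic")
    use_seasonal = seasonal if seasonal is not None else (
        growth is not None and growth.alpha_season > 0
    )
    traj = _as_trajectory(traj)
    T = traj.shape[-2]
    if T < 2:
        raise ValueError("trajectory must have at least two steps")
    z_now = traj[..., :-1, :]
    z_next = traj[..., 1:, :]
    if use_seasonal:
        r_t = seasonal_growth_rate(grid.times[:-1], growth)[:, None]  # (T-1, 1)
        if isinstance(r, Tensor):  # learnable r0 with a fixed seasonal profile
            r_t = r * Tensor(r_t / growth.r0)
    else:
        r_t = r
    pred = z_now + _growth_increment(z_now, r_t, K, model, grid.dt)
    return ((z_next - pred) ** 2).sum()


def gompertz_rate(z, growth: GrowthParams):
    """Gompertz growth rate r z ln(K/z), with z clamped to
    [1e-6 K, K] to keep the logarithm finite near zero."""
    z_arr = z.data if isinstance(z, Tensor) else np.asarray(z)
    if np.any(z_arr <= 0):
        raise ValueError("gompertz rate requires z > 0")
    K = growth.K
    zc = ad.clip(z, GOMPERTZ_ZMIN_FRAC * K, K)
    return growth.r0 * zc * ad.log(K / zc)


def _as_trajectory(traj):
    """Coerce a trajectory to at least (T, d); scalar series become (T, 1)."""
    if not isinstance(traj, Tensor):
        traj = np.asarray(traj, dtype=float)
    if traj.ndim == 1:
        traj = traj.reshape(traj.shape[0], 1)
    return traj


def smoothness_loss(traj):
    """sum_t || z^{t+1} - z^t ||^2 over a (T, d) or (N, T, d) trajectory."""
    traj = _as_trajectory(traj)
    if traj.shape[-2] < 2:
        raise ValueError("trajectory must have at least two steps")
    diff = traj[..., 1:, :] - traj[..., :-1, :]
    return (diff ** 2).sum()
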