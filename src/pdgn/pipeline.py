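"""End-to-end training, evaluation, growth-parameter recovery and
deterministic trait-to-text rendering.

The full model composes the three stages: patch images are encoded to an
initial latent state, the gated temporal cell rolls the latent forward
under the (standardized) environment series, and the decoder maps each
latent state (plus environment) to normalized local and global traits,
which a stored per-column positive scale converts back to physical
units. A small softmax head on the mean latent classifies the plant's
condition. Training minimizes the composite objective — multi-scale
reconstruction, trait-correlation, hierarchy, bounds-free physical
penalties, growth and smoothness regularizers on the latent trajectory,
cross-scale consistency, environment-perturbation robustness, and the
classification cross-entropy — with Adam, and is bit-reproducible given
the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, recall_score

from . import autodiff as ad
from . import bgos, decoder as dec, encoder as enc, temporal as tmp
from .autodiff import Adam, Tensor
from .bgos import PerturbationSpec, ScaleWeights
from .constraints import ConstraintSet, default_wheat_constraints
from .decoder import LossWeights
from .simulate import (
    CONDITIONS,
    ENV_CHANNELS,
    ENV_UNITS,
    STAGES,
    CohortConfig,
    GrowthParams,
    SyntheticCohort,
    TimeGrid,
    generate_cohort,
)

__all__ = [
    "RunConfig",
    "PDGNModel",
    "MetricsReport",
    "train",
    "evaluate",
    "fit_growth_params",
    "describe",
    "split_cohort",
    "toy_run_config",
    "toy_cohort_config",
]

TRAIT_UNITS = {
    "leaf_area": "cm^2",
    "plant_height": "cm",
    "leaf_count": "count",
    "root_volume": "cm^3",
    "canopy_area": "cm^2",
    "shoot_biomass": "g",
}


# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    """Training-run settings; validated at construction."""

    d_z: int = 8
    conv_channels: tuple[int, ...] = (6, 6)
    attention_dim: int = 8
    decoder_hidden: int = 24
    env_conditioned: bool = True
    weights: LossWeights = field(default_factory=lambda: LossWeights(
        lambda_cor=0.1, lambda_struct=0.01, lambda_env=0.1,
        growth=0.01, smooth=0.01, consistency=0.05, classification=0.1,
    ))
    scale: ScaleWeights = field(default_factory=ScaleWeights)
    latent_growth: GrowthParams = field(
        default_factory=lambda: GrowthParams(r0=0.08, K=1.0)
    )
    perturbation_frac: float = 0.05
    perturbation_samples: int = 4
    lr: float = 3e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    train_frac: float = 0.75  # remainder split equally into val / test

    def __post_init__(self):
        if self.d_z < 1 or self.decoder_hidden < 1 or self.attention_dim < 1:
            raise ValueError("model dimensions must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid optimizer settings")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")

    def to_dict(self) -> dict:
        d = {
            "d_z": self.d_z, "conv_channels": list(self.conv_channels),
            "attention_dim": self.attention_dim,
            "decoder_hidden": self.decoder_hidden,
            "env_conditioned": self.env_conditioned,
            "weights": vars(self.weights).copy(),
            "scale": {"alpha": self.scale.alpha, "beta": self.scale.beta},
            "latent_growth": {"r0": self.latent_growth.r0, "K": self.latent_growth.K},
            "perturbation_frac": self.perturbation_frac,
            "perturbation_samples": self.perturbation_samples,
            "lr": self.lr, "beta1": self.beta1, "beta2": self.beta2,
            "epochs": self.epochs, "batch_size": self.batch_size,
            "seed": self.seed, "train_frac": self.train_frac,
        }
        return d


def toy_cohort_config(n_plants: int = 100, T: int = 20) -> CohortConfig:
    """The default toy study conditions: 100 plants on a 20-step grid."""
    return CohortConfig(n_plants=n_plants, grid=TimeGrid(t0=0.0, T=T, dt=3.0))


def toy_run_config(**overrides) -> RunConfig:
    return replace(RunConfig(), **overrides) if overrides else RunConfig()


# ----------------------------------------------------------------------
@dataclass
class PDGNModel:
    encoder: enc.EncoderParams
    temporal: tmp.TemporalParams
    decoder: dec.DecoderParams
    W_cls: Tensor
    b_cls: Tensor
    local_traits: list[str]
    global_traits: list[str]
    trait_scale: np.ndarray      # positive per-column scale, local then global
    env_mean: np.ndarray
    env_std: np.ndarray
    agg_norm: np.ndarray         # aggregation matrix in normalized trait space
    config: RunConfig

    def parameters(self) -> list[Tensor]:
        return (self.encoder.parameters() + self.temporal.parameters()
                + self.decoder.parameters() + [self.W_cls, self.b_cls])

    @property
    def all_traits(self) -> list[str]:
        return self.local_traits + self.global_traits

    @property
    def n_local(self) -> int:
        return len(self.local_traits)

    def standardize_env(self, env: np.ndarray) -> np.ndarray:
        return (env - self.env_mean) / self.env_std

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    # ------------------------------------------------------------------
    def forward(self, images, env_std, numpy_only: bool = False):
        """images (N,P,P,c), env_std (N,T,k) standardized.

        Returns latents (N,T,d_z), normalized trait predictions
        (N,T,d_all) and class logits (N,4)."""
        x = images
        if numpy_only:
            x = np.asarray(images)
        z1 = enc.encode_batch(x, self.encoder)
        if numpy_only and isinstance(z1, Tensor):
            z1 = z1.data
        traj = tmp.rollout(z1, env_std, self.temporal)
        dec_in_env = env_std
        preds = dec.decode(traj, dec_in_env if self.decoder.env_conditioned else None,
                           self.decoder)
        z_mean = traj.mean(axis=1)
        if isinstance(z_mean, Tensor):
            logits = z_mean @ self.W_cls.transpose() + self.b_cls
        else:
            logits = z_mean @ self.W_cls.data.T + self.b_cls.data
        return traj, preds, logits

    def predict_traits(self, cohort: SyntheticCohort, idx=None):
        """Physical-unit trait predictions (N, T, d_all) for plants idx."""
        images, env_std, _, _, _ = _batch_arrays(cohort, self, idx)
        _, preds, logits = self.forward(images, env_std)
        preds = preds.data if isinstance(preds, Tensor) else preds
        logits = logits.data if isinstance(logits, Tensor) else logits
        phys = preds * self.trait_scale
        cls = np.argmax(logits, axis=1)
        return phys, [CONDITIONS[i] for i in cls]


def _softmax_xent(logits, labels_onehot):
    logp = logits - np.max(logits.data if isinstance(logits, Tensor) else logits,
                           axis=1, keepdims=True)
    lse = ad.log(ad.exp(logp).sum(axis=1, keepdims=True))
    return -((logp - lse) * labels_onehot).sum() / labels_onehot.shape[0]


# ----------------------------------------------------------------------
def split_cohort(cohort: SyntheticCohort, config: RunConfig):
    """Deterministic train/val/test split (train_frac, rest halved)."""
    n = len(cohort.plants)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 901)))
    order = rng.permutation(n)
    n_train = int(round(config.train_frac * n))
    n_val = (n - n_train) // 2
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


def _cohort_scales(cohort: SyntheticCohort):
    """Per-column positive trait scales (95th percentile of the noiseless
    values) and environment mean/std, computed on the whole cohort."""
    loc = np.stack([p.local_true for p in cohort.plants])
    glo = np.stack([p.global_true for p in cohort.plants])
    s_loc = np.percentile(loc.reshape(-1, loc.shape[-1]), 95, axis=0)
    s_glo = np.percentile(glo.reshape(-1, glo.shape[-1]), 95, axis=0)
    scale = np.concatenate([s_loc, s_glo])
    scale = np.maximum(scale, 1e-9)
    env = np.stack([p.env.data for p in cohort.plants]).reshape(-1, len(ENV_CHANNELS))
    std = env.std(axis=0)
    return scale, env.mean(axis=0), np.where(std > 0, std, 1.0)


def _batch_arrays(cohort: SyntheticCohort, model_or_stats, idx=None):
    """Stack images, standardized envs, normalized targets and labels."""
    plants = cohort.plants if idx is None else [cohort.plants[i] for i in idx]
    images = np.stack([p.image_t0.values for p in plants])
    env = np.stack([p.env.data for p in plants])
    if isinstance(model_or_stats, PDGNModel):
        scale = model_or_stats.trait_scale
        env_std = model_or_stats.standardize_env(env)
    else:
        scale, e_mean, e_std = model_or_stats
        env_std = (env - e_mean) / e_std
    d_loc = len(cohort.local_traits)
    loc = np.stack([p.local_obs for p in plants]) / scale[:d_loc]
    glo = np.stack([p.global_obs for p in plants]) / scale[d_loc:]
    labels = np.array([CONDITIONS.index(p.condition) for p in plants])
    return images, env_std, loc, glo, labels


LOG_COLUMNS = ["epoch", "total", "recon_local", "recon_global", "correlation",
               "hierarchy", "growth", "smooth", "consistency", "env_perturbation",
               "classification"]


def train(cohort: SyntheticCohort, config: RunConfig,
          constraints: ConstraintSet | None = None):
    """Joint gradient training of encoder, temporal cell, decoder and the
    condition head. Returns (model, log) with one log row per epoch."""
    constraints = constraints or default_wheat_constraints()
    _check_schema(cohort, constraints)
    scale, env_mean, env_std = _cohort_scales(cohort)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    d_loc, d_glo = len(cohort.local_traits), len(cohort.global_traits)
    n_env = len(ENV_CHANNELS)
    c = cohort.plants[0].image_t0.n_channels

    model = PDGNModel(
        encoder=enc.init_encoder(rng, c, config.conv_channels, 3,
                                 config.attention_dim, config.d_z),
        temporal=tmp.init_temporal(rng, config.d_z, n_env, config.latent_growth),
        decoder=dec.init_decoder(rng, config.d_z, n_env, d_loc + d_glo,
                                 config.decoder_hidden, config.env_conditioned),
        W_cls=Tensor(rng.normal(0, 1 / np.sqrt(config.d_z),
                                size=(len(CONDITIONS), config.d_z)), requires_grad=True),
        b_cls=Tensor(np.zeros(len(CONDITIONS)), requires_grad=True),
        local_traits=list(cohort.local_traits),
        global_traits=list(cohort.global_traits),
        trait_scale=scale, env_mean=env_mean, env_std=env_std,
        agg_norm=_normalized_agg(cohort, scale),
        config=config,
    )
    train_idx, _, _ = split_cohort(cohort, config)
    images, env_s, loc_t, glo_t, labels = _batch_arrays(
        cohort, (scale, env_mean, env_std), train_idx)
    onehot = np.eye(len(CONDITIONS))[labels]
    sample_t = np.array([cohort.plants[i].sample_time_idx for i in train_idx])

    opt = Adam(model.parameters(), lr=config.lr, beta1=config.beta1,
               beta2=config.beta2)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 13)))
    log_rows = []
    w = config.weights
    n = len(train_idx)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        comps_sum = np.zeros(len(LOG_COLUMNS) - 1)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            b = order[start:start + config.batch_size]
            loss, comps = _batch_loss(model, cohort, constraints, config,
                                      images[b], env_s[b], loc_t[b], glo_t[b],
                                      onehot[b], sample_t[b], epoch)
            if not np.isfinite(loss.data):
                bad = [k for k, v in comps.items() if not np.isfinite(v)]
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: first bad component(s) {bad}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            comps_sum += np.array([loss.item()] + [comps[k] for k in LOG_COLUMNS[2:]])
            n_batches += 1
        log_rows.append([epoch] + list(comps_sum / n_batches))
    log = pd.DataFrame(log_rows, columns=LOG_COLUMNS)
    return model, log


def _normalized_agg(cohort: SyntheticCohort, scale: np.ndarray) -> np.ndarray:
    """Aggregation matrix mapped into normalized trait space:
    T'_{gj} = T_{gj} * s_local_j / s_global_g."""
    T = cohort.aggregation.matrix
    d_loc = T.shape[1]
    return T * scale[:d_loc][None, :] / scale[d_loc:][:, None]


def _batch_loss(model, cohort, constraints, config, images, env_s, loc_t, glo_t,
                onehot, sample_t, epoch):
    w = config.weights
    traj, preds, logits = model.forward(images, env_s)
    n_b = images.shape[0]
    d_loc = model.n_local
    loc_p = preds[:, :, :d_loc]
    glo_p = preds[:, :, d_loc:]
    recon_loc = ((loc_p - loc_t) ** 2).sum() / n_b
    recon_glo = ((glo_p - glo_t) ** 2).sum() / n_b
    recon = config.scale.alpha * recon_loc + config.scale.beta * recon_glo

    # physical-unit predictions at each plant's sampled time, for the
    # correlation and hierarchy penalties
    rows = preds[np.arange(n_b), sample_t, :] * model.trait_scale
    cor = dec.correlation_loss(rows, constraints.graph, columns=model.all_traits) \
        if (w.lambda_cor > 0 and n_b >= 3) else 0.0
    hier = dec.hierarchy_loss(rows, constraints.hierarchy_pairs,
                              columns=model.all_traits) / n_b \
        if w.lambda_struct > 0 else 0.0

    growth = tmp.growth_residual_loss(traj, config.latent_growth,
                                      cohort.config.grid) / n_b \
        if w.growth > 0 else 0.0
    smooth = tmp.smoothness_loss(traj) / n_b if w.smooth > 0 else 0.0
    cons = bgos.consistency_loss(glo_p, loc_p, Tensor(model.agg_norm)) / n_b \
        if w.consistency > 0 else 0.0

    if w.lambda_env > 0 and model.decoder.env_conditioned:
        spec = PerturbationSpec(sigma=config.perturbation_frac,
                                n_samples=config.perturbation_samples,
                                seed=config.seed * 1000 + epoch)
        def decode_rows(z, e):
            return dec.decode(z, e, model.decoder)
        # penalize sensitivity along the whole trajectory, per plant
        T = env_s.shape[1]
        z_rows = traj.reshape(n_b * T, traj.shape[-1])
        e_rows = env_s.reshape(n_b * T, env_s.shape[-1])
        env_pert = bgos.env_perturbation_loss(decode_rows, z_rows, e_rows, spec) / n_b
    else:
        env_pert = 0.0

    cls = _softmax_xent(logits, onehot) if w.classification > 0 else 0.0

    loss = (recon + w.lambda_cor * cor + w.lambda_struct * hier
            + w.growth * growth + w.smooth * smooth + w.consistency * cons
            + w.lambda_env * env_pert + w.classification * cls)
    comps = {
        "recon_local": _val(recon_loc), "recon_global": _val(recon_glo),
        "correlation": _val(cor), "hierarchy": _val(hier), "growth": _val(growth),
        "smooth": _val(smooth), "consistency": _val(cons),
        "env_perturbation": _val(env_pert), "classification": _val(cls),
    }
    return loss, comps


def _val(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


def _check_schema(cohort: SyntheticCohort, constraints: ConstraintSet):
    names = set(cohort.local_traits) | set(cohort.global_traits)
    for pair in constraints.hierarchy_pairs:
        if pair.smaller not in names or pair.larger not in names:
            raise ValueError(
                f"constraint pair ({pair.smaller}, {pair.larger}) not in cohort traits"
            )
    for e in constraints.graph:
        if e.trait_i not in names or e.trait_j not in names:
            raise ValueError(f"constraint edge ({e.trait_i}, {e.trait_j}) not in cohort")


# ----------------------------------------------------------------------
@dataclass
class MetricsReport:
    rmse: dict[str, float]
    hierarchy_violation_rate: float
    bounds_violation_rate: float
    realized_correlations: dict[str, float]
    target_correlations: dict[str, float]
    condition_accuracy: float
    condition_recall: float
    condition_f1: float
    n_plants: int

    def to_dict(self) -> dict:
        return {
            "rmse": {k: float(v) for k, v in self.rmse.items()},
            "hierarchy_violation_rate": float(self.hierarchy_violation_rate),
            "bounds_violation_rate": float(self.bounds_violation_rate),
            "realized_correlations": {k: float(v) for k, v in self.realized_correlations.items()},
            "target_correlations": {k: float(v) for k, v in self.target_correlations.items()},
            "condition_accuracy": float(self.condition_accuracy),
            "condition_recall": float(self.condition_recall),
            "condition_f1": float(self.condition_f1),
            "n_plants": int(self.n_plants),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def evaluate(model: PDGNModel, cohort: SyntheticCohort, idx=None,
             constraints: ConstraintSet | None = None,
             violation_tol: float = 1e-9) -> MetricsReport:
    """Held-out metrics: per-trait RMSE against the noiseless truth,
    hierarchy/bounds violation rates over all plant-time rows, realized
    vs target correlations at the sampled times, and condition
    classification metrics (macro-averaged)."""
    constraints = constraints or default_wheat_constraints()
    _check_schema(cohort, constraints)
    if idx is None:
        idx = np.arange(len(cohort.plants))
    idx = np.asarray(idx)
    phys, cond_pred = model.predict_traits(cohort, idx)
    plants = [cohort.plants[i] for i in idx]
    truth = np.concatenate(
        [np.stack([p.local_true for p in plants]),
         np.stack([p.global_true for p in plants])], axis=2)
    names = model.all_traits
    rmse = {
        name: float(np.sqrt(np.mean((phys[:, :, k] - truth[:, :, k]) ** 2)))
        for k, name in enumerate(names)
    }
    flat = phys.reshape(-1, phys.shape[-1])
    viol = 0
    for pair in constraints.hierarchy_pairs:
        i, j = names.index(pair.smaller), names.index(pair.larger)
        viol += int(np.sum(flat[:, i] - flat[:, j] > violation_tol))
    n_pair_rows = max(flat.shape[0] * max(len(constraints.hierarchy_pairs), 1), 1)
    hier_rate = viol / n_pair_rows

    b_viol, b_total = 0, 0
    for name, (lo, hi) in constraints.bounds.items():
        if name not in names:
            continue
        col = flat[:, names.index(name)]
        b_viol += int(np.sum((col < lo - violation_tol) | (col > hi + violation_tol)))
        b_total += col.size
    bounds_rate = b_viol / max(b_total, 1)

    sample_t = np.array([p.sample_time_idx for p in plants])
    rows = phys[np.arange(len(plants)), sample_t, :]
    realized, target = {}, {}
    for e in constraints.graph:
        i, j = names.index(e.trait_i), names.index(e.trait_j)
        key = f"{e.trait_i}~{e.trait_j}"
        xi, xj = rows[:, i], rows[:, j]
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            realized[key] = float("nan")
        else:
            realized[key] = float(np.corrcoef(xi, xj)[0, 1])
        target[key] = e.rho

    y_true = [p.condition for p in plants]
    acc = accuracy_score(y_true, cond_pred)
    rec = recall_score(y_true, cond_pred, labels=list(CONDITIONS),
                       average="macro", zero_division=0)
    f1 = f1_score(y_true, cond_pred, labels=list(CONDITIONS),
                  average="macro", zero_division=0)
    return MetricsReport(
        rmse=rmse, hierarchy_violation_rate=hier_rate,
        bounds_violation_rate=bounds_rate, realized_correlations=realized,
        target_correlations=target, condition_accuracy=float(acc),
        condition_recall=float(rec), condition_f1=float(f1),
        n_plants=len(plants),
    )


# ----------------------------------------------------------------------
def _euler_logistic(z0: float, r: float, K: float, T: int, dt: float) -> np.ndarray:
    z = np.empty(T)
    z[0] = z0
    for j in range(T - 1):
        z[j + 1] = z[j] + r * z[j] * (1 - z[j] / K) * dt
    return z


def fit_growth_params(trajectory: np.ndarray, grid: TimeGrid, refine: bool = True):
    """Recover (r, K) of a logistic trajectory.

    Stage 1: on the explicit-Euler update, y_t = (z_{t+1} - z_t)/(z_t dt)
    is exactly linear in z_t (intercept r, slope -r/K). The regression is
    solved in its generalized-least-squares form — increments against
    (z_t, z_t^2) — which is the same line reweighted by z_t^2 and is
    exact on noiseless Euler data while far less noise-sensitive.

    Stage 2 (``refine``): nonlinear least squares of the observed path
    against the Euler recursion itself, jointly over (r, K, z0), started
    at the stage-1 estimate. On noiseless data stage 1 is already the
    exact optimum, so refinement leaves it untouched.

    Returns (r_hat, K_hat, diagnostics) with the stage-1 R^2 and an
    identifiability flag.
    """
    z = np.asarray(trajectory, dtype=float)
    if z.ndim != 1 or z.size < 3:
        raise ValueError("need a 1-D trajectory of length >= 3")
    if np.any(z <= 0):
        raise ValueError("trajectory values must be positive")
    x = z[:-1]
    if np.ptp(z) < 1e-12 * max(abs(z[0]), 1.0):
        raise ValueError("trajectory is constant (or pinned at K); "
                         "growth parameters are not identifiable")
    dz = z[1:] - x
    X = np.column_stack([x, x ** 2])
    (a, b), *_ = np.linalg.lstsq(X, dz, rcond=None)
    r_hat = float(a / grid.dt)
    ident = b < 0 and r_hat > 0
    K_hat = float(-a / b) if b != 0 else float("inf")
    resid = dz - X @ np.array([a, b])
    ss_tot = float(np.sum((dz - dz.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

    if refine and ident and np.isfinite(K_hat):
        from scipy.optimize import least_squares

        z_max = float(z.max())

        def residual(p):
            return _euler_logistic(p[2], p[0], p[1], z.size, grid.dt) - z

        x0 = np.array([
            min(max(r_hat, 1e-4), 5.0),
            min(max(K_hat, z_max * 0.5), z_max * 10.0),
            min(max(z[0], 1e-6), z_max),
        ])
        sol = least_squares(residual, x0=x0,
                            bounds=([1e-4, 1e-6, 1e-9],
                                    [5.0, z_max * 10.0, z_max * 2.0]))
        if sol.success:
            r_hat, K_hat = float(sol.x[0]), float(sol.x[1])
    return r_hat, K_hat, {"r_squared": r2, "identifiable": bool(ident)}


# ----------------------------------------------------------------------
def save_model(model: PDGNModel, outdir: str | Path):
    """Write a JSON manifest plus an .npz weight blob."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = model.parameters()
    manifest = {
        "config": model.config.to_dict(),
        "local_traits": model.local_traits,
        "global_traits": model.global_traits,
        "trait_scale": model.trait_scale.tolist(),
        "env_mean": model.env_mean.tolist(),
        "env_std": model.env_std.tolist(),
        "agg_norm": model.agg_norm.tolist(),
        "n_params": len(params),
    }
    (outdir / "model_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    np.savez(outdir / "model_weights.npz",
             **{f"p{i:03d}": p.data for i, p in enumerate(params)})


def load_weights_into(model: PDGNModel, outdir: str | Path):
    """Load an .npz weight blob back into a freshly initialized model of
    the same architecture (same parameter order)."""
    blob = np.load(Path(outdir) / "model_weights.npz")
    for i, p in enumerate(model.parameters()):
        p.data = blob[f"p{i:03d}"]
    return model


# ----------------------------------------------------------------------
_NUM_FMT = "{:.2f}"  # every reported number round-trips via this format


def describe(traits: dict[str, float], violations=None, stage: str = "seedling",
             condition: str = "healthy", env_summary: dict[str, float] | None = None) -> str:
    """Deterministic template rendering of one plant observation.

    Sentences, in order: stage/condition, one per trait (with units), one
    per active constraint violation (naming both traits with the word
    "exceeds"), and one summarizing the environment.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    lines = [f"The plant is at the {stage.replace('_', ' ')} stage and appears {condition}."]
    for name, value in traits.items():
        unit = TRAIT_UNITS.get(name, "")
        pretty = name.replace("_", " ").capitalize()
        num = _NUM_FMT.format(float(value))
        lines.append(f"{pretty} is {num} {unit}.".replace(" .", "."))
    for v in violations or []:
        small, large = v["smaller"], v["larger"]
        s_val = _NUM_FMT.format(float(v["smaller_value"]))
        l_val = _NUM_FMT.format(float(v["larger_value"]))
        lines.append(
            f"Constraint violation: {small.replace('_', ' ')} ({s_val} "
            f"{TRAIT_UNITS.get(small, '')}) exceeds {large.replace('_', ' ')} "
            f"({l_val} {TRAIT_UNITS.get(large, '')})."
        )
    if env_summary:
        parts = []
        for ch in ENV_CHANNELS:
            if ch in env_summary:
                parts.append(
                    f"{ch.replace('_', ' ')} {_NUM_FMT.format(float(env_summary[ch]))} "
                    f"{ENV_UNITS[ch]}"
                )
        if parts:
            lines.append("Environment: mean " + ", ".join(parts) + ".")
    return "\n".join(lines)
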