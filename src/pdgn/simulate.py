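"""Synthetic plant-cohort simulator with known ground truth.

Generates cohorts whose statistical structure matches the modeling
assumptions of the rest of the package, so every loss and estimator can
be validated against a known optimum:

* per-genotype local trait trajectories follow explicit-Euler logistic or
  Gompertz growth with an optional seasonal modulation of the growth rate
  r(t) = r0 (1 + alpha sin(2 pi t / T_season));
* global traits are an exact linear aggregation of local traits, so
  hierarchy and cross-scale consistency hold exactly before noise;
* environments are seasonal sinusoids plus Gaussian noise in physical
  units (temperature degC, relative humidity %, soil moisture g/cm^3,
  PAR umol m^-2 s^-1), clipped to physical ranges;
* condition labels (healthy / stressed / diseased / damaged) derive from
  accumulated environmental stress, stage labels (seedling / tillering /
  heading / grain_filling) from the fraction of carrying capacity reached
  — 4 x 4 = 16 stage-by-condition classes;
* patch-grid pseudo-images carry an affine encoding of normalized traits
  in their leaf regions, standing in for real multi-spectral imagery.

Noise is observation-only: it never feeds back into the dynamics, which
keeps the closed-form growth solutions exact oracles for the noiseless
paths. All randomness flows from one integer seed through a documented
``numpy.random.SeedSequence`` spawn hierarchy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import AggregationMap, ConstraintSet, default_wheat_constraints
from .encoder import PatchImage

__all__ = [
    "TimeGrid",
    "GrowthParams",
    "GenotypeProfile",
    "EnvironmentSeries",
    "EnvSeasonality",
    "NoiseSpec",
    "CohortConfig",
    "PlantRecord",
    "SyntheticCohort",
    "seasonal_growth_rate",
    "simulate_logistic_trajectory",
    "simulate_gompertz_trajectory",
    "generate_environment_series",
    "generate_cohort",
    "render_patch_image",
    "make_layout",
    "write_patch_csv",
    "read_patch_csv",
    "write_patch_png",
    "read_patch_png",
]

ENV_CHANNELS = ("temperature", "humidity", "soil_moisture", "par")
ENV_UNITS = {
    "temperature": "degC",
    "humidity": "%",
    "soil_moisture": "g/cm^3",
    "par": "umol m^-2 s^-1",
}
STAGES = ("seedling", "tillering", "heading", "grain_filling")
CONDITIONS = ("healthy", "stressed", "diseased", "damaged")
# fractions of carrying capacity splitting the four stages
STAGE_THRESHOLDS = (0.15, 0.45, 0.8)

# documented affine map used by render_patch_image on leaf regions:
# channel j of a leaf patch encodes normalized trait j (cycled) as
# LEAF_OFFSET + LEAF_GAIN * x_norm
LEAF_OFFSET = 0.2
LEAF_GAIN = 0.6
STEM_VALUE = 0.5
BACKGROUND_LEVEL = 0.05


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid: points t0 + j*dt (days) for j in [0, T)."""

    t0: float = 0.0
    T: int = 40
    dt: float = 3.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 2:
            raise ValueError("grid needs at least two steps")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.T)


@dataclass(frozen=True)
class GrowthParams:
    """Growth-curve parameters: rate r0 (day^-1), carrying capacity K
    (trait units), seasonal amplitude alpha and period T_season (days)."""

    r0: float
    K: float
    alpha_season: float = 0.0
    T_season: float = 365.0
    model: str = "logistic"

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("growth rate r0 must be positive")
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if not 0.0 <= self.alpha_season < 1.0:
            raise ValueError("seasonal amplitude must lie in [0, 1)")
        if self.T_season <= 0:
            raise ValueError("seasonal period must be positive")
        if self.model not in ("logistic", "gompertz"):
            raise ValueError(f"unknown growth model {self.model!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise standard deviations and the base seed."""

    obs_sigma: float = 0.0
    env_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.obs_sigma < 0 or self.env_sigma < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class GenotypeProfile:
    """A genotype: one GrowthParams per trait plus a stress susceptibility
    coefficient (fractional reduction of r under stress, dimensionless)."""

    genotype_id: int
    growth: dict[str, GrowthParams]
    stress_susceptibility: float = 0.3
    z0_fraction: float = 0.03  # initial trait value as a fraction of K


@dataclass
class EnvSeasonality:
    """Channel means, seasonal amplitudes and period for the environment."""

    means: dict[str, float] = field(
        default_factory=lambda: {
            "temperature": 22.0, "humidity": 65.0, "soil_moisture": 0.30, "par": 900.0,
        }
    )
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "temperature": 6.0, "humidity": 12.0, "soil_moisture": 0.08, "par": 350.0,
        }
    )
    period: float = 365.0


@dataclass
class EnvironmentSeries:
    """Time-indexed environment vectors; columns follow ENV_CHANNELS order."""

    data: np.ndarray  # (T, 4)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != len(ENV_CHANNELS):
            raise ValueError(f"environment data must be (T, {len(ENV_CHANNELS)})")

    def __len__(self):
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, ENV_CHANNELS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=list(ENV_CHANNELS))


# ----------------------------------------------------------------------
def seasonal_growth_rate(t, params: GrowthParams):
    """Seasonally modulated growth rate r(t) = r0 (1 + alpha sin(2 pi t / T_season))."""
    return params.r0 * (1.0 + params.alpha_season * np.sin(2.0 * np.pi * np.asarray(t) / params.T_season))


def _euler_trajectory(z0, params, grid, noise, rate_term):
    if not 0 < z0 <= params.K:
        raise ValueError(f"initial value z0={z0} must lie in (0, K={params.K}]")
    z = np.empty(grid.T)
    z[0] = z0
    times = grid.times
    for j in range(grid.T - 1):
        r_t = seasonal_growth_rate(times[j], params)
        z[j + 1] = z[j] + rate_term(r_t, z[j]) * grid.dt
    if noise is not None and noise.obs_sigma > 0:
        rng = np.random.default_rng(noise.seed)
        return z + rng.normal(0.0, noise.obs_sigma, size=z.shape)
    return z


def simulate_logistic_trajectory(z0, params: GrowthParams, grid: TimeGrid,
                                 noise: NoiseSpec | None = None) -> np.ndarray:
    """Explicit-Euler logistic growth z' = r(t) z (1 - z/K), observation
    noise (if any) added after integration."""
    return _euler_trajectory(z0, params, grid, noise,
                             lambda r, z: r * z * (1.0 - z / params.K))


def simulate_gompertz_trajectory(z0, params: GrowthParams, grid: TimeGrid,
                                 noise: NoiseSpec | None = None) -> np.ndarray:
    """Explicit-Euler Gompertz growth z' = r(t) z ln(K/z)."""
    return _euler_trajectory(z0, params, grid, noise,
                             lambda r, z: r * z * np.log(params.K / z))


def generate_environment_series(grid: TimeGrid, noise: NoiseSpec,
                                season: EnvSeasonality | None = None,
                                rng: np.random.Generator | None = None) -> EnvironmentSeries:
    """Seasonal sinusoid + Gaussian noise per channel, clipped to physical
    ranges (humidity in [0, 100], soil moisture and PAR non-negative)."""
    season = season or EnvSeasonality()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    t = grid.times
    cols = []
    for ch in ENV_CHANNELS:
        base = season.means[ch] + season.amplitudes[ch] * np.sin(2.0 * np.pi * t / season.period)
        if noise.env_sigma > 0:
            # env_sigma scales each channel's seasonal amplitude
            base = base + rng.normal(0.0, noise.env_sigma * max(season.amplitudes[ch], 1e-12), size=t.shape)
        cols.append(base)
    data = np.stack(cols, axis=1)
    hum = ENV_CHANNELS.index("humidity")
    data[:, hum] = np.clip(data[:, hum], 0.0, 100.0)
    for ch in ("soil_moisture", "par"):
        k = ENV_CHANNELS.index(ch)
        data[:, k] = np.maximum(data[:, k], 0.0)
    return EnvironmentSeries(data)


# ----------------------------------------------------------------------
def make_layout(grid_size: int, rng: np.random.Generator,
                leaf_frac: float = 0.5, stem_frac: float = 0.15) -> np.ndarray:
    """Random region-type layout for a patch grid."""
    types = rng.choice(
        REGION_TYPES_ARR,
        size=(grid_size, grid_size),
        p=[leaf_frac, stem_frac, 1.0 - leaf_frac - stem_frac],
    )
    return types


REGION_TYPES_ARR = np.array(["leaf", "stem", "background"], dtype=object)


def render_patch_image(local_traits_norm: np.ndarray, layout: np.ndarray,
                       noise_sigma: float = 0.0,
                       rng: np.random.Generator | int | None = None,
                       n_channels: int | None = None) -> PatchImage:
    """Render a pseudo-image from normalized local traits.

    Leaf regions encode trait j (cycled over channels) through the affine
    map LEAF_OFFSET + LEAF_GAIN * x_norm_j; stem regions carry a constant;
    background regions carry pure noise around BACKGROUND_LEVEL.
    """
    x = np.asarray(local_traits_norm, dtype=np.float64)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    c = n_channels or max(len(x), 3)
    p = layout.shape[0]
    img = np.zeros((p, p, c))
    leaf_signal = np.array([LEAF_OFFSET + LEAF_GAIN * x[j % len(x)] for j in range(c)])
    img[layout == "leaf"] = leaf_signal
    img[layout == "stem"] = STEM_VALUE
    img[layout == "background"] = BACKGROUND_LEVEL
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return PatchImage(values=img, layout=layout)


# ----------------------------------------------------------------------
@dataclass
class CohortConfig:
    """All knobs of the cohort generator, with study-condition defaults."""

    n_plants: int = 200
    grid: TimeGrid = field(default_factory=TimeGrid)
    local_traits: tuple[str, ...] = ("leaf_area", "plant_height", "leaf_count", "root_volume")
    global_traits: tuple[str, ...] = ("canopy_area", "shoot_biomass")
    # per-trait base growth parameters (r0 day^-1, K in trait units)
    base_growth: dict[str, GrowthParams] = field(
        default_factory=lambda: {
            "leaf_area": GrowthParams(0.10, 120.0),
            "plant_height": GrowthParams(0.08, 90.0),
            "leaf_count": GrowthParams(0.09, 12.0, model="gompertz"),
            "root_volume": GrowthParams(0.07, 35.0),
        }
    )
    aggregation: np.ndarray | None = None  # (d_global, d_local); default set below
    n_genotypes: int = 8
    genotype_r_jitter: float = 0.15   # lognormal sigma of per-genotype r multiplier
    genotype_k_jitter: float = 0.10
    stress_threshold_pct: float = 60.0  # percentile of the stress score
    p_disease_given_stress: float = 0.3
    p_damage_given_stress: float = 0.2
    damage_drop: float = 0.7          # damaged plants lose this fraction retained
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(obs_sigma=0.0, env_sigma=0.5))
    obs_sigma_frac: float = 0.02      # per-trait obs noise as a fraction of K
    patch_grid_size: int = 6
    patch_channels: int = 4
    patch_noise_sigma: float = 0.02
    seasonal: bool = False
    env_season: EnvSeasonality = field(default_factory=EnvSeasonality)

    def aggregation_map(self) -> AggregationMap:
        mat = self.aggregation
        if mat is None:
            mat = np.array(
                [
                    [1.8, 0.0, 0.0, 0.0],     # canopy_area = 1.8 * leaf_area
                    [0.02, 0.05, 0.10, 0.08], # shoot_biomass, g
                ]
            )
        return AggregationMap(matrix=mat, local_names=list(self.local_traits),
                              global_names=list(self.global_traits))

    def validate(self, constraints: ConstraintSet | None = None):
        if self.n_plants < 1:
            raise ValueError("n_plants must be positive")
        for name in self.local_traits:
            if name not in self.base_growth:
                raise ValueError(f"no growth parameters for trait {name!r}")
        if constraints is not None:
            for name, gp in self.base_growth.items():
                lo, hi = constraints.bounds.get(name, (-np.inf, np.inf))
                if not lo < gp.K <= hi:
                    raise ValueError(
                        f"carrying capacity K={gp.K} for {name!r} outside bounds [{lo}, {hi}]"
                    )


@dataclass
class PlantRecord:
    plant_id: int
    genotype: GenotypeProfile
    env: EnvironmentSeries
    local_true: np.ndarray   # (T, d_local), noiseless
    local_obs: np.ndarray    # (T, d_local), with observation noise
    global_true: np.ndarray  # (T, d_global)
    global_obs: np.ndarray
    stage: str
    condition: str
    sample_time_idx: int
    image: PatchImage       # rendered at the sampled observation time
    image_t0: PatchImage    # rendered at the first grid point (encoder input)
    stress_score: float


@dataclass
class SyntheticCohort:
    plants: list[PlantRecord]
    config: CohortConfig
    aggregation: AggregationMap
    genotype_pool: list[GenotypeProfile]
    seed: int

    @property
    def local_traits(self):
        return list(self.config.local_traits)

    @property
    def global_traits(self):
        return list(self.config.global_traits)

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant_id": [p.plant_id for p in self.plants],
                "stage": [p.stage for p in self.plants],
                "condition": [p.condition for p in self.plants],
                "class_label": [f"{p.stage}/{p.condition}" for p in self.plants],
            }
        )

    def to_tidy_frame(self, observed: bool = True) -> pd.DataFrame:
        """One row per plant x time x variable (traits and environment)."""
        rows = []
        times = self.config.grid.times
        for p in self.plants:
            loc = p.local_obs if observed else p.local_true
            glo = p.global_obs if observed else p.global_true
            for j, t in enumerate(times):
                for k, name in enumerate(self.local_traits):
                    rows.append((p.plant_id, t, name, loc[j, k]))
                for k, name in enumerate(self.global_traits):
                    rows.append((p.plant_id, t, name, glo[j, k]))
                for k, name in enumerate(ENV_CHANNELS):
                    rows.append((p.plant_id, t, name, p.env.data[j, k]))
        return pd.DataFrame(rows, columns=["plant_id", "time", "variable", "value"])

    def write(self, outdir: str | Path, images: str = "csv"):
        """Write traits/environment CSV, labels CSV, manifest + ground-truth
        JSON, and per-plant pseudo-images (CSV matrices or uint16 PNG)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_tidy_frame().to_csv(outdir / "trajectories.csv", index=False,
                                    float_format="%.10g")
        self.labels().to_csv(outdir / "labels.csv", index=False)
        manifest = {
            "seed": self.seed,
            "n_plants": len(self.plants),
            "local_traits": self.local_traits,
            "global_traits": self.global_traits,
            "grid": {"t0": self.config.grid.t0, "T": self.config.grid.T,
                     "dt": self.config.grid.dt},
            "aggregation_matrix": self.aggregation.matrix.tolist(),
            "genotypes": [
                {
                    "genotype_id": g.genotype_id,
                    "stress_susceptibility": g.stress_susceptibility,
                    "z0_fraction": g.z0_fraction,
                    "growth": {k: asdict(v) for k, v in g.growth.items()},
                }
                for g in self.genotype_pool
            ],
            "plant_genotypes": {p.plant_id: p.genotype.genotype_id for p in self.plants},
            "sample_time_idx": {p.plant_id: p.sample_time_idx for p in self.plants},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for p in self.plants:
            if images == "png":
                write_patch_png(p.image, img_dir / f"plant_{p.plant_id:04d}.png")
            else:
                write_patch_csv(p.image, img_dir / f"plant_{p.plant_id:04d}.csv")


# ----------------------------------------------------------------------
def _stage_from_fraction(frac: float) -> str:
    if frac < STAGE_THRESHOLDS[0]:
        return STAGES[0]
    if frac < STAGE_THRESHOLDS[1]:
        return STAGES[1]
    if frac < STAGE_THRESHOLDS[2]:
        return STAGES[2]
    return STAGES[3]


def _stress_score(env: EnvironmentSeries, season: EnvSeasonality) -> float:
    """Accumulated environmental stress: mean absolute deviation of
    temperature and soil moisture from their seasonal means, z-scored by
    the seasonal amplitude, summed over the two channels."""
    score = 0.0
    for ch in ("temperature", "soil_moisture"):
        dev = env.channel(ch) - season.means[ch]
        score += float(np.mean(np.abs(dev))) / max(season.amplitudes[ch], 1e-12)
    return score


def _make_genotype_pool(config: CohortConfig, rng: np.random.Generator):
    pool = []
    for gid in range(config.n_genotypes):
        growth = {}
        for name in config.local_traits:
            base = config.base_growth[name]
            r_mult = float(np.exp(rng.normal(0.0, config.genotype_r_jitter)))
            k_mult = float(np.exp(rng.normal(0.0, config.genotype_k_jitter)))
            growth[name] = GrowthParams(
                r0=base.r0 * r_mult,
                K=base.K * k_mult,
                alpha_season=base.alpha_season if config.seasonal else 0.0,
                T_season=base.T_season,
                model=base.model,
            )
        pool.append(
            GenotypeProfile(
                genotype_id=gid,
                growth=growth,
                stress_susceptibility=float(rng.uniform(0.2, 0.5)),
                z0_fraction=float(rng.uniform(0.02, 0.05)),
            )
        )
    return pool


def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    constraints: ConstraintSet | None = None) -> SyntheticCohort:
    """Generate a full cohort; deterministic given (config, seed)."""
    config = config or CohortConfig()
    config.validate(constraints if constraints is not None else default_wheat_constraints())
    agg = config.aggregation_map()
    root = np.random.SeedSequence(seed)
    ss_pool, ss_env, ss_assign, ss_obs, ss_img = root.spawn(5)
    rng_pool = np.random.default_rng(ss_pool)
    rng_assign = np.random.default_rng(ss_assign)

    pool = _make_genotype_pool(config, rng_pool)
    grid = config.grid
    n = config.n_plants

    # environments and stress scores
    env_rngs = [np.random.default_rng(s) for s in ss_env.spawn(n)]
    envs = [
        generate_environment_series(grid, config.noise, config.env_season, rng=r)
        for r in env_rngs
    ]
    scores = np.array([_stress_score(e, config.env_season) for e in envs])

    # condition assignment: stressed above the percentile threshold; a
    # seeded fraction of stressed plants progress to diseased or damaged
    threshold = np.percentile(scores, config.stress_threshold_pct)
    conditions = np.array(["healthy"] * n, dtype=object)
    stressed_idx = np.where(scores > threshold)[0]
    u = rng_assign.uniform(size=n)
    for i in stressed_idx:
        if u[i] < config.p_disease_given_stress:
            conditions[i] = "diseased"
        elif u[i] < config.p_disease_given_stress + config.p_damage_given_stress:
            conditions[i] = "damaged"
        else:
            conditions[i] = "stressed"

    genotype_ids = rng_assign.integers(0, config.n_genotypes, size=n)
    sample_idx = rng_assign.integers(0, grid.T, size=n)
    damage_times = rng_assign.integers(grid.T // 2, grid.T, size=n)

    obs_rngs = [np.random.default_rng(s) for s in ss_obs.spawn(n)]
    img_rngs = [np.random.default_rng(s) for s in ss_img.spawn(n)]
    layout_rng = np.random.default_rng(root.spawn(1)[0])
    layout = make_layout(config.patch_grid_size, layout_rng)

    d_loc = len(config.local_traits)
    plants = []
    for i in range(n):
        geno = pool[genotype_ids[i]]
        cond = conditions[i]
        local = np.empty((grid.T, d_loc))
        for k, name in enumerate(config.local_traits):
            gp = geno.growth[name]
            r_eff = gp.r0
            k_eff = gp.K
            if cond in ("stressed", "damaged"):
                r_eff = gp.r0 * (1.0 - geno.stress_susceptibility)
            elif cond == "diseased":
                r_eff = gp.r0 * (1.0 - 0.5 * geno.stress_susceptibility)
                k_eff = gp.K * 0.85
            eff = GrowthParams(r_eff, k_eff, gp.alpha_season, gp.T_season, gp.model)
            z0 = geno.z0_fraction * k_eff
            sim = (simulate_gompertz_trajectory if gp.model == "gompertz"
                   else simulate_logistic_trajectory)
            local[:, k] = sim(z0, eff, grid, noise=None)
        if cond == "damaged":
            local[damage_times[i]:, :] *= config.damage_drop
        glob = agg.apply(local)

        sigma = config.obs_sigma_frac * np.array(
            [geno.growth[nm].K for nm in config.local_traits]
        )
        local_obs = local + obs_rngs[i].normal(0.0, 1.0, size=local.shape) * sigma
        glob_sigma = np.abs(agg.matrix) @ sigma
        global_obs = glob + obs_rngs[i].normal(0.0, 1.0, size=glob.shape) * glob_sigma

        ref = config.local_traits[0]
        ref_k = geno.growth[ref].K
        frac = local[sample_idx[i], 0] / ref_k
        stage = _stage_from_fraction(frac)

        k_vec = np.array([geno.growth[nm].K for nm in config.local_traits])
        x_norm = local[sample_idx[i]] / k_vec
        image = render_patch_image(
            x_norm, layout, noise_sigma=config.patch_noise_sigma,
            rng=img_rngs[i], n_channels=config.patch_channels,
        )
        image_t0 = render_patch_image(
            local[0] / k_vec, layout, noise_sigma=config.patch_noise_sigma,
            rng=img_rngs[i], n_channels=config.patch_channels,
        )
        plants.append(
            PlantRecord(
                plant_id=i, genotype=geno, env=envs[i],
                local_true=local, local_obs=local_obs,
                global_true=glob, global_obs=global_obs,
                stage=stage, condition=str(cond),
                sample_time_idx=int(sample_idx[i]), image=image,
                image_t0=image_t0, stress_score=float(scores[i]),
            )
        )
    return SyntheticCohort(plants=plants, config=config, aggregation=agg,
                           genotype_pool=pool, seed=seed)


# ----------------------------------------------------------------------
# patch image IO
def write_patch_csv(image: PatchImage, path: str | Path):
    p, c = image.grid_size, image.n_channels
    flat = image.values.reshape(p * p, c)
    df = pd.DataFrame(flat, columns=[f"ch{j}" for j in range(c)])
    df.insert(0, "col", np.tile(np.arange(p), p))
    df.insert(0, "row", np.repeat(np.arange(p), p))
    if image.layout is not None:
        df["region"] = image.layout.reshape(-1)
    df.to_csv(path, index=False, float_format="%.12g")


def read_patch_csv(path: str | Path) -> PatchImage:
    df = pd.read_csv(path)
    p = int(df["row"].max()) + 1
    chans = [c for c in df.columns if c.startswith("ch")]
    vals = df[chans].to_numpy().reshape(p, p, len(chans))
    layout = None
    if "region" in df.columns:
        layout = df["region"].to_numpy().reshape(p, p)
    return PatchImage(values=vals, layout=layout)


PNG_SCALE = 65535.0
PNG_VALUE_RANGE = 4.0  # values in [-2, 2] map onto the uint16 range


def write_patch_png(image: PatchImage, path: str | Path):
    """Write channels side by side as one uint16 grayscale PNG."""
    from PIL import Image

    vals = np.clip((image.values + PNG_VALUE_RANGE / 2) / PNG_VALUE_RANGE, 0, 1)
    tiled = np.concatenate([vals[:, :, j] for j in range(image.n_channels)], axis=1)
    arr = np.round(tiled * PNG_SCALE).astype(np.uint16)
    im = Image.frombytes("I;16", (arr.shape[1], arr.shape[0]), arr.tobytes())
    im.save(path)


def read_patch_png(path: str | Path, n_channels: int) -> PatchImage:
    from PIL import Image

    arr = np.asarray(Image.open(path), dtype=np.float64) / PNG_SCALE
    p = arr.shape[0]
    chans = np.split(arr, n_channels, axis=1)
    vals = np.stack(chans, axis=2) * PNG_VALUE_RANGE - PNG_VALUE_RANGE / 2
    return PatchImage(values=vals)
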