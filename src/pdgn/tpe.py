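"""Tree-structured Parzen Estimator (TPE) Bayesian optimization.

TPE optimizes an expensive black-box objective f(theta) by maximization.
Completed trials are split by a quantile gamma into "good" and "bad"
sets; two Parzen (kernel) density models l(theta) and g(theta) are fit
over them, and the next configuration is the candidate — drawn from
l — that maximizes the density ratio l(theta)/g(theta), which is
equivalent to maximizing expected improvement under the TPE construction.
A Gaussian-process surrogate is deliberately avoided: kernel densities
scale better with dimension and trial count.

Continuous dimensions use mixtures of truncated Gaussians centred on the
observed samples plus one uniform prior component spanning the range
(bandwidth max(range * 1.06 n^{-1/5}, range * 1e-3), Silverman-style);
log-scaled dimensions apply the same machinery in log space. Categorical
dimensions use Laplace-smoothed frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Dimension",
    "ContinuousDim",
    "CategoricalDim",
    "HyperparamSpace",
    "TrialRecord",
    "split_trials",
    "parzen_density",
    "ParzenDensity",
    "CategoricalDensity",
    "suggest",
    "optimize",
]

DEFAULT_GAMMA = 0.25
DEFAULT_N_STARTUP = 10
DEFAULT_N_CANDIDATES = 24
BANDWIDTH_FLOOR_FRAC = 1e-3


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ContinuousDim:
    name: str
    lo: float
    hi: float
    log: bool = False

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo must be < hi")
        if self.log and self.lo <= 0:
            raise ValueError(f"{self.name}: log-scaled range must be positive")

    def to_internal(self, x):
        return np.log(x) if self.log else np.asarray(x, dtype=float)

    def from_internal(self, u):
        return np.exp(u) if self.log else u

    @property
    def internal_range(self):
        return (math.log(self.lo), math.log(self.hi)) if self.log else (self.lo, self.hi)


@dataclass(frozen=True)
class CategoricalDim:
    name: str
    choices: tuple

    def __post_init__(self):
        if len(self.choices) == 0:
            raise ValueError(f"{self.name}: choice set must be non-empty")


Dimension = ContinuousDim | CategoricalDim


@dataclass
class HyperparamSpace:
    dimensions: list[Dimension]

    def __post_init__(self):
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")

    def names(self):
        return [d.name for d in self.dimensions]

    def sample_uniform(self, rng: np.random.Generator) -> dict:
        theta = {}
        for d in self.dimensions:
            if isinstance(d, CategoricalDim):
                theta[d.name] = d.choices[rng.integers(len(d.choices))]
            else:
                lo, hi = d.internal_range
                theta[d.name] = float(d.from_internal(rng.uniform(lo, hi)))
        return theta

    def contains(self, theta: dict) -> bool:
        for d in self.dimensions:
            v = theta.get(d.name)
            if isinstance(d, CategoricalDim):
                if v not in d.choices:
                    return False
            elif v is None or not (d.lo <= v <= d.hi):
                return False
        return True


@dataclass
class TrialRecord:
    """One evaluated configuration. ``objective`` is maximized."""

    params: dict
    objective: float
    index: int
    seed: int = 0
    status: str = "ok"  # "ok" or "failed"


# ----------------------------------------------------------------------
def split_trials(trials: Sequence[TrialRecord], gamma: float = DEFAULT_GAMMA):
    """Top ceil(gamma n) trials by objective (maximization) form the good
    set, the rest the bad set; ties break toward the earlier trial index,
    and both sets are forced non-empty."""
    done = [t for t in trials if t.status == "ok"]
    if len(done) < 2:
        raise ValueError("need at least two completed trials to split")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    n_good = max(1, min(math.ceil(gamma * len(done)), len(done) - 1))
    order = sorted(done, key=lambda t: (-t.objective, t.index))
    return order[:n_good], order[n_good:]


class ParzenDensity:
    """1-D mixture of truncated Gaussians plus a uniform prior component.

    Operates in the dimension's internal (possibly log) coordinates. All
    n+1 components have equal weight; the density integrates to one over
    [lo, hi] by construction of the truncation.
    """

    def __init__(self, samples: np.ndarray, dim: ContinuousDim):
        samples = np.asarray([dim.to_internal(s) for s in np.atleast_1d(samples)],
                             dtype=float)
        lo, hi = dim.internal_range
        in_range = samples[(samples >= lo) & (samples <= hi)]
        if in_range.size == 0:
            raise ValueError("parzen density requires at least one in-range sample")
        self.dim = dim
        self.lo, self.hi = lo, hi
        self.mus = in_range
        rng_width = hi - lo
        n = in_range.size
        # Silverman's rule on the sample spread; the range/(n+1) clip keeps
        # the mixture from collapsing onto its samples and starving
        # exploration, the range*1e-3 floor handles degenerate spreads
        spread = float(np.std(in_range))
        self.bw = max(1.06 * spread * n ** (-0.2),
                      rng_width / min(100.0, n + 1.0),
                      rng_width * BANDWIDTH_FLOOR_FRAC)
        self.bw = min(self.bw, rng_width)
        self.n_comp = n + 1  # plus the uniform prior component

    def _trunc(self, mu):
        a, b = (self.lo - mu) / self.bw, (self.hi - mu) / self.bw
        return stats.truncnorm(a, b, loc=mu, scale=self.bw)

    def pdf(self, x) -> np.ndarray:
        """Density in the dimension's *internal* coordinates."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.full(x.shape, 1.0 / (self.hi - self.lo))  # prior component
        for mu in self.mus:
            out = out + self._trunc(mu).pdf(x)
        return out / self.n_comp

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        comp = rng.integers(0, self.n_comp, size=size)
        out = np.empty(size)
        for i, c in enumerate(comp):
            if c == len(self.mus):  # prior
                out[i] = rng.uniform(self.lo, self.hi)
            else:
                d = self._trunc(self.mus[c])
                out[i] = d.ppf(rng.uniform())
        return out


class CategoricalDensity:
    """Laplace-smoothed categorical frequencies."""

    def __init__(self, samples, dim: CategoricalDim, smoothing: float = 1.0):
        samples = list(samples)
        if len(samples) == 0:
            raise ValueError("categorical density requires at least one sample")
        counts = np.array([sum(s == c for s in samples) for c in dim.choices], dtype=float)
        self.dim = dim
        self.probs = (counts + smoothing) / (counts.sum() + smoothing * len(dim.choices))

    def pdf(self, choice) -> float:
        return float(self.probs[self.dim.choices.index(choice)])

    def sample(self, rng: np.random.Generator, size: int):
        idx = rng.choice(len(self.dim.choices), size=size, p=self.probs)
        return [self.dim.choices[i] for i in idx]


def parzen_density(samples, dim: Dimension):
    """Fit the per-dimension density model for a set of samples."""
    if isinstance(dim, CategoricalDim):
        return CategoricalDensity(samples, dim)
    return ParzenDensity(np.asarray(samples, dtype=float), dim)


# ----------------------------------------------------------------------
def suggest(trials: Sequence[TrialRecord], space: HyperparamSpace,
            n_candidates: int = DEFAULT_N_CANDIDATES, gamma: float = DEFAULT_GAMMA,
            seed: int = 0, n_startup: int = DEFAULT_N_STARTUP) -> dict:
    """Propose the next configuration.

    During startup (fewer than ``n_startup`` completed trials) the draw is
    uniform over the space. Afterwards, candidates are sampled from the
    good-set density l and scored by the ratio l/g; the best candidate
    (ties toward the lowest candidate index) is returned. The suggestion
    always lies inside the declared space.
    """
    rng = np.random.default_rng(seed)
    done = [t for t in trials if t.status == "ok"]
    if len(done) < max(n_startup, 2):
        return space.sample_uniform(rng)
    good, bad = split_trials(done, gamma)
    log_ratio = np.zeros(n_candidates)
    candidate_vals: dict[str, list] = {}
    for d in space.dimensions:
        l_model = parzen_density([t.params[d.name] for t in good], d)
        g_model = parzen_density([t.params[d.name] for t in bad], d)
        if isinstance(d, CategoricalDim):
            cands = l_model.sample(rng, n_candidates)
            l_pdf = np.array([l_model.pdf(c) for c in cands])
            g_pdf = np.array([g_model.pdf(c) for c in cands])
            candidate_vals[d.name] = cands
        else:
            internal = l_model.sample(rng, n_candidates)
            l_pdf = l_model.pdf(internal)
            g_pdf = g_model.pdf(internal)
            vals = d.from_internal(internal)
            candidate_vals[d.name] = [float(np.clip(v, d.lo, d.hi)) for v in vals]
        log_ratio = log_ratio + np.log(np.maximum(l_pdf, 1e-300)) \
            - np.log(np.maximum(g_pdf, 1e-300))
    best = int(np.argmax(log_ratio))  # argmax takes the lowest index on ties
    return {name: vals[best] for name, vals in candidate_vals.items()}


def optimize(objective: Callable[[dict], float], space: HyperparamSpace,
             n_trials: int, gamma: float = DEFAULT_GAMMA, seed: int = 0,
             n_candidates: int = DEFAULT_N_CANDIDATES,
             n_startup: int = DEFAULT_N_STARTUP):
    """Run the suggest → evaluate → record loop.

    Returns ``(best_trial, history)``; the best trial is the argmax over
    completed trials. A raising objective marks the trial failed and
    excludes it from the density models. Fully reproducible under
    ``seed`` for deterministic objectives.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    root = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_trials)]
    history: list[TrialRecord] = []
    for i in range(n_trials):
        theta = suggest(history, space, n_candidates=n_candidates, gamma=gamma,
                        seed=trial_seeds[i], n_startup=n_startup)
        try:
            value = float(objective(theta))
            status = "ok"
        except Exception:
            value, status = float("nan"), "failed"
        history.append(TrialRecord(params=theta, objective=value, index=i,
                                   seed=trial_seeds[i], status=status))
    done = [t for t in history if t.status == "ok"]
    if not done:
        raise RuntimeError("all trials failed")
    best = min(done, key=lambda t: (-t.objective, t.index))
    return best, history


def history_frame(history: Sequence[TrialRecord]):
    """Trial history as a DataFrame (trial, params..., objective, status)."""
    import pandas as pd

    rows = []
    for t in history:
        row = {"trial": t.index, **t.params, "objective": t.objective,
               "status": t.status}
        rows.append(row)
    return pd.DataFrame(rows)
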