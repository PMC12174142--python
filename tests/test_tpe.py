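"""TPE optimizer: trial splitting, Parzen densities, suggestion logic,
and the full optimize loop against a random-search baseline."""

import numpy as np
import pytest
from scipy import integrate

from pdgn.tpe import (
    CategoricalDim,
    ContinuousDim,
    HyperparamSpace,
    TrialRecord,
    optimize,
    parzen_density,
    split_trials,
    suggest,
)


def make_trials(objectives):
    return [TrialRecord(params={"x": 0.5}, objective=o, index=i)
            for i, o in enumerate(objectives)]


class TestSplit:
    def test_ceiling_arithmetic(self):
        good, bad = split_trials(make_trials(range(8)), gamma=0.25)
        assert len(good) == 2 and len(bad) == 6
        assert {t.objective for t in good} == {7, 6}

    def test_two_trials_always_split_one_one(self):
        for gamma in (0.01, 0.5, 0.99):
            good, bad = split_trials(make_trials([1.0, 2.0]), gamma=gamma)
            assert len(good) == 1 and len(bad) == 1
            assert good[0].objective == 2.0

    def test_tie_break_toward_earlier_index(self):
        good, _ = split_trials(make_trials([5.0] * 8), gamma=0.25)
        assert [t.index for t in good] == [0, 1]

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            split_trials(make_trials([1.0]), gamma=0.25)

    def test_failed_trials_excluded(self):
        trials = make_trials([1.0, 2.0, 3.0])
        trials[2].status = "failed"
        good, bad = split_trials(trials, gamma=0.5)
        assert {t.objective for t in good} | {t.objective for t in bad} == {1.0, 2.0}


class TestParzenDensity:
    dim = ContinuousDim("x", 0.0, 1.0)

    def test_integrates_to_one(self, rng):
        d = parzen_density(rng.uniform(0, 1, size=6), self.dim)
        total, _ = integrate.quad(lambda x: d.pdf(x)[0], 0.0, 1.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_single_midpoint_sample_symmetric(self):
        d = parzen_density([0.5], self.dim)
        left, _ = integrate.quad(lambda x: d.pdf(x)[0], 0.0, 0.5, limit=200)
        right, _ = integrate.quad(lambda x: d.pdf(x)[0], 0.5, 1.0, limit=200)
        assert left == pytest.approx(right, abs=1e-6)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            parzen_density(np.array([]), self.dim)

    def test_density_concentrates_near_samples(self):
        d = parzen_density([0.2, 0.25, 0.22], self.dim)
        assert d.pdf(0.22)[0] > d.pdf(0.9)[0]

    def test_log_dim_operates_in_log_space(self):
        dim = ContinuousDim("lr", 1e-4, 1e-1, log=True)
        d = parzen_density([1e-3, 2e-3], dim)
        # density over internal (log) coords integrates to one
        total, _ = integrate.quad(lambda u: d.pdf(u)[0],
                                  np.log(1e-4), np.log(1e-1), limit=200)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_categorical_laplace_formula(self):
        dim = CategoricalDim("c", ("a", "b"))
        d = parzen_density(["a", "a", "a"], dim)
        # counts (3, 0), smoothing 1 -> P(a) = 4/5
        assert d.pdf("a") == pytest.approx(4 / 5)
        assert d.pdf("b") == pytest.approx(1 / 5)


class TestSuggest:
    space = HyperparamSpace([ContinuousDim("x", 0.0, 1.0)])

    def test_startup_uniform_and_reproducible(self):
        a = suggest([], self.space, seed=11)
        b = suggest([], self.space, seed=11)
        assert a == b and 0.0 <= a["x"] <= 1.0

    def test_same_trials_same_seed_identical(self):
        trials = [TrialRecord({"x": v}, -(v - 0.4) ** 2, i)
                  for i, v in enumerate(np.linspace(0.05, 0.95, 12))]
        assert suggest(trials, self.space, seed=3) == suggest(trials, self.space, seed=3)

    def test_suggestions_stay_in_space(self):
        mixed = HyperparamSpace([
            ContinuousDim("x", -2.0, 3.0),
            ContinuousDim("lr", 1e-5, 1e-1, log=True),
            CategoricalDim("c", ("u", "v", "w")),
        ])
        rng = np.random.default_rng(0)
        trials = []
        for i in range(30):
            theta = mixed.sample_uniform(rng)
            trials.append(TrialRecord(theta, rng.normal(), i))
        for seed in range(200):
            assert mixed.contains(suggest(trials, mixed, seed=seed))

    def test_suggestion_tracks_good_cluster(self):
        """Good trials cluster at 0.3, bad at 0.9: the density-ratio pick
        should land near the good cluster almost always."""
        rng = np.random.default_rng(42)
        trials = []
        for i in range(12):
            x = float(np.clip(rng.normal(0.3, 0.03), 0, 1))
            trials.append(TrialRecord({"x": x}, 1.0 - i * 1e-3, i))
        for i in range(36):
            x = float(np.clip(rng.normal(0.9, 0.03), 0, 1))
            trials.append(TrialRecord({"x": x}, -1.0 - i * 1e-3, 12 + i))
        hits = sum(
            0.1 <= suggest(trials, self.space, n_candidates=64, seed=s)["x"] <= 0.5
            for s in range(100)
        )
        assert hits >= 95


class TestOptimize:
    def test_constant_objective(self):
        best, hist = optimize(lambda th: 7.5, HyperparamSpace([ContinuousDim("x", 0, 1)]),
                              n_trials=5, seed=0)
        assert best.objective == 7.5 and len(hist) == 5

    def test_single_trial(self):
        best, hist = optimize(lambda th: th["x"],
                              HyperparamSpace([ContinuousDim("x", 0, 1)]),
                              n_trials=1, seed=3)
        assert len(hist) == 1 and best.index == 0

    def test_failed_trials_marked_and_excluded(self):
        def f(theta):
            if theta["x"] > 0.5:
                raise RuntimeError("boom")
            return theta["x"]
        best, hist = optimize(f, HyperparamSpace([ContinuousDim("x", 0, 1)]),
                              n_trials=20, seed=1)
        statuses = {t.status for t in hist}
        assert "failed" in statuses and best.objective <= 0.5

    def test_reproducible_history(self):
        space = HyperparamSpace([ContinuousDim("x", 0, 1)])
        f = lambda th: -(th["x"] - 0.3) ** 2
        _, h1 = optimize(f, space, n_trials=15, seed=9)
        _, h2 = optimize(f, space, n_trials=15, seed=9)
        assert [t.params for t in h1] == [t.params for t in h2]

    def test_quadratic_benchmark_beats_random_search(self):
        """Median best objective over seeds must be at least that of
        uniform random search with the same budget, and most runs must
        land within 0.05 of the optimum."""
        space = HyperparamSpace([ContinuousDim("x", 0.0, 1.0)])
        f = lambda th: -(th["x"] - 0.3) ** 2
        n_seeds, n_trials = 10, 60
        tpe_best, rand_best, hits = [], [], 0
        for seed in range(n_seeds):
            best, _ = optimize(f, space, n_trials=n_trials, seed=seed)
            tpe_best.append(best.objective)
            hits += abs(best.params["x"] - 0.3) <= 0.05
            rng = np.random.default_rng(seed)
            rand_best.append(max(f({"x": rng.uniform()}) for _ in range(n_trials)))
        assert np.median(tpe_best) >= np.median(rand_best)
        assert hits >= int(0.9 * n_seeds)
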