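"""Simulator: growth curves vs closed forms, environment generation,
cohort structure and determinism, patch-image rendering."""

import numpy as np
import pytest

import pdgn
from pdgn import bgos, decoder
from pdgn.simulate import (
    CohortConfig,
    EnvSeasonality,
    GrowthParams,
    LEAF_GAIN,
    LEAF_OFFSET,
    NoiseSpec,
    TimeGrid,
    generate_cohort,
    generate_environment_series,
    make_layout,
    read_patch_csv,
    read_patch_png,
    render_patch_image,
    seasonal_growth_rate,
    simulate_gompertz_trajectory,
    simulate_logistic_trajectory,
    write_patch_csv,
    write_patch_png,
)


# ----------------------------------------------------------------------
class TestSeasonalRate:
    def test_at_t0_equals_baseline(self):
        p = GrowthParams(0.2, 1.0, alpha_season=0.5, T_season=100.0)
        assert seasonal_growth_rate(0.0, p) == pytest.approx(0.2)

    def test_zero_amplitude_is_constant(self):
        p = GrowthParams(0.2, 1.0, alpha_season=0.0)
        t = np.linspace(0, 500, 7)
        np.testing.assert_allclose(seasonal_growth_rate(t, p), 0.2)

    def test_quarter_period_peak(self):
        # sin(pi/2) = 1 -> r = r0 (1 + alpha) = 0.3
        p = GrowthParams(0.2, 1.0, alpha_season=0.5, T_season=40.0)
        assert seasonal_growth_rate(10.0, p) == pytest.approx(0.3)

    def test_positive_given_invariants(self, rng):
        p = GrowthParams(0.15, 2.0, alpha_season=0.99, T_season=365.0)
        assert np.all(seasonal_growth_rate(rng.uniform(0, 1000, 200), p) > 0)


# ----------------------------------------------------------------------
class TestLogistic:
    def test_fixed_point_at_K(self):
        p = GrowthParams(0.3, 2.5)
        z = simulate_logistic_trajectory(2.5, p, TimeGrid(0, 20, 1.0))
        np.testing.assert_allclose(z, 2.5)

    def test_single_euler_step(self):
        # z1 = 0.5 + 0.2*0.5*(1-0.5) = 0.55
        z = simulate_logistic_trajectory(
            0.5, GrowthParams(0.2, 1.0), TimeGrid(0, 2, 1.0))
        np.testing.assert_allclose(z, [0.5, 0.55])

    def test_converges_to_closed_form(self):
        p = GrowthParams(0.5, 1.0)
        grid = TimeGrid(0, 600, 0.1)
        z = simulate_logistic_trajectory(0.1, p, grid)
        assert abs(z[-1] - 1.0) < 1e-3
        t = grid.times
        exact = p.K / (1 + (p.K - 0.1) / 0.1 * np.exp(-p.r0 * t))
        assert np.max(np.abs(z - exact)) < 1e-2  # O(dt) Euler bias

    def test_monotone_when_step_small(self):
        z = simulate_logistic_trajectory(
            0.05, GrowthParams(0.9, 1.0), TimeGrid(0, 50, 1.0))
        assert np.all(np.diff(z) >= -1e-15)

    @pytest.mark.parametrize("z0", [0.0, -0.1, 1.5])
    def test_domain_errors(self, z0):
        with pytest.raises(ValueError):
            simulate_logistic_trajectory(z0, GrowthParams(0.2, 1.0), TimeGrid(0, 5, 1.0))

    def test_noise_is_observation_only(self):
        p = GrowthParams(0.2, 1.0)
        grid = TimeGrid(0, 30, 1.0)
        clean = simulate_logistic_trajectory(0.1, p, grid)
        noisy = simulate_logistic_trajectory(0.1, p, grid, NoiseSpec(obs_sigma=0.05, seed=3))
        resid = noisy - clean
        # residuals are iid draws, not integrated: same draw count as steps
        assert np.std(resid) < 0.2 and np.std(resid) > 0.0
        again = simulate_logistic_trajectory(0.1, p, grid, NoiseSpec(obs_sigma=0.05, seed=3))
        np.testing.assert_array_equal(noisy, again)


class TestGompertz:
    def test_fixed_point_at_K(self):
        z = simulate_gompertz_trajectory(1.0, GrowthParams(0.2, 1.0), TimeGrid(0, 10, 1.0))
        np.testing.assert_allclose(z, 1.0)

    def test_single_step_from_K_over_e(self):
        # ln(K/z0) = 1 -> z1 = z0 + r*z0 = z0 + 0.2/e
        z0 = 1.0 / np.e
        z = simulate_gompertz_trajectory(z0, GrowthParams(0.2, 1.0), TimeGrid(0, 2, 1.0))
        assert z[1] == pytest.approx(z0 + 0.2 / np.e, rel=1e-12)

    def test_first_order_convergence_under_step_halving(self):
        p = GrowthParams(0.2, 1.0)
        z0 = 0.05

        def max_err(dt, horizon=50.0):
            n = int(horizon / dt) + 1
            grid = TimeGrid(0, n, dt)
            z = simulate_gompertz_trajectory(z0, p, grid)
            exact = p.K * np.exp(np.log(z0 / p.K) * np.exp(-p.r0 * grid.times))
            return np.max(np.abs(z - exact))

        ratio = max_err(0.5) / max_err(0.25)
        assert 1.5 <= ratio <= 2.5


# ----------------------------------------------------------------------
class TestEnvironment:
    def test_constant_when_no_noise_no_amplitude(self):
        season = EnvSeasonality(amplitudes={k: 0.0 for k in
                                            ("temperature", "humidity", "soil_moisture", "par")})
        env = generate_environment_series(TimeGrid(0, 20, 1.0), NoiseSpec(env_sigma=0.0), season)
        for ch, mean in season.means.items():
            np.testing.assert_allclose(env.channel(ch), mean)

    def test_seed_determinism(self):
        grid = TimeGrid(0, 50, 1.0)
        a = generate_environment_series(grid, NoiseSpec(env_sigma=1.0, seed=9))
        b = generate_environment_series(grid, NoiseSpec(env_sigma=1.0, seed=9))
        np.testing.assert_array_equal(a.data, b.data)

    def test_humidity_stays_physical_over_many_steps(self):
        grid = TimeGrid(0, 10_000, 1.0)
        env = generate_environment_series(grid, NoiseSpec(env_sigma=3.0, seed=1))
        h = env.channel("humidity")
        assert h.min() >= 0.0 and h.max() <= 100.0
        assert env.channel("par").min() >= 0.0


# ----------------------------------------------------------------------
class TestCohort:
    def test_noiseless_hierarchy_and_consistency_are_zero(self, small_cohort, constraints):
        names = small_cohort.local_traits + small_cohort.global_traits
        agg = small_cohort.aggregation
        for p in small_cohort.plants:
            allx = np.concatenate([p.local_true, p.global_true], axis=1)
            h = decoder.hierarchy_loss(allx, constraints.hierarchy_pairs, columns=names)
            assert float(h) == 0.0
            c = bgos.consistency_loss(p.global_true, p.local_true, agg)
            assert float(c) < 1e-18

    def test_bounds_satisfied_pre_noise(self, small_cohort, constraints):
        names = small_cohort.local_traits + small_cohort.global_traits
        for p in small_cohort.plants:
            allx = np.concatenate([p.local_true, p.global_true], axis=1)
            assert float(bgos.bounds_loss(allx, constraints.bounds, columns=names)) == 0.0

    def test_seed_determinism_bytewise(self, tmp_path):
        cfg = pdgn.toy_cohort_config(n_plants=15, T=8)
        for sub in ("a", "b"):
            pdgn.generate_cohort(cfg, seed=42).write(tmp_path / sub)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_stress_threshold_sets_nonhealthy_fraction(self):
        cfg = pdgn.toy_cohort_config(n_plants=200, T=10)
        cfg.stress_threshold_pct = 60.0
        cohort = pdgn.generate_cohort(cfg, seed=3)
        frac = np.mean([p.condition != "healthy" for p in cohort.plants])
        assert frac == pytest.approx(0.40, abs=0.02)

    def test_sixteen_class_taxonomy(self):
        cohort = pdgn.generate_cohort(pdgn.toy_cohort_config(n_plants=400, T=20), seed=11)
        labels = cohort.labels()
        assert set(labels["stage"]).issubset(set(pdgn.simulate.STAGES))
        assert set(labels["condition"]).issubset(set(pdgn.simulate.CONDITIONS))
        # a reasonably large cohort populates most of the 16 classes
        assert labels["class_label"].nunique() >= 10

    def test_inconsistent_config_rejected(self, constraints):
        cfg = pdgn.toy_cohort_config(10, 8)
        cfg.base_growth = dict(cfg.base_growth)
        cfg.base_growth["leaf_area"] = GrowthParams(0.1, 1e6)  # K above bounds
        with pytest.raises(ValueError):
            pdgn.generate_cohort(cfg, seed=0, constraints=constraints)


# ----------------------------------------------------------------------
class TestPatchImage:
    def test_noiseless_rendering_is_deterministic(self, rng):
        layout = make_layout(5, np.random.default_rng(0))
        x = rng.uniform(0.1, 0.9, size=4)
        a = render_patch_image(x, layout, noise_sigma=0.0)
        b = render_patch_image(x, layout, noise_sigma=0.0)
        np.testing.assert_array_equal(a.values, b.values)

    def test_background_only_layout_carries_no_signal(self, rng):
        layout = np.full((4, 4), "background", dtype=object)
        a = render_patch_image(rng.uniform(size=3), layout, noise_sigma=0.0)
        b = render_patch_image(rng.uniform(size=3), layout, noise_sigma=0.0)
        np.testing.assert_array_equal(a.values, b.values)

    def test_leaf_patches_invert_to_traits(self, rng):
        layout = make_layout(6, np.random.default_rng(1))
        x = rng.uniform(0.05, 0.95, size=4)
        img = render_patch_image(x, layout, noise_sigma=0.0, n_channels=4)
        leaf_mean = img.values[layout == "leaf"].mean(axis=0)
        recovered = (leaf_mean - LEAF_OFFSET) / LEAF_GAIN
        np.testing.assert_allclose(recovered, x, atol=1e-12)

    def test_csv_roundtrip(self, tmp_path, rng):
        layout = make_layout(4, np.random.default_rng(2))
        img = render_patch_image(rng.uniform(size=3), layout, noise_sigma=0.01,
                                 rng=np.random.default_rng(5))
        write_patch_csv(img, tmp_path / "img.csv")
        back = read_patch_csv(tmp_path / "img.csv")
        np.testing.assert_allclose(back.values, img.values, atol=1e-10)
        np.testing.assert_array_equal(back.layout, img.layout)

    def test_png_roundtrip_within_quantization(self, tmp_path, rng):
        layout = make_layout(4, np.random.default_rng(2))
        img = render_patch_image(rng.uniform(size=3), layout, noise_sigma=0.0)
        write_patch_png(img, tmp_path / "img.png")
        back = read_patch_png(tmp_path / "img.png", n_channels=3)
        np.testing.assert_allclose(back.values, img.values, atol=1e-4)
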