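"""BGOS losses: hinge correlation, bounds, multi-scale, consistency,
environment perturbation — value checks, brute-force oracle equivalence,
monotonicity and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdgn.autodiff import Tensor
from pdgn.bgos import (
    PerturbationSpec,
    ScaleWeights,
    bounds_loss,
    consistency_loss,
    env_perturbation_loss,
    hier_threshold_loss,
    multiscale_loss,
)
from pdgn.constraints import AggregationMap, CorrelationEdge, TraitDependencyGraph
from pdgn.decoder import DecoderParams, decode

from conftest import assert_grads_close, numeric_grad, scalar


def columns_with_correlation(rng, n, target_rho):
    """Construct two columns whose sample Pearson is exactly target_rho
    (Gram–Schmidt on centered, unit-norm vectors)."""
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = a - a.mean()
    a /= np.linalg.norm(a)
    b = b - b.mean()
    b = b - (b @ a) * a
    b /= np.linalg.norm(b)
    y = target_rho * a + np.sqrt(1 - target_rho**2) * b
    return a, y


class TestHingeCorrelation:
    def graph(self, thr):
        return TraitDependencyGraph([CorrelationEdge("a", "b", rho=thr)])

    def test_inactive_below_threshold(self, rng):
        a, y = columns_with_correlation(rng, 30, 0.3)
        x = np.column_stack([a, y])
        assert scalar(hier_threshold_loss(x, self.graph(0.5), columns=["a", "b"])) == 0.0

    def test_exact_excess_above_threshold(self, rng):
        a, y = columns_with_correlation(rng, 40, 0.9)
        x = np.column_stack([a, y])
        val = scalar(hier_threshold_loss(x, self.graph(0.5), columns=["a", "b"]))
        assert val == pytest.approx(0.4, abs=1e-9)

    def test_threshold_one_never_fires(self, rng):
        x = rng.normal(size=(20, 2))
        assert scalar(hier_threshold_loss(x, self.graph(1.0), columns=["a", "b"])) == 0.0

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            hier_threshold_loss(rng.normal(size=(2, 2)), self.graph(0.5),
                                columns=["a", "b"])


class TestBounds:
    bounds = {"a": (0.0, 1.0)}

    def test_inside_bounds_zero(self, rng):
        x = rng.uniform(0.05, 0.95, size=(10, 1))
        assert scalar(bounds_loss(x, self.bounds, columns=["a"])) == 0.0

    def test_upper_violation(self):
        x = np.array([[1.3]])
        assert scalar(bounds_loss(x, self.bounds, columns=["a"])) == pytest.approx(0.3)

    def test_both_sides_sum(self):
        x = np.array([[1.3], [-0.1]])
        assert scalar(bounds_loss(x, self.bounds, columns=["a"])) == pytest.approx(0.4)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            bounds_loss(np.ones((2, 1)), {"a": (1.0, 1.0)}, columns=["a"])

    @given(
        lo=st.floats(-2, 0), width=st.floats(0.1, 3),
        widen=st.floats(0, 2), seed=st.integers(0, 2**16),
    )
    @settings(max_examples=60, deadline=None)
    def test_enlarging_interval_never_increases_loss(self, lo, width, widen, seed):
        x = np.random.default_rng(seed).normal(0, 2, size=(15, 1))
        narrow = scalar(bounds_loss(x, {"a": (lo, lo + width)}, columns=["a"]))
        wide = scalar(bounds_loss(x, {"a": (lo - widen, lo + width + widen)},
                                  columns=["a"]))
        assert wide <= narrow + 1e-12


class TestMultiscale:
    def test_zero_at_perfect_predictions(self, rng):
        lp = rng.normal(size=(5, 3))
        gp = rng.normal(size=(5, 2))
        assert scalar(multiscale_loss(lp, lp, gp, gp)) == 0.0

    def test_beta_zero_is_local_only(self, rng):
        lp, lt = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        gp, gt = rng.normal(size=(4, 1)), rng.normal(size=(4, 1))
        w = ScaleWeights(alpha=1.0, beta=0.0)
        assert scalar(multiscale_loss(lp, lt, gp, gt, w)) == \
            pytest.approx(np.sum((lp - lt) ** 2), rel=1e-12)

    def test_direct_arithmetic(self):
        # local errors (1,1), global error (2): 0.5*2 + 2*4 = 9
        got = multiscale_loss(
            np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]]),
            np.array([[2.0]]), np.array([[0.0]]),
            ScaleWeights(alpha=0.5, beta=2.0))
        assert scalar(got) == pytest.approx(9.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            multiscale_loss(np.ones((2, 2)), np.ones((3, 2)),
                            np.ones((2, 1)), np.ones((2, 1)))

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ValueError):
            ScaleWeights(alpha=0.0, beta=0.0)


class TestConsistency:
    def test_summation_aggregation(self):
        T = np.array([[1.0, 1.0, 1.0]])
        assert scalar(consistency_loss(np.array([[6.0]]), np.array([[1.0, 2.0, 3.0]]), T)) == 0.0
        assert scalar(consistency_loss(np.array([[7.0]]), np.array([[1.0, 2.0, 3.0]]), T)) \
            == pytest.approx(1.0)

    def test_zero_on_simulator_ground_truth(self, small_cohort):
        p = small_cohort.plants[0]
        assert scalar(consistency_loss(p.global_true, p.local_true,
                                       small_cohort.aggregation)) < 1e-18

    def test_accepts_aggregation_map_object(self, rng):
        agg = AggregationMap(np.array([[2.0, 0.0]]), ["a", "b"], ["g"])
        loc = rng.normal(size=(6, 2))
        glob = agg.apply(loc)
        assert scalar(consistency_loss(glob, loc, agg)) < 1e-18


class TestEnvPerturbation:
    def linear_env_decoder(self, W_e):
        d_out, k = W_e.shape
        d_z = 2
        W1 = np.eye(d_z + k)
        W2 = np.concatenate([np.zeros((d_out, d_z)), W_e], axis=1)
        return DecoderParams(W1=W1, b1=np.zeros(d_z + k), W2=W2,
                             b2=np.zeros(d_out), env_conditioned=True,
                             activation="identity")

    def test_env_blind_model_gives_zero(self, rng):
        def f(z, e):
            return np.asarray(z) * 2.0
        spec = PerturbationSpec(sigma=1.0, n_samples=4, seed=0)
        assert scalar(env_perturbation_loss(f, rng.normal(size=3),
                                            rng.normal(size=2), spec)) == 0.0

    def test_zero_sigma_gives_zero(self, rng):
        p = self.linear_env_decoder(rng.normal(size=(2, 3)))
        def f(z, e):
            return decode(z, e, p)
        spec = PerturbationSpec(sigma=0.0, n_samples=3, seed=1)
        assert scalar(env_perturbation_loss(f, rng.normal(size=2),
                                            rng.normal(size=3), spec)) == 0.0

    def test_linear_decoder_closed_form(self, rng):
        W_e = rng.normal(size=(2, 3))
        p = self.linear_env_decoder(W_e)
        spec = PerturbationSpec(sigma=np.array([0.1, 0.2, 0.3]), n_samples=5, seed=4)
        deltas = spec.draw(3)
        expected = np.mean([np.sum((W_e @ d) ** 2) for d in deltas])
        def f(z, e):
            return decode(z, e, p)
        got = scalar(env_perturbation_loss(f, rng.normal(size=2),
                                           rng.normal(size=3), spec))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_quadratic_scaling_in_sigma(self, rng):
        """For a linear decoder the penalty is quadratic in sigma:
        doubling sigma quadruples the loss (same seed, same draws)."""
        W_e = rng.normal(size=(2, 2))
        p = self.linear_env_decoder(W_e)
        def f(z, e):
            return decode(z, e, p)
        z, e = rng.normal(size=2), rng.normal(size=2)
        v1 = scalar(env_perturbation_loss(f, z, e, PerturbationSpec(0.05, 64, seed=9)))
        v2 = scalar(env_perturbation_loss(f, z, e, PerturbationSpec(0.10, 64, seed=9)))
        assert v2 / v1 == pytest.approx(4.0, rel=1e-9)

    def test_unconditioned_model_rejected(self, rng):
        def f(z, e):
            return z
        f.env_conditioned = False
        with pytest.raises(ValueError):
            env_perturbation_loss(f, rng.normal(size=2), rng.normal(size=2),
                                  PerturbationSpec(0.1, 2, 0))

    def test_deterministic_under_seed(self, rng):
        p = self.linear_env_decoder(rng.normal(size=(2, 2)))
        def f(z, e):
            return decode(z, e, p)
        z, e = rng.normal(size=2), rng.normal(size=2)
        spec = PerturbationSpec(0.1, 8, seed=3)
        assert scalar(env_perturbation_loss(f, z, e, spec)) == \
            scalar(env_perturbation_loss(f, z, e, spec))


# ----------------------------------------------------------------------
class TestOracleEquivalence:
    """Every vectorized loss equals a brute-force double loop."""

    def test_bounds_oracle(self, rng):
        bounds = {"a": (-0.5, 0.5), "b": (0.0, 2.0)}
        for _ in range(100):
            x = rng.normal(size=(8, 2))
            oracle = 0.0
            for row in x:
                for j, name in enumerate(["a", "b"]):
                    lo, hi = bounds[name]
                    oracle += max(0.0, row[j] - hi) + max(0.0, lo - row[j])
            assert scalar(bounds_loss(x, bounds, columns=["a", "b"])) == \
                pytest.approx(oracle, abs=1e-10)

    def test_multiscale_oracle(self, rng):
        w = ScaleWeights(alpha=0.7, beta=1.3)
        for _ in range(100):
            lp, lt = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
            gp, gt = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
            oracle = 0.0
            for i in range(6):
                oracle += w.alpha * sum((lp[i, j] - lt[i, j]) ** 2 for j in range(3))
                oracle += w.beta * sum((gp[i, j] - gt[i, j]) ** 2 for j in range(2))
            assert scalar(multiscale_loss(lp, lt, gp, gt, w)) == \
                pytest.approx(oracle, abs=1e-10)

    def test_consistency_oracle(self, rng):
        T = rng.normal(size=(2, 4))
        for _ in range(100):
            loc = rng.normal(size=(5, 4))
            glo = rng.normal(size=(5, 2))
            oracle = 0.0
            for i in range(5):
                mapped = [sum(T[g, j] * loc[i, j] for j in range(4)) for g in range(2)]
                oracle += sum((glo[i, g] - mapped[g]) ** 2 for g in range(2))
            assert scalar(consistency_loss(glo, loc, T)) == pytest.approx(oracle, abs=1e-10)


# ----------------------------------------------------------------------
class TestGradients:
    def test_bounds_gradient(self, rng):
        x0 = rng.normal(0, 2, size=(6, 2))
        bounds = {"a": (-0.5, 0.5), "b": (0.0, 1.0)}
        t = Tensor(x0, requires_grad=True)
        bounds_loss(t, bounds, columns=["a", "b"]).backward()
        g = numeric_grad(lambda x: scalar(bounds_loss(x, bounds, columns=["a", "b"])), x0)
        assert_grads_close(t.grad, g)

    def test_hinge_correlation_gradient(self, rng):
        graph = TraitDependencyGraph([CorrelationEdge("a", "b", rho=-0.5)])
        a, y = columns_with_correlation(rng, 12, 0.4)
        x0 = np.column_stack([a, y])  # hinge active: 0.4 > -0.5
        t = Tensor(x0, requires_grad=True)
        hier_threshold_loss(t, graph, columns=["a", "b"]).backward()
        g = numeric_grad(
            lambda x: scalar(hier_threshold_loss(x, graph, columns=["a", "b"])), x0)
        assert_grads_close(t.grad, g)

    def test_consistency_gradient(self, rng):
        T = rng.normal(size=(2, 3))
        loc0 = rng.normal(size=(4, 3))
        glo = rng.normal(size=(4, 2))
        t = Tensor(loc0, requires_grad=True)
        consistency_loss(glo, t, T).backward()
        g = numeric_grad(lambda x: scalar(consistency_loss(glo, x, T)), loc0)
        assert_grads_close(t.grad, g)

    def test_env_perturbation_gradient(self, rng):
        d_z, k = 2, 2
        W1 = Tensor(rng.normal(size=(5, d_z + k)), requires_grad=True)
        p = DecoderParams(W1=W1, b1=Tensor(np.zeros(5), requires_grad=True),
                          W2=Tensor(rng.normal(size=(2, 5)), requires_grad=True),
                          b2=Tensor(np.zeros(2), requires_grad=True))
        z, e = rng.normal(size=2), rng.normal(size=2)
        spec = PerturbationSpec(0.3, 4, seed=2)
        def f_loss(w):
            p.W1.data = w
            return scalar(env_perturbation_loss(
                lambda zz, ee: decode(zz, ee, p), z, e, spec))
        w0 = p.W1.data.copy()
        env_perturbation_loss(lambda zz, ee: decode(zz, ee, p), z, e, spec).backward()
        g_auto = p.W1.grad.copy()
        g_num = numeric_grad(f_loss, w0)
        p.W1.data = w0
        assert_grads_close(g_auto, g_num)
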