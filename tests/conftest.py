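import numpy as np
import pytest

import pdgn
from pdgn.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-plant, 12-step cohort shared across read-only tests."""
    return pdgn.generate_cohort(pdgn.toy_cohort_config(n_plants=40, T=12), seed=7)


@pytest.fixture(scope="session")
def constraints():
    return pdgn.default_wheat_constraints()


def numeric_grad(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
        it.iternext()
    return g


def assert_grads_close(g_auto: np.ndarray, g_num: np.ndarray, rtol: float = 1e-4):
    denom = np.maximum(np.abs(g_auto) + np.abs(g_num), 1e-6)
    rel = np.abs(g_auto - g_num) / denom
    assert np.max(rel) < rtol, f"max relative gradient error {np.max(rel):.2e}"


def scalar(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)
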