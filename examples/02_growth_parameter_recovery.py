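"""Recover logistic growth parameters (r, K) from trajectories.

On noiseless Euler data the increment regression is exact; with 2%-of-K
observation noise the refined estimator keeps the median error on the
growth rate under a few percent.
"""

import numpy as np

from pdgn import fit_growth_params
from pdgn.simulate import GrowthParams, NoiseSpec, TimeGrid, simulate_logistic_trajectory

grid = TimeGrid(t0=0, T=60, dt=1.0)
truth = GrowthParams(r0=0.2, K=1.0)

z = simulate_logistic_trajectory(0.1, truth, grid)
r, K, diag = fit_growth_params(z, grid)
print(f"noiseless: r_hat={r:.12f}  K_hat={K:.12f}  R^2={diag['r_squared']:.6f}")

errs = []
for i in range(200):
    zn = simulate_logistic_trajectory(0.1, truth, grid,
                                      NoiseSpec(obs_sigma=0.02, seed=i))
    r_hat, _, _ = fit_growth_params(np.clip(zn, 1e-6, None), grid)
    errs.append(abs(r_hat - truth.r0) / truth.r0)
print(f"noisy (sigma=0.02K, 200 plants): median |r_hat-r|/r = "
      f"{100 * np.median(errs):.2f}%")
# The noiseless fit matches (0.2, 1.0) to machine precision because the
# Euler update is exactly linear in (z, z^2); the noisy median error is
# the realistic operating accuracy at this noise level.
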