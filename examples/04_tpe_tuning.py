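"""Tree-structured Parzen Estimator search on a known objective.

TPE fits separate kernel densities to good and bad trials and proposes
the candidate maximizing their ratio; on a 1-D quadratic it localizes
the optimum far more precisely than random search at the same budget.
"""

import numpy as np

from pdgn.tpe import ContinuousDim, HyperparamSpace, optimize

space = HyperparamSpace([ContinuousDim("x", 0.0, 1.0)])
objective = lambda theta: -(theta["x"] - 0.3) ** 2

best, history = optimize(objective, space, n_trials=60, seed=0)
xs = [t.params["x"] for t in history]
print(f"best x = {best.params['x']:.4f} (true optimum 0.3), "
      f"objective {best.objective:.2e} after {len(history)} trials")
print("first 10 trials (uniform startup):", np.round(xs[:10], 3))
print("last 10 trials (density-ratio driven):", np.round(xs[-10:], 3))

# Single seeds are noisy, so compare medians over 10 repeats
tpe_runs, rand_runs = [], []
for seed in range(10):
    b, _ = optimize(objective, space, n_trials=60, seed=seed)
    tpe_runs.append(b.objective)
    rng = np.random.default_rng(seed)
    rand_runs.append(max(objective({"x": rng.uniform()}) for _ in range(60)))
print(f"median best over 10 seeds: TPE {np.median(tpe_runs):.2e} "
      f"vs random search {np.median(rand_runs):.2e}")
# The late trials cluster tightly around 0.3; over repeated runs the
# density-ratio search is consistently at least as good as uniform
# sampling with the same 60-trial budget.
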