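"""Deterministic trait-to-text rendering.

Each observation becomes a fixed-grammar report: stage and condition,
trait values with units, one sentence per active constraint violation,
and an environment summary. Identical inputs always give identical text.
"""

import numpy as np

import pdgn
from pdgn.pipeline import describe

cohort = pdgn.generate_cohort(pdgn.toy_cohort_config(30, 12), seed=4)
names = cohort.local_traits + cohort.global_traits
constraints = pdgn.default_wheat_constraints()

for p in cohort.plants[:2]:
    t = p.sample_time_idx
    traits = dict(zip(names, np.concatenate([p.local_obs[t], p.global_obs[t]])))
    violations = []
    for pair in constraints.hierarchy_pairs:
        if traits[pair.smaller] > traits[pair.larger]:
            violations.append({
                "smaller": pair.smaller, "larger": pair.larger,
                "smaller_value": traits[pair.smaller],
                "larger_value": traits[pair.larger]})
    env = {ch: float(np.mean(p.env.channel(ch)))
           for ch in ("temperature", "humidity", "soil_moisture", "par")}
    print(describe(traits, violations, p.stage, p.condition, env))
    print()
# Violation sentences appear only when observation noise pushes the
# reported leaf area above the canopy area — the noiseless traits satisfy
# the hierarchy by construction.
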