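# Methods

## Scope and data model

The package models per-plant trait trajectories x(g, e, t) = f(g, e, t) + ε:
traits are driven by genotype g, environment e and time t (days), with
additive observation noise ε. Raw traits x carry physical units (cm²,
cm, counts, cm³, g); latent states z are dimensionless. Environments are
4-vectors in fixed channel order — temperature (°C), relative humidity
(%), soil moisture (g/cm³), PAR (µmol m⁻² s⁻¹). Time lives on a uniform
grid t₀ + jΔt, j ∈ [0, T).

No public dataset backs this pipeline, so the simulator is a first-class
component: it defines the data-generating process all losses are tested
against, and every regularizer's true optimum is known by construction.

## The simulator

**Growth.** Each genotype carries per-trait parameters (r₀ in day⁻¹, K
in trait units, optional seasonal amplitude and period, curve family).
Noiseless trajectories follow the explicit-Euler update
z_{j+1} = z_j + r(t_j) z_j (1 − z_j/K) Δt (logistic) or the
r z ln(K/z) increment (Gompertz). Euler is deliberate: the temporal
regularizers penalize exactly this discrete update, so simulator output
is the exact zero of the growth residual, and the closed-form solutions
K/(1+((K−z₀)/z₀)e^{−rt}) and K exp(ln(z₀/K) e^{−rt}) serve as
convergence oracles (first-order: halving Δt halves the maximum
deviation, tested with ratio bounds [1.5, 2.5]).

**Noise is observation-only.** Gaussian noise (σ = 2% of each trait's K
by default) is added to observed copies after integration and never fed
back into the dynamics. This keeps the noiseless path an exact oracle; a
process-noise variant would destroy that property and is intentionally
not offered.

**Hierarchy by construction.** Global traits are a fixed linear map of
local traits (canopy area = 1.8 × leaf area; shoot biomass a positive
combination of all four locals). Hierarchy pairs and cross-scale
consistency therefore hold exactly pre-noise, giving the corresponding
losses known zeros.

**Labels.** Accumulated environmental stress (mean absolute deviation of
temperature and soil moisture from their seasonal means, scaled by the
seasonal amplitude) is thresholded at a percentile (default 60th) to
mark plants non-healthy; a seeded fraction of those progress to diseased
(30%) or damaged (20%), so the non-healthy fraction equals
1 − threshold. Conditions act on the dynamics before noise: stress and
damage reduce the effective growth rate by the genotype's
susceptibility, disease also lowers K by 15%, damage multiplies the
trajectory tail by 0.7 from a random mid-season point. Stage labels
(seedling, tillering, heading, grain filling) come from the fraction of
K reached by the reference trait at the plant's sampled time, with
boundaries at 0.15 / 0.45 / 0.8 of K — arbitrary but fixed. Four stages
× four conditions give the 16-class taxonomy.

**Pseudo-images.** A P×P region layout (leaf/stem/background) is shared
by a cohort. Leaf patches encode normalized traits through the affine
map 0.2 + 0.6·x_norm per channel, stem patches carry a constant,
background is noise — enough structure for the attention mechanism to
have a verifiable ground truth (signal lives only in leaf patches), with
no pretense of radiometric realism. Images can be written as CSV
matrices or 16-bit PNGs.

**Determinism.** One integer seed feeds a `numpy.random.SeedSequence`;
children are spawned per purpose (genotype pool, environments, label
assignment, observation noise, images) so regenerating a cohort is
byte-identical and adding plants does not reshuffle existing ones.

## Model components and numerical choices

The whole model is differentiated by a compact reverse-mode autodiff
engine over float64 numpy arrays (`pdgn.autodiff`); the model sizes here
(thousands of parameters) make a framework dependency unnecessary, and
every loss doubles as a plain numpy function on array input. Softmax is
max-subtracted before exponentiation; Pearson correlations are computed
from centered sums (edges touching a constant column are skipped with a
warning and recorded in a diagnostics dict rather than erroring
mid-training); the Gompertz rate clamps z to [10⁻⁶K, K] against the
logarithm's singularity, with pass-through gradients inside the
interval.

The growth equation is scalar but z is a vector; it is applied
element-wise with shared (r, K) by default (per-dimension values and
learnable tensors are accepted). The growth prior on the *latent* space
is (r₀ = 0.08 day⁻¹, K = 1): latents are dimensionless, and the
regularizer acts on them rather than on physical traits — the symbols in
the growth-residual definition are latent states, and this reading keeps
the regularizer independent of trait units. Traits are predicted in
normalized space (per-column positive scale = 95th percentile of the
noiseless cohort values) and de-normalized before the hierarchy and
bounds penalties, which are physical-unit statements.

Both correlation penalties are implemented — squared deviation from a
target ρ_ij and a one-sided hinge above a threshold — because both
appear in the constraint formulation; which one enters training is a
configuration choice (the squared form is the default, the hinge
threshold defaults to ρ_ij). The environment-perturbation penalty draws
its Gaussian δ per channel at 5% of the standardized channel scale, M=4
samples during training (M=32 when measuring), seeded per epoch; it is
applied along the entire trajectory rather than at a single time point
so its gradient is commensurate with the reconstruction term.

Training uses Adam (β₁ = 0.9, β₂ = 0.999). The toy configuration runs
100 plants × 20 steps for 30 epochs at learning rate 3·10⁻³ and batch
size 32 — sizes chosen so the whole constrained/unconstrained ablation
completes in seconds while the ablation directions are stable across
seeds; 10⁻⁴ is the conventional rate at full scale and remains the
optimizer default. The split is 75% train, 12.5% validation, 12.5% test.
Condition classification is a softmax head on the time-averaged latent;
the architecture for this head is otherwise unconstrained by the method,
so the simplest linear head was chosen. A NaN anywhere in the objective
aborts training with the first non-finite component named.

## Growth-parameter recovery

`fit_growth_params` inverts the logistic Euler update. The textbook
regression of y_t = (z_{t+1} − z_t)/(z_t Δt) on z_t is exact on
noiseless data but noise-amplifying (dividing by z_t inflates early-time
errors); the package solves the same line in GLS form — increments
regressed on (z_t, z_t²), i.e. the identical relationship weighted by
z_t² — and then refines (r, K, z₀) by nonlinear least squares against
the Euler recursion itself. On noiseless trajectories stage 1 is already
the exact optimum and refinement is a no-op, preserving machine-precision
recovery; under 2%-of-K noise the median relative error on r is ~1.6%
(200 plants). Constant trajectories (including z ≡ K, where increments
vanish) raise an identifiability error; diagnostics carry the stage-1 R²
and an identifiability flag (positive r, negative quadratic
coefficient).

## TPE

γ = 0.25, 10 uniform startup trials, 24 candidates per suggestion, ties
broken toward earlier trial indices / lower candidate indices;
maximization orientation throughout. Continuous densities are mixtures
of truncated Gaussians centred on the observed samples plus one uniform
prior component spanning the range, all equally weighted; log-scaled
dimensions run the same machinery in log space; categoricals use
Laplace-smoothed frequencies. The bandwidth is Silverman's rule on the
sample spread, 1.06·std·n^{−1/5}, clipped from below by
range/min(100, n+1): the clip is essential — without it the good-set
spread collapses onto the incumbent best, the mixture degenerates, and
the search stops exploring (observed directly on the quadratic
benchmark). Failed objective evaluations are recorded and excluded from
the densities. A Gaussian-process surrogate is out of scope by design;
the density-ratio acquisition is the standard expected-improvement
equivalent.

## Text rendering

Reports are produced by a fixed sentence grammar — stage/condition
sentence, one sentence per trait with its unit, one sentence per active
hierarchy violation (always naming both traits with the word
"exceeds"), one environment summary — with every number formatted
through a single fixed `%.2f` template, so identical inputs yield
byte-identical text. This is an explicit scope decision: the rendering
is deterministic and template-based, not a learned language model.

## What the synthetic tests do and do not show

Passing tests establish that each penalty is exactly zero on its
feasible set, matches brute-force oracles, differentiates correctly, and
moves trained models in the intended direction (fewer hierarchy
violations, smaller perturbation response) under the simulator's
assumptions: noise-free dynamics with additive observation noise, exact
linear local→global aggregation, environments that influence conditions
but only mildly influence trait values. Real phenotyping data violate
all three — process noise, nonlinear canopy closure, strong
genotype-by-environment interaction — so these results certify the
machinery, not field-scale accuracy. No claim of distributional fidelity
to any particular imaging dataset is made.

## Known limitations

- Explicit Euler only; stiff or irregularly-sampled series are out of
  scope.
- The transformer variant of the temporal module and adversarial domain
  adaptation are not implemented; environment handling is conditioning
  plus the perturbation penalty.
- Patch images are schematic; no spectral attention or 3D point-cloud
  ingestion.
- The condition classifier is linear on the latent summary and is meant
  as a diagnostic head, not a competitive classifier.
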