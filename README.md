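# pdgn

Biologically-constrained deep generative modeling for plant phenotyping:
a patch-attention image encoder, a growth-constrained latent temporal
model, a trait decoder regularized by agronomic knowledge, and a
from-scratch Tree-structured Parzen Estimator (TPE) for hyperparameter
search — exercised end to end on a built-in wheat-cohort simulator with
known ground truth.

## The problem

High-throughput phenotyping platforms image plants repeatedly over a
season and record environmental covariates (temperature in °C, relative
humidity in %, soil moisture in g/cm³, photosynthetically active
radiation in µmol m⁻² s⁻¹). The analysis task is to map those images and
covariates to quantitative trait trajectories — leaf area, plant height,
leaf count, root volume, canopy area, biomass — that are not only
accurate but *biologically plausible*: leaf area cannot exceed canopy
area, traits stay within physiological bounds, growth follows saturating
curves, and known trait correlations (leaf number rises with stem
height) are respected. Purely data-driven models violate these rules
freely; this package builds them into the training objective.

## The model

**Encoder.** An image is a P×P grid of c-channel patch features. A small
convolutional stack produces multi-scale per-patch hiddens h_j; additive
attention
e_j = vᵀ tanh(W_a h_j + b_a), α = softmax(e), z = Σ_j α_j h_j
pools them into a latent state (projected to dimension d_z), letting the
model weight leaf/stem patches over background.

**Temporal dynamics.** The latent evolves Markovianly under the
environment, z^{t+1} = cell(z^t, e^t) + η ⊙ (W_e e^t), with a single
gated recurrent cell and a per-dimension environmental sensitivity η.
Two regularizers shape the trajectory: a growth residual

L_growth = Σ_t ‖z^{t+1} − (z^t + r(t) z^t (1 − z^t/K) Δt)‖²

penalizing deviation from discrete logistic growth (Gompertz
r z ln(K/z) as an alternative; optionally seasonal
r(t) = r₀(1 + α sin 2πt/T_season)), and a smoothness term
Σ_t ‖z^{t+1} − z^t‖².

**Constrained decoder.** A feed-forward map from (z, e) to named traits,
trained with L = L_recon + λ₁ L_cor + λ₂ L_struct + λ₃ L_env, where
L_cor penalizes squared deviation of batch Pearson correlations from
target values ρ_ij on a trait dependency graph, L_struct is the hinge
Σ max(0, x_smaller − x_larger) over hierarchical pairs, and L_env is a
Monte-Carlo perturbation penalty ‖φ(z, e+δ) − φ(z, e)‖² that rewards
stability under environmental noise. Further penalties: physiological
bounds Σ ReLU(x̂−u) + ReLU(l−x̂), a weighted local/global multi-scale
loss α L_local + β L_global, and cross-scale consistency
‖x̂_global − T x̂_local‖² against a linear aggregation map T.

**TPE tuner.** Completed trials are split at quantile γ into good/bad
sets; kernel densities l(θ) and g(θ) are fit to each (truncated-Gaussian
mixtures with a uniform prior component; Laplace-smoothed frequencies
for categoricals) and the next configuration maximizes l/g — Bayesian
optimization θ* = argmax f(θ) without a Gaussian-process surrogate.

**Simulator.** Because every constraint has a known optimum on synthetic
data, the package ships a cohort generator: per-genotype logistic or
Gompertz local traits, globals produced by an exact linear aggregation
(so hierarchy and consistency hold exactly before noise), seasonal
environments in physical units, 4 growth stages × 4 condition classes =
16 labels, and patch-grid pseudo-images whose leaf regions carry an
affine encoding of the traits.

## Worked example

`examples/03_constrained_training.py` trains the full pipeline on a
100-plant, 20-step cohort with and without the hierarchy hinge:

```
lambda_struct=0.05: held-out hierarchy violations 4.6% | leaf-area RMSE 17.66 cm^2 | final loss 4.221
lambda_struct=0   : held-out hierarchy violations 6.5% | leaf-area RMSE 17.61 cm^2 | final loss 4.169
```

With the constraint active, the fraction of held-out predictions where
leaf area impossibly exceeds canopy area drops from 6.5% to 4.6% while
reconstruction accuracy is unchanged — the penalty removes implausible
outputs rather than trading them against fit. The other examples cover
cohort simulation, growth-parameter recovery (`r̂` exact on noiseless
trajectories, 1.6% median error at 2%-of-K noise), TPE search (best x
0.3024 against a true optimum of 0.3 in 60 trials), and deterministic
trait-to-text rendering.

A thin CLI wraps the same functions:

```bash
pdgn simulate --seed 0 --out runs/sim
pdgn evaluate --config cfg.yaml --seed 0 --out runs/eval   # train + metrics
pdgn tune     --config cfg.yaml --seed 0 --out runs/tune
pdgn describe --config cfg.yaml --seed 0 --out runs/txt
```

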