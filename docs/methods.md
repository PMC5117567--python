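# Methods

This note documents the models, algorithms, defaults and design choices in
`uncertime`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and what
a passing test does and does not establish.

## 1. Probabilistic pseudotime (GPLVM)

### Model

Cells are observed as N points x_i in a P-dimensional embedding (P = 2
throughout; PCA or Laplacian eigenmaps, or any externally supplied
coordinates). Each embedding dimension j is modelled as a Gaussian-process
function of a latent pseudotime t_i ∈ [0, 1):

- γ ~ Gamma(γ_α, γ_β), shape–rate, so E[γ] = γ_α/γ_β;
- λ_j ~ Exponential(γ) — inverse squared length-scales;
- σ_j² ~ InvGamma(α, β) — per-dimension noise variances;
- t_i ~ TruncNormal_[0,1)(μ_t, σ_t²), with the truncation constant included
  in the density;
- K⁽ʲ⁾(t, t′) = exp(−λ_j (t − t′)²), a unit-amplitude squared-exponential
  kernel;
- the GP mean functions are marginalized analytically, leaving
  X_{·j} | t ~ N(0, K⁽ʲ⁾ + σ_j² I).

Because the kernel amplitude is fixed at 1, the embedding must be
standardized (zero mean, unit sd per dimension) before fitting;
`standardize()` does this and `sample_posterior` documents it as a
precondition. |λ| plays the role of trajectory arc-length: increasing the
shrinkage prior on γ pulls λ down and produces smoother mean trajectories.
This is verified directionally in the test suite (posterior mean of Σλ_j
decreases from (γ_α, γ_β) = (3, 1) to (30, 5)).

Defaults: (γ_α, γ_β) = (30, 5) — the high-shrinkage regime in which
independent chains agree on the mean trajectory; α = β = 1 (diffuse noise
prior); μ_t = 0.5, σ_t² = 1 (nearly flat over [0, 1), symmetric so the
model is exactly invariant under t → 1 − t).

### Inference

No probabilistic-programming backend is available in the supported
environment, so the sampler is implemented here directly:

- **Parameterization.** All parameters are mapped to an unconstrained
  space — logit(t), log λ, log σ², log γ — with the change-of-variables
  Jacobian included. Gradients of the GP marginal likelihood are computed
  analytically via the standard identity
  d logL = ½ tr((αα′ − C⁻¹) dC), α = C⁻¹x, and are unit-tested against
  finite differences.
- **Sampler.** Hamiltonian Monte Carlo with: leapfrog integration
  (trajectory length drawn uniformly from 5–15 steps), dual-averaging
  step-size adaptation toward 0.8 acceptance, and a diagonal mass matrix
  estimated from the first warmup window. Divergent trajectories
  (non-finite density, |z| > 50) are rejected. An adaptive random-walk
  Metropolis fallback (`method="rw"`) is provided for debugging; the
  contract is "draws from the model posterior", not a specific algorithm.
- **Defaults.** 2 chains, 1000 warmup + 1000 retained draws each, thinning
  1; the seed is required and all chain RNGs are spawned from it, so runs
  are bit-reproducible.
- **Initialization.** Chains start from the rank order of the first
  embedding coordinate (the standard PC1 heuristic), with even-numbered
  chains ascending and odd-numbered chains descending plus per-chain
  jitter. The posterior over orderings is multimodal; a purely random
  initialization (`init="prior"`) is available but mixes into the dominant
  ordering mode much more slowly. Starting the chains in *opposite*
  orientations keeps the multi-chain agreement check honest.
- **Numerics.** The kernel gets 10⁻⁶ jitter on the diagonal; Cholesky
  failures escalate the jitter ×10 up to 10⁻³ before raising. Likelihoods
  are computed by Cholesky factorization, never explicit inversion.
- **Diagnostics.** Split-R̂ and effective sample size per parameter (via
  arviz). Chains are first aligned to a common orientation (the model is
  exactly t → 1 − t symmetric, so unaligned chains would report the
  reversal symmetry as a mixing failure). R̂ > 1.1 attaches a warning to
  the result and emits a RuntimeWarning — never silent. A single chain is
  split in half for the same diagnostics.

### Summaries

- **Orientation** is unidentifiable; `orient_and_map` flips each draw
  t → 1 − t when it anticorrelates with a user-supplied per-cell anchor
  covariate (default in the pipeline: the first embedding dimension), or
  when a cell declared "early" lands in the second half. Idempotent.
- **MAP** is the retained draw with the highest joint log density — a point
  summary of the same MCMC run, not a separate optimization.
- **HPD intervals** use the empirical shortest-interval method (Chen–Shao):
  the narrowest window containing ⌈mass·S⌉ sorted draws. Requires ≥ 20
  draws.
- **Predictive densities** average the per-dimension GP conditional normal
  (mean k*ᵀC⁻¹x, variance 1 − k*ᵀC⁻¹k* + σ_j²) over posterior draws, and —
  for the unconditional version — over pseudotimes drawn from the prior.

## 2. Sigmoidal switch differential expression

Per gene, y_j ~ N(μ(t_j), σ²) with μ(t) = 2μ₀/(1 + exp(−k(t − t₀))). The
constant-mean null is the k = 0 slice of the alternative, so the LRT
statistic 2(ℓ₁ − ℓ₀) is referred to χ²(2) (the alternative adds k and t₀).

- The null MLE is closed-form (μ̂₀ = ȳ, σ̂² the mean squared deviation).
- The alternative profiles σ² analytically and optimizes (μ₀, k, t₀) by
  L-BFGS-B with analytic gradients, bounds μ₀ ≥ 0, t₀ ∈ [0, 1], k free,
  from the start grid t₀ ∈ {0.1, …, 0.9} × k ∈ {±1, ±10, ±50}; best final
  log-likelihood wins, ties broken by smallest |k|. **All 54 starts are
  refined by default**: restricting refinement to the best few
  coarse-screened starts makes the null distribution of the statistic
  conservative (the global alternative optimum is missed on null data,
  deflating the LRT), which breaks type-I calibration. `n_refine` exists
  as an explicit speed knob for large posterior sweeps, with that caveat.
- Zero-variance genes and optimizer failures are reported with
  `converged=False` and p = 1, never dropped.
- Multiple testing: Benjamini–Hochberg step-up (statsmodels), applied
  jointly over retained genes, within each pseudotime draw.

Calibration on 500 simulated null genes: type-I error at 5% is 0.064 and
the KS distance of the p-values from uniform is 0.045 (recomputed in the
acceptance tests).

## 3. Posterior uncertainty propagation

- `de_across_samples` refits the test on each retained posterior ordering
  (evenly thinned to a cap, default 100 draws — the sweep is O(S × G)
  optimizations) with BH within draw.
- `classify_robustness`: robust iff q_MAP < α and the gene is significant
  in ≥ τ of draws; unstable iff q_MAP < α only; defaults α = 0.05,
  τ = 0.95.
- `activation_posterior` collects per-draw alternative MLEs of (k, t₀);
  medians and 95% HPD intervals over converged fits. Note that for a
  saturated switch the steepness k is only weakly identified upward, so
  its *absolute* CI can be wide; the informative contrast with non-switch
  genes is the CI width relative to the median strength.
- `ordering_probability(a, b)` is the fraction of aligned draws with
  t₀(a) < t₀(b); exact ties count ½ so the two directions always sum to 1.

## 4. Point-estimate baseline and stability experiments

- `mst_pseudotime`: Euclidean minimum spanning tree over cells; the
  diameter path (double BFS) carries normalized cumulative distance as
  pseudotime; off-path cells inherit the value of the diameter vertex
  through which their tree branch attaches. Output spans [0, 1]; direction
  is arbitrary.
- `subsample_stability`: B random subsets of a fraction of cells (defaults
  80%, B = 30), pseudotime refitted per subset by the MST baseline, the
  GPLVM posterior mean, or the full PCA → GPLVM → robust-DE pipeline
  (which additionally accumulates, per gene, the number of subsamples in
  which it is classified robust). Each subsample's estimate is oriented
  against the full-data first principal component so the arbitrary
  direction does not inflate spreads. Reported per cell: appearances,
  mean, sd and the 2σ spread.

## 5. The synthetic world

The generator emulates the structure of published single-cell
differentiation datasets at desk scale: N ≈ 60–400 cells; true pseudotimes
uniform on [0, 1) (truncated-normal optional); a smooth non-self-intersecting
half-circle mean trajectory scaled to the unit box, with isotropic Gaussian
scatter (default sd 0.05); log₂ expression with a configurable fraction
(default 20%) of sigmoidal switch genes (|k| ∈ [5, 20], t₀ ∈ [0.2, 0.8],
μ₀ ∈ [1, 4]) among constant-mean genes, Gaussian noise (default sd 0.5),
clamped at 0 because log₂(counts+1) data are nonnegative.

What it does **not** emulate: count-level noise (negative binomial,
dropout/zero inflation), heteroscedastic scatter along the trajectory,
batch structure, bifurcations, or non-sigmoidal temporal profiles. A green
test therefore establishes correctness of the inference machinery on
on-model data, not robustness to the full messiness of real scRNA-seq;
the clamp at 0 is the one deliberate off-model feature and is mild at the
default noise levels.

## 6. Known limitations

- O(N³) Cholesky per likelihood evaluation: hundreds of cells are
  comfortable, thousands are not (no sparse/variational approximations by
  design).
- Single non-bifurcating trajectories only.
- The ordering posterior is multimodal; with very noisy embeddings the
  chains can disagree (this is reported via R̂, and is a finding about the
  data, not suppressed).
- The LRT's χ²(2) reference is asymptotic; at very small N (< ~50 cells)
  p-values become conservative.
- Laplacian eigenmaps use a binary symmetric k-NN graph and the normalized
  Laplacian — the simplest standard form; heat-kernel weights are not
  implemented.
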