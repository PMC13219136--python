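# Methods

## Model

### Decision process and moment equations

Each participant–condition cell is modeled as an unbiased Wiener diffusion:
evidence starts at α/2, accumulates with drift ν (signed) and diffusion
coefficient s between absorbing boundaries 0 and α; a response is correct
when the upper boundary is reached, and RT = first-passage time + τ. The
diffusion coefficient is a model-wide constant fixed at **s = 1**: the
parameter ranges used throughout (α ∈ [2,4], |ν| ≤ 3, τ ∈ [0.2,0.4] s)
produce second-scale RTs only under this scaling (the Ratcliff s = 0.1
convention would put RTs in the 100-second range).

`forward_moments` implements the closed-form accuracy/mean/variance of this
process (see README); with k = αν/s², a series branch for |k| < 1e−3
(`MRT = τ + α²/4s² − α⁴ν²/48s⁶`, `VRT = α⁴/24s⁴ − α⁶ν²/160s⁸`, relative
truncation error O(k⁴) < 1e−12) keeps both outputs continuous through ν = 0
and avoids the ν³ cancellation. `inverse_ez` is the exact closed-form
inverse; round-trip error is < 1e−8 across the study ranges. An optional
trial-count argument enables the classical edge correction (pc ∈ {0, ½, 1}
→ 1/2n, ½ + 1/4n, 1 − 1/2n); it is used only for starting values and
diagnostics, never inside the likelihood. The ½ + 1/4n direction is a
convention (the nudge direction is arbitrary at exactly chance accuracy).

### Trial sampling

`sample_trials` draws from the exact first-passage distribution rather than
discretizing the SDE: Euler–Maruyama has an O(√dt) boundary-overshoot bias
(≈ 0.02 s in mean RT at α = 2 with dt = 1e−3) that is an order of magnitude
larger than the Monte-Carlo standard error at n = 1e5, the scale at which
the sampler is validated. Because the start point is unbiased, decision
time and boundary choice are independent, so accuracy is a Bernoulli(Pc)
draw and decision times come from the common marginal density

    g(t) = (2 cosh(νa/2) / a²) · exp(−ν²t/2) · f₁(t/a²),   a = α/s, ν → ν/s

where f₁ is the zero-drift two-boundary density at relative start ½,
evaluated by its small-time representation below scaled time 0.1 (11 image
terms) and its large-time eigenfunction series above it (12 terms, both
converged far past double precision at the switch point). The density is
tabulated on an 8192-point grid reaching survival mass < 5e−12 (grid length
26/λ with λ = ν²/2 + π²/2a² the slowest tail rate), turned into a CDF by
trapezoid, and inverted by linear interpolation. Validation: sampled
moments match the closed forms within 3 standard errors at n = 1e5 across
parameter sets spanning the study ranges, and a 30-replicate pooled z-test
of the mean shows no detectable bias.

### Synthetic data

`draw_population` draws (μν, μα, μτ) uniformly per named preset — `main`:
μν ~ U(−3,3), μα ~ U(2,4); four follow-up presets crossing μν low/high
(U(0,1) / U(2,3)) with μα low/high (U(2,2.5) / U(3.5,4)); μτ ~ U(0.2,0.4)
always — with dispersions fixed study-wide at σν² = 0.75, σα² = 0.5,
στ² = 0.1. `draw_individuals` samples the hierarchy (README); because
στ ≈ 0.32 with μτ ≤ 0.4 puts non-negligible normal mass below zero, α_p is
resampled until positive and τ_p until ≥ 0.05 s (tau_floor). Resampling
(rather than clipping) keeps the bulk of the stated distributions intact;
the small truncation is a deliberate deviation from the pure normals, which
cannot feed a first-passage process.

`contaminate` replaces exactly round(rate·T) trials (default rate 0.05) per
participant-by-condition cell, chosen uniformly without replacement. Each
replaced trial is independently, with probability ½, a *delayed startup*
(original RT + U(2,3) s, accuracy kept) or a *guess* (rt and accuracy
redrawn from a zero-drift process with the participant's own α_p, τ_p).
All other trials are returned bit-identical, so a contaminated dataset
shares 95% of its records with its clean counterpart.

What the generator does **not** emulate: across-trial parameter
variability (sv, sz, st), response bias, RT censoring/truncation, fast
guesses below the non-decision time, fatigue or practice drifts, or any
non-stationarity. Passing tests therefore demonstrate robustness to this
specific two-component contaminant mixture, not to every irregularity of
real data.

### Proxy likelihood and priors

Each cell contributes three terms at its predicted moments (Pc, MRT, VRT):
Binomial(n_total, Pc) for the correct count, Normal(MRT, VRT/n) for the
location statistic, Normal(VRT, 2VRT²/(n−1)) for the scale statistic. These
are the exact sampling distributions of the mean and (asymptotically) the
variance under normality; the robust variant plugs the median and Var_IQR
into the *identical* structure, leaning on their shared asymptotic targets.
The n−1 convention in the scale term matches the unbiased sample variance.

RT statistics can be computed over correct trials only (the classical EZ
convention, the library default) or over all trials. The study runner
defaults to **all trials**: with μν ~ U(−3,3), below-chance cells are
common, and at T = 20 a cell can easily have fewer than four correct
trials, leaving quartiles undefined; since the unbiased start point makes
the RT distribution identical for correct and error responses, all-trials
summaries estimate the same moments without that fragility. The choice is
recorded in every result file.

Hyperpriors (the validation studies state none, so these are the package's
weakly informative defaults, covering the generating ranges): μν ~ N(0,2²),
β ~ N(0,1²) (also the Savage–Dickey reference density), μα ~ N(3,1²)
truncated > 0, μτ ~ N(0.3,0.25²) truncated > 0, and half-Normal(1) on
σν, σα, στ. Individual parameters are kept latent and sampled; the support
constraints α_p > 0, τ_p ≥ 0 are enforced by proposal rejection.

## Posterior sampling

The sampler is a numba-compiled adaptive Metropolis-within-Gibbs chain,
default 4 chains × (1000 warmup + 1000 draws) for `fit`:

- **(μν, β)**: exact conjugate joint Gibbs (2-dim normal linear model),
  which is why the effect-size parameter always mixes essentially perfectly
  (ESS ≈ 3000, split-R̂ ≤ 1.005 in every fit we have inspected).
- **μα, μτ**: conjugate Gibbs with rejection against the positivity
  truncation.
- **log σν, log σα, log στ**: adaptive random-walk Metropolis (target
  acceptance 0.44) with the log-scale Jacobian.
- **Individuals**: component-wise adaptive RW plus, after a third of
  warmup, per-participant joint 4-dim proposals from the warmup-estimated
  covariance of (ν_p0, ν_p1, α_p, τ_p) (adaptive Metropolis, target 0.23).
  At ceiling accuracy the per-participant posterior is a narrow ridge —
  the binomial term saturates and only the two RT statistics constrain
  three parameters — which component-wise moves cannot walk.
- **Collective boundary moves**: two scaling moves with exact Jacobians
  address the slow collective mode in the spread of α_p (which carries
  σα): (i) spread scaling α_p → μα + c(α_p − μα) with σα → cσα, drift
  compensated to preserve each cell's predicted accuracy and τ_p to
  preserve mean predicted RT; (ii) whole-hierarchy scaling of (μα, σα,
  α_p) by c with ν → c^{1/3}ν, which preserves predicted RT variance in
  the accuracy-saturated regime. Both adapt toward 0.23 acceptance.

All step sizes and covariances are frozen at the end of warmup, so the
post-warmup kernel is Markovian. Chains are deterministic given the seed
(per-chain seeds from a `SeedSequence`); overdispersed starts come from
jittered method-of-moments (edge-corrected EZ inversion) estimates.

Convergence is assessed with split-R̂ and bulk ESS (arviz) on all seven
hyperparameters; a fit with any R̂ > 1.05 is returned flagged, never
silently. **Known limitation**: in the extreme ceiling-accuracy regime
(high-drift presets, where most cells are at ~100% accuracy), σα mixes
slowly even with the collective moves; at the study-runner settings
(warmup 3000, thin 3, ≈ 1.4 s per fit on one CPU) about 80% of such fits
meet the 1.05 threshold and the flagged remainder fail almost exclusively
on σα (worst observed R̂ ≈ 1.3). β is unaffected. Flagged fits are
retained in study outputs, marked in the `converged` column.

## Decision statistics and evaluation

`z_abs` = |posterior mean β| / posterior sd β is the study default: ROC
construction needs only an ordering, and any monotone transform leaves the
ROC unchanged. `savage_dickey_bf10` (prior over posterior density of β at
0, posterior via normal approximation) is provided for Bayes-factor
reporting; the two give identical AUCs by the invariance property.

AUC uses the rank (Mann–Whitney) formulation with ties counted ½,
identical to the trapezoidal area under the threshold-swept curve; the
AUC of a null set against itself is ½ exactly by construction, which is the
convention used at β = 0. Bias is reported as **estimate − truth**
(negative = underestimation; headers record the convention), RMSE as
√mean((estimate − truth)²), so RMSE² = bias² + error variance. Binned
follow-up summaries (`bin_by_truth`) use equal-width bins over the true μν
range, score each bin's effect replicates against the pooled null, and
report empty bins as missing rather than fabricating values.

## Study harness and problem sizes

Each replicate of a design cell draws one truth, one clean dataset, one
contaminated counterpart, and fits the 2 × 2 grid (clean/contaminated ×
standard/robust) on shared data. Per-replicate seeds derive from
`SeedSequence([master, P, T, 1000β, preset, replicate])`, so any execution
order — or a rerun of one cell in isolation — is bit-reproducible.

The published-scale design (4 × 5 × 4 grid × 1000 replicates, and 1000-
replicate follow-ups at P = 160) is expressible via `StudyConfig` but is
cluster-scale. The package's own validation batteries are desk-scale by
design: 20 replicates at P = 40, T = 80 for clean-data recovery, and 30
replicates per effect size at P = 40, T = 40 (high-drift preset) for the
robustness ordering — sizes chosen so the full battery completes in
minutes on one CPU while leaving the qualitative contrasts far above
Monte-Carlo noise (the contaminated-standard AUC deficit is ≈ 0.22 against
a pairwise Monte-Carlo error of ≈ 0.05).

## Numerical conventions and degenerate inputs

- Quartiles: linear interpolation of order statistics (numpy default,
  "type 7"); median = midpoint of central order statistics for even n.
  Cells need n ≥ 4 so quartiles are defined by interpolation; smaller
  cells raise.
- Pc is clipped to [1e−15, 1 − 1e−15] inside the likelihood so all-correct
  cells remain finite; parameter proposals outside the support (α ≤ 0,
  τ < 0, σ ≤ 0) are rejected.
- Zero posterior sd of β (impossible in practice) raises rather than
  returning an infinite statistic.
- Contamination rates outside [0, 0.5] and re-contamination of an already
  tagged dataset raise.
- At rate 0.05 every study T (20…320) gives an integer contaminant count;
  the round() rule only matters for non-study rates.
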