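# Methods

## The decision model

`antdrift` models two-choice flanker decisions as a Wiener diffusion
process: evidence accumulates from a starting point `z_rel * a` between
absorbing boundaries at 0 (error) and `a` (correct) with mean rate `v`
(the drift rate) and unit diffusion coefficient; the observed response
time adds a non-decision offset `t0` for stimulus encoding and motor
execution.  Responses are accuracy-coded (upper boundary = correct),
which is appropriate because left/right responses are counterbalanced
and the starting point is fixed unbiased at `z_rel = 0.5`.

**Diffusion-scale convention.** All parameters use the unit-scale
convention (s = 1), not the s = 0.1 convention of some of the
literature.  Drift and boundary magnitudes are therefore ~10x larger
than s = 0.1 values; only the products `v*a` and ratios are
convention-free.  This matters when comparing numbers across toolboxes
and is the single most common source of cross-implementation confusion.

**Likelihood.** The first-passage density is evaluated with the two
classical series expansions (image-charge sum for small scaled time,
spectral sine series for large), choosing per evaluation whichever
needs fewer terms for the requested truncation error (`eps = 1e-6` by
default).  A fixed-weight contaminant mixture — uniform on
(0, `rt_max` = 3 s, the task response window) with a fair coin for the
choice — absorbs fast guesses and lapses; the analysis default is
`p_outlier = 0.05`.  With the contaminant the log-likelihood is finite
for any response time in the window, which keeps MCMC well-behaved when
`t0` proposals exceed an observed RT.

**Reference sampler.** Trials are simulated by Euler–Maruyama with
`dt = 1e-4 s`.  Discrete barrier monitoring systematically misses
crossings between steps; the sampler therefore monitors the path
against barriers inset by `0.5826 * sqrt(dt)` (the
Broadie–Glasserman–Kou continuity correction), which cancels the
first-order discretization bias.  Without the correction the mean
decision time is biased upward by about 0.7% at `dt = 1e-4`, which is
detectable at Monte-Carlo sample sizes of 1e5.  Closed forms for the
absorption probability, `1/(1 + exp(-v a))` at an unbiased start, and
the mean decision time, `(a/2v) tanh(v a / 2)`, serve as independent
oracles for both the density and the sampler.

## The synthetic cohort

The generator reproduces the statistical structure of a scanner-based
attention (flanker) study with three conflict conditions (congruent,
incongruent-EASY, incongruent-HARD):

* **Schedule** — 36 trials per run, 5–6 runs per subject (reduced-size
  studies may schedule fewer), 200 ms cue, 3 s response window, and two
  fixed delay multisets (12 cue–target values 0.70–3.20 s, 12
  target–cue values 4.30–8.30 s), each value used exactly three times
  per run in random order.  Because the multisets are fixed, the task
  portion of every run lasts exactly 280 s and always fits a
  156-volume, TR = 1.92 s acquisition.  Conditions are split 12/12/12
  per run (the split is not dictated by the emulated task description;
  equal allocation is assumed).
* **Groups** — healthy controls, Alzheimer's disease (AD) and Lewy body
  dementia (LBD).  Default generating values (invented configuration
  chosen once to reproduce the qualitative orderings the analysis
  targets, not fitted to any dataset): drift per condition
  Control (2.8, 2.2, 2.0), AD (2.0, 1.5, 1.3), LBD (1.6, 1.1, 0.9);
  boundary 2.0 for controls and 1.5 for both patient groups
  (condition-constant by default); non-decision time 0.35 / 0.45 /
  0.55 s; between-subject SDs 0.3 / 0.2 / 0.05 for drift / boundary /
  t0.  Subjects deviate from their group by a single additive offset
  per parameter, so condition effects are genuinely group-level — the
  same structure the hierarchical model estimates.  A separate
  `model_selection_groups()` configuration adds +0.25 / +0.5 boundary
  increments under conflict for model-comparison studies in which both
  parameters truly vary.
* **Coupling** — per-trial standard-normal network activations
  (default-mode and dorsal-attention) shift the drift linearly:
  `b_dorsal = +0.3` in every group; `b_default` = +0.1 (Control),
  +0.05 (AD), -0.2 (LBD).  Activations are recorded as ground truth so
  coupling recovery can be scored.
* **Censoring** — simulated RTs exceeding the 3 s window are emitted as
  censored records (`response = -1`), so the inclusion filters
  (5–6 runs, >= 70% correct, <= 10% missed) operate on realistic input.
* **BOLD runs** — the network time course is
  `baseline * (1 + x/100)` with `x` summing HRF-convolved stick
  responses at target onsets (amplitude `1.0 + 1.0 * z` percent signal
  for activation `z`), a low-frequency drift confined to the span of
  the 128 s high-pass basis, a linear leak of the six random-walk
  motion regressors, and AR(1) noise (innovation SD 0.5% signal,
  rho = 0.3).  These SNR defaults were chosen once as a favourable but
  plausible single-trial regime; empirical single-trial betas from real
  data are substantially noisier, so beta-level results here bound what
  real data could show.  Because the drift lives inside the high-pass
  span and motion enters through the modelled regressors, a noiseless
  run is recovered exactly — a sharp correctness oracle for the GLM.

What the generator does *not* emulate: volumetric images and spatial
preprocessing, physiological noise structure beyond AR(1),
condition-dependent BOLD amplitudes, slow drifts outside the high-pass
span, and any relationship between head motion and diagnosis.  Passing
tests therefore demonstrate correctness of the estimation machinery
under the stated generative assumptions, not robustness to real-data
violations of them.

## Hierarchical estimation

Each diagnostic group has its own hyper-distributions (mean and SD) for
subject-level drift, boundary and non-decision time, so group
posteriors can be compared directly.  Condition effects are
treatment-coded indicator coefficients (incongruent-EASY,
incongruent-HARD) against the congruent baseline, estimated at the
group level; the three standard variants let drift only, boundary only,
or both vary by condition.  Trial-wise covariates (z-scored beta
series) enter the drift with one coefficient per group shared across
subjects, avoiding collinearity between subject drifts and subject-level
slopes.

**Priors** (the emulated analysis reports none; these follow common
toolbox practice and are configurable): group-mean drift N(2, 3^2);
group-mean boundary N(1.5, 1^2) truncated to (0.3, 4); group-mean t0
N(0.3, 0.25^2) truncated to (0.05, 1); group SDs half-normal(1);
condition effects N(0, 2^2); covariate coefficients N(0, 1).
Subject-level parameters are normal around their group with fixed
support bounds (drift ±8, boundary (0.05, 6), t0 (0.005, 2)); because
the bounds are constants, the implied truncation constants cancel in
the Metropolis ratio.

**Sampler.** Adaptive Metropolis-within-Gibbs: every scalar gets a
Gaussian random-walk proposal; scales adapt every 50 sweeps during
burn-in toward ~0.3 acceptance and are frozen afterwards, so retained
draws come from a fixed kernel.  Single-site updates alone mix slowly
through the hierarchical funnel (a group SD near zero pins all its
subjects), so each sweep adds two joint moves per group and parameter:
a location move translating the group mean together with all its
subjects, and a scale move multiplying the group SD and all subject
deviations by a common factor (with the Jacobian term in the
acceptance ratio).  These moves traverse the group-level directions
the single-site sweep explores only diffusively.  Chains (>= 2) start from
data-informed, chain-overdispersed initializations (crude
logit-accuracy drift, RT-quantile t0) with bounded retries on
non-finite posteriors.  Per-block likelihood caching plus a compiled
kernel that evaluates a subject-condition block in one call makes a
full desk-scale fit (45 subjects x 216 trials, 2 chains x 5000 sweeps)
run in under two minutes on one CPU.  Convergence is monitored with the
split-chain Gelman–Rubin statistic (R-hat < 1.1).  The sampler driver
is validated end to end on a conjugate normal-mean reference model with
a closed-form posterior, and by a prior-recovery null (no data →
posterior = prior, Kolmogorov–Smirnov).

Desk-scale MCMC (5000 sweeps, 2000 burn-in, no thinning, 2 chains) is
the default; the emulated study's single-run settings (95 000 samples,
35 000 burn-in, thinning 5) are available as `MCMCConfig.paper_preset()`.

## Model evaluation

* **DIC** = mean posterior deviance + pD, with pD = mean deviance minus
  deviance at the per-parameter posterior mean (computed on the
  sampling scale; pD is parameterization-dependent and this choice is
  deliberate and documented).  Stored per-draw likelihoods make DIC
  essentially free after sampling.
* **Posterior predictive checks** simulate full replicate datasets on
  the observed design from posterior draws (default 500; desk runs use
  fewer) and compare accuracy and RT deciles per group x condition via
  percentile ranks.  PPC simulation uses the Euler–Maruyama sampler at
  `dt = 1e-3` — summary statistics are insensitive to the coarser step
  and it keeps 500-draw checks fast.
* **Overlap P** between two group posteriors is the paired-difference
  tail mass: shuffle both draw streams (seeded), pair them, and report
  `100 * min(Pr(diff > 0), Pr(diff < 0))`; P < 5 is read as a credible
  difference.  The phrase "percentage of overlap" is genuinely
  ambiguous; a density-overlap variant (overlapping coefficient of the
  two KDEs) is implemented behind `method="density"`, with the tail
  mass as default because it is the convention of the hierarchical-DDM
  community.
* **Probability of non-zero** for a coefficient is
  `100 * max(Pr(>0), Pr(<0))` with P > 95 flagged.

## Beta-series estimation

Each trial's target event is a stick regressor (duration 0 — trial
durations vary with RT and modelling them is not attempted) convolved
with a canonical double-gamma HRF (gamma shapes 6 and 16, undershoot
ratio 1/6, peak normalized to 1).  The run-level design adds six motion
covariates, an intercept, and `floor(2 * run_length / 128)`
discrete-cosine components (4 for a 299.52 s run), implementing the
128 s high-pass cutoff.  The time course is scaled to percent signal
change about the run mean — the generating amplitudes are therefore
reported on the same percent-of-run-mean scale (`amplitudes_psc`) that
the estimator measures.  Ordinary least squares yields one beta per
trial; optional prewhitening estimates a single pooled AR(1)
coefficient from OLS residuals and applies a Cochrane–Orcutt transform
(off by default on the synthetic path; the emulated analysis used a
global AR(1)).  Rank-deficient designs fall back to a tiny ridge
penalty with a warning.  Betas are z-scored per subject across all runs
before entering the drift regression (the per-network series of one
subject is pooled over runs; per-run scoping would discard
between-run variance).

QC mirrors standard practice: mean/max frame-to-frame translation and
rotation (Euclidean norm of the first differences), and standardized
DVARS — per-transition RMS of the temporal derivative over voxels,
divided by its expected value under stationary noise computed from the
half-IQR-based robust variance of the frame differences, so clean data
average ~1.  The exact standardization of the scripts referenced in the
emulated study is not public; the robust-variance form is a documented
approximation.

## Numerical and design choices

* Truncation tolerance of the first-passage series: `eps = 1e-6`;
  normalization of upper + lower defective densities verified to 1e-4
  over a (v, a) grid.
* Effective boundaries `a_subject + condition effect` must exceed 0.05
  evidence units; proposals below are rejected (impossible model).
* Group SDs have a floor of 1e-3 to avoid degenerate hierarchies.
* Recovery "bias" for group-mean drift is measured against the realized
  mean of the simulated subjects' true parameters (the finite-sample
  estimand); credible-interval coverage is scored against the
  population-level generating values.
* Per-stage pipeline seeds derive from the master seed by spawning one
  `SeedSequence` child per stage in a fixed documented order, so every
  artifact is reproducible from (config, master seed) and stages cannot
  leak randomness into each other.
* The pipeline stamps every run directory with a hash of the full
  configuration; artifacts from a different configuration are
  recomputed, never reused.

## Problem sizes

Default study sizes used by the examples, tests and the acceptance
script: 3 groups x 15 subjects x 216 trials for recovery and
group-contrast analyses (desk-scale MCMC, 2 chains x 5000 sweeps);
3 replicates of 3 groups x 5 subjects x 108 trials for the DIC
model-selection study; 36-trial single runs for beta-series recovery;
1e5–2e5 trials for the Monte-Carlo oracles.  These sizes give each
check a comfortable signal-to-noise margin while keeping a full
desk run in the minutes range.

## Known limitations

* The sampler is random-walk Metropolis; it is validated for the model
  sizes used here but would mix slowly on much larger hierarchies where
  gradient-based samplers are preferable.
* Inter-trial variability parameters (sv, st, sz) of the full Ratcliff
  model are deliberately not implemented — the emulated analysis uses
  none.
* Stimulus coding (left/right) is not implemented; accuracy coding is
  assumed throughout.
* The overlap statistic's two variants can disagree in magnitude
  (tail mass vs overlapping coefficient); only the significance
  convention (P < 5) is shared.
* DIC is reported as defined above; WAIC/LOO are out of scope.
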