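# antdrift

Hierarchical drift-diffusion analysis of a scanner-based attention
(flanker) task, with trial-wise brain-network covariates — built as a
fully synthetic, reproducible study replica.

## The scientific problem

Attention deficits in Lewy body dementia (LBD) are clinically prominent
but coarsely measured.  Drift-diffusion models (DDMs) decompose
two-choice reaction-time performance into interpretable sub-processes:
the **drift rate** *v* (quality of sensory evidence accumulation), the
**decision boundary** *a* (response caution), and the **non-decision
time** *t0* (encoding and motor latency).  Comparing these parameters
between LBD, Alzheimer's disease (AD) and healthy controls — and
relating trial-by-trial drift fluctuations to activity in the default
and dorsal-attention brain networks — asks whether impaired evidence
accumulation specifically distinguishes LBD.

`antdrift` provides the complete analysis machinery for this design:

* **`antdrift.ddm`** — exact Wiener first-passage-time densities
  (small/large-time series expansions, unit diffusion scale s = 1),
  closed-form choice probabilities `1/(1+e^{-va})` and mean decision
  times `(a/2v)·tanh(va/2)`, and a bias-corrected Euler–Maruyama trial
  sampler, all with a 5% uniform-contaminant mixture.
* **`antdrift.cohort`** — a synthetic-cohort generator emulating the
  task (36 trials/run, 3 conflict conditions, the fixed cue–target and
  target–cue delay multisets, 3 s response window), three diagnostic
  groups with hierarchical parameter structure, drift-coupled trial-wise
  network activity, and raw network-averaged BOLD runs (TR 1.92 s,
  156 volumes).
* **`antdrift.hierarchical`** — hierarchical Bayesian estimation
  (per-group hyper-distributions, group-level condition effects
  v_{s,k} = v_s + b·Condition_k, group-level covariate coefficients
  v_{s,k} = v_s + b1·Condition_k + b2·BetaSeries_{s,k}) by adaptive
  Metropolis-within-Gibbs with split-chain R-hat diagnostics.
* **`antdrift.evaluate`** — DIC model comparison, posterior predictive
  checks, posterior-overlap tests (P < 5% ⇒ credible group difference)
  and probability-of-nonzero coefficients (P > 95% ⇒ credible effect).
* **`antdrift.betaseries`** — single-trial GLM (one HRF-convolved
  regressor per trial, six motion covariates, 128 s discrete-cosine
  high-pass, optional AR(1) prewhitening, percent-signal-change
  scaling, per-subject z-scoring) plus motion and DVARS QC.
* **`antdrift.pipeline` / the `antdrift` CLI** — the end-to-end study:
  simulate → filter (5–6 runs, ≥ 70% correct, ≤ 10% missed) → betas →
  fit 3 model variants → DIC → PPC → contrasts → regression → report.

See `docs/methods.md` for the model, priors, numerical choices and
limitations.

## Worked example

Simulate a reduced cohort (10 subjects per group, 5 runs of 36 trials),
fit the full model variant (drift and boundary condition-dependent) and
test the group contrasts (~3 minutes on one CPU):

```python
from antdrift import (default_groups, generate_cohort, build_model, ModelSpec,
                      MCMCConfig, sample_posterior, gelman_rubin,
                      reconstruct_condition_posteriors, posterior_overlap)
from antdrift.cohort import ScheduleConfig

table, truth = generate_cohort(default_groups(), 10, ScheduleConfig(n_runs=5), seed=1)
data = table[table["response"].isin([0, 1])]          # drop censored trials
model = build_model(ModelSpec(varies_by_condition=("v", "a")), data)
samples = sample_posterior(model, MCMCConfig(n_samples=5000, n_burn_in=2000, seed=1))
print(f"max R-hat: {gelman_rubin(samples).max():.3f}")
rec = reconstruct_condition_posteriors(samples)
for g in model.groups:
    v = rec[("v", g, "incongruent-HARD")].mean()
    a = rec[("a", g, "incongruent-HARD")].mean()
    print(f"{g:8s} hard-conflict drift {v:.2f} (true {truth['groups'][g]['drift'][2]}), "
          f"boundary {a:.2f} (true {truth['groups'][g]['boundary'][2]})")
P = posterior_overlap(rec[("v", "LBD", "incongruent-HARD")],
                      rec[("v", "AD", "incongruent-HARD")]).P
print(f"drift overlap LBD vs AD (hard): P = {P:.2f}%")
```

Output:

```
max R-hat: 1.025
Control  hard-conflict drift 1.86 (true 2.0), boundary 1.98 (true 2.0)
AD       hard-conflict drift 1.32 (true 1.3), boundary 1.52 (true 1.5)
LBD      hard-conflict drift 1.01 (true 0.9), boundary 1.61 (true 1.5)
drift overlap LBD vs AD (hard): P = 2.85%
```

All chains converge (R-hat < 1.1); the posterior group means recover
the generating values, and the overlap test separates the LBD group's
drift rate from AD (P = 2.85% < 5%) while their boundaries overlap —
the inference pattern this analysis is designed to detect.

The same study runs from the shell:

```bash
antdrift all --out-dir run --seed 1          # full pipeline, desk-scale MCMC
antdrift simulate --out-dir run --seed 1     # or stage by stage
```

producing a run directory with the cohort, exclusion report, draws,
DIC table, overlap matrix, PPC tables, density figures and `report.md`,
all stamped with the configuration hash and seed.

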