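"""Model comparison, posterior predictive checking and Bayesian tests.

* DIC — posterior mean deviance plus the effective parameter count
  pD = mean deviance minus deviance at the posterior mean; lower values
  indicate better fit at comparable complexity.
* Posterior predictive checks — datasets re-simulated on the observed
  design from parameter vectors drawn from the joint posterior, compared
  with the observed accuracy and reaction-time quantiles.
* Posterior overlap P — for two parameter posteriors, the tail mass of
  the paired-difference distribution (in percent); P < 5 is read as a
  credible group difference.  A density-overlap variant (overlapping
  coefficient) is available behind a switch.
* Probability-of-nonzero P — percentage of a coefficient's posterior on
  its dominant side of zero; P > 95 is read as a credible effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._wfpt import em_sample

__all__ = [
    "DICResult",
    "PPCSummary",
    "OverlapResult",
    "ProbNonzeroResult",
    "dic",
    "posterior_predictive",
    "posterior_overlap",
    "prob_nonzero",
]

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


class DICResult(NamedTuple):
    dic: float
    p_d: float
    mean_deviance: float
    n_excluded: int


def dic(samples, model) -> DICResult:
    """Deviance information criterion from stored per-draw likelihoods.

    D(theta) = -2 log L; pD = mean(D) - D(posterior mean), with the
    posterior mean taken per parameter on the sampling scale.
    Non-finite deviance draws are counted and excluded with a warning.
    """
    dev = -2.0 * samples.loglik.ravel()
    finite = np.isfinite(dev)
    n_excluded = int((~finite).sum())
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} non-finite deviance draws", stacklevel=2)
    mean_dev = float(dev[finite].mean())
    at_mean = -2.0 * model.log_likelihood(samples.posterior_mean())
    p_d = mean_dev - float(at_mean)
    return DICResult(dic=mean_dev + p_d, p_d=p_d, mean_deviance=mean_dev,
                     n_excluded=n_excluded)


@dataclass
class PPCSummary:
    """Observed vs posterior-predictive summaries per group x condition."""

    observed: pd.DataFrame   # group, condition, stat, value
    simulated: pd.DataFrame  # draw, group, condition, stat, value
    ranks: pd.DataFrame      # group, condition, stat, observed, rank_pct

    def coverage(self, lo: float = 2.5, hi: float = 97.5) -> float:
        """Fraction of observed summaries inside the central simulated
        interval [lo, hi] (percentile ranks)."""
        r = self.ranks["rank_pct"]
        return float(((r >= lo) & (r <= hi)).mean())


def _summarize(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (g, c), sub in df.groupby(["group", "condition"], sort=False):
        responded = sub[sub["response"].isin([0, 1])]
        rows.append({"group": g, "condition": c, "stat": "accuracy",
                     "value": float((responded["response"] == 1).mean())})
        rts = responded["rt"].dropna().to_numpy()
        for q in RT_QUANTILES:
            rows.append({"group": g, "condition": c, "stat": f"rt_q{int(q * 100)}",
                         "value": float(np.quantile(rts, q)) if rts.size else np.nan})
    return pd.DataFrame(rows)


def posterior_predictive(samples, model, data: pd.DataFrame, n_draws: int = 500,
                         seed: int = 0, dt: float = 1e-3) -> PPCSummary:
    """Simulate replicate datasets from posterior draws on the observed design.

    For each of ``n_draws`` randomly selected posterior parameter
    vectors, every observed trial is re-simulated with its subject's
    drawn parameters (condition effects and covariate terms included),
    censored at the response window like the observed data, and
    summarized as accuracy plus RT deciles per group x condition.  The
    percentile rank of each observed summary within its simulated
    distribution is returned.  Fixed seeds reproduce the tables exactly.
    """
    total = samples.draws.shape[0] * samples.n_draws
    if n_draws > total:
        raise ValueError("n_draws exceeds the number of retained posterior draws")
    rng = np.random.default_rng(seed)
    flat = samples.draws.reshape(total, -1)
    idx = rng.choice(total, size=n_draws, replace=False)

    spec = model.spec
    sim_frames = []
    col = {p: j for j, p in enumerate(samples.params)}
    for d, i in enumerate(idx):
        vec = flat[i]
        recs = []
        for s in model.subjects:
            g = model.subject_group[s]
            for ci, c in enumerate(model.conditions):
                rt_obs, _, X = model._blocks[(s, ci)]
                n = rt_obs.size
                if n == 0:
                    continue
                v = vec[col[f"v[{s}]"]]
                a = vec[col[f"a[{s}]"]]
                t0 = vec[col[f"t0[{s}]"]]
                if ci > 0 and "v" in spec.varies_by_condition:
                    v = v + vec[col[f"b_v[{g},{c}]"]]
                if ci > 0 and "a" in spec.varies_by_condition:
                    a = a + vec[col[f"b_a[{g},{c}]"]]
                drift = np.full(n, v)
                for j, cov in enumerate(spec.covariates):
                    drift = drift + vec[col[f"b_{cov}[{g}]"]] * X[:, j]
                em_seed = int(rng.integers(0, 2**31 - 1))
                rts, choices = em_sample(drift, np.full(n, max(a, 0.06)), 0.5, t0,
                                         dt, spec.rt_max, em_seed)
                contam = rng.random(n) < spec.p_outlier
                n_c = int(contam.sum())
                if n_c:
                    rts[contam] = rng.uniform(0, spec.rt_max, n_c)
                    choices[contam] = (rng.random(n_c) < 0.5).astype(np.int64)
                late = ~np.isfinite(rts) | (rts > spec.rt_max)
                choices[late] = -1
                recs.append(pd.DataFrame({"group": g, "condition": c,
                                          "response": choices, "rt": rts}))
        summ = _summarize(pd.concat(recs, ignore_index=True))
        summ.insert(0, "draw", d)
        sim_frames.append(summ)

    simulated = pd.concat(sim_frames, ignore_index=True)
    observed = _summarize(data)
    rows = []
    for _, row in observed.iterrows():
        sims = simulated[
            (simulated["group"] == row["group"])
            & (simulated["condition"] == row["condition"])
            & (simulated["stat"] == row["stat"])
        ]["value"].to_numpy()
        rank = 100.0 * float(np.mean(sims <= row["value"])) if sims.size else np.nan
        rows.append({"group": row["group"], "condition": row["condition"],
                     "stat": row["stat"], "observed": row["value"], "rank_pct": rank})
    return PPCSummary(observed=observed, simulated=simulated, ranks=pd.DataFrame(rows))


class OverlapResult(NamedTuple):
    P: float
    significant: bool
    method: str

    def __float__(self):
        return self.P


def posterior_overlap(samples_a, samples_b, seed: int = 0,
                      method: str = "tail") -> OverlapResult:
    """Overlap P (percent) between two posterior draw sets.

    ``method="tail"`` (default): randomly pair equal-length shuffled
    draw streams and report 100 * min(Pr(A-B > 0), Pr(A-B < 0)).
    ``method="density"``: overlapping coefficient of the two kernel
    density estimates.  P < 5 flags a credible difference.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("draw sets must be non-empty")
    if method == "tail":
        rng = np.random.default_rng(seed)
        m = min(a.size, b.size)
        diff = rng.permutation(a)[:m] - rng.permutation(b)[:m]
        p = 100.0 * min(float(np.mean(diff > 0)), float(np.mean(diff < 0)))
    elif method == "density":
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        pad = 0.2 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, 2048)
        fa = stats.gaussian_kde(a)(grid)
        fb = stats.gaussian_kde(b)(grid)
        p = 100.0 * float(np.trapezoid(np.minimum(fa, fb), grid))
    else:
        raise ValueError(f"unknown method {method!r}")
    return OverlapResult(P=p, significant=p < 5.0, method=method)


class ProbNonzeroResult(NamedTuple):
    P: float
    sign: int
    significant: bool

    def __float__(self):
        return self.P


def prob_nonzero(draws) -> ProbNonzeroResult:
    """Percentage of the posterior on its dominant side of zero.

    P = 100 * max(Pr(draw > 0), Pr(draw < 0)); the sign reports the
    dominant side; P > 95 flags a credible (non-zero) effect.
    """
    d = np.asarray(draws, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("draws must be non-empty")
    pos = float(np.mean(d > 0))
    neg = float(np.mean(d < 0))
    p = 100.0 * max(pos, neg)
    return ProbNonzeroResult(P=p, sign=1 if pos >= neg else -1, significant=p > 95.0)
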