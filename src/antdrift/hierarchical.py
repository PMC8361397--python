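"""Hierarchical Bayesian estimation of diffusion parameters.

Subjects' drift rate, boundary separation and non-decision time are
drawn from separate hyper-distributions per diagnostic group, so group
posteriors can be compared directly.  Condition effects on drift and/or
boundary are treatment-coded indicator coefficients (incongruent-EASY,
incongruent-HARD) against the congruent baseline, estimated at the group
level; per-trial covariates (z-scored network beta series) enter the
drift linearly with one coefficient per group, shared across that
group's subjects to avoid collinearity with the subject-level drifts.

Inference is adaptive Metropolis-within-Gibbs: every scalar parameter
gets a Gaussian random-walk proposal whose scale is tuned toward a
0.2–0.5 acceptance rate during burn-in and frozen afterwards, so the
retained draws come from a fixed kernel.  Two or more chains are run
from overdispersed initializations and convergence is monitored with
the split-chain Gelman–Rubin statistic (R-hat < 1.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._wfpt import loglik_cond
from .ddm import CONDITIONS

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "HDDMModel",
    "NormalMeanModel",
    "build_model",
    "sample_posterior",
    "reconstruct_condition_posteriors",
    "gelman_rubin",
]

_LOG2PI = math.log(2.0 * math.pi)

#: default priors (location, scale[, lower, upper]); the study this
#: emulates reports none, so these follow common toolbox practice
DEFAULT_PRIORS = {
    "mu_v": (2.0, 3.0),
    "mu_a": (1.5, 1.0, 0.3, 4.0),
    "mu_t0": (0.3, 0.25, 0.05, 1.0),
    "sigma": 1.0,  # half-normal scale for all group SDs
    "effect": (0.0, 2.0),
    "coef": (0.0, 1.0),
}

# hard support bounds for subject-level parameters (fixed, so the
# implied truncation constants do not affect the Metropolis ratio)
_SUBJECT_BOUNDS = {"v": (-8.0, 8.0), "a": (0.05, 6.0), "t0": (0.005, 2.0)}
_SIGMA_FLOOR = 1e-3


def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG2PI


@dataclass(frozen=True)
class ModelSpec:
    """Which diffusion parameters vary by condition, and the covariates.

    The three standard variants are ``("v",)`` (drift varies, boundary
    constant), ``("a",)`` and ``("v", "a")``.  Non-decision time is
    always constant across conditions and the starting point is fixed
    unbiased (z_rel = 0.5).  ``covariates`` names per-trial columns of
    the behavioural table entering the drift with group-level-only
    coefficients.  ``p_outlier`` is the fixed contaminant weight of the
    likelihood (5% in the emulated analysis).
    """

    varies_by_condition: tuple = ("v",)
    covariates: tuple = ()
    p_outlier: float = 0.05
    rt_max: float = 3.0
    eps: float = 1e-6
    priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def __post_init__(self):
        bad = set(self.varies_by_condition) - {"v", "a"}
        if bad:
            raise ValueError(f"only v and a may vary by condition, got {bad}")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  Desk-scale defaults; ``paper_preset`` gives the
    emulated study's 95 000 / 35 000 / thin-5 single-model settings."""

    n_samples: int = 5000
    n_burn_in: int = 2000
    thin: int = 1
    n_chains: int = 2
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.3
    init_retries: int = 20

    def __post_init__(self):
        if not (self.n_samples > self.n_burn_in >= 0):
            raise ValueError("need n_samples > n_burn_in >= 0")
        if self.thin < 1 or self.n_chains < 2:
            raise ValueError("need thin >= 1 and n_chains >= 2")

    @classmethod
    def paper_preset(cls, seed: int = 0, n_chains: int = 2) -> "MCMCConfig":
        return cls(n_samples=95_000, n_burn_in=35_000, thin=5,
                   n_chains=n_chains, seed=seed)


@dataclass
class PosteriorSamples:
    """Multi-chain MCMC draws with per-draw data log-likelihood."""

    params: list
    draws: np.ndarray            # (n_chains, n_draws, n_params)
    loglik: np.ndarray           # (n_chains, n_draws)
    meta: dict = field(default_factory=dict)
    accept_rates: dict = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_draws) draw array for one parameter."""
        return self.draws[:, :, self.params.index(name)]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def posterior_mean(self) -> dict:
        return {p: float(self.draws[:, :, i].mean()) for i, p in enumerate(self.params)}

    def to_frame(self, params=None) -> pd.DataFrame:
        """Long-format (chain, iter, parameter, value) table."""
        params = list(params) if params is not None else self.params
        frames = []
        for name in params:
            arr = self.get(name)
            for c in range(arr.shape[0]):
                frames.append(pd.DataFrame({
                    "chain": c, "iter": np.arange(arr.shape[1]),
                    "parameter": name, "value": arr[c],
                }))
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path, params=None) -> None:
        self.to_frame(params).to_csv(path, index=False)

    def save(self, prefix) -> None:
        """Persist all draws (plus per-draw log-likelihood) and metadata
        to ``<prefix>.csv`` / ``<prefix>.meta.json``."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        frame = self.to_frame()
        ll = []
        for c in range(self.draws.shape[0]):
            ll.append(pd.DataFrame({"chain": c, "iter": np.arange(self.n_draws),
                                    "parameter": "__loglik__", "value": self.loglik[c]}))
        pd.concat([frame] + ll, ignore_index=True).to_csv(
            prefix.with_suffix(".csv"), index=False, float_format="%.8g")
        prefix.with_suffix(".meta.json").write_text(json.dumps(self.meta, default=list))

    @classmethod
    def load(cls, prefix) -> "PosteriorSamples":
        import json
        from pathlib import Path

        prefix = Path(prefix)
        frame = pd.read_csv(prefix.with_suffix(".csv"))
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        names = [p for p in frame["parameter"].unique() if p != "__loglik__"]
        chains = sorted(frame["chain"].unique())
        n_draws = int(frame["iter"].max()) + 1
        draws = np.empty((len(chains), n_draws, len(names)))
        loglik = np.empty((len(chains), n_draws))
        piv = frame.pivot_table(index=["chain", "iter"], columns="parameter",
                                values="value", sort=False)
        for c in chains:
            sub = piv.loc[c]
            for j, p in enumerate(names):
                draws[c, :, j] = sub[p].to_numpy()
            loglik[c] = sub["__loglik__"].to_numpy()
        return cls(params=list(names), draws=draws, loglik=loglik, meta=meta)


# ---------------------------------------------------------------------------
# model graph
# ---------------------------------------------------------------------------


class HDDMModel:
    """Parameter graph plus cached-likelihood Metropolis sweep.

    Built by :func:`build_model`; sampled by :func:`sample_posterior`.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        required = {"subject_id", "group", "condition", "response", "rt"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"trial table lacks columns {sorted(missing)}")
        if len(data) == 0:
            raise ValueError("trial table is empty")
        for cov in spec.covariates:
            if cov not in data.columns:
                raise ValueError(f"covariate column {cov!r} missing from data")
            if not np.all(np.isfinite(data[cov].to_numpy(dtype=float))):
                raise ValueError(f"covariate {cov!r} has non-finite values")
        bad_cond = set(data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"conditions {sorted(bad_cond)} not in the task schema")
        if data["rt"].isna().any() or (data["rt"] <= 0).any():
            raise ValueError("missing/invalid rts present; apply inclusion filters first")
        if not data["response"].isin([0, 1]).all():
            raise ValueError("responses must be 0/1; drop censored trials first")

        self.conditions = [c for c in CONDITIONS if c in set(data["condition"])]
        self.baseline = self.conditions[0]
        self.groups = list(dict.fromkeys(data["group"]))
        self.subjects = list(dict.fromkeys(data["subject_id"]))
        self.subject_group = {
            s: data.loc[data["subject_id"] == s, "group"].iloc[0] for s in self.subjects
        }
        self.group_subjects = {
            g: [s for s in self.subjects if self.subject_group[s] == g] for g in self.groups
        }

        # per (subject, condition) trial blocks
        self._blocks = {}
        n_cov = len(spec.covariates)
        for s in self.subjects:
            sub = data[data["subject_id"] == s]
            for ci, c in enumerate(self.conditions):
                rows = sub[sub["condition"] == c]
                rt = np.ascontiguousarray(rows["rt"].to_numpy(dtype=float))
                ch = np.ascontiguousarray(rows["response"].to_numpy(dtype=np.int64))
                X = (np.ascontiguousarray(rows[list(spec.covariates)].to_numpy(dtype=float))
                     if n_cov else np.zeros((len(rows), 0)))
                self._blocks[(s, ci)] = (rt, ch, X)
        self._zero = {k: np.zeros(v[0].size) for k, v in self._blocks.items()}

        self.params: list[str] = []
        for g in self.groups:
            self.params += [f"mu_v[{g}]", f"sigma_v[{g}]", f"mu_a[{g}]",
                            f"sigma_a[{g}]", f"mu_t0[{g}]", f"sigma_t0[{g}]"]
            if "v" in spec.varies_by_condition:
                self.params += [f"b_v[{g},{c}]" for c in self.conditions[1:]]
            if "a" in spec.varies_by_condition:
                self.params += [f"b_a[{g},{c}]" for c in self.conditions[1:]]
            self.params += [f"b_{cov}[{g}]" for cov in spec.covariates]
        for s in self.subjects:
            self.params += [f"v[{s}]", f"a[{s}]", f"t0[{s}]"]

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return len(self.params)

    @property
    def update_names(self) -> list:
        """Scalar parameters plus the joint group moves (for proposal-scale
        bookkeeping); joint moves are not model parameters."""
        extra = []
        for g in self.groups:
            for kind in ("v", "a", "t0"):
                extra += [f"_loc_{kind}[{g}]", f"_scale_{kind}[{g}]"]
        return self.params + extra

    def _effect(self, state, kind, g, ci):
        if ci == 0 or kind not in self.spec.varies_by_condition:
            return 0.0
        return state[f"b_{kind}[{g},{self.conditions[ci]}]"]

    def _cov_shift_arrays(self, state):
        """Per-block covariate contribution to the drift."""
        shifts = {}
        for s in self.subjects:
            g = self.subject_group[s]
            coefs = np.array([state[f"b_{cov}[{g}]"] for cov in self.spec.covariates])
            for ci in range(len(self.conditions)):
                X = self._blocks[(s, ci)][2]
                shifts[(s, ci)] = X @ coefs if coefs.size else self._zero[(s, ci)]
        return shifts

    def _block_ll(self, state, s, ci, shift, v=None, a=None, t0=None):
        g = self.subject_group[s]
        rt, ch, _ = self._blocks[(s, ci)]
        v_eff = (v if v is not None else state[f"v[{s}]"]) + self._effect(state, "v", g, ci)
        a_eff = (a if a is not None else state[f"a[{s}]"]) + self._effect(state, "a", g, ci)
        t0v = t0 if t0 is not None else state[f"t0[{s}]"]
        return loglik_cond(rt, ch, shift, self._zero[(s, ci)], 0.0, v_eff, a_eff,
                           t0v, self.spec.p_outlier, self.spec.rt_max, self.spec.eps)

    # -- full (cache-free) evaluations ------------------------------------

    def log_likelihood(self, state: dict) -> float:
        """Total trial log-likelihood under a complete assignment."""
        shifts = self._cov_shift_arrays(state)
        total = 0.0
        for s in self.subjects:
            for ci in range(len(self.conditions)):
                ll = self._block_ll(state, s, ci, shifts[(s, ci)])
                if not np.isfinite(ll):
                    return -np.inf
                total += ll
        return total

    def log_prior(self, state: dict) -> float:
        pr = self.spec.priors
        total = 0.0
        for g in self.groups:
            total += _norm_logpdf(state[f"mu_v[{g}]"], *pr["mu_v"])
            for kind in ("a", "t0"):
                loc, scale, lo, hi = pr[f"mu_{kind}"]
                x = state[f"mu_{kind}[{g}]"]
                if not (lo < x < hi):
                    return -np.inf
                total += _norm_logpdf(x, loc, scale)
            for kind in ("v", "a", "t0"):
                sd = state[f"sigma_{kind}[{g}]"]
                if sd < _SIGMA_FLOOR:
                    return -np.inf
                total += -0.5 * (sd / pr["sigma"]) ** 2
            for name in self.params:
                if name.startswith(("b_v[", "b_a[")) and f"[{g}," in name:
                    total += _norm_logpdf(state[name], *pr["effect"])
                elif name.startswith("b_") and name.endswith(f"[{g}]"):
                    total += _norm_logpdf(state[name], *pr["coef"])
        for s in self.subjects:
            g = self.subject_group[s]
            for kind in ("v", "a", "t0"):
                lo, hi = _SUBJECT_BOUNDS[kind]
                x = state[f"{kind}[{s}]"]
                if not (lo < x < hi):
                    return -np.inf
                total += _norm_logpdf(x, state[f"mu_{kind}[{g}]"], state[f"sigma_{kind}[{g}]"])
        return total

    # -- sampling interface -------------------------------------------------

    def initial_state(self, rng) -> dict:
        """Data-informed, chain-overdispersed starting point."""
        state = {}
        sub_init = {}
        for s in self.subjects:
            rts, chs = [], []
            for ci in range(len(self.conditions)):
                rt, ch, _ = self._blocks[(s, ci)]
                rts.append(rt)
                chs.append(ch)
            rt = np.concatenate(rts)
            ch = np.concatenate(chs)
            acc = float(np.clip(ch.mean(), 0.55, 0.97))
            a0 = float(np.clip(1.5 + rng.normal(0, 0.3), 0.5, 3.0))
            t0 = float(np.clip(0.5 * np.quantile(rt, 0.05) + rng.normal(0, 0.05), 0.05, 0.8))
            v0 = float(np.clip(math.log(acc / (1 - acc)) / a0 + rng.normal(0, 0.4), 0.1, 6.0))
            sub_init[s] = (v0, a0, t0)
            state[f"v[{s}]"] = v0
            state[f"a[{s}]"] = a0
            state[f"t0[{s}]"] = t0
        for g in self.groups:
            vals = np.array([sub_init[s] for s in self.group_subjects[g]])
            for j, kind in enumerate(("v", "a", "t0")):
                state[f"mu_{kind}[{g}]"] = float(
                    np.clip(vals[:, j].mean() + rng.normal(0, 0.1),
                            *_mu_bounds(kind, self.spec.priors))
                )
                state[f"sigma_{kind}[{g}]"] = float(0.1 + abs(rng.normal(0, 0.1)))
            for name in self.params:
                if name.startswith(("b_v[", "b_a[")) and f"[{g}," in name:
                    state[name] = float(rng.normal(0, 0.1))
                elif name.startswith("b_") and name.endswith(f"[{g}]"):
                    state[name] = float(rng.normal(0, 0.05))
        return state

    def initial_scales(self) -> dict:
        scales = {}
        for name in self.update_names:
            if name.startswith("_scale_"):
                scales[name] = 0.15
            elif name.startswith("_loc_t0") or name.startswith(("t0[", "mu_t0", "sigma")):
                scales[name] = 0.03
            elif name.startswith(("b_", "_loc_")):
                scales[name] = 0.05
            else:
                scales[name] = 0.1
        return scales

    def begin_chain(self, state: dict) -> float:
        """Validate the state and fill the per-block likelihood cache."""
        lp = self.log_prior(state)
        if not np.isfinite(lp):
            return -np.inf
        self._shift = self._cov_shift_arrays(state)
        self._ll = {}
        total = 0.0
        for s in self.subjects:
            arr = np.empty(len(self.conditions))
            for ci in range(len(self.conditions)):
                arr[ci] = self._block_ll(state, s, ci, self._shift[(s, ci)])
            self._ll[s] = arr
            total += arr.sum()
        return lp + total if np.isfinite(total) else -np.inf

    def total_loglik(self, state: dict) -> float:
        return float(sum(self._ll[s].sum() for s in self.subjects))

    def sweep(self, state, rng, scales, accept, attempts) -> None:
        """One full scan of scalar Metropolis updates."""
        pr = self.spec.priors
        n_cond = len(self.conditions)

        def mh(name, logratio_fn):
            attempts[name] += 1
            old = state[name]
            prop = old + scales[name] * rng.standard_normal()
            out = logratio_fn(old, prop)
            if out is None:
                return
            logr, commit = out
            if logr >= 0 or math.log(rng.random()) < logr:
                state[name] = prop
                accept[name] += 1
                commit()

        # group-level structural parameters (no data likelihood)
        for g in self.groups:
            subs = self.group_subjects[g]
            for kind in ("v", "a", "t0"):
                vals = np.array([state[f"{kind}[{s}]"] for s in subs])

                def mu_ratio(old, prop, kind=kind, g=g, vals=vals):
                    lo, hi = _mu_bounds(kind, pr)
                    if not (lo < prop < hi):
                        return None
                    sd = state[f"sigma_{kind}[{g}]"]
                    hp = pr["mu_v"] if kind == "v" else pr[f"mu_{kind}"][:2]
                    logr = (_norm_logpdf(prop, *hp) - _norm_logpdf(old, *hp)
                            - 0.5 * (((vals - prop) ** 2).sum()
                                     - ((vals - old) ** 2).sum()) / sd**2)
                    return logr, lambda: None

                mh(f"mu_{kind}[{g}]", mu_ratio)

                def sig_ratio(old, prop, kind=kind, g=g, vals=vals):
                    if prop < _SIGMA_FLOOR:
                        return None
                    mu = state[f"mu_{kind}[{g}]"]
                    ss = ((vals - mu) ** 2).sum()
                    n = vals.size
                    logr = (-0.5 * (prop**2 - old**2) / pr["sigma"] ** 2
                            - n * (math.log(prop) - math.log(old))
                            - 0.5 * ss * (1.0 / prop**2 - 1.0 / old**2))
                    return logr, lambda: None

                mh(f"sigma_{kind}[{g}]", sig_ratio)

            # condition-effect coefficients (likelihood over one condition)
            for kind in ("v", "a"):
                if kind not in self.spec.varies_by_condition:
                    continue
                for ci in range(1, n_cond):
                    name = f"b_{kind}[{g},{self.conditions[ci]}]"

                    def eff_ratio(old, prop, kind=kind, g=g, ci=ci, name=name):
                        logr = _norm_logpdf(prop, *pr["effect"]) - _norm_logpdf(old, *pr["effect"])
                        news = {}
                        for s in self.group_subjects[g]:
                            # override the subject value so that adding the
                            # current effect yields the proposed effect
                            if kind == "v":
                                ll = self._block_ll(state, s, ci, self._shift[(s, ci)],
                                                    v=state[f"v[{s}]"] + prop
                                                    - self._effect(state, "v", g, ci))
                            else:
                                ll = self._block_ll(state, s, ci, self._shift[(s, ci)],
                                                    a=state[f"a[{s}]"] + prop
                                                    - self._effect(state, "a", g, ci))
                            if not np.isfinite(ll):
                                return None
                            news[s] = ll
                            logr += ll - self._ll[s][ci]

                        def commit():
                            for s, ll in news.items():
                                self._ll[s][ci] = ll

                        return logr, commit

                    mh(name, eff_ratio)

            # covariate coefficients (likelihood over all the group's trials)
            for j, cov in enumerate(self.spec.covariates):
                name = f"b_{cov}[{g}]"

                def cov_ratio(old, prop, g=g, j=j, name=name):
                    delta = prop - old
                    logr = _norm_logpdf(prop, *pr["coef"]) - _norm_logpdf(old, *pr["coef"])
                    news = {}
                    for s in self.group_subjects[g]:
                        for ci in range(n_cond):
                            rt, ch, X = self._blocks[(s, ci)]
                            v_eff = state[f"v[{s}]"] + self._effect(state, "v", g, ci)
                            a_eff = state[f"a[{s}]"] + self._effect(state, "a", g, ci)
                            ll = loglik_cond(
                                rt, ch, self._shift[(s, ci)],
                                np.ascontiguousarray(X[:, j]), delta, v_eff, a_eff,
                                state[f"t0[{s}]"], self.spec.p_outlier,
                                self.spec.rt_max, self.spec.eps,
                            )
                            if not np.isfinite(ll):
                                return None
                            news[(s, ci)] = ll
                            logr += ll - self._ll[s][ci]

                    def commit():
                        for (s, ci), ll in news.items():
                            self._ll[s][ci] = ll
                            self._shift[(s, ci)] = (
                                self._shift[(s, ci)] + self._blocks[(s, ci)][2][:, j] * delta
                            )

                    return logr, commit

                mh(name, cov_ratio)

        # subject-level parameters
        for s in self.subjects:
            g = self.subject_group[s]
            for kind in ("v", "a", "t0"):
                name = f"{kind}[{s}]"

                def sub_ratio(old, prop, s=s, g=g, kind=kind):
                    lo, hi = _SUBJECT_BOUNDS[kind]
                    if not (lo < prop < hi):
                        return None
                    mu = state[f"mu_{kind}[{g}]"]
                    sd = state[f"sigma_{kind}[{g}]"]
                    logr = _norm_logpdf(prop, mu, sd) - _norm_logpdf(old, mu, sd)
                    news = np.empty(n_cond)
                    for ci in range(n_cond):
                        ll = self._block_ll(state, s, ci, self._shift[(s, ci)],
                                            **{kind: prop})
                        if not np.isfinite(ll):
                            return None
                        news[ci] = ll
                    logr += news.sum() - self._ll[s].sum()

                    def commit():
                        self._ll[s][:] = news

                    return logr, commit

                mh(name, sub_ratio)

        # joint group moves: translate (mu, all subjects) along the
        # likelihood-constrained direction, and rescale (sigma, all
        # deviations) to traverse the hierarchical funnel
        for g in self.groups:
            for kind in ("v", "a", "t0"):
                self._joint_location_move(state, rng, scales, accept, attempts,
                                          g, kind, n_cond)
                self._joint_scale_move(state, rng, scales, accept, attempts,
                                       g, kind, n_cond)

    def _group_block_lls(self, state, g, kind, values, n_cond):
        """Block log-likelihoods for group g with subject parameter
        ``kind`` overridden per subject; None on an impossible state."""
        news = {}
        for s, val in zip(self.group_subjects[g], values):
            for ci in range(n_cond):
                ll = self._block_ll(state, s, ci, self._shift[(s, ci)],
                                    **{kind: val})
                if not np.isfinite(ll):
                    return None
                news[(s, ci)] = ll
        return news

    def _apply_group_move(self, state, g, kind, mu_new, sigma_new, values, news):
        state[f"mu_{kind}[{g}]"] = mu_new
        if sigma_new is not None:
            state[f"sigma_{kind}[{g}]"] = sigma_new
        for s, val in zip(self.group_subjects[g], values):
            state[f"{kind}[{s}]"] = val
        for (s, ci), ll in news.items():
            self._ll[s][ci] = ll

    def _joint_location_move(self, state, rng, scales, accept, attempts,
                             g, kind, n_cond):
        name = f"_loc_{kind}[{g}]"
        attempts[name] += 1
        delta = scales[name] * rng.standard_normal()
        pr = self.spec.priors
        mu_old = state[f"mu_{kind}[{g}]"]
        mu_new = mu_old + delta
        lo, hi = _mu_bounds(kind, pr)
        if not (lo < mu_new < hi):
            return
        slo, shi = _SUBJECT_BOUNDS[kind]
        values = [state[f"{kind}[{s}]"] + delta for s in self.group_subjects[g]]
        if any(not (slo < v < shi) for v in values):
            return
        hp = pr["mu_v"] if kind == "v" else pr[f"mu_{kind}"][:2]
        logr = _norm_logpdf(mu_new, *hp) - _norm_logpdf(mu_old, *hp)
        news = self._group_block_lls(state, g, kind, values, n_cond)
        if news is None:
            return
        logr += sum(news.values()) - sum(self._ll[s][ci] for (s, ci) in news)
        if logr >= 0 or math.log(rng.random()) < logr:
            accept[name] += 1
            self._apply_group_move(state, g, kind, mu_new, None, values, news)

    def _joint_scale_move(self, state, rng, scales, accept, attempts,
                          g, kind, n_cond):
        name = f"_scale_{kind}[{g}]"
        attempts[name] += 1
        lam = scales[name] * rng.standard_normal()
        c = math.exp(lam)
        pr = self.spec.priors
        mu = state[f"mu_{kind}[{g}]"]
        sig_old = state[f"sigma_{kind}[{g}]"]
        sig_new = sig_old * c
        if sig_new < _SIGMA_FLOOR:
            return
        slo, shi = _SUBJECT_BOUNDS[kind]
        values = [mu + (state[f"{kind}[{s}]"] - mu) * c
                  for s in self.group_subjects[g]]
        if any(not (slo < v < shi) for v in values):
            return
        # deviation priors are invariant under the rescaling; the Jacobian
        # of (sigma, deviations) -> c * (sigma, deviations) leaves + lam
        logr = lam - 0.5 * (sig_new**2 - sig_old**2) / pr["sigma"] ** 2
        news = self._group_block_lls(state, g, kind, values, n_cond)
        if news is None:
            return
        logr += sum(news.values()) - sum(self._ll[s][ci] for (s, ci) in news)
        if logr >= 0 or math.log(rng.random()) < logr:
            accept[name] += 1
            self._apply_group_move(state, g, kind, mu, sig_new, values, news)


def _mu_bounds(kind, priors):
    if kind == "v":
        return (-8.0, 8.0)
    return priors[f"mu_{kind}"][2:]


def build_model(spec: ModelSpec, data: pd.DataFrame) -> HDDMModel:
    """Construct the hierarchical parameter graph for a trial table."""
    return HDDMModel(spec, data)


# ---------------------------------------------------------------------------
# reference model for sampler validation
# ---------------------------------------------------------------------------


class NormalMeanModel:
    """Normal mean with known SD and conjugate normal prior.

    Implements the same sampling interface as :class:`HDDMModel`; its
    posterior is available in closed form, which makes it the oracle for
    validating :func:`sample_posterior` end to end (initialization,
    adaptation, burn-in, thinning, recording).
    """

    def __init__(self, data, sigma=1.0, prior_mu=0.0, prior_sd=10.0):
        self.data = np.asarray(data, dtype=float)
        self.sigma = sigma
        self.prior_mu = prior_mu
        self.prior_sd = prior_sd
        self.params = ["mu"]

    def conjugate_posterior(self):
        n = self.data.size
        prec = 1.0 / self.prior_sd**2 + n / self.sigma**2
        mean = (self.prior_mu / self.prior_sd**2 + self.data.sum() / self.sigma**2) / prec
        return mean, math.sqrt(1.0 / prec)

    def initial_state(self, rng):
        return {"mu": float(self.prior_mu + rng.normal(0, 2.0))}

    def initial_scales(self):
        return {"mu": 1.0}

    def begin_chain(self, state):
        self._ll = self._loglik(state["mu"])
        return self._ll + _norm_logpdf(state["mu"], self.prior_mu, self.prior_sd)

    def _loglik(self, mu):
        return float(np.sum(-0.5 * ((self.data - mu) / self.sigma) ** 2
                            - math.log(self.sigma) - 0.5 * _LOG2PI))

    def total_loglik(self, state):
        return self._ll

    def log_likelihood(self, state):
        return self._loglik(state["mu"])

    def sweep(self, state, rng, scales, accept, attempts):
        attempts["mu"] += 1
        old = state["mu"]
        prop = old + scales["mu"] * rng.standard_normal()
        new_ll = self._loglik(prop)
        logr = (new_ll + _norm_logpdf(prop, self.prior_mu, self.prior_sd)
                - self._ll - _norm_logpdf(old, self.prior_mu, self.prior_sd))
        if logr >= 0 or math.log(rng.random()) < logr:
            state["mu"] = prop
            self._ll = new_ll
            accept["mu"] += 1


# ---------------------------------------------------------------------------
# sampler driver
# ---------------------------------------------------------------------------


def sample_posterior(model, config: MCMCConfig) -> PosteriorSamples:
    """Run multi-chain adaptive Metropolis-within-Gibbs.

    Chains start from independent overdispersed initializations,
    proposal scales adapt only during burn-in (the retained draws come
    from a frozen kernel), and identical (model, config) reproduce the
    draws exactly.
    """
    names = list(model.params)
    update_names = list(getattr(model, "update_names", model.params))
    n_keep = (config.n_samples - config.n_burn_in + config.thin - 1) // config.thin
    draws = np.empty((config.n_chains, n_keep, len(names)))
    logliks = np.empty((config.n_chains, n_keep))
    accept_rates = {}
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    for chain in range(config.n_chains):
        rng = np.random.default_rng(children[chain])
        state = None
        for _ in range(config.init_retries):
            cand = model.initial_state(rng)
            if np.isfinite(model.begin_chain(cand)):
                state = cand
                break
        if state is None:
            raise RuntimeError("could not find a finite-posterior initialization")

        scales = model.initial_scales()
        accept = {n: 0 for n in update_names}
        attempts = {n: 0 for n in update_names}
        kept = 0
        for it in range(config.n_samples):
            model.sweep(state, rng, scales, accept, attempts)
            if it < config.n_burn_in:
                if (it + 1) % config.adapt_interval == 0:
                    for n in update_names:
                        if attempts[n]:
                            rate = accept[n] / attempts[n]
                            scales[n] *= math.exp(0.5 * (rate - config.target_accept))
                        accept[n] = 0
                        attempts[n] = 0
            else:
                if (it - config.n_burn_in) % config.thin == 0:
                    draws[chain, kept] = [state[n] for n in names]
                    logliks[chain, kept] = model.total_loglik(state)
                    kept += 1
        accept_rates[chain] = {
            n: (accept[n] / attempts[n] if attempts[n] else np.nan)
            for n in update_names
        }
        assert kept == n_keep
    meta = {
        "groups": getattr(model, "groups", None),
        "subjects": getattr(model, "subjects", None),
        "conditions": getattr(model, "conditions", None),
        "varies_by_condition": tuple(getattr(getattr(model, "spec", None),
                                             "varies_by_condition", ())),
        "covariates": tuple(getattr(getattr(model, "spec", None), "covariates", ())),
        "config": {"n_samples": config.n_samples, "n_burn_in": config.n_burn_in,
                   "thin": config.thin, "n_chains": config.n_chains, "seed": config.seed},
    }
    return PosteriorSamples(params=names, draws=draws, loglik=logliks,
                            meta=meta, accept_rates=accept_rates)


# ---------------------------------------------------------------------------
# posterior post-processing
# ---------------------------------------------------------------------------


def reconstruct_condition_posteriors(samples: PosteriorSamples) -> dict:
    """Draw-wise group-level parameter posteriors per condition.

    For each group and each varying parameter, returns baseline + effect
    draws combined draw by draw; the congruent (baseline) condition is
    the baseline draws themselves.  Keys are (parameter, group,
    condition).
    """
    conditions = samples.meta.get("conditions") or []
    groups = samples.meta.get("groups") or []
    varies = samples.meta.get("varies_by_condition") or ()
    out = {}
    for g in groups:
        for kind in ("v", "a"):
            base = samples.get(f"mu_{kind}[{g}]")
            for ci, c in enumerate(conditions):
                if ci == 0 or kind not in varies:
                    out[(kind, g, c)] = base.copy()
                else:
                    out[(kind, g, c)] = base + samples.get(f"b_{kind}[{g},{c}]")
        out[("t0", g, "all")] = samples.get(f"mu_t0[{g}]").copy()
    return out


def gelman_rubin(samples: PosteriorSamples) -> pd.Series:
    """Split-chain potential scale reduction factor per parameter.

    Each chain is split in half, giving 2 x n_chains sequences; R-hat is
    sqrt(((m-1)/m W + B/m) / W) with W the mean within-sequence variance
    and B/m the between-sequence variance of means.  Values >= 1.1 flag
    non-convergence; a parameter with zero within-chain variance is
    reported as NaN (degenerate) rather than raising.  R-hat >= sqrt((m-1)/m)
    always (the small-sample floor of the variance decomposition).
    """
    if samples.draws.shape[0] < 2 or samples.n_draws < 10:
        raise ValueError("need >= 2 chains with >= 10 retained draws")
    half = samples.n_draws // 2
    out = {}
    for i, name in enumerate(samples.params):
        seqs = []
        for c in range(samples.draws.shape[0]):
            arr = samples.draws[c, :, i]
            seqs.append(arr[:half])
            seqs.append(arr[half: 2 * half])
        seqs = np.asarray(seqs)
        w = seqs.var(axis=1, ddof=1).mean()
        b = half * seqs.mean(axis=1).var(ddof=1)
        if w <= 0:
            out[name] = np.nan
            continue
        var_hat = (half - 1) / half * w + b / half
        out[name] = float(np.sqrt(var_hat / w))
    return pd.Series(out, name="rhat")
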