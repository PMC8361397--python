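"""End-to-end study replica on synthetic data.

Orchestrates: cohort simulation -> inclusion filtering -> (optional)
BOLD synthesis and beta-series estimation -> fitting the condition-
dependence model variants -> DIC comparison -> posterior predictive
checks -> group-contrast overlap tests -> trial-wise network covariate
regression -> report.  Every stage derives its seed from the master
seed, artifacts are stamped with a hash of the configuration, and stale
intermediates from a different configuration are never reused.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import betaseries as bs
from . import cohort as ch
from . import evaluate as ev
from . import hierarchical as hm
from .ddm import CONDITIONS

__all__ = ["PipelineConfig", "run_inclusion_filters", "run_study"]

log = logging.getLogger("antdrift.pipeline")

STAGES = ("simulate", "betas", "fit", "compare", "ppc", "regress", "report")

VARIANT_SPECS = {"v": ("v",), "a": ("a",), "va": ("v", "a")}

MCMC_PRESETS = {
    "desk": dict(n_samples=5000, n_burn_in=2000, thin=1, n_chains=2),
    "paper": dict(n_samples=95_000, n_burn_in=35_000, thin=5, n_chains=2),
}


@dataclass
class PipelineConfig:
    """Declarative description of one study run."""

    out_dir: str = "run"
    seed: int = 0
    n_subjects_per_group: int = 15
    schedule: ch.ScheduleConfig = field(default_factory=ch.ScheduleConfig)
    groups: tuple = field(default_factory=ch.default_groups)
    model_variants: tuple = ("v", "a", "va")
    networks: tuple = ("default", "dorsal")
    use_bold: bool = True
    bold: ch.BOLDRunConfig = field(default_factory=ch.BOLDRunConfig)
    p_outlier: float = 0.05
    mcmc_preset: str = "desk"
    mcmc_overrides: dict = field(default_factory=dict)
    ppc_draws: int = 100

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [asdict(g) for g in self.groups]
        return d

    @property
    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def mcmc_config(self, seed: int) -> hm.MCMCConfig:
        kw = dict(MCMC_PRESETS[self.mcmc_preset])
        kw.update(self.mcmc_overrides)
        return hm.MCMCConfig(seed=seed, **kw)

    def stage_seed(self, stage: str) -> int:
        """Documented per-stage seed derivation from the master seed."""
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[STAGES.index(stage)]
        return int(child.generate_state(1)[0] % 2**31)


def run_inclusion_filters(
    table: pd.DataFrame,
    min_runs: int = 5,
    max_runs: int = 6,
    min_accuracy: float = 0.70,
    max_missed: float = 0.10,
):
    """Apply the study's inclusion criteria subject-wise.

    A subject is retained when they completed ``min_runs``–``max_runs``
    runs, answered at least 70% of responded trials correctly, and
    missed responses on no more than 10% of trials (boundaries
    inclusive: exactly 70% correct or 10% missed is retained).
    No-response trials of retained subjects are then dropped.  Returns
    (filtered table, exclusion report).
    """
    reasons: dict = {}
    for sid, sub in table.groupby("subject_id", sort=False):
        why = []
        n_runs = sub["run"].nunique()
        if not (min_runs <= n_runs <= max_runs):
            why.append("run_count")
        responded = sub[sub["response"].isin([0, 1])]
        acc = (responded["response"] == 1).mean() if len(responded) else 0.0
        if acc < min_accuracy:
            why.append("accuracy")
        missed = (sub["response"] == -1).mean()
        if missed > max_missed:
            why.append("missed_responses")
        if why:
            reasons[sid] = why
    kept = table[~table["subject_id"].isin(reasons)].copy()
    n_no_response = int((kept["response"] == -1).sum())
    kept = kept[kept["response"].isin([0, 1])].reset_index(drop=True)
    report = {
        "n_subjects_in": int(table["subject_id"].nunique()),
        "n_subjects_excluded": len(reasons),
        "excluded_subjects": reasons,
        "n_excluded_run_count": sum("run_count" in w for w in reasons.values()),
        "n_excluded_accuracy": sum("accuracy" in w for w in reasons.values()),
        "n_excluded_missed": sum("missed_responses" in w for w in reasons.values()),
        "n_no_response_trials_dropped": n_no_response,
    }
    return kept, report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    table, truth = ch.generate_cohort(
        cfg.groups, cfg.n_subjects_per_group, cfg.schedule,
        seed=cfg.stage_seed("simulate"), p_outlier=cfg.p_outlier,
        networks=cfg.networks,
    )
    table.to_csv(out / "cohort.csv", index=False, float_format="%.6f")
    truth["subjects"].to_csv(out / "truth_subjects.csv", index=False)
    (out / "truth_groups.json").write_text(
        json.dumps({"groups": truth["groups"], "p_outlier": truth["p_outlier"]}, indent=2)
    )
    # reduced-size studies schedule fewer runs; the run-count criterion
    # then applies at the scheduled count rather than the standard 5-6
    filtered, report = run_inclusion_filters(
        table, min_runs=min(5, cfg.schedule.n_runs),
        max_runs=max(6, cfg.schedule.n_runs))
    filtered.to_csv(out / "filtered.csv", index=False, float_format="%.6f")
    (out / "exclusions.json").write_text(json.dumps(report, indent=2))
    return filtered


def _stage_betas(cfg: PipelineConfig, out: Path, filtered: pd.DataFrame) -> pd.DataFrame:
    """Synthesize BOLD runs per network and re-estimate beta series."""
    if not (cfg.networks and cfg.use_bold):
        return filtered
    rng = np.random.default_rng(cfg.stage_seed("betas"))
    qc = []
    # the cohort table only keeps responded trials after filtering; the
    # BOLD model needs every scheduled trial, so re-read the full table
    full = pd.read_csv(out / "cohort.csv")
    full = full[full["subject_id"].isin(filtered["subject_id"].unique())]
    est_cols = {net: {} for net in cfg.networks}
    for sid, sub in full.groupby("subject_id", sort=False):
        for net in cfg.networks:
            betas = []
            for run_id, run_tab in sub.groupby("run", sort=False):
                z = run_tab[f"beta_{net}"].to_numpy()
                amps = cfg.bold.amp_baseline + cfg.bold.amp_sd * z
                run_sched = run_tab.rename(columns={"target_onset": "target_onset"})
                run, truth = ch.generate_bold_run(
                    run_sched, amps, cfg.bold, seed=int(rng.integers(0, 2**31 - 1))
                )
                series = bs.fit_beta_series(run)
                betas.append(series.table.assign(subject_id=sid))
                mo = bs.qc_motion(run.motion)
                dv = bs.qc_dvars(truth["voxels"])
                qc.append({"subject_id": sid, "network": net, "run": int(run_id),
                           **mo, "mean_dvars": dv["mean_standardized"]})
            tab = pd.concat(betas, ignore_index=True)
            zs = bs.zscore_betas(bs.BetaSeries(tab))
            for _, row in zs.table.iterrows():
                est_cols[net][(sid, int(row["run"]), int(row["trial_index"]))] = row["beta"]
    for net in cfg.networks:
        col = est_cols[net]
        filtered[f"beta_{net}_est"] = [
            col[(r.subject_id, int(r.run), int(r.trial_index))]
            for r in filtered.itertuples()
        ]
    pd.DataFrame(qc).to_csv(out / "qc.csv", index=False)
    filtered.to_csv(out / "filtered.csv", index=False, float_format="%.6f")
    return filtered


def _stage_fit(cfg: PipelineConfig, out: Path, filtered: pd.DataFrame) -> dict:
    results = {}
    dic_rows = []
    for k, variant in enumerate(cfg.model_variants):
        spec = hm.ModelSpec(varies_by_condition=VARIANT_SPECS[variant],
                            p_outlier=cfg.p_outlier)
        model = hm.build_model(spec, filtered)
        mcfg = cfg.mcmc_config(seed=cfg.stage_seed("fit") + k)
        log.info("fitting variant %s (%d parameters)", variant, model.n_parameters)
        samples = hm.sample_posterior(model, mcfg)
        rhat = hm.gelman_rubin(samples)
        d = ev.dic(samples, model)
        dic_rows.append({"variant": variant, "dic": d.dic, "p_d": d.p_d,
                         "mean_deviance": d.mean_deviance,
                         "max_rhat": float(rhat.max()),
                         "n_rhat_flagged": int((rhat >= 1.1).sum())})
        samples.save(out / f"draws_{variant}")
        rhat.to_csv(out / f"rhat_{variant}.csv")
        results[variant] = (model, samples)
    dic_table = pd.DataFrame(dic_rows)
    dic_table.to_csv(out / "dic_table.csv", index=False)
    best = dic_table.loc[dic_table["dic"].idxmin(), "variant"]
    (out / "dic_table.json").write_text(json.dumps(
        {"table": dic_rows, "best_variant": best}, indent=2))
    return {"results": results, "dic_table": dic_table, "best": best}


def _stage_compare(cfg: PipelineConfig, out: Path, fit: dict) -> dict:
    """Group-contrast overlap matrix and density-plot data for the
    best-fitting variant."""
    model, samples = fit["results"][fit["best"]]
    rec = hm.reconstruct_condition_posteriors(samples)
    groups = model.groups
    contrasts = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    overlap = {}
    rows = []
    for kind in ("v", "a"):
        for c in model.conditions:
            for ga, gb in contrasts:
                res = ev.posterior_overlap(rec[(kind, ga, c)], rec[(kind, gb, c)],
                                           seed=cfg.stage_seed("compare"))
                overlap[f"{kind}|{c}|{ga}-vs-{gb}"] = {
                    "P": res.P, "significant": res.significant}
    for ga, gb in contrasts:
        res = ev.posterior_overlap(rec[("t0", ga, "all")], rec[("t0", gb, "all")],
                                   seed=cfg.stage_seed("compare"))
        overlap[f"t0|all|{ga}-vs-{gb}"] = {"P": res.P, "significant": res.significant}
    (out / "overlap.json").write_text(json.dumps(overlap, indent=2))
    for (kind, g, c), draws in rec.items():
        rows.append(pd.DataFrame({"parameter": kind, "group": g, "condition": c,
                                  "value": draws.ravel()}))
    dens = pd.concat(rows, ignore_index=True)
    dens.to_csv(out / "density_data.csv", index=False, float_format="%.6g")
    _density_figures(dens, out)
    return overlap


def _density_figures(dens: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for kind, fname in (("v", "drift_densities.png"), ("a", "boundary_densities.png"),
                        ("t0", "nondecision_densities.png")):
        sub = dens[dens["parameter"] == kind]
        conds = sub["condition"].unique()
        fig, axes = plt.subplots(1, len(conds), figsize=(4 * len(conds), 3),
                                 squeeze=False, sharey=True)
        for ax, c in zip(axes[0], conds):
            for g, gsub in sub[sub["condition"] == c].groupby("group", sort=False):
                gsub["value"].plot.kde(ax=ax, label=g)
            ax.set_title(f"{kind} — {c}")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=110)
        plt.close(fig)


def _stage_ppc(cfg: PipelineConfig, out: Path, fit: dict, filtered: pd.DataFrame):
    model, samples = fit["results"][fit["best"]]
    ppc = ev.posterior_predictive(samples, model, filtered,
                                  n_draws=cfg.ppc_draws, seed=cfg.stage_seed("ppc"))
    ppc.observed.to_csv(out / "ppc_observed.csv", index=False)
    ppc.ranks.to_csv(out / "ppc_ranks.csv", index=False)
    ppc.simulated.to_csv(out / "ppc_simulated.csv", index=False, float_format="%.6g")
    return ppc


def _stage_regress(cfg: PipelineConfig, out: Path, filtered: pd.DataFrame) -> dict:
    """Per-network drift-rate regression on the trial-wise beta series."""
    if not cfg.networks:
        return {}
    results = {}
    for k, net in enumerate(cfg.networks):
        col = f"beta_{net}_est" if (cfg.use_bold and f"beta_{net}_est" in filtered) \
            else f"beta_{net}"
        spec = hm.ModelSpec(varies_by_condition=("v", "a"), covariates=(col,),
                            p_outlier=cfg.p_outlier)
        model = hm.build_model(spec, filtered)
        mcfg = cfg.mcmc_config(seed=cfg.stage_seed("regress") + k)
        samples = hm.sample_posterior(model, mcfg)
        rhat = hm.gelman_rubin(samples)
        coef = {}
        for g in model.groups:
            draws = samples.get(f"b_{col}[{g}]").ravel()
            res = ev.prob_nonzero(draws)
            coef[g] = {"mean": float(draws.mean()), "P": res.P, "sign": res.sign,
                       "significant": res.significant}
        results[net] = {"coefficients": coef, "max_rhat": float(rhat.max()),
                        "covariate_column": col}
        samples.save(out / f"draws_regress_{net}")
    (out / "regression.json").write_text(json.dumps(results, indent=2))
    return results


def _stage_report(cfg: PipelineConfig, out: Path, fit, overlap, ppc, regress) -> str:
    lines = ["# Study replica report", "",
             f"config hash: `{cfg.config_hash}`, master seed: {cfg.seed}", ""]
    lines += ["## Model comparison (DIC)", "", fit["dic_table"].to_string(index=False),
              "", f"best variant: **{fit['best']}**", ""]
    lines += ["## Group contrasts (overlap P, %)", ""]
    for key, val in overlap.items():
        mark = "*" if val["significant"] else ""
        lines.append(f"- {key}: P = {val['P']:.2f}{mark}")
    if ppc is not None:
        lines += ["", "## Posterior predictive check",
                  f"observed summaries inside central 95% simulated interval: "
                  f"{100 * ppc.coverage():.1f}%", ""]
    if regress:
        lines += ["## Trial-wise network regression on drift rate", ""]
        for net, res in regress.items():
            for g, c in res["coefficients"].items():
                lines.append(f"- {net} / {g}: mean {c['mean']:+.3f}, "
                             f"P = {c['P']:.2f}% ({'+' if c['sign'] > 0 else '-'})")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text


def run_study(config: PipelineConfig, stages=None) -> dict:
    """Execute the study pipeline (all stages by default).

    Artifacts are written under ``config.out_dir`` and stamped with the
    configuration hash; if the directory holds artifacts from a
    different configuration they are recomputed, never reused.  Two
    invocations with the same configuration produce identical reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGES)
    manifest_path = out / "manifest.json"
    status_path = out / "status.json"
    status = {}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == config.config_hash and status_path.exists():
            status = json.loads(status_path.read_text())
        else:
            log.info("configuration changed; recomputing all stages")
    manifest_path.write_text(json.dumps(
        {"config_hash": config.config_hash, "seed": config.seed,
         "config": config.to_dict()}, indent=2, default=str))

    def mark(stage):
        status[stage] = True
        status_path.write_text(json.dumps(status, indent=2))

    filtered = None
    if "simulate" in stages or not (out / "filtered.csv").exists() \
            or not status.get("simulate"):
        filtered = _stage_simulate(config, out)
        mark("simulate")
    else:
        filtered = pd.read_csv(out / "filtered.csv")

    if "betas" in stages and config.networks and config.use_bold:
        filtered = _stage_betas(config, out, filtered)
        mark("betas")

    fit = overlap = ppc = regress = None
    if {"fit", "compare", "ppc"} & set(stages):
        fit = _stage_fit(config, out, filtered)
        mark("fit")
    if "compare" in stages and fit:
        overlap = _stage_compare(config, out, fit)
        mark("compare")
    if "ppc" in stages and fit:
        ppc = _stage_ppc(config, out, fit, filtered)
        mark("ppc")
    if "regress" in stages and config.networks:
        regress = _stage_regress(config, out, filtered)
        mark("regress")
    report = None
    if "report" in stages and fit:
        report = _stage_report(config, out, fit, overlap or {}, ppc, regress)
        mark("report")
    return {"filtered": filtered, "fit": fit, "overlap": overlap,
            "ppc": ppc, "regress": regress, "report": report,
            "out_dir": str(out), "config_hash": config.config_hash}
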