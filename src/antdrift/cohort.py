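"""Synthetic cohorts emulating a flanker-style attention task in the scanner.

The generator reproduces the statistical structure the analysis assumes:

* the task schedule — 36 trials per 5-minute run, 5–6 runs per subject,
  three conflict conditions (congruent / incongruent-EASY /
  incongruent-HARD), a 200 ms cue, a 3 s response window, and fixed
  multisets of cue–target and target–cue delays, each value occurring
  exactly three times per run in random order;
* three diagnostic groups (healthy controls, Alzheimer's disease,
  Lewy body dementia) whose diffusion parameters are drawn from
  group-level distributions — drift rate falls and non-decision time
  rises from controls through AD to LBD, patients set narrower
  boundaries than controls;
* trial-wise network activity (default / dorsal attention) linearly
  coupled to the drift rate;
* raw network-averaged BOLD runs (TR 1.92 s, 156 volumes) from which
  single-trial beta series can be re-estimated.

Every observable is reproducible from (config, seed); the hidden
ground-truth parameters are returned alongside the behavioural table so
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._wfpt import em_sample
from .betaseries import RunTimecourse, canonical_hrf, dct_highpass_basis, _convolved_regressors
from .ddm import CONDITIONS

__all__ = [
    "ScheduleConfig",
    "GroupSpec",
    "BOLDRunConfig",
    "default_groups",
    "model_selection_groups",
    "generate_trial_schedule",
    "generate_cohort",
    "generate_coupled_trials",
    "generate_bold_run",
]

#: cue-offset -> target-onset delays (seconds); approximately
#: exponentially spaced, each used exactly three times per run
CUE_TARGET_DELAYS = (
    0.700, 0.770, 0.850, 0.960, 1.080, 1.240,
    1.430, 1.660, 1.940, 2.300, 2.700, 3.200,
)
#: target-onset -> next-cue delays (seconds), same three-per-run scheme
TARGET_CUE_DELAYS = (
    4.300, 4.500, 4.750, 5.000, 5.350, 5.700,
    6.100, 6.400, 6.800, 7.200, 7.700, 8.300,
)


@dataclass(frozen=True)
class ScheduleConfig:
    """Timing and composition of the task runs."""

    n_runs: int = 6
    trials_per_run: int = 36
    cue_duration: float = 0.200
    response_window: float = 3.0
    cue_target_delays: tuple = CUE_TARGET_DELAYS
    target_cue_delays: tuple = TARGET_CUE_DELAYS
    condition_split: tuple = (12, 12, 12)
    initial_fixation: float = 4.0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        if sum(self.condition_split) != self.trials_per_run:
            raise ValueError("condition split must sum to trials_per_run")
        if 3 * len(self.cue_target_delays) != self.trials_per_run:
            raise ValueError("each cue-target delay occurs exactly three times per run")


@dataclass(frozen=True)
class GroupSpec:
    """Generating distribution of one diagnostic group.

    ``drift`` and ``boundary`` give the group-mean parameter per
    condition (congruent, incongruent-EASY, incongruent-HARD).  Subjects
    deviate from the congruent group mean by a single additive offset
    per parameter (SD ``*_sd``), so condition effects are shared at the
    group level — the structure the hierarchical model estimates.
    ``b_default`` / ``b_dorsal`` couple z-scored trial-wise network
    activity to the drift rate (drift units per covariate SD).
    """

    label: str
    drift: tuple
    boundary: tuple
    t0: float
    drift_sd: float = 0.3
    boundary_sd: float = 0.2
    t0_sd: float = 0.05
    b_default: float = 0.0
    b_dorsal: float = 0.0

    def __post_init__(self):
        if len(self.drift) != 3 or len(self.boundary) != 3:
            raise ValueError("drift and boundary need one value per condition")
        if min(self.boundary) <= 0:
            raise ValueError("boundaries must be positive")
        if min(self.drift_sd, self.boundary_sd, self.t0_sd) < 0:
            raise ValueError("between-subject SDs must be >= 0")


@dataclass(frozen=True)
class BOLDRunConfig:
    """Generating model of one network-averaged BOLD run.

    Amplitudes and noise are expressed in % signal change about the
    baseline level; the low-frequency drift lives in the span of the
    high-pass basis the estimator removes.
    """

    tr: float = 1.92
    n_volumes: int = 156
    noise_sd: float = 0.5          # % signal, AR(1) innovation scale
    noise_ar1: float = 0.3
    drift_amplitude: float = 1.0   # % signal on low-frequency cosines
    motion_step_mm: float = 0.02   # random-walk step, translations
    motion_step_deg: float = 0.01  # random-walk step, rotations
    motion_leak: float = 0.05      # % signal per mm / degree
    baseline: float = 1000.0       # raw scanner units
    amp_baseline: float = 1.0      # % signal evoked per trial, mean
    amp_sd: float = 1.0            # % signal, per-trial deviation scale
    n_voxels: int = 30
    voxel_noise_sd: float = 1.0    # % signal, independent per voxel


def default_groups() -> tuple:
    """Default three-group configuration (invented, not fitted values).

    Chosen to reproduce the qualitative ordering the analysis targets:
    drift Control > AD > LBD in every condition, boundaries reduced in
    both patient groups but equal between them, non-decision time
    Control < AD < LBD, a positive dorsal-attention coupling everywhere
    and a default-network coupling that flips sign in LBD.
    """
    return (
        GroupSpec("Control", (2.8, 2.2, 2.0), (2.0, 2.0, 2.0), 0.35,
                  b_default=+0.1, b_dorsal=+0.3),
        GroupSpec("AD", (2.0, 1.5, 1.3), (1.5, 1.5, 1.5), 0.45,
                  b_default=+0.05, b_dorsal=+0.3),
        GroupSpec("LBD", (1.6, 1.1, 0.9), (1.5, 1.5, 1.5), 0.55,
                  b_default=-0.2, b_dorsal=+0.3),
    )


def model_selection_groups() -> tuple:
    """Variant with condition-dependent boundaries (+0.25 / +0.5 under
    conflict) for model-comparison studies where both drift and boundary
    truly vary by condition."""
    out = []
    for g in default_groups():
        a0 = g.boundary[0]
        out.append(
            GroupSpec(g.label, g.drift, (a0, a0 + 0.25, a0 + 0.5), g.t0,
                      g.drift_sd, g.boundary_sd, g.t0_sd, g.b_default, g.b_dorsal)
        )
    return tuple(out)


def generate_trial_schedule(config: ScheduleConfig, seed: int) -> pd.DataFrame:
    """Event table for all runs of one subject.

    Each run permutes the two delay multisets (every printed delay value
    exactly three times) and randomly interleaves conditions subject to
    the per-run split.  Onset accounting: a cue lasts 200 ms, the target
    appears after the cue-target delay, and the next cue follows the
    target by the target-cue delay.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(config.n_runs):
        ctd = np.repeat(config.cue_target_delays, 3)
        tcd = np.repeat(config.target_cue_delays, 3)
        rng.shuffle(ctd)
        rng.shuffle(tcd)
        conds = np.repeat(np.arange(3), config.condition_split)
        rng.shuffle(conds)
        t = config.initial_fixation
        for k in range(config.trials_per_run):
            cue_onset = t
            target_onset = cue_onset + config.cue_duration + ctd[k]
            rows.append(
                {
                    "run": run,
                    "trial_index": k,
                    "condition": CONDITIONS[conds[k]],
                    "cue_onset": cue_onset,
                    "target_onset": target_onset,
                    "cue_target_delay": ctd[k],
                    "target_cue_delay": tcd[k],
                }
            )
            t = target_onset + tcd[k]
    return pd.DataFrame(rows)


def generate_coupled_trials(
    v_cond,
    a_cond,
    t0: float,
    conditions,
    betas,
    coupling: float,
    seed: int,
    p_outlier: float = 0.0,
    rt_max: float = 3.0,
    response_window: float | None = 3.0,
    dt: float = 1e-4,
) -> pd.DataFrame:
    """Simulate trials whose drift is shifted by a per-trial covariate.

    Trial k runs with drift ``v_cond[condition_k] + coupling * betas[k]``
    and the condition's boundary; boundary and non-decision time are
    unchanged by the covariate.  ``betas`` should be z-scored.  With
    ``coupling = 0`` the output is identical (same seed path) to
    uncoupled generation.  Trials whose rt would exceed the response
    window are emitted censored (``response = -1``, rt = NaN).
    """
    conditions = np.asarray(conditions)
    betas = np.asarray(betas, dtype=float)
    if not np.all(np.isfinite(betas)):
        raise ValueError("betas must be finite")
    cond_idx = np.array([CONDITIONS.index(c) for c in conditions])
    v_cond = np.asarray(v_cond, dtype=float)
    a_cond = np.asarray(a_cond, dtype=float)
    drift = v_cond[cond_idx] + coupling * betas
    bound = a_cond[cond_idx]
    if np.any(bound <= 0):
        raise ValueError("boundaries must be positive")

    rng = np.random.default_rng(seed)
    contam = rng.random(drift.size) < p_outlier
    em_seed = int(rng.integers(0, 2**31 - 1))
    ceiling = response_window if response_window is not None else 30.0
    rts, choices = em_sample(drift, bound, 0.5, t0, dt, ceiling, em_seed)
    n_c = int(contam.sum())
    if n_c:
        rts[contam] = rng.uniform(0.0, rt_max, n_c)
        choices[contam] = (rng.random(n_c) < 0.5).astype(np.int64)
    if response_window is not None:
        late = rts > response_window
        choices[late] = -1
        rts[np.asarray(late) | (choices == -1)] = np.nan
    return pd.DataFrame(
        {"condition": conditions, "response": choices, "rt": rts, "contaminant": contam}
    )


def generate_cohort(
    groups,
    n_subjects_per_group: int,
    schedule: ScheduleConfig | None = None,
    seed: int = 0,
    p_outlier: float = 0.05,
    networks: tuple = (),
    dt: float = 1e-4,
):
    """Simulate a full cohort; returns (trial table, ground-truth ledger).

    Subject parameters are drawn from the group distributions (normal
    offsets for drift, positively-truncated normal for boundary and
    non-decision time); condition effects are fixed at the group level.
    When ``networks`` names covariates (``"default"``, ``"dorsal"``),
    per-trial standard-normal network activations are drawn, recorded in
    ``beta_<network>`` columns, and coupled into the drift via the group
    coupling coefficients.
    """
    if n_subjects_per_group < 1:
        raise ValueError("need at least one subject per group")
    schedule = schedule or ScheduleConfig()
    rng = np.random.default_rng(seed)
    tables = []
    truth_rows = []
    for g in groups:
        dv = np.array(g.drift) - g.drift[0]
        da = np.array(g.boundary) - g.boundary[0]
        for i in range(n_subjects_per_group):
            sid = f"{g.label}-{i:02d}"
            v0 = rng.normal(g.drift[0], g.drift_sd)
            a0 = _trunc_normal(rng, g.boundary[0], g.boundary_sd, 0.05)
            t0 = _trunc_normal(rng, g.t0, g.t0_sd, 0.01)
            v_cond = v0 + dv
            a_cond = a0 + da
            sched = generate_trial_schedule(schedule, int(rng.integers(0, 2**31 - 1)))
            n_tr = len(sched)
            beta_cols = {}
            shift = np.zeros(n_tr)
            for net in networks:
                z = rng.standard_normal(n_tr)
                beta_cols[f"beta_{net}"] = z
                shift = shift + getattr(g, f"b_{net}") * z
            trials = generate_coupled_trials(
                v_cond, a_cond, t0, sched["condition"].to_numpy(), shift,
                1.0, int(rng.integers(0, 2**31 - 1)), p_outlier=p_outlier,
                rt_max=schedule.response_window,
                response_window=schedule.response_window, dt=dt,
            )
            trials.insert(0, "subject_id", sid)
            trials.insert(1, "group", g.label)
            trials.insert(2, "run", sched["run"].to_numpy())
            trials.insert(3, "trial_index", sched["trial_index"].to_numpy())
            trials["target_onset"] = sched["target_onset"].to_numpy()
            for name, vals in beta_cols.items():
                trials[name] = vals
            tables.append(trials)
            truth_rows.append(
                {
                    "subject_id": sid, "group": g.label,
                    "v_congruent": v_cond[0], "v_easy": v_cond[1], "v_hard": v_cond[2],
                    "a_congruent": a_cond[0], "a_easy": a_cond[1], "a_hard": a_cond[2],
                    "t0": t0,
                }
            )
    table = pd.concat(tables, ignore_index=True)
    truth = {
        "subjects": pd.DataFrame(truth_rows),
        "groups": {g.label: asdict(g) for g in groups},
        "p_outlier": p_outlier,
        "seed": seed,
    }
    return table, truth


def _trunc_normal(rng, mu, sd, lo):
    """Normal draw truncated below at ``lo`` (simple rejection)."""
    if sd == 0:
        return max(mu, lo)
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if x > lo:
            return x
    raise RuntimeError("truncated-normal rejection failed; check configuration")


def generate_bold_run(
    run_schedule: pd.DataFrame,
    amplitudes,
    config: BOLDRunConfig | None = None,
    seed: int = 0,
):
    """Synthesize one network-averaged BOLD run from trial amplitudes.

    The raw series is baseline * (1 + x/100) where the % modulation x
    sums the HRF-convolved trial responses, a low-frequency drift
    (confined to the span of the 128 s high-pass basis), a linear
    leakage of the six motion regressors, and AR(1) noise.  Returns
    ``(run, truth)`` where truth holds the generating amplitudes, the
    same amplitudes on the percent-of-run-mean scale an estimator of
    this run measures (``amplitudes_psc``), and a small voxel-by-time
    matrix sharing the network signal for QC exercises.
    """
    config = config or BOLDRunConfig()
    amplitudes = np.asarray(amplitudes, dtype=float)
    onsets = run_schedule["target_onset"].to_numpy()
    onsets = onsets - 0.0
    if amplitudes.size != onsets.size:
        raise ValueError("one amplitude per trial in the run is required")
    rng = np.random.default_rng(seed)
    n = config.n_volumes

    motion = np.empty((n, 6))
    steps = np.column_stack(
        [rng.normal(0, config.motion_step_mm, (n, 3)),
         rng.normal(0, config.motion_step_deg, (n, 3))]
    )
    motion[:] = np.cumsum(steps, axis=0)

    run = RunTimecourse(
        samples=np.zeros(n), tr=config.tr, onsets=onsets,
        durations=np.zeros(onsets.size), motion=motion, run=int(run_schedule["run"].iloc[0]),
    )
    regs = _convolved_regressors(run, canonical_hrf)
    dct = dct_highpass_basis(n, config.tr)
    drift_w = rng.normal(0, config.drift_amplitude, dct.shape[1]) if dct.shape[1] else np.zeros(0)

    noise = np.zeros(n)
    if config.noise_sd > 0:
        innov = rng.normal(0, config.noise_sd, n)
        rho = config.noise_ar1
        noise[0] = innov[0]
        for t in range(1, n):
            noise[t] = rho * noise[t - 1] + np.sqrt(1 - rho**2) * innov[t]

    x = regs @ amplitudes + dct @ drift_w + motion @ np.full(6, config.motion_leak) + noise
    run.samples = config.baseline * (1.0 + x / 100.0)

    psc_factor = 100.0 / (100.0 + x.mean())
    voxels = run.samples[None, :] + config.baseline * (
        rng.normal(0, config.voxel_noise_sd, (config.n_voxels, n)) / 100.0
    )
    truth = {
        "amplitudes": amplitudes,
        "amplitudes_psc": amplitudes * psc_factor,
        "voxels": voxels,
        "motion": motion,
        "drift_weights": drift_w,
    }
    return run, truth
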