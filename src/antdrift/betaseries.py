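"""Single-trial (beta-series) GLM estimation from network-averaged BOLD runs.

Each trial's target event enters the run-level general linear model as
its own HRF-convolved regressor, alongside six motion covariates, an
intercept and a discrete-cosine high-pass basis (periods above 128 s).
Ordinary least squares on the percent-signal-change-scaled time course
yields one beta (% BOLD signal change) per trial; an optional single-lag
autoregressive prewhitening removes serial correlation first.  Betas are
z-scored per subject before entering the drift-rate regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RunTimecourse",
    "BetaSeries",
    "canonical_hrf",
    "build_trial_design",
    "fit_beta_series",
    "zscore_betas",
    "qc_motion",
    "qc_dvars",
]

HIGHPASS_CUTOFF_S = 128.0
HRF_DURATION_S = 32.0


@dataclass
class RunTimecourse:
    """One run's network-averaged BOLD series plus its event schedule.

    samples : BOLD values at TR spacing (arbitrary scanner units).
    tr : repetition time, seconds (1.92 s in the emulated acquisition).
    onsets : trial target onsets, seconds from run start.
    durations : event durations, seconds (0 for stick functions).
    motion : (n_volumes, 6) motion-correction parameters
        (x/y/z translation in mm, three rotations in degrees).
    run : run identifier.
    """

    samples: np.ndarray
    tr: float
    onsets: np.ndarray
    durations: np.ndarray
    motion: np.ndarray
    run: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        dur = self.samples.size * self.tr
        if np.any(self.onsets < 0) or np.any(self.onsets >= dur):
            raise ValueError("event onsets must lie within the run duration")
        if self.motion.shape != (self.samples.size, 6):
            raise ValueError("motion must be (n_volumes, 6)")

    @property
    def duration(self) -> float:
        return self.samples.size * self.tr


@dataclass
class BetaSeries:
    """Per-trial beta estimates aligned to trial indices across runs."""

    table: pd.DataFrame  # columns: run, trial_index, beta
    zscored: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.table["beta"].to_numpy()


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma haemodynamic impulse response.

    Difference of two gamma densities (shapes 6 and 16, unit scale,
    undershoot ratio 1/6), peak-normalized to 1.  Peaks near 5 s with an
    undershoot around 15 s; zero at t = 0 and for t < 0.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    h = np.where(t < 0, 0.0, h)
    fine = np.linspace(0.0, HRF_DURATION_S, 3201)
    peak = np.max(stats.gamma.pdf(fine, 6.0) - stats.gamma.pdf(fine, 16.0) / 6.0)
    return h / peak


def dct_highpass_basis(n_volumes: int, tr: float, cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff_s``.

    The number of components is floor(2 * run_length / cutoff): each
    cosine k has period 2 * run_length / k, so this keeps every
    component slower than the cutoff.  The constant term is excluded
    (the design carries its own intercept).
    """
    run_len = n_volumes * tr
    n_comp = int(np.floor(2.0 * run_len / cutoff_s))
    frames = np.arange(n_volumes)
    basis = np.empty((n_volumes, n_comp))
    for k in range(1, n_comp + 1):
        basis[:, k - 1] = np.cos(np.pi * k * (2 * frames + 1) / (2 * n_volumes))
    return basis


def _convolved_regressors(run: RunTimecourse, hrf=canonical_hrf, dt: float = 0.05) -> np.ndarray:
    """One HRF-convolved unit-amplitude event regressor per trial,
    sampled at the volume acquisition times."""
    n_vol = run.samples.size
    n_fine = int(np.ceil(run.duration / dt)) + 1
    grid = np.arange(n_fine) * dt
    kernel = hrf(np.arange(0.0, HRF_DURATION_S + dt, dt))
    cols = np.empty((n_vol, run.onsets.size))
    vol_idx = np.round(np.arange(n_vol) * run.tr / dt).astype(int)
    for j, (onset, dur) in enumerate(zip(run.onsets, run.durations)):
        stick = np.zeros(n_fine)
        i0 = int(np.round(onset / dt))
        if dur <= dt:
            stick[i0] = 1.0
        else:
            i1 = min(n_fine, i0 + int(np.round(dur / dt)))
            stick[i0:i1] = 1.0
        conv = np.convolve(stick, kernel)[:n_fine]
        cols[:, j] = conv[vol_idx]
    return cols


def build_trial_design(run: RunTimecourse, hrf=canonical_hrf) -> pd.DataFrame:
    """Design matrix with one regressor per trial plus nuisance columns.

    Columns: ``trial_00 .. trial_NN`` (HRF-convolved events), the six
    motion parameters, ``intercept``, and ``dct_1 ..`` high-pass
    components for periods above 128 s.
    """
    onsets = run.onsets
    if np.unique(np.round(onsets, 6)).size != onsets.size:
        raise ValueError("duplicate event onsets in run")
    trial_cols = _convolved_regressors(run, hrf)
    dct = dct_highpass_basis(run.samples.size, run.tr)
    names = [f"trial_{j:02d}" for j in range(onsets.size)]
    names += [f"motion_{k}" for k in range(6)]
    names += ["intercept"] + [f"dct_{k + 1}" for k in range(dct.shape[1])]
    mat = np.column_stack(
        [trial_cols, run.motion, np.ones(run.samples.size), dct]
    )
    return pd.DataFrame(mat, columns=names)


def percent_signal_change(samples: np.ndarray) -> np.ndarray:
    """Scale a raw series to percent change about its run mean."""
    mean = float(np.mean(samples))
    if mean == 0:
        raise ValueError("run mean is zero; cannot scale to percent signal change")
    return 100.0 * (samples / mean - 1.0)


def fit_beta_series(
    run: RunTimecourse,
    design: pd.DataFrame | None = None,
    whiten: bool = False,
) -> BetaSeries:
    """Estimate one beta (% BOLD signal change) per trial by OLS.

    With ``whiten=True`` an AR(1) coefficient is estimated from the
    pooled OLS residuals and both sides are prewhitened before the
    final solve.  Falls back to a small ridge penalty (with a warning)
    if the design is rank-deficient.
    """
    if design is None:
        design = build_trial_design(run)
    y = percent_signal_change(run.samples)
    X = design.to_numpy()
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in design or data")

    def solve(Xm, ym):
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            warnings.warn("rank-deficient design; using ridge fallback", stacklevel=2)
            lam = 1e-8 * np.trace(Xm.T @ Xm) / Xm.shape[1]
            return np.linalg.solve(Xm.T @ Xm + lam * np.eye(Xm.shape[1]), Xm.T @ ym)
        return np.linalg.lstsq(Xm, ym, rcond=None)[0]

    coef = solve(X, y)
    if whiten:
        resid = y - X @ coef
        rho = float(np.sum(resid[1:] * resid[:-1]) / np.sum(resid[:-1] ** 2))
        rho = float(np.clip(rho, -0.98, 0.98))
        yw = np.empty_like(y)
        Xw = np.empty_like(X)
        scale = np.sqrt(1.0 - rho**2)
        yw[0] = y[0] * scale
        Xw[0] = X[0] * scale
        yw[1:] = y[1:] - rho * y[:-1]
        Xw[1:] = X[1:] - rho * X[:-1]
        coef = solve(Xw, yw)

    n_trials = run.onsets.size
    table = pd.DataFrame(
        {
            "run": run.run,
            "trial_index": np.arange(n_trials),
            "beta": coef[:n_trials],
        }
    )
    return BetaSeries(table=table)


def zscore_betas(series: BetaSeries) -> BetaSeries:
    """Z-score the betas (mean 0, SD 1) across all trials in the series.

    The scope is per subject: concatenate all of a subject's runs into
    one series before calling.  Raises on degenerate (constant) input.
    """
    vals = series.values
    if vals.size < 2:
        raise ValueError("need at least two betas to z-score")
    sd = float(np.std(vals))
    if sd == 0:
        raise ValueError("beta series has zero variance; cannot z-score")
    table = series.table.copy()
    table["beta"] = (vals - np.mean(vals)) / sd
    return BetaSeries(table=table, zscored=True)


def qc_motion(motion: np.ndarray) -> dict:
    """Frame-to-frame motion summaries.

    Returns the mean and maximum Euclidean displacement between
    consecutive frames, separately for the three translation columns
    (mm) and the three rotation columns (degrees).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] < 2:
        raise ValueError("need at least two frames")
    d = np.diff(motion, axis=0)
    trans = np.linalg.norm(d[:, :3], axis=1)
    rot = np.linalg.norm(d[:, 3:], axis=1)
    return {
        "mean_translation_mm": float(np.mean(trans)),
        "max_translation_mm": float(np.max(trans)),
        "mean_rotation_deg": float(np.mean(rot)),
        "max_rotation_deg": float(np.max(rot)),
    }


def qc_dvars(frames: np.ndarray) -> dict:
    """Standardized DVARS of a voxel-by-time matrix.

    Raw DVARS at each transition is the root-mean-square over voxels of
    the temporal difference.  Standardization divides by the expected
    raw value for stationary noise, computed from the per-voxel robust
    (half-IQR-based) variance of the differences, so an i.i.d. noise
    series averages ~1.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[1] < 2:
        raise ValueError("need a voxel x time matrix with >= 2 time points")
    d = np.diff(frames, axis=1)
    raw = np.sqrt(np.mean(d**2, axis=0))
    iqr = np.subtract(*np.percentile(d, [75, 25], axis=1))
    robust_sd = iqr / 1.349
    expected = float(np.sqrt(np.mean(robust_sd**2)))
    if expected == 0:
        std = np.full_like(raw, np.nan)
    else:
        std = raw / expected
    return {
        "raw": raw,
        "standardized": std,
        "mean_standardized": float(np.mean(std)),
    }
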