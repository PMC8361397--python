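"""Wiener diffusion decision process: densities, closed forms, samplers.

The model describes a two-choice decision as noisy evidence accumulating
from a starting point ``z_rel * a`` between two absorbing boundaries at 0
(lower / error) and ``a`` (upper / correct), with mean rate ``v`` and
unit diffusion scale (s = 1).  The observed response time is the first
passage time plus a non-decision offset ``t0``.  A small uniform
contaminant mixture absorbs fast guesses and lapses.

Accuracy coding is used throughout: the upper boundary is the correct
response.  This is appropriate for tasks with counterbalanced left/right
responses and an unbiased starting point (``z_rel = 0.5``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._wfpt import em_sample, loglik_block, wfpt_logp

__all__ = [
    "DDMParams",
    "wfpt_log_density",
    "choice_probability",
    "mean_decision_time",
    "simulate_trials",
    "trials_to_csv",
    "trials_from_csv",
]

#: conditions of the flanker task, in increasing order of perceptual conflict
CONDITIONS = ("congruent", "incongruent-EASY", "incongruent-HARD")

TRIAL_COLUMNS = ["subject_id", "group", "run", "trial_index", "condition", "response", "rt"]


@dataclass(frozen=True)
class DDMParams:
    """One subject-condition diffusion parameterization (s = 1 scale).

    Parameters
    ----------
    v : drift rate, evidence units per second.
    a : boundary separation, evidence units (> 0).
    z_rel : relative starting point in (0, 1); 0.5 means no bias.
    t0 : non-decision time, seconds.
    p_outlier : contaminant mixture weight in [0, 1).
    rt_max : upper support of the uniform contaminant, seconds; defaults
        to the 3 s task response window.
    """

    v: float
    a: float
    z_rel: float = 0.5
    t0: float = 0.3
    p_outlier: float = 0.0
    rt_max: float = 3.0

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got {self.a}")
        if not (0 < self.z_rel < 1):
            raise ValueError(f"relative start must be in (0,1), got {self.z_rel}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")
        if not (0 <= self.p_outlier < 1):
            raise ValueError(f"contaminant weight must be in [0,1), got {self.p_outlier}")
        if self.rt_max <= self.t0:
            raise ValueError("contaminant support rt_max must exceed t0")


def wfpt_log_density(rt, choice, params: DDMParams, eps: float = 1e-6):
    """Log first-passage density at the indicated boundary.

    ``choice`` is 1 for the upper (correct) boundary, 0 for the lower.
    Vectorized over ``rt``/``choice``.  The series truncation error of
    the diffusion component is below ``eps``; with ``p_outlier > 0`` the
    result is finite for any ``rt`` inside the contaminant support.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    rt_arr = np.asarray(rt, dtype=float)
    ch_arr = np.broadcast_to(np.asarray(choice, dtype=np.int64), rt_arr.shape)
    if np.any(rt_arr <= 0):
        raise ValueError("response times must be positive")
    out = np.empty(rt_arr.shape)
    flat_rt = rt_arr.ravel()
    flat_ch = ch_arr.ravel()
    flat_out = out.ravel()
    for i in range(flat_rt.size):
        flat_out[i] = wfpt_logp(
            flat_rt[i], flat_ch[i], params.v, params.a, params.z_rel,
            params.t0, params.p_outlier, params.rt_max, eps,
        )
    return out if out.shape else float(out)


def choice_probability(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary.

    For drift v, separation a and start z_rel*a (unit diffusion scale)
    this is (1 - exp(-2 v a z_rel)) / (1 - exp(-2 v a)); at z_rel = 0.5
    it reduces to the logistic 1 / (1 + exp(-v a)).
    """
    if params.p_outlier > 0:
        raise ValueError("choice_probability is defined for the pure diffusion (p_outlier = 0)")
    v, a, z = params.v, params.a, params.z_rel
    if abs(v) < 1e-12:
        return z
    x = z * a
    # numerically stable form of expm1 ratio
    return math.expm1(-2.0 * v * x) / math.expm1(-2.0 * v * a)


def mean_decision_time(params: DDMParams) -> float:
    """Closed-form unconditional mean first-passage time (excludes t0).

    General-start formula (a/v) * P_upper - z/v with the drift-free
    limit z (a - z); at z_rel = 0.5 this is (a / 2v) tanh(v a / 2), with
    limit a^2 / 4 as v -> 0.
    """
    if params.p_outlier > 0:
        raise ValueError("mean_decision_time is defined for the pure diffusion (p_outlier = 0)")
    v, a = params.v, params.a
    z = params.z_rel * a
    if abs(v) < 1e-8:
        return z * (a - z)
    return (a * choice_probability(params) - z) / v


def simulate_trials(
    params: DDMParams,
    n: int,
    seed: int,
    dt: float = 1e-4,
    t_ceiling: float = 30.0,
) -> pd.DataFrame:
    """Draw ``n`` independent (choice, rt) pairs by Euler–Maruyama.

    Contaminant trials (weight ``p_outlier``) get a uniform rt on
    (0, rt_max) and a fair coin choice.  Diffusion paths unabsorbed at
    ``t_ceiling`` seconds of decision time are returned with
    ``response = -1`` and ``rt = NaN`` (censored).  Identical seeds give
    identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    contam = rng.random(n) < params.p_outlier
    drift = np.full(n, params.v)
    bound = np.full(n, params.a)
    em_seed = int(rng.integers(0, 2**31 - 1))
    rts, choices = em_sample(drift, bound, params.z_rel, params.t0, dt, t_ceiling, em_seed)
    n_c = int(contam.sum())
    if n_c:
        rts[contam] = rng.uniform(0.0, params.rt_max, n_c)
        choices[contam] = (rng.random(n_c) < 0.5).astype(np.int64)
    return pd.DataFrame(
        {"rt": rts, "response": choices, "contaminant": contam, "trial_index": np.arange(n)}
    )


def trials_to_csv(table: pd.DataFrame, path) -> None:
    """Write a behavioural trial table to CSV (rt in seconds, 6 d.p.)."""
    cols = [c for c in TRIAL_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.6f")


def trials_from_csv(path) -> pd.DataFrame:
    """Read a behavioural trial table written by :func:`trials_to_csv`."""
    return pd.read_csv(path)
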