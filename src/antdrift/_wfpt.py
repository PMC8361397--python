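"""Low-level compiled kernels for the Wiener diffusion process.

Everything here assumes the *unit* diffusion-scale convention (s = 1): a
drift rate of 1 means one evidence unit per second of standard-normal
noise with variance 1 per second.  Parameter magnitudes are therefore not
comparable with implementations using the s = 0.1 convention.

The first-passage density uses the two classical series expansions of the
density for a Brownian motion with drift between two absorbing barriers:
a small-time expansion (sum over image charges) and a large-time
expansion (spectral sine series).  For each evaluation the number of
terms needed by either series to reach the requested tolerance is bounded
analytically and the cheaper series is used.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# first-passage density
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fpt_std(u, w, eps):
    """Density of first passage through the lower barrier for the
    standardized process (a = 1, v = 0) at scaled time ``u``, relative
    start ``w``; series truncated so the error is below ``eps``."""
    if u <= 0.0:
        return 0.0

    # analytic term-count bounds for either expansion
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        if ks < math.sqrt(u) + 1.0:
            ks = math.sqrt(u) + 1.0
    else:
        ks = 2.0
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    p = 0.0
    if ks < kl:  # small-time expansion is cheaper
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            q = w + 2.0 * k
            p += q * math.exp(-q * q / (2.0 * u))
        p /= math.sqrt(2.0 * math.pi * u * u * u)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def wfpt_logp(rt, choice, v, a, z_rel, t0, p_outlier, rt_max, eps):
    """Log of the defective first-passage density at ``rt`` for the
    indicated boundary (choice 1 = upper, 0 = lower), mixed with a
    uniform contaminant of weight ``p_outlier`` on (0, rt_max) split
    evenly across choices."""
    contam = 0.0
    if p_outlier > 0.0 and 0.0 < rt < rt_max:
        contam = p_outlier * 0.5 / rt_max

    t = rt - t0
    dens = 0.0
    if t > 0.0:
        if choice == 1:  # upper boundary: reflect
            drift = -v
            w = 1.0 - z_rel
        else:
            drift = v
            w = z_rel
        u = t / (a * a)
        f = _fpt_std(u, w, eps)
        if f > 0.0:
            dens = math.exp(-drift * a * w - drift * drift * t / 2.0) / (a * a) * f
    total = (1.0 - p_outlier) * dens + contam
    if total <= 0.0:
        return -np.inf
    return math.log(total)


@njit(cache=True)
def loglik_block(rt, choice, drift, bound, t0, p_outlier, rt_max, eps):
    """Summed trial log-likelihood with per-trial drift and boundary."""
    total = 0.0
    for i in range(rt.shape[0]):
        lp = wfpt_logp(rt[i], choice[i], drift[i], bound[i], 0.5, t0, p_outlier, rt_max, eps)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


@njit(cache=True)
def loglik_cond(rt, choice, cov_shift, xcol, delta, v_eff, a_eff, t0, p_outlier, rt_max, eps):
    """Summed log-likelihood of one subject-condition block.

    Per-trial drift is ``v_eff + cov_shift[i] + xcol[i] * delta`` (the
    delta term lets a covariate-coefficient proposal be evaluated
    without rebuilding the shift array); boundary is the scalar
    ``a_eff``.  Non-positive effective boundaries are impossible.
    """
    if a_eff <= 0.05:
        return -np.inf
    total = 0.0
    for i in range(rt.shape[0]):
        lp = wfpt_logp(
            rt[i], choice[i], v_eff + cov_shift[i] + xcol[i] * delta,
            a_eff, 0.5, t0, p_outlier, rt_max, eps,
        )
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


# ---------------------------------------------------------------------------
# Euler–Maruyama trial sampler
# ---------------------------------------------------------------------------


#: Broadie–Glasserman–Kou constant: a discretely monitored barrier acts
#: like a continuous one shifted outward by this multiple of sigma*sqrt(dt)
_BGK = 0.5826


@njit(cache=True)
def em_sample(drift, bound, z_rel, t0, dt, t_ceiling, seed, bg_correct=True):
    """Simulate one diffusion trial per (drift, bound) pair.

    Returns (rt, choice); choice is 1 for upper absorption, 0 for lower,
    -1 when the path is still unabsorbed at ``t_ceiling`` (decision time,
    excluding t0).  Deterministic for a fixed seed.

    With ``bg_correct`` the path is monitored against barriers inset by
    0.5826 * sqrt(dt), cancelling the first-order discretization bias of
    discrete barrier monitoring.
    """
    np.random.seed(seed)
    n = drift.shape[0]
    rts = np.empty(n)
    choices = np.empty(n, dtype=np.int64)
    sqdt = math.sqrt(dt)
    inset = _BGK * sqdt if bg_correct else 0.0
    max_steps = int(t_ceiling / dt)
    chunk = 1024
    for i in range(n):
        a = bound[i] - inset
        vdt = drift[i] * dt
        x = z_rel * bound[i]
        step = 0
        choice = -1
        while step < max_steps and choice < 0:
            noise = np.random.standard_normal(chunk)
            for j in range(chunk):
                step += 1
                x += vdt + sqdt * noise[j]
                if x >= a:
                    choice = 1
                    break
                if x <= inset:
                    choice = 0
                    break
                if step >= max_steps:
                    break
        choices[i] = choice
        if choice >= 0:
            rts[i] = t0 + step * dt
        else:
            rts[i] = np.nan
    return rts, choices
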