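"""Numba kernel for the clip-window marginal likelihood.

Computes, per annotated 15-s window, the probability that the classifier's
total for one target class equals the observed count — the convolution of
the four per-source double-Poisson pmfs — and accumulates log probabilities
per recording.  Numerically equivalent to the pure-numpy path in
:mod:`.confusion` (which remains the exact reference); the normalization
constant and the mean-calibrated raw parameter are linearly interpolated
from a :class:`~vocalib.dpo.LognormTable` grid exactly as in that path.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _interp(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    t = (x - xs[lo]) / (xs[hi] - xs[lo])
    return ys[lo] + t * (ys[hi] - ys[lo])


@njit(cache=True)
def lognorm_table_kernel(targets, tau, raw0, rtol, max_iter):
    """Mean-calibrated raw parameters and log normalization constants.

    For every target mean, Newton-solves the raw Efron parameter so that the
    renormalized density has exactly that mean, returning (raw, lognorm).
    Same windowed truncation (tail < 1e-12) as the numpy reference path.
    """
    n = targets.shape[0]
    out_raw = np.empty(n)
    out_ln = np.empty(n)
    half_ltau = 0.5 * np.log(tau)
    for idx in range(n):
        t = targets[idx]
        raw = raw0[idx]
        lognorm = 0.0
        for _ in range(max_iter):
            sd = np.sqrt(max(raw, 1e-12) / tau)
            lo = int(max(0.0, np.floor(raw - 16.0 * sd) - 2.0))
            hi = int(np.ceil(raw + 16.0 * sd)) + 30
            lraw = np.log(raw)
            base = half_ltau - tau * raw
            # peak of the summand is near y ~ raw; subtract for stability
            ym = float(int(raw))
            ylogym = ym * np.log(ym) if ym > 0 else 0.0
            peak = (tau - 1.0) * (ym - ylogym) - math.lgamma(ym + 1.0) + tau * ym * lraw
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            for y in range(lo, hi + 1):
                yf = float(y)
                ylogy = yf * np.log(yf) if y > 0 else 0.0
                lw = (tau - 1.0) * (yf - ylogy) - math.lgamma(yf + 1.0) + tau * yf * lraw - peak
                w = np.exp(lw)
                s0 += w
                s1 += w * yf
                s2 += w * yf * yf
            if s0 <= 0.0:
                s0 = 1e-300
            mean = s1 / s0
            var = s2 / s0 - mean * mean
            lognorm = base + peak + np.log(s0)
            err = mean - t
            if abs(err) <= rtol * max(t, 1e-300):
                break
            step = err * raw / max(tau * var, 1e-300)
            nxt = raw - step
            if nxt < 0.25 * raw:
                nxt = 0.25 * raw
            elif nxt > 4.0 * raw:
                nxt = 4.0 * raw
            raw = nxt
        out_raw[idx] = raw
        out_ln[idx] = lognorm
    return out_raw, out_ln


@njit(cache=True)
def recording_col_kernel(
    lam_col,  # (K, 4) rates feeding the target class
    v,  # (K, 4) latent true counts
    n_obs,  # (K,) observed totals for the target class
    tau,
    log_grid,  # LognormTable grids
    log_raw,
    lognorms,
    m_lo,
    m_hi,
):
    """Continuous-count log pmf of each recording's total for one class."""
    K = lam_col.shape[0]
    out = np.empty(K)
    half_ltau = 0.5 * np.log(tau)
    for k in range(K):
        m = 0.0
        for i in range(4):
            m += lam_col[k, i] * v[k, i]
        mm = min(max(m, m_lo), m_hi)
        lm = np.log(mm)
        raw = np.exp(_interp(lm, log_grid, log_raw))
        ln = _interp(lm, log_grid, lognorms)
        y = float(n_obs[k])
        ylogy = y * np.log(y) if y > 0 else 0.0
        out[k] = (
            half_ltau
            - tau * raw
            - math.lgamma(y + 1.0)
            + (tau - 1.0) * (y - ylogy)
            + tau * y * np.log(raw)
            - ln
        )
    return out


@njit(cache=True)
def col_loglik_kernel(
    lam_col,  # (n_rec, 4) rates feeding the target class
    tau,
    V,  # (W, 4) true counts per window
    nj,  # (W,) observed totals for the target class
    rec_idx,  # (W,)
    n_rec,
    log_grid,  # LognormTable grids
    log_raw,
    lognorms,
    lgam,  # cached y-tables
    ylogy,
    m_lo,
    m_hi,
):
    out = np.zeros(n_rec)
    half_ltau = 0.5 * np.log(tau)
    pmf = np.zeros(64)
    acc = np.zeros(64)
    nxt = np.zeros(64)
    for w in range(V.shape[0]):
        ymax = nj[w]
        rec = rec_idx[w]
        first = True
        for i in range(4):
            m = V[w, i] * lam_col[rec, i]
            if m <= 0.0:
                for y in range(ymax + 1):
                    pmf[y] = 0.0
                pmf[0] = 1.0
            else:
                mm = min(max(m, m_lo), m_hi)
                lm = np.log(mm)
                raw = np.exp(_interp(lm, log_grid, log_raw))
                ln = _interp(lm, log_grid, lognorms)
                lraw = np.log(raw)
                base = half_ltau - tau * raw - ln
                for y in range(ymax + 1):
                    pmf[y] = np.exp(
                        base - lgam[y] + (tau - 1.0) * ylogy[y] + tau * y * lraw
                    )
            if first:
                for y in range(ymax + 1):
                    acc[y] = pmf[y]
                first = False
            else:
                for y in range(ymax + 1):
                    nxt[y] = 0.0
                for a in range(ymax + 1):
                    va = acc[a]
                    if va > 0.0:
                        for b in range(ymax + 1 - a):
                            nxt[a + b] += va * pmf[b]
                for y in range(ymax + 1):
                    acc[y] = nxt[y]
        p = acc[ymax]
        if p < 1e-300:
            p = 1e-300
        out[rec] += np.log(p)
    return out
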