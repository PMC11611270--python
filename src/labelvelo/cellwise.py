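"""Gene-cell-specific rates via duration-stratified kNN neighborhoods.

The gene-wise fits assume constant rates across cells; this post-processing
relaxes everything except the degradation rate.  Within each cell's
neighborhood N_{j,t_k} (same labeling duration, similar expression) the
counts are treated as locally homogeneous, giving the pooled local estimator

    lhat_j = sum_{i in N_j} l_i / sum_{i in N_j} p_i,

from which the cell-specific transcription rate follows in closed form once
gamma is fixed from the gene-wise fit.  For the splicing model the local
spliced/unspliced ratio determines a cell-specific splicing rate by
root-finding; for the switching model only the product alpha * (1 - p_off)
is identifiable and it obeys the same closed form as the baseline.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .data_model import Neighborhoods
from .distributions import mean_new_splicing

__all__ = [
    "pooled_local_estimator",
    "cellwise_baseline",
    "cellwise_splicing",
    "cellwise_switching",
]


def pooled_local_estimator(x, p, neighborhoods: Neighborhoods) -> np.ndarray:
    """lhat_j = sum_N x / sum_N p per cell (vector x) — exact x_j/p_j at k=1."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.empty(x.shape[0])
    for j in range(x.shape[0]):
        neigh = neighborhoods[j]
        out[j] = x[neigh].sum() / p[neigh].sum()
    return out


def cellwise_baseline(l, p, neighborhoods: Neighborhoods, gamma_t: float, t) -> np.ndarray:
    """Cell-specific transcription rate alpha_j = lhat_j gamma_t / (1 - e^{-gamma_t t_j})."""
    if gamma_t <= 0:
        raise ValueError("gamma_t must be positive (fixed from the gene-wise fit)")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("labeling durations must be positive")
    lhat = pooled_local_estimator(l, p, neighborhoods)
    return lhat * gamma_t / -np.expm1(-gamma_t * t)


def cellwise_switching(l, p, neighborhoods: Neighborhoods, gamma_t: float, t) -> np.ndarray:
    """Cell-specific (alpha (1 - p_off))_j — the moment shortcut shares the
    baseline closed form, applied to the local labeled mean."""
    return cellwise_baseline(l, p, neighborhoods, gamma_t, t)


def cellwise_splicing(
    ul,
    sl,
    p,
    neighborhoods: Neighborhoods,
    gamma_s: float,
    beta_init: float,
    t,
    tol: float = 1e-10,
):
    """Cell-specific (alpha_j, beta_j) for the splicing model.

    Solves the local ratio equation shat/uhat = c(t; 1, beta, gamma_s) /
    b(t; 1, beta, gamma_s) for beta_j by bisection after geometric bracket
    expansion around the gene-wise ``beta_init`` (bracket capped at
    [1e-4, 100] x beta_init); then alpha_j = uhat beta_j / (1 - e^{-beta_j t}).
    Cells with uhat = 0 get (0, 0); cells without a root fall back to the
    global beta.  Returns ``(alpha, beta, flags)`` where flags marks fallback
    or zero cells.
    """
    if gamma_s <= 0 or beta_init <= 0:
        raise ValueError("gamma_s and beta_init must be positive")
    t = np.asarray(t, dtype=float)
    uhat = pooled_local_estimator(ul, p, neighborhoods)
    shat = pooled_local_estimator(sl, p, neighborhoods)
    n = uhat.shape[0]
    alpha = np.zeros(n)
    beta = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    lo_cap, hi_cap = 1e-4 * beta_init, 100.0 * beta_init
    for j in range(n):
        if uhat[j] <= 0:
            flags[j] = True
            continue
        ratio = shat[j] / uhat[j]
        tj = t[j]

        def f(b):
            bb, cc = mean_new_splicing(1.0, b, gamma_s, tj)
            return cc / bb - ratio

        if ratio <= 0:
            # no spliced signal: beta at the lower bracket boundary
            beta[j] = lo_cap
            flags[j] = True
        else:
            lo = hi = beta_init
            f0 = f(beta_init)
            root = None
            if f0 == 0:
                root = beta_init
            elif f0 > 0:
                # c/b too large: shrink beta
                while lo > lo_cap and f(lo) > 0:
                    lo /= 2.0
                if f(max(lo, lo_cap)) <= 0:
                    root = brentq(f, max(lo, lo_cap), hi, xtol=tol)
                else:
                    beta[j] = lo_cap
                    flags[j] = True
            else:
                while hi < hi_cap and f(hi) < 0:
                    hi *= 2.0
                if f(min(hi, hi_cap)) >= 0:
                    root = brentq(f, lo, min(hi, hi_cap), xtol=tol)
                else:
                    beta[j] = beta_init
                    flags[j] = True
            if root is not None:
                beta[j] = root
        if beta[j] > 0:
            alpha[j] = uhat[j] * beta[j] / -np.expm1(-beta[j] * t[j])
    return alpha, beta, flags
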