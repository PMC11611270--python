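"""Closed-form count distributions for metabolically labeled mRNA.

Three chemical master equations describe the accumulation of new (labeled)
transcripts over a labeling window of length ``t``:

* **baseline** — transcription at rate ``alpha`` and first-order degradation of
  total mRNA at rate ``gamma_t``.  The labeled count is Poisson with mean
  ``a(t) = alpha (1 - exp(-gamma_t t)) / gamma_t``.
* **splicing** — transcription, splicing at rate ``beta`` and degradation of
  spliced mRNA at rate ``gamma_s``.  Labeled unspliced and spliced counts are
  independent Poisson with means ``b(t)`` and ``c(t)``.
* **switching** — a slow on/off promoter; a fraction ``p_off`` of cells is
  silent, the rest behave like the baseline model, giving a zero-inflated
  Poisson.

Sequencing capture is modeled as binomial thinning with per-cell probability
``p_j`` (the size factor).  Poisson thinning keeps the family closed: measured
counts follow the same laws with means multiplied by ``p_j``.  These are the
cell-specific Poisson (CSP), independent cell-specific Poisson (ICSP) and
cell-specific zero-inflated Poisson (CSZIP) distributions.

All rates are per hour, durations in hours.  Computation is in log space;
samplers take an explicit :class:`numpy.random.Generator` or seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "mean_new_baseline",
    "mean_new_splicing",
    "csp_logpmf",
    "icsp_logpmf",
    "cszip_logpmf",
    "csp_sample",
    "icsp_sample",
    "cszip_sample",
]

#: relative tolerance below which beta and gamma_s are treated as equal
EQUAL_RATE_TOL = 1e-8


def _phi(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, with the x -> 0 limit of 1, cancellation-safe."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def _check_nonneg(**kwargs) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite")
        if np.any(arr < 0):
            raise ValueError(f"{name} must be non-negative")


def mean_new_baseline(alpha, gamma_t, t):
    """Mean labeled count ``a(t) = alpha (1 - e^{-gamma_t t}) / gamma_t``.

    Returns ``alpha * t`` in the ``gamma_t -> 0`` limit.  Broadcasts over any
    argument.
    """
    _check_nonneg(alpha=alpha, gamma_t=gamma_t, t=t)
    alpha, gamma_t, t = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (alpha, gamma_t, t))
    )
    out = alpha * t * _phi(gamma_t * t)
    if out.ndim == 0:
        return float(out)
    return out


def mean_new_splicing(alpha, beta, gamma_s, t):
    """Mean labeled unspliced/spliced counts ``(b(t), c(t))``.

    ``b(t) = alpha (1 - e^{-beta t}) / beta`` and

    ``c(t) = alpha/gamma_s (1 - e^{-gamma_s t})
             + alpha/(gamma_s - beta) (e^{-gamma_s t} - e^{-beta t})``

    with the equal-rate branch ``c = alpha/beta (1 - e^{-beta t})
    - alpha t e^{-beta t}`` taken when |beta - gamma_s| is within
    :data:`EQUAL_RATE_TOL` relative.  Both branches are evaluated through
    ``expm1`` so the general form stays cancellation-safe arbitrarily close to
    the boundary.
    """
    _check_nonneg(alpha=alpha, beta=beta, gamma_s=gamma_s, t=t)
    alpha, beta, gamma_s, t = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (alpha, beta, gamma_s, t))
    )
    b = alpha * t * _phi(beta * t)
    # c(t) = alpha t phi(g t) - alpha t e^{-g t} phi((beta - g) t); the second
    # term reduces exactly to the printed equal-rate branch when beta == g.
    equal = np.abs(beta - gamma_s) < EQUAL_RATE_TOL * np.maximum(beta, gamma_s)
    diff = np.where(equal, 0.0, beta - gamma_s)
    x = diff * t
    # e^{-g t} phi(x) = (e^{-g t} - e^{-beta t}) / x; expm1 form for small |x|
    # (cancellation), direct difference for large |x| (overflow-safe)
    small = np.abs(x) < 1.0
    with np.errstate(over="ignore", invalid="ignore"):
        term_small = np.exp(-gamma_s * t) * _phi(np.where(small, x, 0.0))
        term_large = np.where(
            x != 0, (np.exp(-gamma_s * t) - np.exp(-beta * t)) / np.where(x != 0, x, 1.0), 0.0
        )
    term = np.where(small, term_small, term_large)
    c = alpha * t * (_phi(gamma_s * t) - term)
    if b.ndim == 0:
        return float(b), float(c)
    return b, c


def _check_counts(n, name: str = "n") -> np.ndarray:
    arr = np.asarray(n)
    if not np.issubdtype(arr.dtype, np.integer):
        flo = np.asarray(arr, dtype=float)
        if np.any(flo != np.floor(flo)):
            raise ValueError(f"{name} must be integer counts")
        arr = flo.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def csp_logpmf(n, p_j, a):
    """log PMF of the cell-specific Poisson: ``Poisson(n; p_j * a)``."""
    n = _check_counts(n)
    _check_nonneg(p_j=p_j, a=a)
    if np.any(np.asarray(p_j, dtype=float) <= 0):
        raise ValueError("p_j must be strictly positive")
    return stats.poisson.logpmf(n, np.asarray(p_j, dtype=float) * np.asarray(a, dtype=float))


def icsp_logpmf(m, n, p_j, b, c):
    """log PMF of the independent cell-specific Poisson pair ``(m, n)``."""
    return csp_logpmf(m, p_j, b) + csp_logpmf(n, p_j, c)


def cszip_logpmf(n, p_j, a, p_off):
    """log PMF of the cell-specific zero-inflated Poisson.

    ``P(0) = p_off + (1 - p_off) e^{-p_j a}``;
    ``P(n>=1) = (1 - p_off) Poisson(n; p_j a)``.
    """
    p_off = np.asarray(p_off, dtype=float)
    if np.any(p_off < 0) or np.any(p_off > 1):
        raise ValueError("p_off must lie in [0, 1]")
    n = _check_counts(n)
    pois = csp_logpmf(n, p_j, a)
    n_b, p_off_b, pois = np.broadcast_arrays(n, p_off, pois)
    with np.errstate(divide="ignore"):
        log_poff = np.log(p_off_b)
        log_pon = np.log1p(-p_off_b)
    positive = np.where(np.isneginf(log_pon) & np.isneginf(pois), -np.inf, log_pon + pois)
    at_zero = np.logaddexp(log_poff, positive)
    out = np.where(n_b == 0, at_zero, positive)
    if out.ndim == 0:
        return float(out)
    return out


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def csp_sample(p_j, a, seed, size=None):
    """Draw CSP counts; ``p_j`` may be a vector (one draw per cell)."""
    rng = _rng(seed)
    mean = np.asarray(p_j, dtype=float) * float(a)
    return rng.poisson(mean, size=size if size is not None else mean.shape)


def icsp_sample(p_j, b, c, seed):
    rng = _rng(seed)
    p = np.asarray(p_j, dtype=float)
    return rng.poisson(p * float(b)), rng.poisson(p * float(c))


def cszip_sample(p_j, a, p_off, seed):
    rng = _rng(seed)
    p = np.asarray(p_j, dtype=float)
    on = rng.random(p.shape) >= float(p_off)
    return np.where(on, rng.poisson(p * float(a)), 0)
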