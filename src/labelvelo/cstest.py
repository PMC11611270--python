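"""Goodness-of-fit testing for cell-specific count distributions.

The classical Pearson chi-square test assumes every observation shares one
categorical law.  Here every cell i has its own fitted distribution (CSP,
ICSP or CSZIP with cell-specific mean ``p_i a``), so the test is rebuilt from
the central limit theorem for independent, non-identically distributed
indicator vectors: with per-cell class-probability vectors ``p_i`` over ``c``
contiguous count classes, the statistic

    chi2 = n (Xbar* - pbar*)^T (Sigmabar*)^{-1} (Xbar* - pbar*)

uses the truncated (c-1)-dimensional class indicators and the averaged
covariance ``Sigmabar* = mean_i [diag(p_i*) - p_i* p_i*^T]``, and is
asymptotically chi-square with ``c - 1`` degrees of freedom.  One degree of
freedom is subtracted per parameter fitted from the same cells.  When all
cells share the same ``p_i`` the statistic reduces exactly to Pearson's.

Classes are contiguous count intervals built greedily from zero upward so
that each class carries total expected count >= 0.25; when fewer than two
classes survive (or the parameter correction exhausts the degrees of
freedom) the verdict is "UTD" — unable to determine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distributions import csp_logpmf, cszip_logpmf

__all__ = [
    "Binning",
    "GOFTestResult",
    "make_binning",
    "cell_specific_chi2",
    "test_total_independence",
    "fit_csp_single",
    "fit_cszip_single",
    "test_gene_csp",
    "test_gene_cszip",
]

MIN_EXPECTED = 0.25


@dataclass
class GOFTestResult:
    statistic: float
    dof: int
    pvalue: float  # nan when the verdict is UTD
    verdict: str  # "accept" | "reject" | "UTD"
    n_cells: int
    n_classes: int


@dataclass
class Binning:
    """Contiguous count classes [lo_j, hi_j] (hi = inf for the tail class)
    with per-cell class probabilities (n_cells x c)."""

    edges: list  # list of (lo, hi) tuples
    class_probs: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.edges)

    def assign(self, counts) -> np.ndarray:
        counts = np.asarray(counts)
        lows = np.array([lo for lo, _ in self.edges])
        # classes are contiguous from 0, so searchsorted on the lower edges works
        return np.clip(np.searchsorted(lows, counts, side="right") - 1, 0, self.n_classes - 1)


def make_binning(observed_counts, cell_pmf, tail_factor: float = 4.0) -> Binning:
    """Build count classes with total expected count >= 0.25 each.

    ``cell_pmf(values)`` must return the (n_cells, len(values)) matrix of
    per-cell probabilities at integer ``values``.  Columns 0,1,...,U are
    scanned left to right and merged rightward until each class reaches the
    expectation floor; the final class absorbs the tail [U+1, inf) (and is
    merged leftward if itself short).
    """
    observed = np.asarray(observed_counts)
    if observed.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    upper = int(max(observed.max(), 1))
    values = np.arange(upper + 1)
    probs = np.asarray(cell_pmf(values), dtype=float)
    if probs.shape != (observed.shape[0], upper + 1):
        raise ValueError("cell_pmf returned a matrix of the wrong shape")
    tail = np.clip(1.0 - probs.sum(axis=1), 0.0, 1.0)

    col_expected = probs.sum(axis=0)
    edges = []
    cols = []  # list of (lo, hi) column ranges, hi inclusive; tail handled last
    lo = 0
    acc = 0.0
    for v in range(upper + 1):
        acc += col_expected[v]
        if acc >= MIN_EXPECTED:
            cols.append((lo, v))
            lo = v + 1
            acc = 0.0
    # remaining columns plus the analytic tail form the last class
    if lo <= upper or not cols:
        cols.append((lo, upper))
    last_lo, _ = cols[-1]
    last_expected = col_expected[last_lo:].sum() + tail.sum()
    if last_expected < MIN_EXPECTED and len(cols) > 1:
        prev_lo, _ = cols[-2]
        cols = cols[:-2] + [(prev_lo, upper)]
    n = observed.shape[0]
    c = len(cols)
    class_probs = np.empty((n, c))
    for j, (a, b) in enumerate(cols):
        class_probs[:, j] = probs[:, a : b + 1].sum(axis=1)
    class_probs[:, -1] += tail  # open-ended final class
    for j, (a, b) in enumerate(cols):
        edges.append((a, np.inf if j == c - 1 else b))
    return Binning(edges=edges, class_probs=class_probs)


def cell_specific_chi2(
    binning: Binning,
    observed_counts,
    n_fitted_params: int,
    significance: float = 0.05,
    ridge: float = 1e-10,
) -> GOFTestResult:
    """The heterogeneous-parameter chi-square test on a prepared binning."""
    observed = np.asarray(observed_counts)
    n = observed.shape[0]
    c = binning.n_classes
    if c < 2:
        return GOFTestResult(np.nan, 0, np.nan, "UTD", n, c)
    labels = binning.assign(observed)
    X = np.zeros((n, c))
    X[np.arange(n), labels] = 1.0
    P = binning.class_probs
    Xs, Ps = X[:, :-1], P[:, :-1]
    xbar = Xs.mean(axis=0)
    pbar = Ps.mean(axis=0)
    sigma = np.diag(pbar) - (Ps.T @ Ps) / n
    diff = xbar - pbar
    try:
        sol = np.linalg.solve(sigma, diff)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        sigma = sigma + np.eye(c - 1) * ridge * np.trace(sigma) / (c - 1)
        sol = np.linalg.solve(sigma, diff)
    statistic = float(n * diff @ sol)
    dof = c - 1 - n_fitted_params
    if dof <= 0:
        return GOFTestResult(statistic, dof, np.nan, "UTD", n, c)
    pvalue = float(stats.chi2.sf(statistic, dof))
    verdict = "reject" if pvalue < significance else "accept"
    return GOFTestResult(statistic, dof, pvalue, verdict, n, c)


def test_total_independence(counts_by_duration: dict, significance: float = 0.05) -> GOFTestResult:
    """Contingency chi-square independence test of binned total counts vs
    labeling duration ("Same" = accept, "Different" = reject).

    Count-value columns are merged left to right until every expected cell of
    the K x c table reaches 0.25.
    """
    groups = {k: np.asarray(v) for k, v in counts_by_duration.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        return GOFTestResult(np.nan, 0, np.nan, "UTD", sum(v.size for v in groups.values()), 0)
    upper = int(max(v.max() for v in groups.values()))
    keys = sorted(groups)
    table = np.stack([np.bincount(groups[k], minlength=upper + 1) for k in keys])
    n = table.sum()
    row_tot = table.sum(axis=1)
    # expected cell (k, j) = row_k * col_j / n; require the smallest row to clear the floor
    min_row = row_tot.min()
    col_floor = MIN_EXPECTED * n / min_row
    merged_cols = []
    acc = np.zeros(len(keys))
    for v in range(upper + 1):
        acc = acc + table[:, v]
        if acc.sum() >= col_floor:
            merged_cols.append(acc)
            acc = np.zeros(len(keys))
    if acc.sum() > 0 or not merged_cols:
        if merged_cols:
            merged_cols[-1] = merged_cols[-1] + acc
        else:
            merged_cols.append(acc)
    merged = np.stack(merged_cols, axis=1)
    if merged.shape[1] < 2:
        return GOFTestResult(np.nan, 0, np.nan, "UTD", int(n), merged.shape[1])
    statistic, pvalue, dof, _ = stats.chi2_contingency(merged, correction=False)
    verdict = "reject" if pvalue < significance else "accept"
    return GOFTestResult(float(statistic), int(dof), float(pvalue), verdict, int(n), merged.shape[1])


# ---------------------------------------------------------------------------
# per-gene workflow: fit the distribution on the tested cells, then test


def fit_csp_single(l, p) -> float:
    """MLE of the CSP mean scale a for one duration: a = sum l / sum p."""
    l = np.asarray(l, dtype=float)
    p = np.asarray(p, dtype=float)
    return float(l.sum() / p.sum())


def fit_cszip_single(l, p) -> tuple:
    """Bounded MLE of (a, p_off) for the CSZIP at one duration.

    Initialized from the moment estimators; falls back to the boundary when
    the data are all zero.
    """
    from scipy.optimize import minimize

    l = np.asarray(l, dtype=float)
    p = np.asarray(p, dtype=float)
    if l.sum() == 0:
        return 0.0, 1.0
    m1, m2 = l.mean(), (l**2).mean()
    pw, pw2 = p.mean(), (p**2).mean()
    denom = pw**2 * (m2 - m1)
    poff0 = 1.0 - m1**2 * pw2 / denom if denom > 0 else 0.5
    poff0 = float(np.clip(poff0, 1e-6, 1 - 1e-6))
    a0 = float(m1 / ((1 - poff0) * pw))
    li = l.astype(np.int64)

    def nll(theta):
        a, poff = theta
        return -float(np.sum(cszip_logpmf(li, p, a, poff)))

    res = minimize(
        nll,
        x0=[a0, poff0],
        method="L-BFGS-B",
        bounds=[(1e-10, 10 * max(a0, 1e-8)), (1e-9, 1 - 1e-9)],
    )
    a, poff = res.x
    return float(a), float(poff)


def test_gene_csp(l, p, significance: float = 0.05) -> GOFTestResult:
    """Fit a CSP on one gene at one duration and test it (1 fitted param)."""
    a = fit_csp_single(l, p)
    pmf = lambda values: np.exp(csp_logpmf(values[None, :], np.asarray(p, float)[:, None], a))
    binning = make_binning(l, pmf)
    return cell_specific_chi2(binning, l, n_fitted_params=1, significance=significance)


def test_gene_cszip(l, p, significance: float = 0.05) -> GOFTestResult:
    """Fit a CSZIP on one gene at one duration and test it (2 fitted params)."""
    a, poff = fit_cszip_single(l, p)
    pmf = lambda values: np.exp(
        cszip_logpmf(values[None, :], np.asarray(p, float)[:, None], a, poff)
    )
    binning = make_binning(l, pmf)
    return cell_specific_chi2(binning, l, n_fitted_params=2, significance=significance)
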