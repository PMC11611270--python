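"""Time-resolved RNA velocity and its evaluation.

Taking expectations of the chemical master equations gives the deterministic
mean dynamics; with the gene-cell-specific rates from
:mod:`labelvelo.cellwise` and smoothed expression xbar (neighborhood mean of
depth-normalized counts), the total-RNA velocity per cell and gene is

* baseline:   v = alpha_j - gamma_t * rbar_j
* splicing:   v = alpha_j - gamma_s * sbar_j   (default; the gamma_t * rbar
  form is available once gamma_t is derived from gamma_s)
* switching:  v = (alpha (1 - p_off))_j - gamma_t * rbar_j

and the spliced velocity is v_s = beta_j ubar_j - gamma_s sbar_j.  Because
total mRNA contains the spliced pool, a zero-intercept regression
rbar = k sbar has slope k >= 1 and links the two degradation rates through
gamma_t = gamma_s / k.

Evaluation metrics: *correctness* (does one-step extrapolation land nearest
a cell later in the temporal ordering) and *consistency* (correlation of a
cell's velocity with its neighbors' mean velocity), plus the phase-duration
algorithm that integrates the velocity field through a labeled embedding in
physical time.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import Neighborhoods

__all__ = [
    "velocity_total",
    "velocity_spliced",
    "gamma_t_from_gamma_s",
    "correctness",
    "consistency",
    "phase_durations",
]


def velocity_total(model: str, alpha_cellwise, gamma, smoothed: dict, use_total_form: bool = False):
    """Total-RNA velocity per cell and gene (molecules/hour).

    ``alpha_cellwise`` is alpha_j (baseline/splicing) or (alpha(1-p_off))_j
    (switching); ``gamma`` is gamma_t, except for the splicing model's
    default spliced form where it is gamma_s.  ``smoothed`` must hold the
    layer the model needs ("total", or "sl"-style spliced for splicing).
    """
    alpha_cellwise = np.asarray(alpha_cellwise, dtype=float)
    if model in ("baseline", "switching") or (model == "splicing" and use_total_form):
        if "total" not in smoothed:
            raise ValueError("smoothed 'total' layer required")
        return alpha_cellwise - gamma * np.asarray(smoothed["total"], dtype=float)
    if model == "splicing":
        key = "spliced" if "spliced" in smoothed else "sl"
        if key not in smoothed:
            raise ValueError("smoothed spliced layer required")
        return alpha_cellwise - gamma * np.asarray(smoothed[key], dtype=float)
    raise ValueError(f"unknown model {model!r}")


def velocity_spliced(beta_cellwise, gamma_s, ubar, sbar):
    """Spliced-RNA velocity v = beta_j ubar_j - gamma_s sbar_j."""
    return np.asarray(beta_cellwise, dtype=float) * np.asarray(ubar, dtype=float) - gamma_s * np.asarray(
        sbar, dtype=float
    )


def gamma_t_from_gamma_s(rbar, sbar, gamma_s):
    """Zero-intercept regression rbar = k sbar per gene; gamma_t = gamma_s / k.

    Returns (k, gamma_t); vectors when rbar/sbar are cells x genes.
    """
    rbar = np.asarray(rbar, dtype=float)
    sbar = np.asarray(sbar, dtype=float)
    ss = (sbar**2).sum(axis=0) if sbar.ndim == 2 else (sbar**2).sum()
    if np.any(ss == 0):
        raise ValueError("spliced expression is identically zero")
    k = ((rbar * sbar).sum(axis=0) if sbar.ndim == 2 else (rbar * sbar).sum()) / ss
    return k, gamma_s / k


def correctness(positions, velocities, temporal_order):
    """Fraction of cells whose one-step extrapolation points forward in time.

    For each cell i the nearest cell j != i to ``x_i + v_i`` is found
    (Euclidean, ties by index); the velocity is correct iff
    ``temporal_order[j] > temporal_order[i]``.  Returns (per-cell 0/1 array,
    average).
    """
    x = np.asarray(positions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    order = np.asarray(temporal_order, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    d = cdist(x + v, x)
    np.fill_diagonal(d, np.inf)
    nearest = np.argmin(d, axis=1)  # argmin takes the first (lowest index) on ties
    correct = (order[nearest] > order).astype(float)
    return correct, float(correct.mean())


def consistency(velocities, neighborhoods: Neighborhoods):
    """Per-cell Pearson correlation (over genes) between a cell's velocity and
    the mean velocity of its neighborhood; cells with zero-variance vectors
    are excluded from the average.  Returns (per-cell scores, average)."""
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("velocities must be cells x genes with >= 2 genes")
    n = v.shape[0]
    scores = np.full(n, np.nan)
    for j in range(n):
        ref = v[neighborhoods[j]].mean(axis=0)
        a = v[j] - v[j].mean()
        b = ref - ref.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na > 0 and nb > 0:
            scores[j] = float(a @ b / (na * nb))
    valid = ~np.isnan(scores)
    avg = float(scores[valid].mean()) if valid.any() else np.nan
    return scores, avg


def phase_durations(
    positions,
    velocities,
    phase_labels,
    relative_position,
    k: int = 300,
    dt: float = 0.01,
    quantile: float = 0.88,
    max_steps: int = 100000,
    stall_tol: float = 1e-12,
):
    """Hours spent in each phase, by integrating the velocity field.

    Starting from the ``k`` cells with the smallest relative position, the
    group state x is extrapolated by x + v dt; at each step the ``k`` cells
    nearest the new state supply the majority phase label and the next mean
    velocity.  Integration stops once the group's mean relative position
    exceeds the given quantile of all positions.  The duration of a phase is
    (number of steps carrying its majority label) x dt.

    Returns a dict phase -> hours.  A stalled field (|v| below ``stall_tol``)
    aborts with a warning and returns the partial result.
    """
    x = np.asarray(positions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    labels = np.asarray(phase_labels)
    pos = np.asarray(relative_position, dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of cells")
    if np.any(pos < 0) or np.any(pos >= 1):
        raise ValueError("relative_position must lie in [0, 1)")
    stop_at = float(np.quantile(pos, quantile))
    group = np.argsort(pos, kind="stable")[:k]
    state = x[group].mean(axis=0)
    vel = v[group].mean(axis=0)
    counts: dict = {}
    for _ in range(max_steps):
        values, freq = np.unique(labels[group], return_counts=True)
        majority = values[np.argmax(freq)]
        counts[majority] = counts.get(majority, 0) + 1
        if float(pos[group].mean()) > stop_at:
            break
        if np.linalg.norm(vel) < stall_tol:
            warnings.warn("velocity field stalled; returning partial phase durations", stacklevel=2)
            break
        state = state + vel * dt
        d = cdist(state[None, :], x)[0]
        group = np.argsort(d, kind="stable")[:k]
        vel = v[group].mean(axis=0)
    else:
        warnings.warn("max_steps reached before the position threshold", stacklevel=2)
    return {phase: steps * dt for phase, steps in counts.items()}
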