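"""Parameter inference for single-labeling-duration (one-shot) experiments.

Two routes are provided:

* :func:`fit_oneshot_steady` — new/total counts only.  Assuming the total
  mRNA is at its stationary Poisson law, the maximum-likelihood estimates of
  (alpha, gamma_t) are closed-form functions of the raw population means.
* the two-stage route for four-layer data (unspliced/spliced x
  labeled/unlabeled), which needs no steady-state assumption: stage 1 fits a
  relative two-state deterministic trajectory to total unspliced/spliced
  expression, of which only the rate ratio rho = beta/gamma_s and the set of
  transcriptionally active cells S_on are consumed; stage 2
  (:func:`fit_oneshot_splicing`) anchors absolute rates to physical time by
  matching the labeled-layer population means b(t), c(t) among on-state cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

from .distributions import mean_new_baseline, mean_new_splicing

__all__ = [
    "RelativeDynamics",
    "fit_oneshot_steady",
    "fit_dynamical_relative",
    "fit_oneshot_splicing",
    "fit_oneshot_two_stage",
]


def fit_oneshot_steady(l, r, p, t: float):
    """Closed-form steady-state estimator from new (l) and total (r) counts.

    gamma_t = -(1/t) log(1 - <l>/<r>),  alpha = gamma_t <r> / <p>,

    with <.> the raw-count population mean.  Requires <l> < <r>; an all-zero
    labeled layer returns the (0, 0) boundary with a warning.
    """
    l = np.asarray(l, dtype=float)
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if t <= 0:
        raise ValueError("labeling duration must be positive")
    lbar, rbar, pbar = l.mean(), r.mean(), p.mean()
    if lbar == 0:
        warnings.warn("labeled counts are all zero; returning gamma_t = alpha = 0", stacklevel=2)
        return 0.0, 0.0
    if lbar >= rbar:
        raise ValueError(
            f"mean labeled count ({lbar:.3g}) must be below mean total ({rbar:.3g}); "
            "gamma_t is not identifiable"
        )
    gamma_t = -np.log1p(-lbar / rbar) / t
    alpha = gamma_t * rbar / pbar
    return float(alpha), float(gamma_t)


@dataclass
class RelativeDynamics:
    """Stage-1 output: relative rates and latent times of the two-state
    deterministic trajectory (induction up to t_s, then repression).

    ``ratio`` is the calibrated beta/gamma_s estimate consumed by stage 2;
    ``beta_rel``/``gamma_rel`` are the raw trajectory-fit rates (relative
    units).  ``t_s`` is infinite when the repression arm did not improve the
    fit (all cells on).
    """

    t_obs: np.ndarray  # per-cell latent time, relative units
    t_s: float  # switching time, relative units
    beta_rel: float
    gamma_rel: float
    ratio: float
    r2: float
    converged: bool = True
    fitted: np.ndarray = field(default=None, repr=False)  # per-cell (u, s) on the trajectory

    @property
    def s_on(self) -> np.ndarray:
        """Boolean mask of on-state cells: latent time before switching."""
        return self.t_obs < self.t_s


def _trajectory(alpha, beta, gamma, t_s, t_grid_on, t_grid_off):
    """(u, s) along induction from (0,0) then repression from the switch state."""
    b_on, c_on = mean_new_splicing(alpha, beta, gamma, t_grid_on)
    u_s, s_s = mean_new_splicing(alpha, beta, gamma, np.array([t_s]))
    u_s, s_s = float(u_s[0]), float(s_s[0])
    tau = t_grid_off
    u_off = u_s * np.exp(-beta * tau)
    if abs(beta - gamma) < 1e-8 * max(beta, gamma):
        s_off = s_s * np.exp(-gamma * tau) + u_s * beta * tau * np.exp(-beta * tau)
    else:
        s_off = s_s * np.exp(-gamma * tau) + u_s * beta * (
            np.exp(-gamma * tau) - np.exp(-beta * tau)
        ) / (beta - gamma)
    u = np.concatenate([np.atleast_1d(b_on), u_off])
    s = np.concatenate([np.atleast_1d(c_on), s_off])
    times = np.concatenate([t_grid_on, t_s + t_grid_off])
    return times, u, s


def _trajectory_r2(u, s, u_fit, s_fit):
    """Goodness of fit of the trajectory, excluding near-zero cells.

    Cells with both coordinates below max/5 are dropped (dropout guard); the
    max is taken once over all cells.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    keep = ~((u < u.max() / 5.0) & (s < s.max() / 5.0))
    if keep.sum() < 2:
        return -np.inf, keep
    du = u[keep] - u_fit[keep]
    ds = s[keep] - s_fit[keep]
    rss = np.sum(du**2 + ds**2)
    tss = np.sum((u[keep] - u[keep].mean()) ** 2 + (s[keep] - s[keep].mean()) ** 2)
    if tss == 0:
        # a constant cloud carries no dynamic information
        return -np.inf, keep
    return float(1.0 - rss / tss), keep


#: relative loss improvement the repression arm must deliver to be kept
_SWITCH_MARGIN = 0.05


def fit_dynamical_relative(u, s, n_grid: int = 80, min_cells: int = 50) -> RelativeDynamics:
    """Minimal relative fitter of the two-state deterministic trajectory.

    Fits (beta_rel, gamma_rel, t_s) by nearest-point projection of the cells
    onto the mean trajectory (transcription is tied to the data scale:
    alpha_rel = beta_rel * q99(u), removing the scale degeneracy), minimizing
    the mean squared distance in axis-standardized coordinates with
    Nelder-Mead from several rate-ratio starts.  Two trajectory shapes
    compete: induction only, and induction followed by repression; the
    repression arm is kept only when it lowers the loss by a margin, since
    free nearest-point assignment lets a superfluous arm soak up noise (and
    would then split cells into on/off states along the noise).

    The ``ratio`` handed to stage 2 is the zero-intercept regression slope of
    s on u, calibrated for transient lag by the fitted trajectory: ratio =
    slope(u, s) * (beta_rel/gamma_rel) / slope(u_fit, s_fit).  On data lying
    exactly on the trajectory this equals the trajectory ratio; on noisy
    clouds the pooled slope is far less sensitive to assignment noise than
    the raw trajectory rates, and the trajectory factor removes the slope's
    lag bias on transient data.  Time and rate units are relative; only the
    ratio and the on-state set are meaningful downstream.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape or u.ndim != 1:
        raise ValueError("u and s must be 1-D and aligned")
    if u.size < min_cells:
        raise ValueError(f"need at least {min_cells} cells")
    u_scale = max(np.quantile(u, 0.99), 1e-12)
    s_scale = max(np.quantile(s, 0.99), 1e-12)

    def loss_and_assign(theta, with_repression):
        log_beta, log_gamma, log_ts = theta
        beta, gamma, t_s = np.exp(log_beta), np.exp(log_gamma), np.exp(log_ts)
        alpha = beta * u_scale
        t_on = np.linspace(0.0, t_s, n_grid)
        if with_repression:
            t_off = np.linspace(0.0, 4.0 / min(beta, gamma), n_grid)[1:]
        else:
            t_off = np.empty(0)
        times, ug, sg = _trajectory(alpha, beta, gamma, t_s, t_on, t_off)
        d2 = (u[:, None] / u_scale - ug[None, :] / u_scale) ** 2 + (
            s[:, None] / s_scale - sg[None, :] / s_scale
        ) ** 2
        idx = np.argmin(d2, axis=1)
        return float(d2[np.arange(u.size), idx].mean()), times[idx], ug[idx], sg[idx]

    def optimize(with_repression):
        best = None
        for ratio0 in (0.5, 1.0, 2.0, 5.0):
            res = minimize(
                lambda th: loss_and_assign(th, with_repression)[0],
                x0=np.log([ratio0, 1.0, 2.0]),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    best_on = optimize(False)
    best_sw = optimize(True)
    use_switch = best_sw.fun < (1.0 - _SWITCH_MARGIN) * best_on.fun
    best = best_sw if use_switch else best_on
    loss, t_obs, u_fit, s_fit = loss_and_assign(best.x, use_switch)
    beta, gamma, t_s = np.exp(best.x)
    if not use_switch:
        t_s = np.inf  # no repression phase: every cell is in the on state
    r2, _ = _trajectory_r2(u, s, u_fit, s_fit)
    denom_obs = float((u * u).sum())
    denom_fit = float((u_fit * u_fit).sum())
    fit_slope = (u_fit * s_fit).sum() / denom_fit if denom_fit > 0 else np.nan
    raw_ratio = beta / gamma
    if denom_obs > 0 and np.isfinite(fit_slope) and fit_slope > 0:
        ratio = float((u * s).sum() / denom_obs * raw_ratio / fit_slope)
    else:
        ratio = float(raw_ratio)
    return RelativeDynamics(
        t_obs=t_obs,
        t_s=float(t_s),
        beta_rel=float(beta),
        gamma_rel=float(gamma),
        ratio=ratio,
        r2=r2,
        converged=bool(np.isfinite(loss)),
        fitted=np.stack([u_fit, s_fit], axis=1),
    )


def fit_oneshot_splicing(ul, sl, p, t: float, s_on, ratio: float):
    """Stage 2: absolute (alpha, beta, gamma_s) from labeled layers.

    Matches the on-state population means

        b(t) = sum_{S_on} ul / sum_{S_on} p,
        c(t) = sum_{S_on} sl / sum_{S_on} p,

    with gamma_s = beta / ratio.  Alpha is eliminated through
    alpha = b_obs * beta / (1 - e^{-beta t}), leaving one scalar equation in
    beta solved by bracketed root finding on [1e-4, 50]/t.
    """
    ul = np.asarray(ul, dtype=float)
    sl = np.asarray(sl, dtype=float)
    p = np.asarray(p, dtype=float)
    s_on = np.asarray(s_on, dtype=bool)
    if ratio <= 0:
        raise ValueError("ratio beta/gamma_s must be positive")
    if not s_on.any():
        raise ValueError("S_on is empty")
    psum = p[s_on].sum()
    if psum <= 0:
        raise ValueError("size factors of on-state cells sum to zero")
    b_obs = ul[s_on].sum() / psum
    c_obs = sl[s_on].sum() / psum
    if b_obs <= 0 or c_obs <= 0:
        raise ValueError("on-state labeled means must be positive")

    def residual(beta):
        alpha = b_obs * beta / -np.expm1(-beta * t)
        _, c = mean_new_splicing(alpha, beta, beta / ratio, t)
        return c - c_obs

    lo, hi = 1e-4 / t, 50.0 / t
    grid = np.geomspace(lo, hi, 200)
    vals = np.array([residual(b) for b in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if sign_change.size == 0:
        raise ValueError(
            "no solution for beta in the bracket "
            f"(b_obs={b_obs:.4g}, c_obs={c_obs:.4g}, ratio={ratio:.4g})"
        )
    i = sign_change[0]
    beta = brentq(residual, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-14)
    gamma_s = beta / ratio
    alpha = b_obs * beta / -np.expm1(-beta * t)
    return float(alpha), float(beta), float(gamma_s)


def fit_oneshot_two_stage(uu, ul, su, sl, p, t: float, relative: RelativeDynamics = None):
    """Run both stages on one gene's four layers.

    ``relative`` may supply externally computed stage-1 output (any dynamical
    model implementation); otherwise the bundled fitter runs on
    u = uu + ul, s = su + sl.  Returns ``(alpha, beta, gamma_s, relative)``.
    """
    if relative is None:
        relative = fit_dynamical_relative(np.asarray(uu) + np.asarray(ul), np.asarray(su) + np.asarray(sl))
    alpha, beta, gamma_s = fit_oneshot_splicing(ul, sl, p, t, relative.s_on, relative.ratio)
    return alpha, beta, gamma_s, relative
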