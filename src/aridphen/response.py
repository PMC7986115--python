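"""Continuous two-segment ("broken-stick") response models.

Whole-plant transpiration responses to soil drying and to atmospheric demand
are both well described by two straight lines joined at a breakpoint: below
the breakpoint the response rises (or falls) with slope1 from intercept1;
at and above it a second regime with slope2 takes over, starting from the
segment-1 value at the breakpoint so the curve is continuous:

    Y1     = slope1 * X + intercept1
    YatX0  = slope1 * X0 + intercept1
    Y2     = YatX0 + slope2 * (X - X0)
    Y      = Y1 if X < X0 else Y2

For water use vs. FTSW the breakpoint is the soil-water threshold at which
stomata begin to restrict transpiration (WU_bp); for transpiration rate vs.
VPD it is the atmospheric-demand threshold of the limited-transpiration
trait (TR_bp).

Given the breakpoint the model is linear in the remaining three parameters,
so fitting profiles the sum of squared errors over candidate breakpoints
(dense grid, then bounded local refinement) with a conditional ordinary
least-squares solve at each candidate.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize_scalar

from .types import ResponseDataset, SegmentedFit, VPDStepLog

__all__ = [
    "predict_segmented",
    "fit_segmented",
    "bootstrap_x0_ci",
    "compute_vpd",
    "saturation_vapour_pressure",
    "compute_tr_from_log",
]

logger = logging.getLogger(__name__)


def predict_segmented(params, x):
    """Evaluate the continuous two-segment model at ``x``.

    ``params`` is anything exposing ``intercept1``, ``slope1``, ``x0`` and
    ``slope2`` (a :class:`~aridphen.types.TruthParams`, a
    :class:`~aridphen.types.SegmentedFit`, ...).
    """
    x = np.asarray(x, dtype=float)
    y1 = params.slope1 * x + params.intercept1
    y_at_x0 = params.slope1 * params.x0 + params.intercept1
    y2 = y_at_x0 + params.slope2 * (x - params.x0)
    out = np.where(x < params.x0, y1, y2)
    return out if out.ndim else float(out)


def _design(x: np.ndarray, x0: float) -> np.ndarray:
    # Continuous reparameterisation: Y = b0 + b1*min(x, x0) + b2*max(x-x0, 0)
    # with b0 = intercept1, b1 = slope1, b2 = slope2.
    return np.column_stack(
        [np.ones_like(x), np.minimum(x, x0), np.clip(x - x0, 0.0, None)]
    )


def _conditional_ols(x: np.ndarray, y: np.ndarray, x0: float):
    a = _design(x, x0)
    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ beta
    return beta, float(resid @ resid)


def fit_segmented(
    data: ResponseDataset,
    x0_bounds: tuple[float, float] | None = None,
    n_grid: int = 400,
    refine: bool = True,
) -> SegmentedFit:
    """Least-squares fit of the continuous two-segment model.

    Parameters
    ----------
    data
        Observations; at least 5 points with non-constant x.
    x0_bounds
        Breakpoint search interval. Defaults to [2nd smallest x, 2nd largest
        x] (shrunk by a small margin) so at least two points flank every
        candidate breakpoint.
    n_grid
        Candidate breakpoints in the initial profile-SSE grid.
    refine
        Refine the grid argmin by bounded scalar minimisation of the
        profile SSE; disable for a pure grid estimate.

    Returns
    -------
    SegmentedFit
        Estimates plus R^2, residual SD, and a ``x0_pinned`` diagnostic flag
        raised when the breakpoint lands on a search bound (the two-segment
        structure is then not supported by the data).
    """
    x = np.asarray(data.x, dtype=float)
    y = np.asarray(data.y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError(f"need >= 5 points to fit the segmented model, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; breakpoint model is unidentifiable")

    xs = np.sort(x)
    span = xs[-1] - xs[0]
    if x0_bounds is None:
        lo, hi = xs[1] + 1e-6 * span, xs[-2] - 1e-6 * span
    else:
        lo, hi = x0_bounds
    if not lo < hi:
        raise ValueError(f"degenerate breakpoint search interval [{lo}, {hi}]")

    grid = np.linspace(lo, hi, n_grid)
    sse_grid = np.array([_conditional_ols(x, y, c)[1] for c in grid])
    i = int(np.argmin(sse_grid))
    x0_hat, sse_hat = grid[i], sse_grid[i]

    if refine:
        b_lo = grid[max(i - 1, 0)]
        b_hi = grid[min(i + 1, n_grid - 1)]
        res = minimize_scalar(
            lambda c: _conditional_ols(x, y, c)[1],
            bounds=(b_lo, b_hi),
            method="bounded",
            options={"xatol": 1e-10 * max(hi - lo, 1e-12)},
        )
        if res.fun <= sse_hat:
            x0_hat, sse_hat = float(res.x), float(res.fun)

    beta, sse = _conditional_ols(x, y, x0_hat)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        r2 = 1.0 if sse <= 1e-12 else 0.0
    dof = n - 4
    residual_sd = float(np.sqrt(sse / dof)) if dof > 0 else float("nan")
    pinned = min(x0_hat - lo, hi - x0_hat) < 1e-3 * (hi - lo)
    if pinned:
        logger.warning(
            "breakpoint pinned at search bound (x0=%.6g in [%.6g, %.6g])",
            x0_hat,
            lo,
            hi,
        )
    return SegmentedFit(
        intercept1=float(beta[0]),
        slope1=float(beta[1]),
        x0=x0_hat,
        slope2=float(beta[2]),
        r2=r2,
        n=n,
        residual_sd=residual_sd,
        x0_pinned=pinned,
    )


def bootstrap_x0_ci(
    data: ResponseDataset,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_grid: int = 100,
) -> tuple[float, float]:
    """Case-resampling bootstrap percentile CI for the breakpoint.

    Resamples (x, y) pairs with replacement, refits, and returns the
    (alpha/2, 1 - alpha/2) percentiles of the breakpoint estimates.
    Resamples with fewer than 5 distinct x values are redrawn.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(data.x, dtype=float)
    y = np.asarray(data.y, dtype=float)
    n = x.size
    estimates = []
    while len(estimates) < n_boot:
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        if np.unique(xb).size < 5:
            continue
        fit = fit_segmented(
            ResponseDataset(xb, y[idx], kind=data.kind), n_grid=n_grid, refine=False
        )
        estimates.append(fit.x0)
    lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def saturation_vapour_pressure(temperature) -> np.ndarray | float:
    """Saturation vapour pressure (kPa) at air temperature (deg C), Tetens:
    es = 0.61078 * exp(17.27 T / (T + 237.3))."""
    t = np.asarray(temperature, dtype=float)
    es = 0.61078 * np.exp(17.27 * t / (t + 237.3))
    return es if es.ndim else float(es)


def compute_vpd(temperature, rh) -> np.ndarray | float:
    """Vapour pressure deficit (kPa) from air temperature (deg C) and
    relative humidity (%): VPD = es(T) * (1 - RH/100)."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr <= 0) or np.any(rh_arr > 100):
        raise ValueError("relative humidity must be in (0, 100] %")
    out = saturation_vapour_pressure(temperature) * (1.0 - rh_arr / 100.0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def compute_tr_from_log(log: VPDStepLog, neg_tolerance: float = 0.0) -> ResponseDataset:
    """Transpiration rate per VPD step from a chamber log.

    Per step, TR = mass loss (g -> mg) / leaf area (m^2) / duration (s),
    in mg H2O m^-2 s^-1; the x value is the VPD recomputed from the step's
    mean temperature and RH. Steps with mass *gain* beyond ``neg_tolerance``
    grams are kept but flagged (condensation or a weighing error).
    """
    log.validate()
    xs, ys, flags = [], [], []
    for i, step in enumerate(log.steps):
        loss_g = step.start_weight - step.end_weight
        duration_s = (step.end - step.start).total_seconds()
        if duration_s <= 0:
            raise ValueError("step duration must be positive")
        if loss_g < -neg_tolerance:
            flags.append(f"step {i}: negative mass loss ({loss_g:.3g} g)")
        tr = loss_g * 1000.0 / (log.leaf_area * duration_s)
        xs.append(compute_vpd(step.mean_temperature, step.mean_rh))
        ys.append(tr)
    return ResponseDataset(
        np.array(xs), np.array(ys), kind="vpd", label=log.plant_id, flags=flags
    )
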