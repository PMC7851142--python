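"""4PL dose-response fitting and GI25/GI50/TGI dose readout.

The four-parameter logistic model

    r(d) = lower + (upper − lower) / (1 + (d/ec50)^hill)

is fit by least squares with a deterministic multi-start grid over Hill
slope and EC50 (local minima are common on sparse dose ladders).  With
hill > 0 the curve decreases from ``upper`` at d=0 to ``lower`` at high
dose — the usual growth-inhibition shape; hill < 0 fits responses that
rise with dose.  GI doses are read from the analytic inverse of the fitted
curve: GI_L is the dose where response falls to ``upper − L·(upper−lower)``
(50% inhibition of the vehicle-normalised span for GI50), and TGI — total
growth inhibition — is the dose where the fitted endpoint equals a
supplied day-0 baseline (net growth zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import DomainError, NoSolutionError

# relative SSE above which a fit is annotated as questionable
_FIT_WARN_FRACTION = 0.2


def four_pl(d: np.ndarray, lower: float, upper: float, log_ec50: float, hill: float) -> np.ndarray:
    """Evaluate the 4PL curve; d=0 handled exactly (limit of the power term)."""
    d = np.asarray(d, dtype=float)
    ec50 = math.exp(log_ec50)
    with np.errstate(divide="ignore", over="ignore"):
        x = np.where(d > 0, np.power(d / ec50, hill), np.inf if hill < 0 else 0.0)
    return lower + (upper - lower) / (1.0 + x)


@dataclass
class DoseResponseFit:
    lower: float
    upper: float
    ec50: float
    hill: float
    residual_sse: float
    n_points: int
    degenerate: bool = False
    fit_warning: str | None = None

    def predict(self, dose) -> np.ndarray:
        if self.degenerate:
            return np.full_like(np.asarray(dose, dtype=float), self.upper)
        return four_pl(dose, self.lower, self.upper, math.log(self.ec50), self.hill)


def fit_4pl(doses, responses, seed: int = 0) -> DoseResponseFit:
    """Fit the 4PL by multi-start least squares; deterministic given seed.

    Requires >= 5 dose points including a zero-dose (vehicle) anchor.
    Starts span hill in {±0.5, ±1, ±2} and EC50 over a log grid of the
    positive dose range; the seed only jitters the grid slightly (a tie-
    break against symmetric local minima) and is recorded by callers.
    Flat data yield a degenerate fit (ec50 NaN) rather than an error; a fit
    whose residual SSE exceeds a fraction of the data's total variation is
    annotated with ``fit_warning``.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape:
        raise ValueError("doses and responses must have equal length")
    if len(d) < 5:
        raise ValueError("need at least 5 dose points")
    if not np.any(d == 0):
        raise ValueError("a zero-dose (vehicle) anchor point is required")
    if np.any(d < 0) or np.any(r < 0):
        raise DomainError("doses and responses must be >= 0")

    span = float(np.ptp(r))
    if span == 0 or span < 1e-12 * max(1.0, float(np.mean(r))):
        return DoseResponseFit(
            lower=float(r.mean()), upper=float(r.mean()), ec50=math.nan, hill=math.nan,
            residual_sse=0.0, n_points=len(d), degenerate=True,
            fit_warning="all responses equal: EC50 undefined",
        )

    rng = np.random.default_rng(seed)
    pos = d[d > 0]
    lo, hi = float(pos.min()), float(pos.max())
    ec50_grid = np.exp(np.linspace(math.log(lo), math.log(hi), 5))
    ec50_grid *= np.exp(rng.uniform(-0.01, 0.01, size=ec50_grid.shape))

    best = None
    for hill0 in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
        for ec0 in ec50_grid:
            p0 = [float(r.min()), float(r.max()), math.log(ec0), hill0]
            try:
                with warnings.catch_warnings():
                    # near-perfect data makes the covariance singular; only
                    # the point estimate is used here
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, _ = curve_fit(four_pl, d, r, p0=p0, maxfev=5000)
            except RuntimeError:
                continue
            sse = float(np.sum((four_pl(d, *popt) - r) ** 2))
            if best is None or sse < best[1]:
                best = (popt, sse)
    if best is None:
        return DoseResponseFit(
            lower=float(r.min()), upper=float(r.max()), ec50=math.nan, hill=math.nan,
            residual_sse=math.inf, n_points=len(d), degenerate=True,
            fit_warning="no converged fit from any start",
        )
    (lower, upper, log_ec50, hill), sse = best
    if upper < lower:  # canonical orientation: upper is the d->0 side for hill>0
        lower, upper, hill = upper, lower, -hill
        log_ec50 = log_ec50  # unchanged under the reflection
    warning = None
    total_var = float(np.sum((r - r.mean()) ** 2))
    if total_var > 0 and sse > _FIT_WARN_FRACTION * total_var:
        warning = f"poor fit: SSE {sse:.4g} exceeds {_FIT_WARN_FRACTION:.0%} of data variation"
    return DoseResponseFit(
        lower=float(lower), upper=float(upper), ec50=float(math.exp(log_ec50)),
        hill=float(hill), residual_sse=sse, n_points=len(d), fit_warning=warning,
    )


def gi_dose(fit: DoseResponseFit, level: float, baseline: float | None = None) -> float:
    """Dose producing the requested growth inhibition (or TGI with baseline).

    Without ``baseline``: target response = (1 − level)·upper — growth
    relative to the vehicle (d=0) level, so GI50 is the dose where growth
    falls to 50% of vehicle and equals EC50 for a full-span (lower=0)
    curve.  With ``baseline`` (a day-0 growth value): returns the TGI dose
    where the fitted response equals the baseline — net growth zero, NCI
    convention; ``level`` is ignored.  Raises :class:`NoSolutionError`
    when the target lies outside the open fitted span (e.g. GI80 on a
    curve that plateaus at 40% of vehicle).
    """
    if fit.degenerate or not np.isfinite(fit.ec50):
        raise NoSolutionError("degenerate fit: EC50 undefined")
    if baseline is None:
        if not 0 < level < 1:
            raise DomainError("level must lie strictly between 0 and 1")
        target = (1.0 - level) * fit.upper
    else:
        target = float(baseline)
    lo, hi = min(fit.lower, fit.upper), max(fit.lower, fit.upper)
    if not lo < target < hi:
        raise NoSolutionError(
            f"target response {target:.4g} outside fitted span ({lo:.4g}, {hi:.4g})"
        )
    # invert r = lower + span/(1+x):  x = (upper-target)/(target-lower)
    x = (fit.upper - target) / (target - fit.lower)
    return float(fit.ec50 * x ** (1.0 / fit.hill))
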