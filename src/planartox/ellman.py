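"""AChE activity from Ellman kinetic reads and log-logistic inhibition fits.

Enzyme activity is the rate of change of absorbance per minute during the
linear portion of the reaction, normalized by protein concentration, and
expressed as percent of vehicle-control activity.  Concentration-inhibition
curves are fit with a two-parameter log-logistic with the lower asymptote
fixed at 0 and the upper at 100:

    f(c) = 100 / (1 + (c / IC50)^b)

parameterized directly by (IC50, b), so the concentration producing p%
inhibition has the closed form IC_p = IC50 * (p / (100 - p))^(1/b).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


def activity_rate(times_min, absorbance, protein_mg_per_ml: float,
                  min_window: int = 4, r2_threshold: float = 0.98) -> float:
    """Slope of the best linear window of a kinetic read, per mg protein.

    The linear portion is the longest window of at least ``min_window``
    points with coefficient of determination >= ``r2_threshold`` (earliest
    such window on ties; highest R² among equals); if no window qualifies
    the full series is used.  A negative slope means no measurable activity
    and is clipped to 0 with a warning.
    """
    t = np.asarray(times_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if protein_mg_per_ml <= 0:
        raise ValueError("protein concentration must be positive")

    best: tuple[int, float, float] | None = None  # (length, r2, slope)
    n = t.size
    for length in range(n, min_window - 1, -1):
        for start in range(0, n - length + 1):
            tt, aa = t[start:start + length], a[start:start + length]
            slope, intercept = np.polyfit(tt, aa, 1)
            resid = aa - (slope * tt + intercept)
            ss_tot = float(np.sum((aa - aa.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
            if r2 >= r2_threshold:
                if best is None or (length, r2) > (best[0], best[1]):
                    best = (length, r2, float(slope))
        if best is not None:
            break  # longest qualifying window found
    if best is None:
        slope = float(np.polyfit(t, a, 1)[0])
    else:
        slope = best[2]
    if slope < -1e-12:
        warnings.warn("negative kinetic slope clipped to 0 (no activity)")
    slope = max(slope, 0.0)
    return slope / protein_mg_per_ml


def percent_activity(sample_rate: float, vehicle_rates) -> float:
    """Activity as percent of the mean vehicle-control rate (vehicle = 100)."""
    veh = np.asarray(vehicle_rates, dtype=float)
    if veh.size == 0 or np.mean(veh) <= 0:
        raise ValueError("vehicle rates must be non-empty with positive mean")
    return 100.0 * sample_rate / float(np.mean(veh))


@dataclass
class InhibitionCurve:
    """Fitted two-parameter log-logistic inhibition curve."""

    ic50_uM: float
    slope_b: float
    residual_se: float
    right_censored: bool = False
    max_tested_uM: float = math.nan

    def activity_at(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return 100.0 / (1.0 + (c / self.ic50_uM) ** self.slope_b)


def fit_inhibition(concentrations, percent_activities) -> InhibitionCurve:
    """Least-squares log-logistic fit with multi-start initialization.

    Optimizes over (log10 IC50, log10 b), guaranteeing positivity.  If the
    best fit pushes the IC50 more than 10x above the highest tested
    concentration the curve carries no usable inhibition signal and is
    flagged right-censored (the IC50 is still reported as fitted).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(percent_activities, dtype=float)
    pos = c > 0
    c, y = c[pos], y[pos]
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct positive concentrations")

    def resid(theta):
        with np.errstate(over="ignore"):
            ic50 = 10.0 ** np.clip(theta[0], -300, 300)
            b = 10.0 ** np.clip(theta[1], -3, 3)
            return 100.0 / (1.0 + (c / ic50) ** b) - y

    lo, hi = math.log10(c.min()), math.log10(c.max())
    starts = [(g, math.log10(b0))
              for g in np.linspace(lo - 1.0, hi + 1.0, 5)
              for b0 in (0.5, 1.0, 2.0)]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0=x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("inhibition fit failed from every start")
    ic50 = 10.0 ** float(np.clip(best.x[0], -300, 300))
    b = 10.0 ** float(np.clip(best.x[1], -3, 3))
    dof = max(len(y) - 2, 1)
    se = math.sqrt(2.0 * best.cost / dof)
    censored = ic50 > 10.0 * c.max()
    return InhibitionCurve(float(ic50), float(b), se, censored, float(c.max()))


def ic_p(curve: InhibitionCurve, p: float) -> dict[str, float | bool]:
    """Concentration producing p% inhibition on the fitted curve.

    Closed form of the two-parameter log-logistic; IC50 is recovered at
    p = 50.  The result is flagged extrapolated when it exceeds the highest
    tested concentration.
    """
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    value = curve.ic50_uM * (p / (100.0 - p)) ** (1.0 / curve.slope_b)
    extrapolated = (math.isfinite(curve.max_tested_uM)
                    and value > curve.max_tested_uM)
    return {"concentration_uM": float(value), "extrapolated": bool(extrapolated)}


def fit_ellman_table(table, *, p: float = 80.0) -> dict:
    """Fit one chemical's percent-activity table and report IC50/IC_p.

    ``table`` is a DataFrame with columns condition, concentration_uM,
    percent_activity (vehicle rows have concentration 0 and are ignored by
    the fit, which pins the upper asymptote at 100 by construction).
    """
    chem = table[table["concentration_uM"] > 0]
    curve = fit_inhibition(chem["concentration_uM"].to_numpy(float),
                           chem["percent_activity"].to_numpy(float))
    icp = ic_p(curve, p)
    return {
        "ic50_uM": curve.ic50_uM,
        "slope_b": curve.slope_b,
        f"ic{p:g}_uM": icp["concentration_uM"],
        "extrapolated": icp["extrapolated"],
        "right_censored": curve.right_censored,
        "residual_se": curve.residual_se,
        "curve": curve,
    }
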