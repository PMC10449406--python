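"""Two-interval superlinearity statistic and the quality-trend regression.

The superlinearity of a curve y(x) is measured descriptively: split the x
range into two equal-width intervals, fit an ordinary least-squares line to
the curve within each interval, and report the difference (upper slope minus
lower slope).  A curve that bends upward has positive superlinearity, one
that bends downward negative.  Note that positive superlinearity does not
imply the curve is increasing — a U shape is superlinear by this measure —
so it is a statement about global convexity of the fit, not monotonicity.

The trend regression relates superlinearity values measured under different
surprisal estimators to estimator quality (conventionally negative log
perplexity, so larger is better) by weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "SuperlinearityResult",
    "superlinearity_of_curve",
    "superlinearity_of_fit",
    "trend_regression",
    "GRID_POINTS_PER_HALF",
]

# when a fitted curve (rather than scatter data) is measured, each half is
# evaluated on a uniform grid of this many points so the statistic does not
# depend on the density of the original fitting data
GRID_POINTS_PER_HALF = 512


@dataclass(frozen=True)
class SuperlinearityResult:
    """Slopes of the lower and upper half of a curve and their difference."""

    slope_low: float
    slope_high: float
    split_point: float
    range: tuple[float, float]

    @property
    def superlinearity(self) -> float:
        return self.slope_high - self.slope_low


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    denom = float(xm @ xm)
    if denom <= 0:
        raise ValueError("degenerate x range within one half: slope undefined")
    return float(xm @ (y - y.mean()) / denom)


def superlinearity_of_curve(x: Sequence[float], y: Sequence[float]) -> SuperlinearityResult:
    """Two-interval slope-difference statistic on scatter or curve points.

    The observed x range is split at its midpoint; points exactly at the
    midpoint are assigned to the lower half.  Each half must contain at
    least two distinct points.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 4:
        raise ValueError("need at least 4 (x, y) points")
    lo, hi = float(xa.min()), float(xa.max())
    if hi <= lo:
        raise ValueError("x range is degenerate")
    mid = 0.5 * (lo + hi)
    lower = xa <= mid
    upper = ~lower
    if lower.sum() < 2 or upper.sum() < 2:
        raise ValueError("insufficient support: fewer than 2 points in one half")
    return SuperlinearityResult(
        slope_low=_ols_slope(xa[lower], ya[lower]),
        slope_high=_ols_slope(xa[upper], ya[upper]),
        split_point=mid,
        range=(lo, hi),
    )


def superlinearity_of_fit(curvefit) -> SuperlinearityResult:
    """Superlinearity of a fitted mean curve, evaluated on dense half-grids.

    Accepts a :class:`~samplingcost.curvefit.CurveFit`; the mean curve is
    interpolated onto a uniform grid of ``GRID_POINTS_PER_HALF`` points per
    half before the slopes are taken.
    """
    lo, hi = float(curvefit.grid[0]), float(curvefit.grid[-1])
    mid = 0.5 * (lo + hi)
    gl = np.linspace(lo, mid, GRID_POINTS_PER_HALF)
    gh = np.linspace(np.nextafter(mid, hi), hi, GRID_POINTS_PER_HALF)
    yl = np.interp(gl, curvefit.grid, curvefit.mu)
    yh = np.interp(gh, curvefit.grid, curvefit.mu)
    return SuperlinearityResult(
        slope_low=_ols_slope(gl, yl),
        slope_high=_ols_slope(gh, yh),
        split_point=mid,
        range=(lo, hi),
    )


def trend_regression(
    points: Sequence[tuple[float, float, float]]
) -> tuple[float, float, float]:
    """Weighted linear regression of superlinearity on estimator quality.

    ``points`` are (quality, superlinearity, weight) triples with positive
    weights.  Returns (slope, intercept, weighted R^2).
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (quality, superlinearity, weight) points")
    q, y, w = arr.T
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.ptp(q) <= 0:
        raise ValueError("constant quality: trend slope unidentifiable")
    model = sm.WLS(y, sm.add_constant(q), weights=w).fit()
    intercept, slope = model.params
    return float(slope), float(intercept), float(model.rsquared)
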