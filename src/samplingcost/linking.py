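"""Parametric linking functions from surprisal (nats) to processing time (ms).

Four families are supported:

``linear``        T = alpha + beta * I      (the classic surprisal-theory link;
                                             proportionality is alpha = 0, beta = 1)
``exponential``   T = c * e^I               (time inversely proportional to
                                             incremental probability)
``power``         T = c * I^k               (empirically fit exponent k, with
                                             k = 1 reducing to proportionality)
``actr``          T = F * (e^I - 1)^f       (the ACT-R retrieval-latency formula
                                             restated in terms of surprisal via
                                             the log-odds identity below)

The log-odds identity: for an event with probability p < 1 and surprisal
I = -ln p, log-odds(p) = ln(p / (1 - p)) = -ln(e^I - 1).  With f = 1 (the
usual assumption) the ACT-R latency is simply exponential in surprisal minus
a constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:
    from .synthetic import RTDataset

__all__ = [
    "LinkingFunction",
    "eval_linking",
    "logodds_from_surprisal",
    "surprisal_from_logodds",
    "fit_linking",
    "FAMILIES",
]

FAMILIES = ("linear", "exponential", "power", "actr")


@dataclass(frozen=True)
class LinkingFunction:
    """Tagged parametric map from surprisal (nats) to processing time (ms)."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown linking family {self.family!r}; choose from {FAMILIES}")
        required = {
            "linear": {"alpha", "beta"},
            "exponential": {"c"},
            "power": {"c", "k"},
            "actr": {"F", "f"},
        }[self.family]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"{self.family} link missing parameters {sorted(missing)}")
        if self.family == "actr" and self.params["f"] < 1:
            raise ValueError("actr exponent f must be >= 1")

    def __call__(self, surprisal):
        return eval_linking(self, surprisal)

    @classmethod
    def linear(cls, alpha: float, beta: float) -> "LinkingFunction":
        return cls("linear", {"alpha": alpha, "beta": beta})

    @classmethod
    def proportional(cls) -> "LinkingFunction":
        """Time directly proportional to surprisal (alpha=0, beta=1)."""
        return cls.linear(0.0, 1.0)

    @classmethod
    def exponential(cls, c: float) -> "LinkingFunction":
        return cls("exponential", {"c": c})

    @classmethod
    def power(cls, c: float, k: float) -> "LinkingFunction":
        return cls("power", {"c": c, "k": k})

    @classmethod
    def actr(cls, F: float, f: float = 1.0) -> "LinkingFunction":
        return cls("actr", {"F": F, "f": f})


def eval_linking(link: LinkingFunction, surprisal):
    """Evaluate a linking function at surprisal values (nats); returns ms.

    Accepts scalars or arrays.  The actr family at I = 0 returns its limit 0
    (valid for f >= 1, enforced at construction).
    """
    s = np.asarray(surprisal, dtype=float)
    if np.any(s < 0):
        raise ValueError("surprisal must be nonnegative")
    p = link.params
    if link.family == "linear":
        out = p["alpha"] + p["beta"] * s
    elif link.family == "exponential":
        out = p["c"] * np.exp(s)
    elif link.family == "power":
        out = p["c"] * np.power(s, p["k"])
    else:  # actr
        out = p["F"] * np.power(np.expm1(s), p["f"])
    if np.isscalar(surprisal):
        return float(out)
    return out


def logodds_from_surprisal(I: float):
    """log-odds = -ln(e^I - 1) for surprisal I > 0 (i.e. probability < 1)."""
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr <= 0):
        raise ValueError("surprisal must be positive: a certain event has infinite log-odds")
    out = -np.log(np.expm1(I_arr))
    return float(out) if np.isscalar(I) else out


def surprisal_from_logodds(logodds: float):
    """Inverse of :func:`logodds_from_surprisal`: I = ln(1 + e^{-logodds})."""
    x = np.asarray(logodds, dtype=float)
    out = np.log1p(np.exp(-x))
    return float(out) if np.isscalar(logodds) else out


# fixed multi-start grids keep the nonlinear fits deterministic
_POWER_K_GRID = (0.5, 0.8, 1.0, 1.2, 1.5, 2.0, 3.0)
_ACTR_F_GRID = (1.0, 1.5, 2.0, 3.0)


def fit_linking(data: "RTDataset | object", family: str) -> tuple[LinkingFunction, float]:
    """Least-squares fit of one linking family to an RT table.

    Accepts anything with ``surprisal`` and ``rt`` columns (an
    :class:`~samplingcost.synthetic.RTDataset` or a DataFrame).  Linear and
    exponential fits are closed-form least squares; power and actr use
    Levenberg–Marquardt from a fixed grid of starts, so the result is
    deterministic given the data.  Returns the fitted function and its RMSE.
    """
    frame = getattr(data, "frame", data)
    s = np.asarray(frame["surprisal"], dtype=float)
    rt = np.asarray(frame["rt"], dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 rows to fit a linking function")
    if np.ptp(s) <= 0:
        raise ValueError("constant surprisal: linking parameters are unidentifiable")

    def rmse(pred: np.ndarray) -> float:
        return float(np.sqrt(np.mean((rt - pred) ** 2)))

    if family == "linear":
        beta, alpha = np.polyfit(s, rt, 1)
        link = LinkingFunction.linear(float(alpha), float(beta))
        return link, rmse(eval_linking(link, s))

    if family == "exponential":
        basis = np.exp(s)
        c = float(basis @ rt / (basis @ basis))
        link = LinkingFunction.exponential(c)
        return link, rmse(eval_linking(link, s))

    if family == "power":
        s_safe = np.where(s > 0, s, np.nan)

        def resid(theta):
            c, k = theta
            pred = c * np.nan_to_num(np.power(s_safe, k), nan=0.0)
            return pred - rt

        best = None
        for k0 in _POWER_K_GRID:
            basis = np.nan_to_num(np.power(s_safe, k0), nan=0.0)
            c0 = max(float(basis @ rt / (basis @ basis)), 1e-6)
            sol = least_squares(resid, x0=[c0, k0], method="lm", max_nfev=2000)
            if best is None or sol.cost < best.cost:
                best = sol
        link = LinkingFunction.power(float(best.x[0]), float(best.x[1]))
        return link, rmse(eval_linking(link, s))

    if family == "actr":

        def resid(theta):
            F, f = theta
            return F * np.power(np.expm1(s), f) - rt

        best = None
        for f0 in _ACTR_F_GRID:
            basis = np.power(np.expm1(s), f0)
            F0 = max(float(basis @ rt / (basis @ basis)), 1e-6)
            sol = least_squares(
                resid, x0=[F0, f0], bounds=([1e-9, 1.0], [np.inf, np.inf]), max_nfev=2000
            )
            if best is None or sol.cost < best.cost:
                best = sol
        link = LinkingFunction.actr(float(best.x[0]), float(best.x[1]))
        return link, rmse(eval_linking(link, s))

    raise ValueError(f"unknown linking family {family!r}; choose from {FAMILIES}")
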