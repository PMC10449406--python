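"""Brute-force ground truth for guessing without replacement.

Enumerates ordered prefixes of distractor items to obtain the exact
distribution of the draw count N on small instances (K <= 8).  This is the
arbiter used to validate the closed-form mean/variance expressions and the
precedence probability on random instances.

Enumerating prefixes rather than full permutations reduces the cost from
(K+1)! orderings to sum_n K!/(K-n+1)! weighted prefixes, which keeps K = 8
tractable in seconds.  Compensated float summation is used throughout; exact
rational arithmetic is deliberately avoided to keep the module
dependency-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .analytic import RuntimeSummary
from .priors import WeightSet

__all__ = ["ExactRuntimePMF", "enumerate_wor_pmf", "oracle_moments", "oracle_precedence", "MAX_ORACLE_K"]

MAX_ORACLE_K = 8


@dataclass(frozen=True)
class ExactRuntimePMF:
    """Exact pmf of the without-replacement draw count, support {1..K+1}."""

    probabilities: dict[int, float]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("pmf entries must be nonnegative")
        total = math.fsum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pmf must sum to 1 within 1e-12 (got {total})")


def _check_k(ws: WeightSet) -> None:
    if ws.K > MAX_ORACLE_K:
        raise ValueError(
            f"enumeration oracle limited to K <= {MAX_ORACLE_K} (got K={ws.K}); "
            "the number of ordered prefixes grows factorially"
        )


def enumerate_wor_pmf(ws: WeightSet) -> ExactRuntimePMF:
    """Exact pmf of N by enumeration over ordered distractor prefixes.

    Pr(N = n) sums, over every ordered length-(n-1) prefix of distractors,
    the product of sequential draw probabilities times the probability that
    the target is drawn next from the remaining mass.
    """
    _check_k(ws)
    w = ws.weights
    u0 = float(w[0])
    total = float(w.sum())
    distractors = list(range(1, ws.K + 1))
    acc: dict[int, list[float]] = {n: [] for n in range(1, ws.K + 2)}

    def recurse(remaining_mass: float, available: tuple[int, ...], depth: int, prob: float) -> None:
        # target drawn next after `depth` distractors
        acc[depth + 1].append(prob * u0 / remaining_mass)
        for idx, item in enumerate(available):
            ui = float(w[item])
            if ui == 0.0:
                continue
            rest = available[:idx] + available[idx + 1 :]
            recurse(remaining_mass - ui, rest, depth + 1, prob * ui / remaining_mass)

    recurse(total, tuple(distractors), 0, 1.0)
    pmf = {n: math.fsum(vals) for n, vals in acc.items() if vals}
    return ExactRuntimePMF(pmf)


def oracle_moments(pmf: ExactRuntimePMF) -> RuntimeSummary:
    """Exact mean and variance computed directly from the pmf."""
    mean = math.fsum(n * p for n, p in pmf.probabilities.items())
    second = math.fsum(n * n * p for n, p in pmf.probabilities.items())
    var = second - mean * mean
    return RuntimeSummary(mean, max(var, 0.0), "oracle", target_surprisal=float("nan"))


def oracle_precedence(ws: WeightSet, i: int, j: int) -> float:
    """Exact Pr(item i drawn before item j) by enumeration over orderings.

    Sums, over ordered prefixes of all items, the probability that i appears
    before j has appeared.  Equals u_i / (u_i + u_j) regardless of every
    other weight.
    """
    _check_k(ws)
    n = ws.K + 1
    if not (0 <= i < n and 0 <= j < n) or i == j:
        raise IndexError(f"invalid item pair ({i}, {j}) for {n} items")
    w = ws.weights
    total = float(w.sum())
    contributions: list[float] = []

    def recurse(remaining_mass: float, available: tuple[int, ...], prob: float) -> None:
        for idx, item in enumerate(available):
            ui = float(w[item])
            if ui == 0.0:
                continue
            p_next = prob * ui / remaining_mass
            if item == i:
                contributions.append(p_next)  # i drawn first: event holds
            elif item == j:
                continue  # j drawn first: event fails on this branch
            else:
                rest = available[:idx] + available[idx + 1 :]
                recurse(remaining_mass - ui, rest, p_next)

    recurse(total, tuple(range(n)), 1.0)
    return math.fsum(contributions)
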