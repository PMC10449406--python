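"""Closed-form runtime moments for the two guessing algorithms.

The *with-replacement* guesser repeatedly samples hypotheses from the prior
until one explains the observed word; its draw count M is geometric with
success probability p, so E[M] = 1/p = e^I and Var[M] = (1-p)/p^2 =
e^{2I} - e^I where I = -ln p is the target surprisal.

The *without-replacement* guesser removes rejected hypotheses from the pool.
With the target at index 0 and distractor weights u_1..u_K, its draw count is
N = 1 + sum_i X_i where X_i indicates that item i precedes the target.  The
precedence probability Pr(i before j) = u_i / (u_i + u_j) depends on those
two weights only, which yields exact mean and variance below.  Both moments
are validated against a brute-force enumeration oracle (see
:mod:`samplingcost.oracle`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .priors import PriorDistribution, WeightSet, posterior_update

__all__ = [
    "RuntimeSummary",
    "geometric_runtime_moments",
    "precedence_probability",
    "wor_expected_runtime",
    "wor_runtime_variance",
    "kl_surprisal_identity_check",
    "MAX_DEFAULT_K",
]

# The pairwise variance sum is O(K^2); beyond this size an explicit opt-in is
# required so a user does not trip over a quadratic wall by accident.
MAX_DEFAULT_K = 5000


@dataclass(frozen=True)
class RuntimeSummary:
    """Mean and variance of the number of draws for one target item."""

    mean_draws: float
    var_draws: Optional[float]
    source: str  # {"analytic", "simulated", "oracle"}
    target_surprisal: float
    n_runs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mean_draws < 1:
            raise ValueError("mean number of draws cannot be below 1")
        if self.var_draws is not None and self.var_draws < -1e-12:
            raise ValueError("variance cannot be negative")
        if self.source not in {"analytic", "simulated", "oracle"}:
            raise ValueError(f"unknown source tag {self.source!r}")


def geometric_runtime_moments(p: float) -> RuntimeSummary:
    """Moments of the with-replacement draw count M ~ Geom(p).

    mean = 1/p = e^I and var = (1-p)/p^2 = e^{2I} - e^I, both strictly
    increasing in the target surprisal I = -ln p.
    """
    if not math.isfinite(p):
        raise ValueError("success probability must be finite")
    if p <= 0:
        raise ValueError("success probability 0: infinite expected runtime")
    if p > 1:
        raise ValueError("success probability cannot exceed 1")
    mean = 1.0 / p
    var = (1.0 - p) / (p * p)
    return RuntimeSummary(mean, var, "analytic", target_surprisal=-math.log(p))


def precedence_probability(u_i: float, u_j: float) -> float:
    """Pr(item i is drawn before item j) = u_i / (u_i + u_j).

    Holds for guessing with or without replacement and is independent of
    every other item's weight.
    """
    if u_i < 0 or u_j < 0:
        raise ValueError("weights must be nonnegative")
    if u_i + u_j <= 0:
        raise ValueError("undefined event: both weights are zero")
    return u_i / (u_i + u_j)


def _check_size(ws: WeightSet, allow_large: bool) -> None:
    if ws.K > MAX_DEFAULT_K and not allow_large:
        raise ValueError(
            f"K={ws.K} exceeds the default cap {MAX_DEFAULT_K} for the O(K^2) "
            "variance sum; pass allow_large=True to override"
        )


def wor_expected_runtime(ws: WeightSet) -> RuntimeSummary:
    """Expected draw count of guessing without replacement.

    E[N] = 1 + sum_{i=1..K} u_i / (u_i + u_0), which lies in [1, K+1] and
    strictly increases in the target's surprisal (decreases in u_0).
    """
    u0 = ws.weights[0]
    rest = ws.weights[1:]
    with np.errstate(invalid="ignore"):
        terms = rest / (rest + u0)
    mean = 1.0 + float(math.fsum(terms.tolist()))
    return RuntimeSummary(mean, None, "analytic", target_surprisal=ws.target_surprisal)


def wor_runtime_variance(ws: WeightSet, allow_large: bool = False) -> RuntimeSummary:
    """Mean and variance of the without-replacement draw count.

    Writing u_ab := u_a + u_b and u_abc := u_a + u_b + u_c, the variance is

        Var[N] = sum_i (E[X_i] - E[X_i]^2)
               + sum_{i != j} (E[X_i X_j] - E[X_i] E[X_j])

    with E[X_i] = u_i / u_i0 and the cross-moment expanded over the two
    orders in which i and j can both precede the target:

        E[X_i X_j] = Pr(i < j < 0) + Pr(j < i < 0)
                   = (u_i/u_ij0)(u_j/u_j0) + (u_j/u_ij0)(u_i/u_i0).

    The pairwise sum is evaluated with vectorized (pairwise-summed) numpy
    reductions; cost is O(K^2) memory-blocked.
    """
    _check_size(ws, allow_large)
    u0 = float(ws.weights[0])
    u = ws.weights[1:].astype(float)
    K = u.size
    mean_summary = wor_expected_runtime(ws)
    if K == 0:
        return RuntimeSummary(1.0, 0.0, "analytic", target_surprisal=ws.target_surprisal)

    ex = u / (u + u0)  # E[X_i]
    diag = float(math.fsum((ex - ex * ex).tolist()))

    # blocked pairwise sum of E[X_i X_j] - E[X_i] E[X_j] over i != j
    block = 2048
    cross = 0.0
    ui0 = u + u0
    for start in range(0, K, block):
        ii = slice(start, min(start + block, K))
        u_i = u[ii][:, None]
        ex_i = ex[ii][:, None]
        uij0 = u_i + u[None, :] + u0
        exixj = (u_i / uij0) * (u[None, :] / ui0[None, :]) + (
            u[None, :] / uij0
        ) * (u_i / ui0[ii][:, None])
        contrib = exixj - ex_i * ex[None, :]
        # zero out the i == j diagonal entries within this block
        idx = np.arange(start, min(start + block, K))
        contrib[idx - start, idx] = 0.0
        cross += float(contrib.sum())
    var = diag + cross
    return RuntimeSummary(
        mean_summary.mean_draws,
        max(var, 0.0),
        "analytic",
        target_surprisal=ws.target_surprisal,
    )


def kl_surprisal_identity_check(
    prior: PriorDistribution, likelihood: Sequence[float]
) -> tuple[float, float, float]:
    """Compare step surprisal with KL(posterior || prior).

    Returns ``(surprisal, kl_divergence, gap)`` where the gap is zero (to
    rounding) exactly when the likelihood is 0/1-valued — i.e. when latent
    structures determine the word, so observing the word just renormalizes
    the prior over its compatible subset.  Graded likelihoods reweight the
    support and break the identity.
    """
    posterior, marginal = posterior_update(prior, likelihood)
    surprisal = -math.log(marginal)
    p = prior.probabilities
    q = posterior.probabilities
    mask = q > 0
    kl = float(np.sum(q[mask] * np.log(q[mask] / p[mask])))
    return surprisal, kl, abs(surprisal - kl)
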