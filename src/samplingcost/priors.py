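"""Weight and probability containers for guessing-algorithm analysis.

A *WeightSet* holds nonnegative item weights with the target item at index 0,
the substrate of both guessing algorithms (with and without replacement).
A *PriorDistribution* is a normalized probability vector together with the
per-item surprisals I_i = -ln p_i (in nats).  The module also provides
heavy-tailed (Pareto) weight generation and the exact one-step Bayesian
posterior update whose marginal defines the step surprisal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightSet",
    "PriorDistribution",
    "make_weightset",
    "sample_pareto_weights",
    "rotate_target",
    "posterior_update",
    "nats_to_bits",
    "bits_to_nats",
    "read_weights_tsv",
    "write_weights_tsv",
]

LN2 = math.log(2.0)


def nats_to_bits(x: float) -> float:
    """Convert an information quantity from nats to bits."""
    return x / LN2


def bits_to_nats(x: float) -> float:
    """Convert an information quantity from bits to nats."""
    return x * LN2


@dataclass(frozen=True)
class WeightSet:
    """Nonnegative item weights with the target at index 0.

    Weights are stored at arbitrary scale; probabilities are computed on
    demand to avoid renormalization error accumulation.  ``K`` is the number
    of non-target items, so ``len(weights) == K + 1``.
    """

    weights: np.ndarray
    normalized: bool = False
    target_index: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(w)):
            bad = int(np.flatnonzero(~np.isfinite(w))[0])
            raise ValueError(f"weight at index {bad} is not finite")
        if np.any(w < 0):
            bad = int(np.flatnonzero(w < 0)[0])
            raise ValueError(f"weight at index {bad} is negative")
        if w[0] <= 0:
            raise ValueError("target weight (index 0) must be positive")
        if self.normalized and abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError("normalized WeightSet must sum to 1 within 1e-12")

    @property
    def K(self) -> int:
        """Number of non-target items."""
        return self.weights.size - 1

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def probabilities(self) -> np.ndarray:
        """Weights rescaled to sum to 1."""
        return self.weights / self.weights.sum()

    @property
    def target_probability(self) -> float:
        return float(self.weights[0] / self.weights.sum())

    @property
    def target_surprisal(self) -> float:
        """Surprisal of the target item, -ln(u_0 / sum u), in nats."""
        return -math.log(self.target_probability)

    def digest(self) -> str:
        """Stable hex checksum of the weight vector (for provenance records)."""
        import hashlib

        return hashlib.sha256(np.ascontiguousarray(self.weights).tobytes()).hexdigest()[:16]


def make_weightset(weights: Sequence[float], normalize: bool = False) -> WeightSet:
    """Validate a weight sequence and wrap it as a :class:`WeightSet`.

    Parameters
    ----------
    weights
        Nonnegative finite reals; the first entry is the target and must be
        positive.
    normalize
        If True, rescale the weights to sum to 1.
    """
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0:
        raise ValueError("empty weight sequence")
    if normalize:
        ws = WeightSet(w)  # validates before scaling
        return WeightSet(ws.weights / ws.weights.sum(), normalized=True)
    return WeightSet(w)


def sample_pareto_weights(
    K_plus_1: int, shape: float = 1.0, scale: float = 1.0, seed: int = 0
) -> WeightSet:
    """Draw ``K_plus_1`` independent Pareto(shape, scale) weights, normalized.

    Generation is by inverse CDF on a seeded uniform stream:
    ``x = scale * (1 - U)^(-1/shape)``, so results are deterministic given
    ``seed``.  The normalized vector sums to 1; any item can subsequently be
    treated as the target via :func:`rotate_target`.
    """
    if K_plus_1 < 1:
        raise ValueError("need at least one item")
    if shape <= 0 or scale <= 0:
        raise ValueError("Pareto shape and scale must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=K_plus_1)
    x = scale * (1.0 - u) ** (-1.0 / shape)
    return WeightSet(x / x.sum(), normalized=True)


def rotate_target(ws: WeightSet, j: int) -> WeightSet:
    """Return a WeightSet with item ``j`` moved to the target slot (index 0).

    The remaining items keep their original relative order, so digests of
    rotated sets are stable functions of (ws, j).
    """
    if not 0 <= j <= ws.K:
        raise IndexError(f"item index {j} out of range for K={ws.K}")
    w = ws.weights
    if w[j] <= 0:
        raise ValueError(f"item {j} has zero weight and cannot be the target")
    rotated = np.concatenate(([w[j]], np.delete(w, j)))
    return WeightSet(rotated, normalized=ws.normalized)


@dataclass(frozen=True)
class PriorDistribution:
    """A discrete probability vector with per-item surprisals in nats.

    Zero entries are permitted so that posteriors with pruned support (e.g.
    after an indicator likelihood) remain representable at full length.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("probabilities must be a non-empty 1-D sequence")
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    @property
    def surprisals(self) -> np.ndarray:
        """I_i = -ln p_i; exactly 0 for a probability-1 item, inf for 0."""
        with np.errstate(divide="ignore"):
            return -np.log(self.probabilities)

    @classmethod
    def from_weights(cls, ws: WeightSet) -> "PriorDistribution":
        if np.any(ws.weights <= 0):
            raise ValueError("all weights must be positive to form a distribution")
        return cls(ws.probabilities())


def posterior_update(
    prior: PriorDistribution, likelihood: Sequence[float]
) -> tuple[PriorDistribution, float]:
    """One step of exact Bayesian belief update over discrete hypotheses.

    Given a prior p(z) and a likelihood vector p(w|z) with entries in [0, 1],
    returns the posterior p(z|w) = p(w|z) p(z) / marginal and the marginal
    p(w) = sum_z p(w|z) p(z).  The step surprisal is -ln(marginal).

    Raises
    ------
    ValueError
        If the likelihood leaves no probability mass ("impossible
        observation") or has entries outside [0, 1].
    """
    lik = np.asarray(likelihood, dtype=float)
    p = prior.probabilities
    if lik.shape != p.shape:
        raise ValueError("likelihood must have the same length as the prior")
    if np.any(lik < 0) or np.any(lik > 1) or not np.all(np.isfinite(lik)):
        raise ValueError("likelihood entries must lie in [0, 1]")
    joint = lik * p
    marginal = float(joint.sum())
    if marginal <= 0:
        raise ValueError("impossible observation: all posterior mass is zero")
    post = joint / marginal
    return PriorDistribution(post / post.sum()), marginal


def read_weights_tsv(path) -> WeightSet:
    """Read a weight vector from a single-column TSV with header ``weight``.

    The first row is the target item by convention.
    """
    df = pd.read_csv(path, sep="\t")
    if "weight" not in df.columns:
        raise ValueError(f"{path}: expected a 'weight' column, got {list(df.columns)}")
    return make_weightset(df["weight"].to_numpy())


def write_weights_tsv(ws: WeightSet, path) -> None:
    """Write a WeightSet as a single-column TSV with header ``weight``."""
    pd.DataFrame({"weight": ws.weights}).to_csv(path, sep="\t", index=False)
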