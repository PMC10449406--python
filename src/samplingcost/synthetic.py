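"""Synthetic self-paced-reading data with a known linking function.

The generator emulates the statistical structure of a word-by-word reading
corpus without any text: items carry abstract surprisal values drawn from a
right-skewed distribution (most words have low surprisal, a heavy right
tail), each subject reads every item in order, and reading time is

    rt = link(I) + spillover_beta * I_prev + b_subj + m_subj * I + eps,

where ``link`` is one of the parametric linking families, ``b_subj`` and
``m_subj`` are per-subject intercept and slope perturbations, and ``eps`` is
Gaussian with a standard deviation that may itself depend on surprisal
(constant log-SD, or log-SD linear in surprisal — the location-scale
structure the curve fitter is designed to recover).  RTs are floored at
1 ms; the number of floored rows is recorded.

Also implements the surprisal-degradation perturbation: multiply the
surprisal of a random subset of rows by a constant while leaving their
reading times unchanged, imitating an estimator that systematically
overestimates the surprisal of some words.  Degradation flattens the
apparent linking function, so fitted superlinearity should drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .linking import LinkingFunction, eval_linking

__all__ = ["RTDataset", "GeneratorConfig", "generate_rt_dataset", "degrade_surprisals"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "item_id", "surprisal", "rt")


@dataclass(frozen=True)
class RTDataset:
    """Long-format reading-time table.

    Columns: subject_id (categorical), item_id (int), surprisal (nats),
    prev_surprisal (nats, 0 for a subject's first item), rt (ms, positive).
    """

    frame: pd.DataFrame
    provenance: str = "external"

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"RT table is missing required columns {missing}")
        if "prev_surprisal" not in df.columns:
            df = df.sort_values(["subject_id", "item_id"], kind="mergesort").copy()
            prev = df.groupby("subject_id")["surprisal"].shift(1).fillna(0.0)
            df["prev_surprisal"] = prev
            object.__setattr__(self, "frame", df.reset_index(drop=True))
            df = self.frame
        bad_rt = df.index[df["rt"] <= 0]
        if len(bad_rt):
            raise ValueError(f"non-positive rt at rows {list(bad_rt[:10])}")
        bad_s = df.index[(df["surprisal"] < 0) | (df["prev_surprisal"] < 0)]
        if len(bad_s):
            raise ValueError(f"negative surprisal at rows {list(bad_s[:10])}")
        dup = df.duplicated(subset=["subject_id", "item_id"])
        if dup.any():
            raise ValueError(f"duplicate (subject, item) pairs at rows {list(df.index[dup][:10])}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic reading-time generator.

    Parameters
    ----------
    linking
        True surprisal-to-time map used for the mean structure (ms).
    logsd_curve
        ``("constant", {"value": v})`` for noise SD exp(v) ms at every
        surprisal, or ``("linear_in_surprisal", {"intercept": a, "slope": b})``
        for SD exp(a + b * I).
    n_subjects, n_items
        Design size; every subject reads every item.
    surprisal_dist
        ``("lognormal", {"mean_log": m, "sigma": s})`` (right-skewed default)
        or ``("pareto_derived", {"n_items_pool": n, "shape": a, "scale": c,
        "seed_offset": k})`` which uses the surprisals of a normalized Pareto
        weight set, tying the reading-time study to the guessing-algorithm
        weight model.
    subject_sd_intercept
        SD of per-subject intercept offsets, ms.
    subject_sd_slope
        SD of per-subject slope perturbations, as a fraction of the secant
        slope of the linking function over the realized surprisal range.
    spillover_beta
        Linear effect of the previous item's surprisal, ms/nat.
    seed
        Parent seed; the generator is fully reproducible given the config.
    """

    linking: LinkingFunction = field(default_factory=lambda: LinkingFunction.linear(250.0, 25.0))
    logsd_curve: tuple = ("constant", {"value": float(np.log(50.0))})
    n_subjects: int = 40
    n_items: int = 800
    surprisal_dist: tuple = ("lognormal", {"mean_log": float(np.log(2.0)), "sigma": 1.0})
    subject_sd_intercept: float = 30.0
    subject_sd_slope: float = 0.1
    spillover_beta: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_items < 1:
            raise ValueError("need at least one subject and one item")
        if self.subject_sd_intercept < 0 or self.subject_sd_slope < 0:
            raise ValueError("subject effect scales must be nonnegative")
        kind, _ = self.logsd_curve
        if kind not in {"constant", "linear_in_surprisal"}:
            raise ValueError(f"unknown logsd_curve kind {kind!r}")
        kind, _ = self.surprisal_dist
        if kind not in {"lognormal", "pareto_derived"}:
            raise ValueError(f"unknown surprisal_dist kind {kind!r}")


def _draw_surprisals(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    kind, params = cfg.surprisal_dist
    if kind == "lognormal":
        return rng.lognormal(mean=params["mean_log"], sigma=params["sigma"], size=cfg.n_items)
    # pareto_derived: surprisals of items in a normalized Pareto weight set
    from .priors import sample_pareto_weights

    pool = int(params.get("n_items_pool", max(cfg.n_items, 1000)))
    ws = sample_pareto_weights(
        pool,
        shape=params.get("shape", 1.0),
        scale=params.get("scale", 1.0),
        seed=int(rng.integers(2**31)),
    )
    surprisals = -np.log(ws.probabilities())
    return rng.choice(surprisals, size=cfg.n_items, replace=cfg.n_items > pool)


def _logsd_at(cfg: GeneratorConfig, surprisal: np.ndarray) -> np.ndarray:
    kind, params = cfg.logsd_curve
    if kind == "constant":
        return np.full_like(surprisal, float(params["value"]))
    return params["intercept"] + params["slope"] * surprisal


def generate_rt_dataset(cfg: GeneratorConfig) -> RTDataset:
    """Generate a complete subjects-by-items reading-time table.

    Deterministic given ``cfg`` (including its seed).  RT values are floored
    at 1 ms; a count of floored rows is logged.
    """
    rng = np.random.default_rng(cfg.seed)
    surprisal = _draw_surprisals(cfg, rng)
    prev = np.concatenate(([0.0], surprisal[:-1]))
    mu_item = eval_linking(cfg.linking, surprisal) + cfg.spillover_beta * prev
    sd_item = np.exp(_logsd_at(cfg, surprisal))

    # per-subject perturbations; slope SD is a fraction of the secant slope
    span = float(surprisal.max() - surprisal.min())
    if span > 0:
        secant = float(
            (eval_linking(cfg.linking, float(surprisal.max()))
             - eval_linking(cfg.linking, float(surprisal.min()))) / span
        )
    else:
        secant = 0.0
    b_subj = rng.normal(0.0, cfg.subject_sd_intercept, size=cfg.n_subjects)
    m_subj = rng.normal(0.0, cfg.subject_sd_slope * abs(secant), size=cfg.n_subjects)

    noise = rng.normal(size=(cfg.n_subjects, cfg.n_items)) * sd_item[None, :]
    rt = mu_item[None, :] + b_subj[:, None] + m_subj[:, None] * surprisal[None, :] + noise

    floored = int((rt < 1.0).sum())
    if floored:
        logger.info("floored %d of %d reading times at 1 ms", floored, rt.size)
    rt = np.maximum(rt, 1.0)

    subj = np.repeat([f"s{i:03d}" for i in range(cfg.n_subjects)], cfg.n_items)
    frame = pd.DataFrame(
        {
            "subject_id": subj,
            "item_id": np.tile(np.arange(cfg.n_items), cfg.n_subjects),
            "surprisal": np.tile(surprisal, cfg.n_subjects),
            "prev_surprisal": np.tile(prev, cfg.n_subjects),
            "rt": rt.ravel(),
        }
    )
    return RTDataset(frame, provenance=f"generated(seed={cfg.seed})")


def degrade_surprisals(
    data: RTDataset, fraction: float, inflation: float, seed: int
) -> RTDataset:
    """Inflate the surprisal of a random subset of rows, keeping RTs fixed.

    Emulates a surprisal estimator that systematically overestimates some
    words: a seeded random ``fraction`` of rows has surprisal multiplied by
    ``inflation`` (>= 1); reading times and all other columns are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if inflation < 1.0:
        raise ValueError("inflation must be >= 1")
    if fraction == 0.0 or inflation == 1.0:
        return RTDataset(data.frame.copy(), provenance=data.provenance)
    rng = np.random.default_rng(seed)
    n = len(data)
    n_pick = int(round(fraction * n))
    picked = rng.choice(n, size=n_pick, replace=False)
    frame = data.frame.copy()
    col = frame.columns.get_loc("surprisal")
    frame.iloc[picked, col] = frame.iloc[picked, col] * inflation
    return RTDataset(frame, provenance=f"{data.provenance}+degraded(f={fraction},x{inflation})")
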