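"""Confusion-matrix comparison of inferred vs gold-standard networks.

Both networks are viewed as adjacency indicators over all unordered
pairs of distinct genes in an evaluation universe (by default the gold
standard's genes). Over those C(n, 2) pairs:

    TP  edge inferred and present in the gold standard
    FP  edge inferred but absent from the gold standard
    FN  edge not inferred but present in the gold standard
    TN  edge in neither network

and the derived measures are

    PPV         = TP / (TP + FP)          (precision)
    Sensitivity = TP / (TP + FN)          (recall)
    Similarity  = sqrt(PPV * Sensitivity) (geometric mean),

with the conservative zero-denominator convention that an undefined
ratio scores 0. For weight-sweep experiments each measure traces a gain
curve over the biological-information weight w2; curves can be min-max
rescaled to [0, 1] to compare gain shapes across gold standards of very
different base rates (raw curves are always kept alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import Network, n_pairs

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "GainCurve",
    "SweepPoint",
    "confusion_matrix",
    "metrics",
    "normalize_curves",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    ppv: float
    sensitivity: float
    similarity: float


@dataclass(frozen=True)
class SweepPoint:
    """One grid point of a weight sweep: w2, raw counts, derived metrics."""

    w2: float
    counts: ConfusionCounts
    metrics: Metrics


@dataclass(frozen=True)
class GainCurve:
    """One metric's values over the weight grid."""

    metric: str
    points: tuple[tuple[float, float], ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        ws = [w for w, _ in self.points]
        if ws != sorted(set(ws)):
            raise ValueError("curve weights must be strictly increasing")

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.points)


def confusion_matrix(
    inferred: Network,
    gold: Network,
    universe: frozenset[str] | set[str] | None = None,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN over all unordered gene pairs in the universe.

    Edges with an endpoint outside the universe are ignored (both
    networks are restricted before counting). Self-pairs never count.
    """
    import logging

    logger = logging.getLogger(__name__)
    if universe is None:
        universe = gold.genes
    universe = frozenset(universe)
    if len(universe) < 2:
        raise ValueError("evaluation universe needs at least 2 genes")

    def restrict(net: Network) -> frozenset[tuple[str, str]]:
        kept = frozenset(
            e for e in net.edges if e[0] in universe and e[1] in universe
        )
        if len(kept) < net.n_edges:
            logger.debug(
                "ignoring %d edges outside the evaluation universe",
                net.n_edges - len(kept),
            )
        return kept

    inf_edges = restrict(inferred)
    gold_edges = restrict(gold)
    tp = len(inf_edges & gold_edges)
    fp = len(inf_edges - gold_edges)
    fn = len(gold_edges - inf_edges)
    tn = n_pairs(len(universe)) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(c: ConfusionCounts) -> Metrics:
    """PPV, sensitivity and their geometric-mean similarity."""
    ppv = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    return Metrics(ppv=ppv, sensitivity=sens, similarity=math.sqrt(ppv * sens))


def normalize_curves(curves: list[GainCurve]) -> list[GainCurve]:
    """Min-max rescale each curve to [0, 1]; constant curves map to 0.

    Input (raw) curves are untouched — callers keep both so the
    normalization choice stays auditable.
    """
    out: list[GainCurve] = []
    for c in curves:
        if len(c.points) < 2:
            raise ValueError("normalization needs curves with >=2 points")
        vals = c.values
        lo, hi = min(vals), max(vals)
        span = hi - lo
        if span == 0:
            scaled = tuple((w, 0.0) for w, _ in c.points)
        else:
            scaled = tuple((w, (v - lo) / span) for w, v in c.points)
        out.append(GainCurve(c.metric, scaled, normalized=True))
    return out
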