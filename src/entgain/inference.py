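"""Per-target predictor search and network assembly.

For each target gene the best predictor subset is found by Sequential
Forward Floating Selection (SFFS) run at every cardinality k = 1..kmax,
keeping the globally best (lowest) biological score across
cardinalities. SFFS alternates greedy forward inclusion of the
best-scoring addition with conditional backward exclusions: after each
inclusion, a feature is removed whenever doing so strictly improves on
the best subset already known at the smaller size. This lets the search
escape the nesting of plain greedy selection at a cost far below
exhaustive enumeration.

All ties are broken deterministically by (score, subset size ascending,
lexicographic gene order); the whole pipeline contains no randomness.

The inferred network is the union, over targets, of undirected
{predictor, target} pairs from each winning subset. Although the
dynamics are directed (predictors at time t, target at t + lag), edges
are stored undirected because the gold standards against which networks
are evaluated are undirected pair sets; direction is not verifiable
against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .criterion import CriterionWeights, PenaltyConfig, Scorer
from .errors import InsufficientDataError
from .evaluation import GainCurve, SweepPoint, confusion_matrix, metrics
from .io import ExpressionMatrix, Network

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSet",
    "InferenceConfig",
    "sffs_search",
    "gn_inference",
    "infer_network",
    "weight_sweep",
]

ScoreFn = Callable[[Sequence[str]], float]


@dataclass(frozen=True)
class PredictorSet:
    """Winning predictor subset for one target and its criterion value."""

    target: str
    predictors: tuple[str, ...]
    value: float


@dataclass(frozen=True)
class InferenceConfig:
    """Search settings: subset-size cap, score weights, entropy penalty, lag."""

    kmax: int = 3
    weights: CriterionWeights = field(
        default_factory=lambda: CriterionWeights.from_w2(0.0)
    )
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    lag: int = 1

    def __post_init__(self) -> None:
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")


def _key(score: float, subset: Sequence[str]) -> tuple:
    return (score, len(subset), tuple(sorted(subset)))


def sffs_search(
    k: int, candidates: Sequence[str], score_fn: ScoreFn
) -> tuple[tuple[str, ...], float]:
    """Best predictor subset of size exactly ``k`` by floating selection.

    Parameters
    ----------
    k
        Required subset cardinality, 1 <= k <= len(candidates).
    candidates
        Candidate predictor genes (must exclude the target).
    score_fn
        Maps a subset to its criterion value; lower is better.

    Returns
    -------
    (subset, value)
        The best size-k subset encountered (sorted tuple) and its score.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")

    # best known (score, size, sorted subset) per cardinality
    best: dict[int, tuple] = {}

    def consider(subset: Sequence[str], score: float) -> None:
        key = _key(score, subset)
        size = len(subset)
        if size not in best or key < best[size]:
            best[size] = key

    def best_addition(current: list[str]) -> tuple[str, float]:
        trial = None
        for g in candidates:
            if g in current:
                continue
            subset = sorted(current + [g])
            key = _key(score_fn(subset), subset)
            if trial is None or key < trial:
                trial = key
                added = g
        return added, trial[0]

    # Prime with a pure greedy-forward pass so the floating result can
    # never be worse than plain sequential forward selection at any size.
    greedy: list[str] = []
    while len(greedy) < k:
        g, score = best_addition(greedy)
        greedy.append(g)
        consider(greedy, score)

    current: list[str] = []
    while len(current) < k:
        # forward step: add the best-scoring candidate
        g, score = best_addition(current)
        current.append(g)
        consider(current, score)
        # backward (floating) steps: drop a feature while that strictly
        # improves the best subset known at the smaller cardinality
        while len(current) > 1:
            drop_trial = None
            for g in current:
                subset = sorted(x for x in current if x != g)
                key = _key(score_fn(subset), subset)
                if drop_trial is None or key < drop_trial:
                    drop_trial = key
                    dropped = g
            smaller = len(current) - 1
            if smaller in best and drop_trial[0] >= best[smaller][0]:
                break
            current = [x for x in current if x != dropped]
            consider(current, drop_trial[0])
    score, _, subset = best[k]
    return subset, score


def gn_inference(
    target: str,
    cfg: InferenceConfig,
    data: ExpressionMatrix,
    prior: Network | None = None,
    candidates: Sequence[str] | None = None,
    scorer: Scorer | None = None,
) -> PredictorSet:
    """Best predictor subset for one target over cardinalities 1..kmax.

    Runs :func:`sffs_search` for each k and keeps the global best under
    strict improvement, so the smallest cardinality wins score ties.
    Candidates default to all other genes in the matrix — the prior
    network scores subsets but never restricts candidacy.
    """
    if scorer is None:
        scorer = Scorer(data, prior, cfg.weights, cfg.penalty, cfg.lag)
    if candidates is None:
        candidates = [g for g in data.gene_ids if g != target]
    else:
        candidates = [g for g in candidates if g != target]
    if not candidates:
        raise ValueError(f"no candidate predictors for target {target!r}")

    def score_fn(subset: Sequence[str]) -> float:
        return scorer.score(target, subset)

    best_value = float("inf")
    best_subset: tuple[str, ...] = ()
    for k in range(1, min(cfg.kmax, len(candidates)) + 1):
        subset, value = sffs_search(k, candidates, score_fn)
        if value < best_value:
            best_value = value
            best_subset = subset
    return PredictorSet(target, best_subset, best_value)


def _degenerate(data: ExpressionMatrix, gene: str) -> bool:
    """True if the gene's observed quantized values are all identical."""
    s = data.series(gene)
    obs = s[s != data.missing_code]
    return obs.size == 0 or bool((obs == obs[0]).all())


def infer_network(
    cfg: InferenceConfig,
    data: ExpressionMatrix,
    prior: Network | None = None,
    targets: Sequence[str] | None = None,
    scorer: Scorer | None = None,
) -> Network:
    """Infer an undirected network by solving every per-target search.

    Targets with degenerate (constant or empty) observed series are
    skipped with a warning; targets for which no aligned sample survives
    the missing-data filter are skipped likewise.
    """
    if not data.quantized:
        raise ValueError("infer_network needs a quantized matrix")
    if targets is None:
        targets = list(data.gene_ids)
    if scorer is None:
        scorer = Scorer(data, prior, cfg.weights, cfg.penalty, cfg.lag)
    scorer.weights = cfg.weights
    edges: list[tuple[str, str]] = []
    for target in targets:
        if _degenerate(data, target):
            logger.warning("skipping degenerate target %s", target)
            continue
        try:
            result = gn_inference(target, cfg, data, prior, scorer=scorer)
        except InsufficientDataError:
            logger.warning("skipping target %s: no aligned observed sample", target)
            continue
        logger.debug(
            "target %s: best=%s value=%.6f", target, result.predictors, result.value
        )
        for p in result.predictors:
            edges.append((p, target))
    return Network.build(edges, genes=data.gene_ids)


DEFAULT_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def weight_sweep(
    cfg_base: InferenceConfig,
    data: ExpressionMatrix,
    prior: Network,
    gold: Network,
    grid: Sequence[float] = DEFAULT_GRID,
    universe: frozenset[str] | None = None,
) -> tuple[list[GainCurve], list[SweepPoint]]:
    """Infer and evaluate across a grid of biological-information weights.

    For each w2 in the (deduplicated, sorted) grid the network is
    inferred with weights (w1, w2) = (1 - w2, w2) and compared with
    ``gold`` over ``universe`` (default: the gold standard's genes).
    Returns raw gain curves for PPV, sensitivity and similarity, plus
    the confusion counts behind every grid point.
    """
    grid = sorted(set(float(w) for w in grid))
    if not grid:
        raise ValueError("weight grid must be non-empty")
    if any(w < 0 or w > 1 for w in grid):
        raise ValueError("weights must lie in [0, 1]")
    points: list[SweepPoint] = []
    # One scorer across grid points: E and P are weight-independent.
    scorer = Scorer(data, prior, cfg_base.weights, cfg_base.penalty, cfg_base.lag)
    for w2 in grid:
        cfg = replace(cfg_base, weights=CriterionWeights.from_w2(w2))
        inferred = infer_network(cfg, data, prior, scorer=scorer)
        counts = confusion_matrix(inferred, gold, universe=universe)
        points.append(SweepPoint(w2=w2, counts=counts, metrics=metrics(counts)))
    curves = [
        GainCurve(name, tuple((p.w2, getattr(p.metrics, name)) for p in points))
        for name in ("ppv", "sensitivity", "similarity")
    ]
    return curves, points
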