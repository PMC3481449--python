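"""The biological-score criterion: penalized entropy plus prior evidence.

For a fixed target gene Y and a candidate predictor subset X the
criterion to be minimized is the weighted biological score

    BS(Y, X) = E(Y, X) * w1 + P(Y, X) * w2,      w1 + w2 = 1,

where E is the penalized mean conditional entropy of the target's
quantized expression given the predictors' quantized expression one time
step earlier, and P is a prior-knowledge penalty measuring how poorly
the subset is supported by a biological interaction network (e.g.
protein-protein links). Both terms lie in [0, 1], so BS does too, and a
lower score means a better predictor subset.

Penalized mean conditional entropy
----------------------------------
Predictors are read at time t and the target at time t + lag (lag 1 by
default): the data are treated dynamically, as a first-order update
process. Tuples containing a not-observed code are dropped. With N
surviving aligned samples, predictor states x occurring n_x times,
empirical conditional entropies H(Y | x) (base 2, divided by log2(3) so
a uniform ternary distribution scores 1), and M unobserved predictor
states out of the 3^k possible, the penalized score is

    E = (alpha * M + sum_x n_x * H(Y | x)) / (alpha * M + N).

Each unobserved state is charged the maximal normalized entropy 1 with
weight alpha (default 1). The penalty grows with 3^k, so predictor sets
too large for the sample size are increasingly punished — the intended
guard against the curse of dimensionality at a few dozen time points.

Prior penalty
-------------
P(Y, X) is the fraction of predictors in X with no edge to the target in
the prior network: 0 when every predictor is supported, 1 when none is.
Genes absent from the prior count as unsupported. For a single predictor
this reduces to a pure {0, 1} indicator of prior support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, LookupError_
from .io import ExpressionMatrix, Network

__all__ = [
    "PenaltyConfig",
    "CriterionWeights",
    "penalized_mce",
    "prior_penalty",
    "biological_score",
    "Scorer",
]

_N_LEVELS = 3  # ternary expression alphabet


@dataclass(frozen=True)
class PenaltyConfig:
    """Knobs of the penalized entropy: penalty weight, log base, scaling."""

    alpha: float = 1.0
    base: float = 2.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.base <= 1:
            raise ValueError("entropy base must exceed 1")


@dataclass(frozen=True)
class CriterionWeights:
    """Expression weight w1 and biological-information weight w2, w1+w2=1."""

    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.w1 + self.w2}")

    @staticmethod
    def from_w2(w2: float) -> "CriterionWeights":
        return CriterionWeights(1.0 - w2, w2)


def _entropy(counts: np.ndarray, base: float) -> float:
    """Shannon entropy of a count vector."""
    from scipy.stats import entropy as _scipy_entropy

    total = counts.sum()
    if total == 0:
        return 0.0
    return float(_scipy_entropy(counts, base=base))


def penalized_mce(
    target: str,
    predictors: Sequence[str],
    data: ExpressionMatrix,
    lag: int = 1,
    cfg: PenaltyConfig = PenaltyConfig(),
) -> float:
    """Penalized mean conditional entropy of ``target`` given ``predictors``.

    Returns a value in [0, 1] when ``cfg.normalize`` is on: 0 for a
    deterministic regulator relation, 1 when the target is uniform and
    independent of fully unobserved predictor states.

    Raises
    ------
    InsufficientDataError
        If no aligned (predictor, target) tuple is fully observed.
    LookupError_
        If the target or a predictor is not in the matrix.
    """
    if not data.quantized:
        raise ValueError("penalized_mce needs a quantized matrix")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if not predictors:
        raise ValueError("predictor list must be non-empty")
    y = data.series(target)
    xs = np.stack([data.series(p) for p in predictors])
    T = data.n_timepoints
    # Aligned pairs: predictors at t, target at t + lag.
    x_win = xs[:, : T - lag]
    y_win = y[lag:]
    ok = (y_win != data.missing_code) & (x_win != data.missing_code).all(axis=0)
    x_win = x_win[:, ok]
    y_win = y_win[ok]
    n = int(ok.sum())
    if n == 0:
        raise InsufficientDataError(
            f"no fully-observed aligned sample for target {target!r}"
        )
    k = len(predictors)
    # Tally the joint (predictor-state, target-value) count table.
    state_counts: dict[tuple[int, ...], np.ndarray] = {}
    for t in range(n):
        state = tuple(int(v) for v in x_win[:, t])
        row = state_counts.setdefault(state, np.zeros(_N_LEVELS, dtype=int))
        row[int(y_win[t]) + 1] += 1
    h_max = float(np.log(_N_LEVELS) / np.log(cfg.base))
    scale = h_max if cfg.normalize else 1.0
    weighted_h = 0.0
    for counts in state_counts.values():
        h = _entropy(counts, cfg.base) / scale
        weighted_h += counts.sum() * h
    m_unobserved = _N_LEVELS**k - len(state_counts)
    num = cfg.alpha * m_unobserved * (1.0 if cfg.normalize else h_max) + weighted_h
    den = cfg.alpha * m_unobserved + n
    return num / den


def prior_penalty(target: str, predictors: Sequence[str], prior: Network) -> float:
    """Fraction of predictors with no prior edge to the target (in [0, 1])."""
    if not predictors:
        raise ValueError("predictor list must be non-empty")
    unsupported = sum(1 for p in predictors if not prior.has_edge(target, p))
    return unsupported / len(predictors)


def biological_score(e: float, p: float, w: CriterionWeights) -> float:
    """Weighted combination E*w1 + P*w2 of entropy and prior terms."""
    return e * w.w1 + p * w.w2


class Scorer:
    """Memoizing criterion evaluator for one dataset/prior pair.

    The search re-scores many overlapping subsets, and a weight sweep
    re-scores the same subsets under different weights; caching the
    (E, P) components on (target, frozenset of predictors) keeps both
    cheap without changing any value. ``weights`` may be reassigned
    between evaluations — the cached components are weight-independent.
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        prior: Network | None,
        weights: CriterionWeights,
        penalty: PenaltyConfig = PenaltyConfig(),
        lag: int = 1,
    ) -> None:
        self.data = data
        self.prior = prior
        self.weights = weights
        self.penalty = penalty
        self.lag = lag
        self._cache: dict[tuple[str, frozenset[str]], tuple[float, float]] = {}

    def components(self, target: str, predictors: Sequence[str]) -> tuple[float, float]:
        """(E, P) for one subset, memoized."""
        key = (target, frozenset(predictors))
        if key not in self._cache:
            e = penalized_mce(target, predictors, self.data, self.lag, self.penalty)
            p = (
                prior_penalty(target, predictors, self.prior)
                if self.prior is not None
                else 0.0
            )
            self._cache[key] = (e, p)
        return self._cache[key]

    def score(self, target: str, predictors: Sequence[str]) -> float:
        e, p = self.components(target, predictors)
        return biological_score(e, p, self.weights)
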