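"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's code paths: entropies are
computed from -sum p*log3(p) over explicit count tables, searches by
exhaustive enumeration, so agreement with the package is a genuine
cross-check and not a tautology.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

MISSING = 3
LEVELS = (-1, 0, 1)


def mce_bruteforce(target, predictors, data, lag=1, alpha=1.0):
    """Penalized mean conditional entropy by full state enumeration."""
    y = list(data.series(target))
    xs = [list(data.series(p)) for p in predictors]
    k = len(predictors)
    pairs = []
    for t in range(len(y) - lag):
        state = tuple(x[t] for x in xs)
        out = y[t + lag]
        if MISSING in state or out == MISSING:
            continue
        pairs.append((state, out))
    n = len(pairs)
    assert n > 0
    num = 0.0
    n_unobserved = 0
    for state in itertools.product(LEVELS, repeat=k):
        outs = [o for s, o in pairs if s == state]
        if not outs:
            n_unobserved += 1
            num += alpha * 1.0  # maximal normalized ternary entropy
            continue
        counts = Counter(outs)
        h = -sum(
            (c / len(outs)) * math.log(c / len(outs), 3) for c in counts.values()
        )
        num += len(outs) * h
    return num / (alpha * n_unobserved + n)


def exhaustive_best(candidates, kmax, score_fn):
    """Exhaustive minimum over all subsets of size 1..kmax.

    Ties broken by (score, size ascending, lexicographic subset), the
    same deterministic rule the package documents.
    """
    best = None
    for k in range(1, kmax + 1):
        for subset in itertools.combinations(sorted(candidates), k):
            key = (score_fn(list(subset)), k, subset)
            if best is None or key < best:
                best = key
    return best  # (score, size, subset)


def greedy_forward(candidates, k, score_fn):
    """Plain sequential forward selection, same tie-break rule."""
    current: list[str] = []
    score = None
    while len(current) < k:
        best = None
        for g in sorted(candidates):
            if g in current:
                continue
            subset = sorted(current + [g])
            key = (score_fn(subset), tuple(subset))
            if best is None or key < best:
                best = key
                pick = g
        current.append(pick)
        score = best[0]
    return tuple(sorted(current)), score


def sffs_reachable_k2(candidates, score_fn):
    """True iff the exhaustive best subset of size <= 2 is provably
    reachable by floating selection: it is a singleton, or a pair
    containing the best singleton."""
    best = exhaustive_best(candidates, 2, score_fn)
    if best[1] == 1:
        return True
    best_single = exhaustive_best(candidates, 1, score_fn)
    return best_single[2][0] in best[2]
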