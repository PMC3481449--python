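import numpy as np
import pytest

from entgain import CriterionWeights, ExpressionMatrix, Network, PenaltyConfig, biological_score, penalized_mce, prior_penalty
from entgain.errors import InsufficientDataError, LookupError_
from conftest import random_ternary_matrix
from oracles import mce_bruteforce


def matrix_from_rows(rows: dict[str, list[int]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        list(rows), np.array(list(rows.values()), dtype=int), quantized=True
    )


class TestPenalizedMce:
    def test_deterministic_relation_scores_zero(self):
        # target(t+1) = predictor(t); all 3 predictor states observed
        pred = [-1, 0, 1, -1, 0, 1, -1, 0, 1, -1]
        target = [0] + pred[:-1]
        data = matrix_from_rows({"y": target, "x": pred})
        assert penalized_mce("y", ["x"], data, cfg=PenaltyConfig(alpha=0)) == pytest.approx(0.0)

    def test_uniform_independent_target_tends_to_one(self):
        # target cycles uniformly over {-1,0,1} regardless of the predictor;
        # all predictor states observed, every conditional is uniform
        t = 91  # 90 aligned pairs = 30 complete blocks of 3
        target = [(-1, 0, 1)[i % 3] for i in range(t)]
        pred = [(-1, 0, 1)[(i // 3) % 3] for i in range(t)]
        data = matrix_from_rows({"y": target, "x": pred})
        value = penalized_mce("y", ["x"], data)
        assert value == pytest.approx(1.0, abs=1e-9)

    def test_hand_evaluated_penalized_table(self):
        # k=2 predictors, 9 possible states, 5 observed, alpha=1:
        # states (-1,-1)x3, (-1,0)x2, (0,0)x1, (0,1)x2 are pure;
        # (1,1)x2 splits {+1, 0} -> H = 1/log2(3); N=10, M=4
        # E = (4 + 2/log2 3) / 14 = 0.37584710765...
        p1 = [-1, -1, -1, -1, -1, 0, 0, 0, 1, 1, 0]
        p2 = [-1, -1, -1, 0, 0, 0, 1, 1, 1, 1, 0]
        y = [0, -1, -1, -1, 0, 0, 0, 1, 1, 1, 0]
        data = matrix_from_rows({"y": y, "p1": p1, "p2": p2})
        value = penalized_mce("y", ["p1", "p2"], data)
        assert value == pytest.approx(0.3758471076529, abs=1e-10)
        assert value == pytest.approx(mce_bruteforce("y", ["p1", "p2"], data), abs=1e-12)

    def test_missing_tuples_dropped(self):
        # missing in either predictor or target removes the aligned pair
        data = matrix_from_rows({"y": [0, 1, 3, 1, 0], "x": [1, 3, 0, 1, 1]})
        # surviving pairs: (x@0,y@1)=(1,1), (x@3,y@4)=(1,0)
        value = penalized_mce("y", ["x"], data)
        expected = mce_bruteforce("y", ["x"], data)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_all_missing_raises(self):
        data = matrix_from_rows({"y": [3, 3, 3, 3], "x": [1, 1, 1, 1]})
        with pytest.raises(InsufficientDataError):
            penalized_mce("y", ["x"], data)

    def test_unknown_gene_raises(self):
        data = matrix_from_rows({"y": [0, 1, 0], "x": [1, 0, 1]})
        with pytest.raises(LookupError_):
            penalized_mce("nope", ["x"], data)

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_agrees_with_bruteforce_oracle(self, rng, k, alpha):
        cfg = PenaltyConfig(alpha=alpha)
        for _ in range(20):
            t = int(rng.integers(5, 31))
            data = random_ternary_matrix(rng, k + 2, t, missing_prob=0.1)
            predictors = data.gene_ids[1 : 1 + k]
            try:
                value = penalized_mce("g0", predictors, data, cfg=cfg)
            except InsufficientDataError:
                continue
            expected = mce_bruteforce("g0", predictors, data, alpha=alpha)
            assert value == pytest.approx(expected, abs=1e-12)

    def test_depends_only_on_aligned_pair_multiset(self):
        # swapping two whole aligned pairs leaves the value unchanged
        p = [-1, 0, 1, -1, 1, 0, 0, 1]
        y = [0, 1, 1, -1, 0, 0, 1, -1]
        d1 = matrix_from_rows({"y": y, "x": p})
        # swap aligned pairs (x@0, y@1) and (x@4, y@5): exchange x[0]<->x[4], y[1]<->y[5]
        p2, y2 = p.copy(), y.copy()
        p2[0], p2[4] = p2[4], p2[0]
        y2[1], y2[5] = y2[5], y2[1]
        d2 = matrix_from_rows({"y": y2, "x": p2})
        v1 = penalized_mce("y", ["x"], d1)
        v2 = penalized_mce("y", ["x"], d2)
        assert v1 == pytest.approx(v2, abs=1e-15)


class TestPriorPenalty:
    net = Network.build([("t", "a"), ("t", "b"), ("c", "d")])

    def test_fully_supported(self):
        assert prior_penalty("t", ["a", "b"], self.net) == 0.0

    def test_unsupported(self):
        assert prior_penalty("t", ["c", "d"], self.net) == 1.0

    def test_half_supported_and_order_invariant(self):
        assert prior_penalty("t", ["a", "c"], self.net) == 0.5
        assert prior_penalty("t", ["c", "a"], self.net) == 0.5

    def test_absent_gene_counts_unsupported(self):
        assert prior_penalty("t", ["zzz"], self.net) == 1.0


class TestBiologicalScore:
    def test_linear_combination(self):
        w = CriterionWeights(0.5, 0.5)
        assert biological_score(0.4, 0.8, w) == pytest.approx(0.6)

    def test_endpoints(self):
        assert biological_score(0.37, 0.99, CriterionWeights.from_w2(0.0)) == pytest.approx(0.37)
        assert biological_score(0.37, 0.99, CriterionWeights.from_w2(1.0)) == pytest.approx(0.99)

    def test_monotone_in_each_argument(self, rng):
        w = CriterionWeights(0.3, 0.7)
        for _ in range(50):
            e1, e2, p = rng.random(), rng.random(), rng.random()
            lo, hi = min(e1, e2), max(e1, e2)
            assert biological_score(lo, p, w) <= biological_score(hi, p, w)
            assert biological_score(p, lo, w) <= biological_score(p, hi, w)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            CriterionWeights(0.5, 0.6)
        with pytest.raises(ValueError):
            CriterionWeights(-0.1, 1.1)
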