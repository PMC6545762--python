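"""AUC-weighted rank aggregation and majority voting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ensemblefs import aggregate_ranks, majority_vote, vote_from_selections
from ensemblefs.ensemble import consensus_subset
from ensemblefs.learners import ImportanceRanking, LearnerResult


def make_result(learner, raw_by_var, auc, seed=0):
    variables = list(raw_by_var)
    return LearnerResult(
        learner=learner,
        ranking=ImportanceRanking.from_raw(variables, list(raw_by_var.values())),
        auc=auc,
        cv_folds=10,
        seed=seed,
    )


def results_from_ranks(rank_lists, aucs, variables):
    """Build LearnerResults whose tied-average ranks equal the given lists."""
    out = []
    for name, ranks, auc in zip("abcd", rank_lists, aucs):
        # raw importance p+1-rank reproduces the desired ordering
        raw = {v: len(variables) + 1.0 - r for v, r in zip(variables, ranks)}
        out.append(make_result(name, raw, auc))
    return out


class TestAggregateRanks:
    def test_symmetric_two_model_tie(self):
        res = results_from_ranks([[1, 2], [2, 1]], [0.8, 0.8], ["A", "B"])
        agg = aggregate_ranks(res[:2])
        assert agg.table["aggregated_rank"].tolist() == [1.5, 1.5]

    def test_weighted_mean_matches_bruteforce(self):
        # 20 random instances, up to 10 variables, 4 learners
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.integers(2, 11)
            variables = [f"v{j}" for j in range(p)]
            raws = rng.random((4, p))
            aucs = rng.uniform(0.5, 1.0, 4)
            res = [
                make_result(n, dict(zip(variables, raws[i])), aucs[i])
                for i, n in enumerate(["lasso", "mars", "rf", "bt"])
            ]
            agg = aggregate_ranks(res)
            # independent brute force: tied ranks by sorting, weighted mean
            from scipy.stats import rankdata

            w = aucs / aucs.sum()
            expect = {}
            for j, v in enumerate(variables):
                rs = [rankdata(-raws[i])[j] for i in range(4)]
                expect[v] = float(np.dot(w, rs))
            got = dict(zip(agg.table["variable"], agg.table["aggregated_rank"]))
            for v in variables:
                assert got[v] == pytest.approx(expect[v], abs=1e-12)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        variables = list("uvwxyz")
        res = [
            make_result(n, dict(zip(variables, rng.random(6))), a)
            for n, a in zip(["lasso", "mars", "rf", "bt"], [0.7, 0.8, 0.75, 0.85])
        ]
        base = aggregate_ranks(res).table
        for perm in itertools.permutations(res):
            other = aggregate_ranks(list(perm)).table
            np.testing.assert_allclose(
                base["aggregated_rank"], other["aggregated_rank"], atol=1e-12
            )

    def test_identical_rankings_independent_of_weights(self):
        variables = list("pqr")
        raw = {"p": 3.0, "q": 2.0, "r": 1.0}
        res = [make_result(n, raw, a) for n, a in zip("abcd", [0.51, 0.7, 0.9, 0.99])]
        agg = aggregate_ranks(res)
        assert agg.table["variable"].tolist() == ["p", "q", "r"]
        np.testing.assert_allclose(agg.table["aggregated_rank"], [1, 2, 3])

    def test_auc_scaling_leaves_ranks_unchanged(self):
        rng = np.random.default_rng(2)
        variables = list("lmnop")
        raws = [dict(zip(variables, rng.random(5))) for _ in range(4)]
        r1 = [make_result(n, raws[i], a) for i, (n, a) in enumerate(zip("abcd", [0.6, 0.7, 0.8, 0.9]))]
        r2 = [make_result(n, raws[i], a / 2) for i, (n, a) in enumerate(zip("abcd", [0.6, 0.7, 0.8, 0.9]))]
        np.testing.assert_allclose(
            aggregate_ranks(r1).table["aggregated_rank"],
            aggregate_ranks(r2).table["aggregated_rank"],
            atol=1e-12,
        )

    def test_weights_sum_to_one(self):
        res = results_from_ranks([[1, 2], [2, 1], [1, 2], [2, 1]], [0.6, 0.7, 0.8, 0.9], ["A", "B"])
        agg = aggregate_ranks(res)
        assert sum(agg.model_weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_variables_rejected(self):
        r1 = make_result("a", {"x": 1.0, "y": 0.5}, 0.8)
        r2 = make_result("b", {"x": 1.0, "z": 0.5}, 0.8)
        with pytest.raises(ValueError, match="y.*z|z.*y"):
            aggregate_ranks([r1, r2])

    def test_nonpositive_auc_rejected(self):
        res = results_from_ranks([[1, 2], [2, 1]], [0.8, 0.8], ["A", "B"])
        res[0].auc = 0.0
        with pytest.raises(ValueError, match="AUC"):
            aggregate_ranks(res)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_aggregated_rank_bounded_by_per_model_ranks(self, seed):
        rng = np.random.default_rng(seed)
        variables = [f"v{j}" for j in range(6)]
        res = [
            make_result(n, dict(zip(variables, rng.random(6))), rng.uniform(0.5, 1))
            for n in ["lasso", "mars", "rf", "bt"]
        ]
        agg = aggregate_ranks(res)
        ranks = np.array([[r.ranking.rank_of()[v] for v in agg.table["variable"]] for r in res])
        lo, hi = ranks.min(axis=0), ranks.max(axis=0)
        mid = agg.table["aggregated_rank"].to_numpy()
        assert ((lo - 1e-9 <= mid) & (mid <= hi + 1e-9)).all()


class TestMajorityVote:
    def test_unanimous_single_variable(self):
        variables = ["X", "Y"]
        res = [make_result(n, {"X": 1.0, "Y": 0.05}, 0.8) for n in "abcd"]
        counts, winners = majority_vote(res)
        assert counts == {"X": 4, "Y": 0}
        assert winners == {"X"}

    def test_min_votes_guard(self):
        res = [make_result(n, {"X": 1.0}, 0.8) for n in "ab"]
        with pytest.raises(ValueError, match="min_votes"):
            majority_vote(res, min_votes=3)

    def test_vote_from_plain_lists(self):
        sels = {"a": ["x", "y"], "b": ["y"], "c": ["y", "z"], "d": ["x", "y"]}
        counts, winners = vote_from_selections(sels, ["x", "y", "z"])
        assert counts == {"x": 2, "y": 4, "z": 1}
        assert winners == {"y"}


class TestConsensusSubset:
    def test_ordered_by_aggregated_rank(self):
        variables = ["A", "B", "C", "D"]
        res = [
            make_result(n, {"A": 4.0, "B": 3.0, "C": 2.0, "D": 0.01}, 0.8)
            for n in ["lasso", "mars", "rf", "bt"]
        ]
        agg = aggregate_ranks(res)
        assert consensus_subset(agg) == ["A", "B", "C"]

    def test_empty_when_nothing_selected(self):
        res = [make_result(n, {"A": 0.0, "B": 0.0}, 0.8) for n in "abcd"]
        agg = aggregate_ranks(res)
        assert consensus_subset(agg) == []
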