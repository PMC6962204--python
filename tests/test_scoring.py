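"""Pscore, decoys, ROC/AUC, FDR cutoffs, model selection, consensus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fucotype.scoring import (
    ModelPerformance,
    PscoreRecord,
    consensus,
    evaluate,
    fdr_cutoff,
    make_decoys,
    pscore,
    pscores,
    roc_auc,
    select_best_model,
)


def brute_force_auc(targets, decoys):
    """All-pairs Mann-Whitney statistic, ties counted one half."""
    wins = sum(1.0 if t > d else 0.5 if t == d else 0.0
               for t in targets for d in decoys)
    return wins / (len(targets) * len(decoys))


def brute_force_fdr_cutoff(targets, decoys, q):
    """Exhaustive search over observed target scores (smallest passing)."""
    best = None
    for thr in sorted(targets):
        n_t = sum(t >= thr for t in targets)
        n_d = sum(d >= thr for d in decoys)
        if n_d / max(1, n_t) < q:
            best = (thr, n_t)
            break
    return best if best is not None else (math.inf, 0)


class TestPscore:
    def test_zero_margin_gives_zero(self):
        assert pscore(np.array([0.5, 0.5, 0.0, 0.0])) == 0.0

    def test_direct_value(self):
        assert pscore(np.array([0.9, 0.1, 0.0, 0.0])) == pytest.approx(
            -math.log(0.2), abs=1e-9)

    def test_clamp_at_unit_margin(self):
        assert pscore(np.array([1.0, 0.0, 0.0, 0.0])) == pytest.approx(
            -math.log(1e-12))

    @given(gaps=st.lists(st.floats(1e-9, 1.0 - 1e-12), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_probability_gap(self, gaps):
        gaps = sorted({round(g, 6) for g in gaps})  # resolvable spacing
        scores = [pscore(np.array([0.5 + g / 2, 0.5 - g / 2, 0.0, 0.0]))
                  for g in gaps]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_vectorised_matches_scalar(self, rng):
        P = rng.dirichlet(np.ones(4), size=50)
        np.testing.assert_allclose(pscores(P), [pscore(p) for p in P], atol=1e-12)


class TestMakeDecoys:
    @given(X=arrays(float, (20, 14), elements=st.floats(0, 1)))
    @settings(max_examples=50, deadline=None)
    def test_multiset_conserved_per_vector(self, X):
        for decoy_set in make_decoys(X, n_repeats=3, seed=9):
            np.testing.assert_allclose(np.sort(decoy_set, axis=1),
                                       np.sort(X, axis=1))

    def test_seeded_and_reproducible(self, rng):
        X = rng.random((30, 14))
        a = make_decoys(X, 5, seed=3)
        b = make_decoys(X, 5, seed=3)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da, db)

    def test_replicates_differ_for_generic_input(self, rng):
        X = rng.random((30, 14))
        d1, d2 = make_decoys(X, 2, seed=3)
        assert not np.array_equal(d1, d2)

    def test_constant_vector_is_fixed_point(self):
        X = np.full((3, 14), 0.7)
        for d in make_decoys(X, 2, seed=0):
            np.testing.assert_array_equal(d, X)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4], [1, 2]).auc == 1.0

    def test_identical_lists_give_half(self):
        assert roc_auc([1, 2, 3], [1, 2, 3]).auc == pytest.approx(0.5)

    def test_small_mixed_instance(self):
        assert roc_auc([2, 0], [1]).auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self, rng):
        r = roc_auc(rng.normal(1, 1, 50), rng.normal(0, 1, 50))
        curve = np.array(r.curve)
        assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            nt, nd = rng.integers(1, 50, size=2)
            t = np.round(rng.normal(1, 1, nt), 1)  # rounding forces ties
            d = np.round(rng.normal(0, 1, nd), 1)
            assert roc_auc(t, d).auc == pytest.approx(
                brute_force_auc(t, d), abs=1e-9)


class TestFdrCutoff:
    @pytest.mark.parametrize(
        "targets, decoys, q, expected",
        [
            ([5, 4, 3, 2], [1, 0.5, 0.2, 0.1], 0.01, (2.0, 4)),
            ([1, 1], [5, 5], 0.01, (math.inf, 0)),
            ([10], [1], 0.01, (10.0, 1)),
        ],
    )
    def test_examples(self, targets, decoys, q, expected):
        assert fdr_cutoff(targets, decoys, q) == expected

    def test_matches_exhaustive_search_on_random_instances(self, rng):
        for _ in range(200):
            nt, nd = rng.integers(1, 40, size=2)
            t = np.round(rng.normal(1, 1, nt), 1)
            d = np.round(rng.normal(0, 1, nd), 1)
            q = float(rng.choice([0.01, 0.05, 0.3]))
            assert fdr_cutoff(t, d, q) == brute_force_fdr_cutoff(t, d, q)

    def test_filtered_count_monotone_in_q(self, rng):
        t = rng.normal(1, 1, 100)
        d = rng.normal(0, 1, 100)
        counts = [fdr_cutoff(t, d, q)[1] for q in (0.01, 0.05, 0.2, 0.5)]
        assert counts == sorted(counts)

    def test_permissive_q_admits_all_targets(self, rng):
        t = rng.normal(3, 1, 50)
        d = rng.normal(0, 1, 50)
        cutoff, n = fdr_cutoff(t, d, q=0.999)
        assert cutoff == t.min() and n == 50

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            fdr_cutoff([], [1.0], 0.01)


class TestModelSelection:
    def test_euclidean_length_examples(self):
        assert ModelPerformance(1.0, 1.0, 0, 0).euclidean_length == pytest.approx(
            math.sqrt(2))
        assert ModelPerformance(0.6, 0.8, 0, 0).euclidean_length == pytest.approx(1.0)

    def test_argmax_with_tie_to_lowest_index(self):
        perfs = [ModelPerformance(0.6, 0.8, 0, 0),
                 ModelPerformance(0.8, 0.9, 0, 0),
                 ModelPerformance(0.9, 0.8, 0, 0)]
        assert select_best_model(perfs) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([])


def rec(gsm, cls, score):
    return PscoreRecord(gsm=gsm, predicted_class=cls, pscore=score)


class TestConsensus:
    def test_agreeing_passing_gsm_kept(self):
        out = consensus([rec("a", "core", 5.0)], [rec("a", "core", 5.0)], 1.0, 1.0)
        assert out == [("a", "core")]

    def test_disagreeing_models_excluded(self):
        out = consensus([rec("a", "core", 5.0)], [rec("a", "outer", 5.0)], 1.0, 1.0)
        assert out == []

    def test_union_rule_needs_one_passing_filter(self):
        out = consensus([rec("a", "core", 0.5)], [rec("a", "core", 5.0)],
                        1.0, 1.0, rule="union")
        assert out == [("a", "core")]

    def test_intersection_rule_needs_both(self):
        out = consensus([rec("a", "core", 0.5)], [rec("a", "core", 5.0)],
                        1.0, 1.0, rule="intersection")
        assert out == []

    def test_symmetric_in_model_order(self, rng):
        gsms = [f"g{i}" for i in range(30)]
        a = [rec(g, rng.choice(["none", "core"]), float(rng.random() * 5))
             for g in gsms]
        b = [rec(g, rng.choice(["none", "core"]), float(rng.random() * 5))
             for g in gsms]
        assert sorted(consensus(a, b, 1.0, 2.0)) == sorted(consensus(b, a, 2.0, 1.0))

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="aligned|same GSM"):
            consensus([rec("a", "core", 1.0)], [rec("b", "core", 1.0)], 0, 0)

    def test_empty_inputs_give_empty_output(self):
        assert consensus([], [], 0.0, 0.0) == []


class TestEvaluate:
    def test_all_correct(self):
        acc, sens, conf = evaluate(["core", "none"], ["core", "none"])
        assert acc == 1.0 and sens == 1.0

    def test_three_of_four(self):
        acc, sens, conf = evaluate(["core", "none", "outer", "dual"],
                                   ["core", "none", "outer", "none"])
        assert acc == 0.75

    def test_unclassified_hits_accuracy_not_sensitivity(self):
        acc, sens, conf = evaluate(["core", None], ["core", "none"])
        assert acc == 0.5 and sens == 1.0

    def test_confusion_row_sums_match_manual_counts(self):
        manual = ["core"] * 3 + ["outer"] * 2
        predicted = ["core", "core", "outer", "outer", "none"]
        _, _, conf = evaluate(predicted, manual)
        assert conf.sum() == 5
        assert conf[1].sum() == 3 and conf[2].sum() == 2  # rows = manual

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["core"], ["core", "none"])
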