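"""Discrimination and calibration metrics: examples, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from docsvm import (
    ScoredPredictions,
    SingleClassError,
    auc_mann_whitney,
    auc_trapezoidal,
    brier_decomposition,
    brier_score,
    compare_auc_z,
    hinge_rank_bound,
    hosmer_lemeshow,
    refinement_auc_bound,
    reliability_bins,
    roc_curve,
    threshold_metrics,
)

from conftest import brute_force_auc


def preds(scores, labels):
    return ScoredPredictions(scores=np.asarray(scores), labels=np.asarray(labels))


# ---------------------------------------------------------------- ScoredPredictions

class TestScoredPredictions:
    def test_rejects_length_mismatch_and_bad_labels(self):
        with pytest.raises(ValueError, match="length mismatch"):
            preds([0.1, 0.2], [1])
        with pytest.raises(ValueError, match="0/1"):
            preds([0.1, 0.2], [1, 2])
        with pytest.raises(ValueError):
            preds([], [])

    def test_calibration_metrics_enforce_probability_scale(self):
        p = preds([1.5, 0.2], [1, 0])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            brier_score(p)


# ---------------------------------------------------------------------------- AUC

class TestAUC:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),  # all positives rank higher
            ([0.3, 0.7], [1, 0], 0.0),  # no positive outranks a negative
            ([0.5, 0.5], [1, 0], 0.5),  # single tied pair counts one half
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auc_mann_whitney(preds(scores, labels)) == expected

    def test_single_class_is_explicit_error(self):
        with pytest.raises(SingleClassError, match="AUC undefined"):
            auc_mann_whitney(preds([0.1, 0.2], [1, 1]))

    def test_matches_pair_counting_oracle(self, random_preds_factory):
        for _ in range(200):
            p = random_preds_factory(n=15, discretize=True)
            assert auc_mann_whitney(p) == pytest.approx(
                brute_force_auc(p.scores, p.labels), abs=1e-12
            )

    def test_invariant_under_score_shrinkage(self, random_preds_factory):
        # a classifier reporting scores ten times lower has the identical AUC
        for _ in range(50):
            p = random_preds_factory(n=30)
            shrunk = ScoredPredictions(scores=p.scores / 10.0, labels=p.labels)
            assert auc_mann_whitney(p) == pytest.approx(auc_mann_whitney(shrunk), abs=1e-15)

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        g = np.random.default_rng(seed)
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        scores = g.random(10)
        p = preds(scores, labels)
        q = preds(np.expm1(3 * scores) / np.expm1(3), labels)
        assert auc_mann_whitney(p) == pytest.approx(auc_mann_whitney(q), abs=1e-12)


# ---------------------------------------------------------------------------- ROC

class TestROC:
    def test_two_point_perfect_curve(self):
        c = roc_curve(preds([0.9, 0.1], [1, 0]))
        assert np.array_equal(np.c_[c.fpr, c.tpr], [[0, 0], [0, 1], [1, 1]])

    def test_all_tied_scores_collapse_to_diagonal(self):
        c = roc_curve(preds([0.4, 0.4, 0.4], [1, 0, 1]))
        assert np.array_equal(np.c_[c.fpr, c.tpr], [[0, 0], [1, 1]])

    def test_against_exhaustive_threshold_enumeration(self):
        p = preds([0.8, 0.6, 0.4], [1, 0, 1])
        c = roc_curve(p)
        # every (fpr, tpr) reachable by thresholding must be on the curve
        for t in np.unique(p.scores):
            tpr = np.mean(p.scores[p.labels == 1] >= t)
            fpr = np.mean(p.scores[p.labels == 0] >= t)
            pts = set(zip(c.fpr.tolist(), c.tpr.tolist()))
            assert (fpr, tpr) in pts

    def test_single_class_error(self):
        with pytest.raises(SingleClassError, match="ROC undefined"):
            roc_curve(preds([0.1, 0.2], [0, 0]))

    def test_trapezoid_equals_mann_whitney(self, random_preds_factory):
        # the trapezoidal area and the rank form agree to machine precision,
        # including over tie-induced diagonal steps
        for _ in range(300):
            p = random_preds_factory(n=20, discretize=True)
            assert auc_trapezoidal(roc_curve(p)) == pytest.approx(
                auc_mann_whitney(p), abs=1e-12
            )

    def test_agrees_with_sklearn(self, random_preds_factory):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            p = random_preds_factory(n=25)
            assert auc_mann_whitney(p) == pytest.approx(
                roc_auc_score(p.labels, p.scores), abs=1e-12
            )


# -------------------------------------------------------------------------- Brier

class TestBrier:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1.0, 0.0, 1.0], [1, 0, 1], 0.0),
            ([0.5, 0.5], [1, 0], 0.25),
            ([1.0, 0.0], [0, 1], 1.0),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert brier_score(preds(scores, labels)) == pytest.approx(expected)

    def test_decomposition_hand_example(self):
        # groups: s=0.2 (n=2, rho=1/2), s=0.8 (n=2, rho=1)
        dec = brier_decomposition(preds([0.2, 0.2, 0.8, 0.8], [0, 1, 1, 1]))
        assert dec.cal == pytest.approx(0.065, abs=1e-12)
        assert dec.ref == pytest.approx(0.125, abs=1e-12)
        assert dec.brier == pytest.approx(0.19, abs=1e-12)
        assert dec.brier == pytest.approx(0.76 / 4, abs=1e-12)

    def test_dichotomous_correct_predictions_have_zero_components(self):
        dec = brier_decomposition(preds([1.0, 0.0], [1, 0]))
        assert dec.cal == 0.0 and dec.ref == 0.0

    def test_uninformative_half_scores(self):
        dec = brier_decomposition(preds([0.5] * 4, [1, 0, 1, 0]))
        assert dec.cal == 0.0
        assert dec.ref == pytest.approx(0.25)

    def test_identity_cal_plus_ref_is_brier(self, random_preds_factory):
        for _ in range(300):
            p = random_preds_factory(n=25, discretize=True)
            dec = brier_decomposition(p)
            assert dec.cal + dec.ref == pytest.approx(brier_score(p), abs=1e-12)
            assert 0.0 <= dec.ref <= 0.25 + 1e-15
            assert dec.groups[:, 1].sum() == p.n

    def test_ref_zero_iff_groups_pure(self, random_preds_factory):
        for _ in range(100):
            p = random_preds_factory(n=12, discretize=True)
            dec = brier_decomposition(p)
            pure = all(rho in (0.0, 1.0) for rho in dec.groups[:, 2])
            assert (dec.ref == 0.0) == pure


# ----------------------------------------------------------------- Hosmer-Lemeshow

class TestHosmerLemeshow:
    def test_perfectly_grouped_calibrated_bin_contributes_zero(self):
        hl = hosmer_lemeshow(preds([0.25] * 4, [1, 0, 0, 0]), scheme="H")
        assert hl.statistic == 0.0

    def test_two_occupied_deciles_hand_value(self):
        # (0-0.1)/(0.1-0.9) degenerate example: each bin (O-E)^2/(E(1-E/n)) = 0.01/0.09
        hl = hosmer_lemeshow(preds([0.1, 0.9], [0, 1]), scheme="H")
        assert hl.statistic == pytest.approx(2 * 0.01 / 0.09, abs=1e-12)
        assert np.isnan(hl.p_value)  # fewer than 3 retained bins: no df left

    def test_critical_value_at_ten_bins(self):
        # the 0.1-level critical value with 8 df is 13.36
        assert stats.chi2.sf(13.36, 8) == pytest.approx(0.1, abs=5e-4)

    def test_order_invariance(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < scores).astype(int)
        perm = rng.permutation(200)
        a = hosmer_lemeshow(preds(scores, labels), scheme="C")
        b = hosmer_lemeshow(preds(scores[perm], labels[perm]), scheme="C")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
        assert a.g == b.g

    def test_equal_count_with_g_equal_n_gives_singleton_bins(self, rng):
        scores = np.sort(rng.random(12))  # distinct with prob 1
        labels = rng.integers(0, 2, 12)
        hl = hosmer_lemeshow(preds(scores, labels), scheme="C", g=12)
        assert (hl.bins[:, 1] == 1).all()

    def test_bin_counts_partition_sample(self, rng):
        scores = rng.random(100)
        labels = (rng.random(100) < scores).astype(int)
        for scheme in ("H", "C"):
            hl = hosmer_lemeshow(preds(scores, labels), scheme=scheme)
            assert hl.bins[:, 1].sum() == 100
            assert (hl.bins[:, 0] <= hl.bins[:, 1]).all()
            assert hl.df == hl.g - 2

    def test_degenerate_bins_merge_toward_center(self):
        # scores of 0 with a positive outcome make E=0 with nonzero numerator
        p = preds([0.0, 0.0, 0.5, 0.5, 0.5, 0.95, 0.95], [1, 0, 1, 0, 1, 1, 1])
        hl = hosmer_lemeshow(p, scheme="H")
        assert np.isfinite(hl.statistic)
        assert hl.bins[:, 1].sum() == 7

    def test_requested_g_below_three_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            hosmer_lemeshow(preds([0.1, 0.9], [0, 1]), scheme="H", g=2)

    def test_all_degenerate_errors(self):
        with pytest.raises(ValueError, match="HL undefined"):
            hosmer_lemeshow(preds([0.0] * 5, [1, 1, 1, 1, 1]), scheme="H")


# -------------------------------------------------------------- reliability bins

class TestReliabilityBins:
    def test_constant_predictions_occupy_one_bin(self):
        rb = reliability_bins(preds([0.55] * 7, [1, 0, 0, 1, 0, 0, 0]))
        assert (rb.counts > 0).sum() == 1
        assert rb.counts.sum() == 7

    def test_dichotomous_perfect_predictions(self):
        rb = reliability_bins(preds([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1]))
        assert np.array_equal(rb.obs_frac, [0.0, 1.0])
        assert np.array_equal(rb.mean_pred, [0.0, 1.0])

    def test_mean_pred_within_bin_edges(self, rng):
        scores = rng.random(500)
        labels = (rng.random(500) < scores).astype(int)
        rb = reliability_bins(preds(scores, labels))
        j = 0
        for i in range(10):
            if rb.counts[i] > 0:
                assert rb.edges[i] <= rb.mean_pred[j] <= rb.edges[i + 1]
                j += 1


# ------------------------------------------------------------------------ bounds

class TestBounds:
    def test_refinement_bound_tight_cases(self):
        assert refinement_auc_bound(preds([1.0, 0.0], [1, 0])) == 1.0
        # all-0.5 balanced: N^2/(2 N+ N-) = 2, REF = 0.25 -> bound 0.5 = AUC
        p = preds([0.5] * 4, [1, 0, 1, 0])
        assert refinement_auc_bound(p) == pytest.approx(0.5)
        assert auc_mann_whitney(p) == 0.5

    def test_refinement_bound_below_auc_on_concordant_groupings(self, rng):
        # grouped scores ordered concordantly with their positive rates
        for _ in range(1000):
            k = rng.integers(2, 5)
            values = np.sort(rng.random(k))
            sizes = rng.integers(1, 6, size=k)
            npos = rng.integers(0, sizes + 1)
            # concordant between-group ordering: assign ascending score values
            # to groups sorted by their realized positive fraction
            order = np.argsort(npos / sizes, kind="stable")
            scores, labels = [], []
            for v, m, o in zip(values, sizes[order], npos[order]):
                scores += [v] * int(m)
                labels += [1] * int(o) + [0] * int(m - o)
            p_arr, l_arr = np.asarray(scores), np.asarray(labels)
            if l_arr.sum() in (0, l_arr.size):
                continue
            p = preds(p_arr, l_arr)
            assert refinement_auc_bound(p) <= brute_force_auc(p_arr, l_arr) + 1e-9

    def test_hinge_bound_examples(self):
        # margins beyond 1 on both sides: zero hinge, perfect ranking
        assert hinge_rank_bound([2.0, -2.0], [1, 0]) == 0.0
        # all-zero scores: unit hinge everywhere, bound 4 covers rank loss 1/2
        b = hinge_rank_bound(np.zeros(4), [1, 0, 1, 0])
        assert b == pytest.approx(4.0)
        assert b >= 0.5

    def test_hinge_bound_dominates_rank_loss(self, rng):
        for _ in range(1000):
            n = rng.integers(4, 20)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.normal(scale=2.0, size=n)
            bound = hinge_rank_bound(scores, labels)
            rank_loss = 1.0 - brute_force_auc(scores, labels)
            assert bound >= rank_loss - 1e-12

    def test_single_class_errors(self):
        with pytest.raises(SingleClassError):
            refinement_auc_bound(preds([0.5, 0.6], [1, 1]))
        with pytest.raises(SingleClassError):
            hinge_rank_bound([0.5, 0.6], [0, 0])


# -------------------------------------------------------------- threshold metrics

class TestThresholdMetrics:
    def test_perfect_dichotomous(self):
        tm = threshold_metrics(preds([1.0, 1.0, 0.0], [1, 1, 0]))
        assert (tm.sensitivity, tm.specificity, tm.f_score) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        tm = threshold_metrics(preds([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]))
        assert tm.sensitivity == 1.0 and tm.specificity == 0.0

    def test_hand_counted_confusion(self):
        tm = threshold_metrics(preds([0.6, 0.4, 0.7, 0.2], [1, 1, 0, 0]))
        assert (tm.tp, tm.fn, tm.fp, tm.tn) == (1, 1, 1, 1)
        assert tm.f_score == pytest.approx(0.5)

    def test_f_undefined_flagged(self):
        with pytest.warns(UserWarning, match="F-score undefined"):
            tm = threshold_metrics(preds([0.1, 0.2], [0, 0]), threshold=0.5)
        assert tm.f_score == 0.0 and tm.f_undefined


# ------------------------------------------------------------------ AUC comparison

class TestCompareAUC:
    def test_identical_scores_give_null_result(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = preds(scores, labels)
        res = compare_auc_z(a, preds(scores.copy(), labels))
        assert res.z == 0.0 and res.p_value == 1.0

    def test_monotone_transform_gives_null_result(self, rng):
        scores = rng.random(30)
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        res = compare_auc_z(preds(scores, labels), preds(scores**3, labels))
        assert res.z == 0.0 and res.p_value == 1.0

    def test_mismatched_labels_error(self):
        a = preds([0.1, 0.9], [0, 1])
        b = preds([0.1, 0.9], [1, 0])
        with pytest.raises(ValueError, match="same labels"):
            compare_auc_z(a, b)

    def test_z_against_bootstrap_oracle(self, rng):
        # fixed moderately-sized instance; paired bootstrap of the AUC
        # difference as the independent variance estimate
        n = 60
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        strength = np.where(labels == 1, 0.8, 0.0)
        sa = rng.random(n) * 0.6 + strength * 0.4
        sb = np.clip(sa + rng.normal(0, 0.25, n), 0, 2)
        res = compare_auc_z(preds(sa, labels), preds(sb, labels))
        diffs = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            if labels[idx].sum() in (0, n):
                continue
            diffs.append(
                brute_force_auc(sa[idx], labels[idx]) - brute_force_auc(sb[idx], labels[idx])
            )
        z_boot = (res.auc_a - res.auc_b) / np.std(diffs, ddof=1)
        assert res.z == pytest.approx(z_boot, abs=0.35)
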