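import numpy as np
import pytest

from citscore import (
    D_BIN_EDGES,
    P_BIN_EDGES,
    INCONCLUSIVE,
    RECOGNIZED,
    UNRECOGNIZED,
    InsufficientDataError,
    Judgment,
    SessionTruth,
    binned_recognition_ratios,
    cohort_rates,
    roc_auc,
    searching_error_decomposition,
)


def J(label, item=None):
    return Judgment(label=label, basis="test", identified_item=item)


def mann_whitney_auc(scores, labels):
    """Independent pair-counting oracle: concordant pairs + half ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total


class TestCohortRates:
    def test_all_recognized_all_recognizing(self):
        r = cohort_rates([J(RECOGNIZED)] * 4, [True] * 4)
        assert (r.inconclusive_rate, r.hit_rate) == (0.0, 100.0)
        assert r.correct_rejection_rate is None  # no unrecognizing cases

    def test_direct_counting(self):
        judgments = [J(RECOGNIZED), J(INCONCLUSIVE), J(UNRECOGNIZED), J(UNRECOGNIZED)]
        truth = [True, True, False, False]
        r = cohort_rates(judgments, truth)
        assert r.inconclusive_rate == 25.0
        assert r.hit_rate == 100.0
        assert r.correct_rejection_rate == 100.0

    def test_all_inconclusive_rates_undefined(self):
        r = cohort_rates([J(INCONCLUSIVE)] * 3, [True, False, True])
        assert r.inconclusive_rate == 100.0
        assert r.hit_rate is None and r.correct_rejection_rate is None

    def test_counts_partition_total(self):
        judgments = [J(RECOGNIZED), J(INCONCLUSIVE), J(UNRECOGNIZED), J(RECOGNIZED)]
        truth = [True, False, False, False]
        r = cohort_rates(judgments, truth)
        n_inconclusive = round(r.inconclusive_rate / 100 * r.n_total)
        assert (
            r.n_conclusive_recognizing + r.n_conclusive_unrecognizing + n_inconclusive
            == r.n_total
        )

    def test_accepts_session_truth_records(self):
        truth = [SessionTruth("a", True, 0), SessionTruth("b", False, None)]
        r = cohort_rates([J(RECOGNIZED), J(UNRECOGNIZED)], truth)
        assert r.hit_rate == 100.0 and r.correct_rejection_rate == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohort_rates([J(RECOGNIZED)], [True, False])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_identical_scores_tie_average(self):
        assert roc_auc([1, 1, 1, 1], [True, False, True, False]) == 0.5

    def test_hand_enumerated_value(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.1], [True, False, True, False]) == 0.75

    def test_p_type_scores_negated(self):
        # small p means recognizing: perfectly separated
        assert roc_auc(
            [0.01, 0.02, 0.8, 0.9], [True, True, False, False],
            higher_means_recognizing=False,
        ) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_auc([1, 2], [True, True])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse -> ties occur
            assert roc_auc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )


class TestBinnedRatios:
    def test_everything_in_one_bin(self):
        df = binned_recognition_ratios([0.5, 0.45, 0.55], [True, True, False])
        row = df[(df.bin_low == 0.4)].iloc[0]
        assert row.share_of_all == 100.0
        assert df.share_of_all.sum() == pytest.approx(100.0)

    def test_conditional_shares(self):
        scores = [0.5, 0.5, 0.5, 0.5, -0.5]
        truth = [True, True, True, False, False]
        df = binned_recognition_ratios(scores, truth)
        row = df[df.bin_low == 0.4].iloc[0]
        assert row.share_recognizing == 75.0
        assert row.share_unrecognizing == 25.0

    def test_empty_bins_undefined(self):
        df = binned_recognition_ratios([0.5], [True])
        empty = df[df.n == 0]
        assert empty.share_recognizing.isna().all()
        assert (empty.share_of_all == 0).all()

    def test_printed_bin_edges(self):
        assert list(D_BIN_EDGES) == [-np.inf, -0.2, 0.0, 0.2, 0.4, 0.6, np.inf]
        assert list(P_BIN_EDGES) == [0.0, 0.025, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0]

    def test_left_closed_right_open_and_top_bin_closure(self):
        df = binned_recognition_ratios(
            [0.025, 1.0, 0.8], [True, False, False], P_BIN_EDGES
        )
        assert df[df.bin_low == 0.025].iloc[0].n == 1  # boundary goes right bin
        assert df[df.bin_low == 0.8].iloc[0].n == 2  # p=1 counted in top bin


class TestSearchingDecomposition:
    def test_error_taxonomy(self):
        truth = [
            SessionTruth("a", True, 2),
            SessionTruth("b", True, 2),
            SessionTruth("c", False, None),
            SessionTruth("d", False, None),
            SessionTruth("e", True, 1),
            SessionTruth("f", False, None),
        ]
        judgments = [
            J(RECOGNIZED, 2),     # hit: right item
            J(RECOGNIZED, 0),     # type-1 FP: recognizing, wrong item
            J(RECOGNIZED, 3),     # type-2 FP: unrecognizing judged recognized
            J(UNRECOGNIZED),      # correct rejection
            J(UNRECOGNIZED),      # miss
            J(INCONCLUSIVE),
        ]
        dec = searching_error_decomposition(judgments, truth)
        assert dec.hits == 1
        assert dec.type1_false_positives == 1
        assert dec.type2_false_positives == 1
        assert dec.correct_rejections == 1
        assert dec.misses == 1
        assert dec.inconclusives == 1
        assert sum(dec.rates.values()) == pytest.approx(100.0)

    def test_counts_sum_to_total(self):
        truth = [SessionTruth(str(i), i % 2 == 0, 0 if i % 2 == 0 else None)
                 for i in range(10)]
        judgments = [J(RECOGNIZED, 0) if i < 5 else J(INCONCLUSIVE) for i in range(10)]
        dec = searching_error_decomposition(judgments, truth)
        total = (dec.hits + dec.type1_false_positives + dec.type2_false_positives
                 + dec.misses + dec.correct_rejections + dec.inconclusives)
        assert total == dec.n_total == 10
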