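"""Sequence-level metrics: SeqAcc, exact-match SeqAcc, SeqIoU, reports, ROC AUC."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octseq import (
    Label,
    Sequence,
    binarize,
    binary_report,
    exact_match_seq_acc,
    multilabel_report,
    roc_auc,
    scan_iou,
    seq_acc,
    seq_acc_label,
    seq_iou,
)
from octseq.records import LABEL_ORDER

from conftest import make_sequence

ALL = [l.value for l in LABEL_ORDER]


def perfect_preds(sequences):
    """Degenerate probabilities: 1 for present labels, 0 for absent."""
    preds = {}
    for seq in sequences:
        for s in seq.scans:
            preds[s.key] = {l: (1.0 if l in s.labels else 0.0) for l in LABEL_ORDER}
    return preds


def preds_from_sets(sequences, sets):
    """Build probabilities 0.9/0.1 from listed predicted label-name sets."""
    preds = {}
    i = 0
    for seq in sequences:
        for s in seq.scans:
            names = sets[i]
            preds[s.key] = {
                l: (0.9 if l.value in names else 0.1) for l in LABEL_ORDER
            }
            i += 1
    return preds


# ---------------------------------------------------------------- oracles


def naive_seq_acc(sequences, preds, label, threshold=0.5):
    per_seq = []
    for seq in sequences:
        correct = 0
        for s in seq.scans:
            pred = preds[s.key][label] >= threshold
            correct += pred == (label in s.labels)
        per_seq.append(correct / len(seq.scans))
    return sum(per_seq) / len(per_seq)


def naive_exact_match(sequences, preds, threshold=0.5):
    per_seq = []
    for seq in sequences:
        correct = 0
        for s in seq.scans:
            pred_set = {l for l in LABEL_ORDER if preds[s.key][l] >= threshold}
            correct += pred_set == set(s.labels)
        per_seq.append(correct / len(seq.scans))
    return sum(per_seq) / len(per_seq)


def naive_seq_iou(sequences, preds, threshold=0.5):
    per_seq = []
    for seq in sequences:
        total = 0.0
        for s in seq.scans:
            pred_set = {l for l in LABEL_ORDER if preds[s.key][l] >= threshold}
            truth = set(s.labels)
            union = truth | pred_set
            total += len(truth & pred_set) / len(union) if union else 1.0
        per_seq.append(total / len(seq.scans))
    return sum(per_seq) / len(per_seq)


def pairwise_auc(scores, truths):
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def random_micro_dataset(rng):
    """<=5 sequences of <=6 scans with random truths and probabilities."""
    sequences = []
    preds = {}
    combos = [
        ("HEALTHY",), ("DME", "HF"), ("DME", "HF", "ND"), ("DME", "ND"), ("HF",),
        ("ND", "HF"),
    ]
    for i in range(rng.randint(1, 5)):
        truths = [combos[rng.randrange(len(combos))] for _ in range(rng.randint(1, 6))]
        seq = make_sequence(truths, pid=f"P{i}", seq=f"v{i}")
        sequences.append(seq)
        for s in seq.scans:
            preds[s.key] = {l: rng.random() for l in LABEL_ORDER}
    return sequences, preds


# ---------------------------------------------------------------- binarize


class TestBinarize:
    def test_rule_application(self):
        probs = {Label.DME: 0.9, Label.ND: 0.2, Label.HF: 0.6, Label.HEALTHY: 0.1}
        assert binarize(probs, 0.5) == {Label.DME, Label.HF}

    def test_all_below_threshold_gives_empty_set(self):
        probs = {l: 0.1 for l in LABEL_ORDER}
        assert binarize(probs, 0.5) == frozenset()

    def test_probability_at_threshold_counts_as_present(self):
        assert Label.DME in binarize({Label.DME: 0.5}, 0.5)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            binarize({Label.DME: 0.5}, 0.0)


# ---------------------------------------------------------------- SeqAcc


class TestSeqAcc:
    def test_hand_enumerated_half_agreement(self):
        # truth ND = [1,1,0,0], predicted ND = [1,0,0,1]: TP=1 TN=1 FP=1 FN=1
        seq = make_sequence([("ND",), ("ND",), ("HF",), ("HF",)])
        preds = preds_from_sets([seq], [("ND",), (), (), ("ND",)])
        assert seq_acc_label(seq, preds, Label.ND) == 0.5

    def test_perfect_and_anti_perfect(self):
        seq = make_sequence([("ND",), ("HF",)])
        assert seq_acc_label(seq, perfect_preds([seq]), Label.ND) == 1.0
        flipped = preds_from_sets([seq], [(), ("ND",)])
        assert seq_acc_label(seq, flipped, Label.ND) == 0.0

    def test_sequence_aggregation_differs_from_pooling(self):
        # per-seq accuracies 1.0 (len 2) and 0.5 (len 4): SeqAcc 0.75, pooled 4/6
        s1 = make_sequence([("ND",), ("ND",)], seq="a")
        s2 = make_sequence([("ND",), ("ND",), ("HF",), ("HF",)], seq="b")
        # s1: both ND correct; s2 truth ND [1,1,0,0], predicted [1,0,0,1] -> 0.5
        preds = preds_from_sets(
            [s1, s2], [("ND",), ("ND",), ("ND",), (), (), ("ND",)]
        )
        assert seq_acc([s1, s2], preds, Label.ND) == pytest.approx(0.75)
        pooled = (2 + 2) / 6
        assert pooled == pytest.approx(4 / 6)
        assert seq_acc([s1, s2], preds, Label.ND) != pooled

    def test_length_one_sequences_reduce_to_accuracy(self):
        truths = [("ND",), ("HF",), ("ND",), ("HEALTHY",)]
        seqs = [make_sequence([t], seq=f"v{i}") for i, t in enumerate(truths)]
        pred_sets = [("ND",), ("ND",), (), ("HEALTHY",)]
        preds = preds_from_sets(seqs, pred_sets)
        # classical per-scan accuracy for ND: scan-by-scan agreement
        agree = [
            ("ND" in t) == ("ND" in p) for t, p in zip(truths, pred_sets)
        ]
        assert seq_acc(seqs, preds, Label.ND) == pytest.approx(np.mean(agree))

    def test_single_sequence_equals_seq_acc_label(self):
        seq = make_sequence([("ND",), ("HF",), ("ND", "HF")])
        preds = preds_from_sets([seq], [("ND",), ("HF",), ("HF",)])
        assert seq_acc([seq], preds, Label.ND) == seq_acc_label(seq, preds, Label.ND)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            seq_acc([], {}, Label.ND)


class TestExactMatch:
    def test_partial_agreement_counts_as_incorrect(self):
        seq = make_sequence([("DME", "HF"), ("DME", "HF")])
        preds = preds_from_sets([seq], [("DME", "HF"), ("DME",)])
        assert exact_match_seq_acc([seq], preds) == pytest.approx(0.5)

    def test_all_exact_gives_one(self):
        seqs = [make_sequence([("DME", "HF"), ("HEALTHY",)], seq=f"v{i}") for i in range(3)]
        assert exact_match_seq_acc(seqs, perfect_preds(seqs)) == 1.0


# ---------------------------------------------------------------- IoU


label_sets = st.sets(st.sampled_from(list(LABEL_ORDER))).map(frozenset)


@given(truth=label_sets, pred=label_sets)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_scan_iou_is_a_bounded_symmetric_similarity(truth, pred):
    v = scan_iou(truth, pred)
    assert 0.0 <= v <= 1.0
    assert scan_iou(pred, truth) == v
    assert (v == 1.0) == (truth == pred)


@given(
    probs=st.dictionaries(
        st.sampled_from(list(LABEL_ORDER)),
        st.floats(0.0, 1.0, allow_nan=False),
        min_size=1,
    ),
    lo=st.floats(0.05, 0.45),
    hi=st.floats(0.55, 0.95),
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_binarize_is_antitone_in_the_threshold(probs, lo, hi):
    assert binarize(probs, hi) <= binarize(probs, lo)


class TestScanIoU:
    def test_worked_example_one_third(self):
        assert scan_iou({Label.DME, Label.ND}, {Label.DME, Label.HF}) == pytest.approx(1 / 3)

    def test_identity(self):
        assert scan_iou({Label.HF}, {Label.HF}) == 1.0

    def test_empty_prediction(self):
        assert scan_iou({Label.HF}, set()) == 0.0

    def test_both_empty_vacuous_agreement(self):
        assert scan_iou(set(), set()) == 1.0


class TestSeqIoU:
    def test_mean_over_sequences(self):
        s1 = make_sequence([("DME", "HF")] * 2, pid="A", seq="a")
        s2 = make_sequence([("DME", "ND", "HF")] * 3, pid="B", seq="b")
        preds = perfect_preds([s1])
        preds.update(
            preds_from_sets([s2], [("DME", "ND"), ("DME", "ND"), ("DME", "ND")])
        )
        # s1 SeqIoU = 1.0, s2 = 2/3 each scan -> 2/3; per spec example style
        result = seq_iou([s1, s2], preds)
        assert result.overall_mean == pytest.approx((1.0 + 2 / 3) / 2)

    def test_healthy_patient_with_perfect_predictions_scores_one(self):
        healthy = make_sequence([("HEALTHY",)] * 4, pid="H1", seq="h")
        dr = make_sequence([("DME", "HF")] * 4, pid="D1", seq="d")
        preds = perfect_preds([healthy, dr])
        result = seq_iou([healthy, dr], preds)
        assert result.healthy_mean == 1.0
        assert result.n_healthy_sequences == 1

    def test_missing_stratum_reported_as_nan(self):
        dr = make_sequence([("DME",)] * 2, pid="D1")
        result = seq_iou([dr], perfect_preds([dr]))
        assert math.isnan(result.healthy_mean)
        assert result.n_healthy_sequences == 0

    def test_singleton_label_sets_reduce_to_seq_acc(self):
        """With multiclass (singleton) truths and predictions, per-scan IoU is
        0/1 and SeqIoU equals exact-match SeqAcc."""
        rng = random.Random(0)
        for _ in range(20):
            seqs = []
            preds = {}
            for i in range(rng.randint(1, 4)):
                truths = [
                    (rng.choice(["DME", "ND", "HF", "HEALTHY"]),)
                    for _ in range(rng.randint(1, 5))
                ]
                seq = make_sequence(truths, pid=f"P{i}", seq=f"v{i}")
                seqs.append(seq)
                for s in seq.scans:
                    choice = rng.choice(["DME", "ND", "HF", "HEALTHY"])
                    preds[s.key] = {
                        l: (0.9 if l.value == choice else 0.1) for l in LABEL_ORDER
                    }
            assert seq_iou(seqs, preds).overall_mean == pytest.approx(
                naive_exact_match(seqs, preds), abs=1e-12
            )

    def test_strata_recombine_to_overall(self):
        h = make_sequence([("HEALTHY",)] * 3, pid="H1", seq="h")
        d1 = make_sequence([("DME",)] * 3, pid="D1", seq="a")
        d2 = make_sequence([("HF",)] * 3, pid="D2", seq="b")
        preds = perfect_preds([h, d1])
        preds.update(preds_from_sets([d2], [(), (), ("HF",)]))
        r = seq_iou([h, d1, d2], preds)
        combined = (
            r.healthy_mean * r.n_healthy_sequences + r.dr_mean * r.n_dr_sequences
        ) / (r.n_healthy_sequences + r.n_dr_sequences)
        assert r.overall_mean == pytest.approx(combined, abs=1e-12)


class TestOracleEquivalence:
    def test_metrics_match_naive_double_loop_on_100_random_datasets(self):
        rng = random.Random(42)
        for _ in range(100):
            seqs, preds = random_micro_dataset(rng)
            for label in LABEL_ORDER:
                assert seq_acc(seqs, preds, label) == pytest.approx(
                    naive_seq_acc(seqs, preds, label), abs=1e-12
                )
            assert exact_match_seq_acc(seqs, preds) == pytest.approx(
                naive_exact_match(seqs, preds), abs=1e-12
            )
            assert seq_iou(seqs, preds).overall_mean == pytest.approx(
                naive_seq_iou(seqs, preds), abs=1e-12
            )

    def test_correcting_a_wrong_scan_never_hurts(self):
        rng = random.Random(7)
        for _ in range(30):
            seqs, preds = random_micro_dataset(rng)
            before = (
                [seq_acc(seqs, preds, l) for l in LABEL_ORDER],
                exact_match_seq_acc(seqs, preds),
                seq_iou(seqs, preds).overall_mean,
            )
            # fix one wrong scan
            fixed = dict(preds)
            for seq in seqs:
                for s in seq.scans:
                    pred_set = binarize(preds[s.key])
                    if pred_set != s.labels:
                        fixed[s.key] = {
                            l: (1.0 if l in s.labels else 0.0) for l in LABEL_ORDER
                        }
                        break
            after = (
                [seq_acc(seqs, fixed, l) for l in LABEL_ORDER],
                exact_match_seq_acc(seqs, fixed),
                seq_iou(seqs, fixed).overall_mean,
            )
            for b, a in zip(before[0], after[0]):
                assert a >= b - 1e-12
            assert after[1] >= before[1] - 1e-12
            assert after[2] >= before[2] - 1e-12


# ---------------------------------------------------------------- ROC AUC


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_full_ties_give_half(self):
        assert roc_auc([0.5] * 6, [True, False, True, False, True, False]) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = random.Random(1)
        for _ in range(50):
            n = rng.randint(4, 20)
            scores = [rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]) for _ in range(n)]
            truths = [rng.random() < 0.5 for _ in range(n)]
            if all(truths) or not any(truths):
                continue
            assert roc_auc(scores, truths) == pytest.approx(
                pairwise_auc(scores, truths), abs=1e-12
            )

    def test_single_class_is_missing(self):
        assert math.isnan(roc_auc([0.2, 0.8], [True, True]))


# ---------------------------------------------------------------- reports


class TestMultilabelReport:
    def test_perfect_probabilities_give_all_ones(self):
        seqs = [
            make_sequence([("DME", "HF"), ("HEALTHY",)], pid="A", seq="a"),
            make_sequence([("ND", "HF"), ("HF",)], pid="B", seq="b"),
        ]
        report = multilabel_report(seqs, perfect_preds(seqs))
        for m in report.per_label.values():
            assert m.sensitivity == 1.0 and m.specificity == 1.0
            assert m.seq_acc == 1.0
            assert m.roc_auc == 1.0
        assert report.exact_match_seq_acc == 1.0
        assert report.seq_iou.overall_mean == 1.0

    def test_label_swap_produces_zero_auc(self):
        seqs = [
            make_sequence(
                [("DME",), ("HF",), ("DME",), ("HF",)], pid="A", seq="a"
            )
        ]
        preds = {}
        for s in seqs[0].scans:
            # anti-oracle: high DME score exactly when DME absent
            preds[s.key] = {
                Label.DME: 0.9 if Label.DME not in s.labels else 0.1,
                Label.ND: 0.1,
                Label.HF: 0.9 if Label.HF not in s.labels else 0.1,
                Label.HEALTHY: 0.1,
            }
        report = multilabel_report(seqs, preds)
        assert report.per_label[Label.DME].roc_auc == 0.0
        assert report.per_label[Label.HF].roc_auc == 0.0

    def test_zero_support_label_has_missing_auc(self):
        seqs = [make_sequence([("DME", "HF"), ("DME", "HF")], pid="A")]
        report = multilabel_report(seqs, perfect_preds(seqs))
        assert math.isnan(report.per_label[Label.ND].roc_auc)

    def test_simulated_rates_recovered_within_binomial_error(self):
        """Bernoulli-noise predictions at sens 0.9 / spec 0.8 on 5000 scans."""
        from octseq.synth import (
            CohortConfig,
            LabelNoise,
            PredictionNoiseConfig,
            generate_cohort,
            simulate_predictions,
        )
        from octseq.records import group_sequences

        scans = generate_cohort(CohortConfig(n_patients=50, seed=3))
        assert len(scans) >= 5000
        noise = PredictionNoiseConfig(
            per_label={l: LabelNoise(sensitivity=0.9, specificity=0.8) for l in Label},
            seed=5,
        )
        preds = simulate_predictions(scans, noise)
        report = multilabel_report(group_sequences(scans), preds)
        for label in (Label.DME, Label.ND, Label.HF):
            m = report.per_label[label]
            se_sens = math.sqrt(0.9 * 0.1 / m.support_yes)
            se_spec = math.sqrt(0.8 * 0.2 / m.support_no)
            assert abs(m.sensitivity - 0.9) <= 3 * se_sens
            assert abs(m.specificity - 0.8) <= 3 * se_spec


class TestBinaryReport:
    def test_all_correct_toy_input(self):
        seqs = [
            make_sequence([("DME", "HF")] * 2, pid="D1", seq="a"),
            make_sequence([("HEALTHY",)] * 2, pid="H1", seq="b"),
        ]
        report = binary_report(seqs, perfect_preds(seqs))
        assert report.accuracy == 1.0
        assert report.wrong_as_dr_from_healthy_patients == 0
        assert report.wrong_as_dr_from_dr_patients == 0
        assert report.wrong_as_healthy == 0

    def test_wrong_as_dr_counter_splits_by_patient_type(self):
        healthy_seq = make_sequence([("HEALTHY",)] * 3, pid="H1", seq="h")
        dr_seq = make_sequence([("DME",)] * 3, pid="D1", seq="d")
        preds = perfect_preds([healthy_seq, dr_seq])
        # one healthy scan of the healthy patient predicted DR
        key = healthy_seq.scans[0].key
        preds[key] = {Label.DME: 0.9, Label.ND: 0.1, Label.HF: 0.1, Label.HEALTHY: 0.1}
        report = binary_report([healthy_seq, dr_seq], preds)
        assert report.wrong_as_dr_from_healthy_patients == 1
        assert report.wrong_as_dr_from_dr_patients == 0

    def test_seq_iou_mean_direct_computation(self):
        # 6 of 8 correct in one sequence + 4 of 4 in another -> mean 0.875
        s1 = make_sequence([("DME",)] * 8, pid="D1", seq="a")
        s2 = make_sequence([("DME",)] * 4, pid="D1", seq="b")
        preds = perfect_preds([s1, s2])
        for s in s1.scans[:2]:
            preds[s.key] = {
                Label.DME: 0.1, Label.ND: 0.1, Label.HF: 0.1, Label.HEALTHY: 0.9,
            }
        report = binary_report([s1, s2], preds)
        assert report.seq_iou.overall_mean == pytest.approx(0.875)
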