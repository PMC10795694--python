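"""Sequence-level evaluation metrics for multilabel B-scan predictions.

Classical per-scan metrics treat every B-scan as independent, but scans come
in sequences (incomplete volumes) from one eye, and clinically a model that
signals a biomarker *somewhere* in every affected sequence is preferable to
one that nails all scans of some volumes while missing others entirely.  Two
metrics capture this by aggregating first within each sequence and only then
across sequences:

* ``SeqAcc`` (per label): the per-sequence fraction of scans whose
  thresholded prediction agrees with truth on that label,
  ``(TP + TN) / (TP + TN + FP + FN)``, averaged unweighted over sequences.
* ``SeqIoU``: the per-scan Jaccard index between the true and predicted
  label sets, ``|c ∩ ĉ| / |c ∪ ĉ|``, averaged within each sequence and then
  unweighted over sequences.  Reported overall and stratified by patient
  type (healthy-type vs DR-type patients).

Both reduce to familiar quantities in limiting cases: with all sequences of
length 1, SeqAcc is classical accuracy; with singleton label sets
(multiclass predictions), per-scan IoU is 0/1 and SeqIoU equals SeqAcc.

Probabilities are binarized at a threshold (default 0.5); a probability
exactly at the threshold counts as present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TSequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .records import (
    BIOMARKERS,
    LABEL_ORDER,
    Label,
    ScanKey,
    Sequence,
    patient_types,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5

Probs = Mapping[Label, float]
Predictions = Mapping[ScanKey, Probs]


def binarize(probs: Probs, threshold: float = DEFAULT_THRESHOLD) -> frozenset[Label]:
    """Threshold per-label probabilities into a predicted label set.

    A label is predicted present iff its probability is >= ``threshold``.
    Only labels present in ``probs`` are considered; a missing label raises
    through :func:`predicted_set` when a dataset-wide vocabulary is enforced.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return frozenset(l for l, p in probs.items() if p >= threshold)


def _probs_for(preds: Predictions, key: ScanKey) -> Probs:
    try:
        return preds[key]
    except KeyError:
        raise ValueError(f"no prediction for scan {key}") from None


def predicted_set(
    preds: Predictions,
    key: ScanKey,
    threshold: float = DEFAULT_THRESHOLD,
    labels: TSequence[Label] = LABEL_ORDER,
) -> frozenset[Label]:
    probs = _probs_for(preds, key)
    missing = [l.value for l in labels if l not in probs]
    if missing:
        raise ValueError(f"prediction for scan {key} is missing labels {missing}")
    return binarize(probs, threshold)


def seq_acc_label(
    seq: Sequence,
    preds: Predictions,
    label: Label,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Per-sequence accuracy for one label: fraction of scans where the
    thresholded prediction agrees with truth on ``label``."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    correct = 0
    for s in seq.scans:
        pred = label in predicted_set(preds, s.key, threshold)
        truth = label in s.labels
        correct += pred == truth
    return correct / len(seq)


def seq_acc(
    sequences: TSequence[Sequence],
    preds: Predictions,
    label: Label,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Sequence-aggregated accuracy for one label: the unweighted mean of
    :func:`seq_acc_label` over sequences (not pooled over scans)."""
    if not sequences:
        raise ValueError("no sequences")
    return sum(seq_acc_label(s, preds, label, threshold) for s in sequences) / len(
        sequences
    )


def exact_match_seq_acc(
    sequences: TSequence[Sequence],
    preds: Predictions,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """SeqAcc where a scan counts as correct only when its full predicted
    label set equals the truth set."""
    if not sequences:
        raise ValueError("no sequences")
    total = 0.0
    for seq in sequences:
        correct = sum(
            predicted_set(preds, s.key, threshold) == s.labels for s in seq.scans
        )
        total += correct / len(seq)
    return total / len(sequences)


def scan_iou(truth: frozenset[Label] | set[Label], pred: frozenset[Label] | set[Label]) -> float:
    """Jaccard index between true and predicted label sets.

    ``scan_iou(∅, ∅)`` is defined as 1 (vacuous agreement); truth sets are
    non-empty for retained scans, so this arises only for defensive use.
    """
    truth, pred = frozenset(truth), frozenset(pred)
    union = truth | pred
    if not union:
        return 1.0
    return len(truth & pred) / len(union)


@dataclass
class SeqIoUResult:
    """SeqIoU overall and stratified by patient type.

    Means/stds are taken with sequences as the sample unit (sample std,
    n−1 denominator; NaN when a stratum holds fewer than two sequences, and
    a stratum with no sequences is reported as missing means).
    """

    overall_mean: float
    overall_std: float
    healthy_mean: float  # NaN when no healthy-type patient sequences
    healthy_std: float
    dr_mean: float
    dr_std: float
    per_sequence: dict[tuple[str, str, str], float] = field(default_factory=dict)
    n_healthy_sequences: int = 0
    n_dr_sequences: int = 0


def _mean_std(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    std = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
    return float(arr.mean()), std


def seq_iou(
    sequences: TSequence[Sequence],
    preds: Predictions,
    threshold: float = DEFAULT_THRESHOLD,
    patient_type: Mapping[str, str] | None = None,
) -> SeqIoUResult:
    """Per-sequence mean scan IoU, aggregated unweighted over sequences.

    Strata are defined by the *patient's* type (healthy-type patients have
    only HEALTHY scans anywhere in the dataset), not by sequence content.
    ``patient_type`` may be supplied explicitly; otherwise it is derived from
    the truth labels of ``sequences``.
    """
    if not sequences:
        raise ValueError("no sequences")
    if patient_type is None:
        patient_type = patient_types(s for seq in sequences for s in seq.scans)
    per_seq: dict[tuple[str, str, str], float] = {}
    strata: dict[str, list[float]] = {"healthy": [], "dr": []}
    for seq in sequences:
        value = sum(
            scan_iou(s.labels, predicted_set(preds, s.key, threshold))
            for s in seq.scans
        ) / len(seq)
        per_seq[seq.key] = value
        strata[patient_type[seq.patient_id]].append(value)
    overall_mean, overall_std = _mean_std(list(per_seq.values()))
    healthy_mean, healthy_std = _mean_std(strata["healthy"])
    dr_mean, dr_std = _mean_std(strata["dr"])
    return SeqIoUResult(
        overall_mean=overall_mean,
        overall_std=overall_std,
        healthy_mean=healthy_mean,
        healthy_std=healthy_std,
        dr_mean=dr_mean,
        dr_std=dr_std,
        per_sequence=per_seq,
        n_healthy_sequences=len(strata["healthy"]),
        n_dr_sequences=len(strata["dr"]),
    )


def roc_auc(scores: TSequence[float], truths: TSequence[bool]) -> float:
    """Area under the ROC curve by rank statistic with tie correction.

    Equivalent to the normalized two-sample rank (Mann–Whitney) statistic:
    the probability that a random positive outscores a random negative,
    counting ties as 1/2.  Returns NaN when truths are single-class.
    """
    truths = np.asarray(truths, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truths.all() or not truths.any():
        return math.nan
    return float(roc_auc_score(truths, scores))


@dataclass
class LabelMetrics:
    """Per-label scan-level metrics plus the label's SeqAcc."""

    label: Label
    support_yes: int
    support_no: int
    precision_yes: float
    recall_yes: float
    f1_yes: float
    precision_no: float
    recall_no: float
    f1_no: float
    sensitivity: float  # = recall of the "yes" class
    specificity: float  # = recall of the "no" class
    roc_auc: float  # NaN when the label has single-class support
    seq_acc: float


@dataclass
class EvaluationReport:
    """The multilabel evaluation report: per-label metrics + sequence metrics."""

    threshold: float
    n_scans: int
    n_sequences: int
    per_label: dict[Label, LabelMetrics]
    exact_match_seq_acc: float
    seq_iou: SeqIoUResult


def _binary_rates(truth: np.ndarray, pred: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """precision/recall/F1 for the positive and negative classes."""

    def prf(t: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
        tp = int((t & p).sum())
        fp = int((~t & p).sum())
        fn = int((t & ~p).sum())
        precision = tp / (tp + fp) if tp + fp else math.nan
        recall = tp / (tp + fn) if tp + fn else math.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if (tp + fp) and (tp + fn) and (precision + recall) > 0
            else (0.0 if (tp + fp) and (tp + fn) else math.nan)
        )
        return precision, recall, f1

    p_yes, r_yes, f_yes = prf(truth, pred)
    p_no, r_no, f_no = prf(~truth, ~pred)
    return p_yes, r_yes, f_yes, p_no, r_no, f_no


def multilabel_report(
    sequences: TSequence[Sequence],
    preds: Predictions,
    threshold: float = DEFAULT_THRESHOLD,
    labels: TSequence[Label] = LABEL_ORDER,
) -> EvaluationReport:
    """Full multilabel evaluation: per-label precision/recall/F1 (both
    classes), sensitivity/specificity, ROC AUC from raw probabilities,
    per-label SeqAcc, exact-match SeqAcc, and SeqIoU with patient-type
    strata."""
    if not sequences:
        raise ValueError("no sequences")
    scans = [s for seq in sequences for s in seq.scans]
    pred_sets = {s.key: predicted_set(preds, s.key, threshold, labels) for s in scans}
    n_inconsistent = sum(
        1
        for ps in pred_sets.values()
        if Label.HEALTHY in ps and ps & BIOMARKERS
    )
    if n_inconsistent:
        logger.warning(
            "%d predicted label sets combine HEALTHY with a biomarker", n_inconsistent
        )
    per_label: dict[Label, LabelMetrics] = {}
    for label in labels:
        truth = np.array([label in s.labels for s in scans], dtype=bool)
        pred = np.array([label in pred_sets[s.key] for s in scans], dtype=bool)
        scores = [_probs_for(preds, s.key)[label] for s in scans]
        p_yes, r_yes, f_yes, p_no, r_no, f_no = _binary_rates(truth, pred)
        per_label[label] = LabelMetrics(
            label=label,
            support_yes=int(truth.sum()),
            support_no=int((~truth).sum()),
            precision_yes=p_yes,
            recall_yes=r_yes,
            f1_yes=f_yes,
            precision_no=p_no,
            recall_no=r_no,
            f1_no=f_no,
            sensitivity=r_yes,
            specificity=r_no,
            roc_auc=roc_auc(scores, truth),
            seq_acc=seq_acc(sequences, preds, label, threshold),
        )
    return EvaluationReport(
        threshold=threshold,
        n_scans=len(scans),
        n_sequences=len(sequences),
        per_label=per_label,
        exact_match_seq_acc=exact_match_seq_acc(sequences, preds, threshold),
        seq_iou=seq_iou(sequences, preds, threshold),
    )


@dataclass
class BinaryReport:
    """Healthy-vs-DR evaluation with the wrong-prediction breakdown.

    ``wrong_as_dr_from_healthy_patients`` / ``..._from_dr_patients`` count
    truly healthy scans predicted DR, split by the type of patient the scan
    comes from; ``wrong_as_healthy`` counts DR scans predicted healthy.
    """

    threshold: float
    n_scans: int
    n_sequences: int
    precision_dr: float
    recall_dr: float  # = sensitivity for DR
    precision_healthy: float
    recall_healthy: float  # = specificity
    accuracy: float
    seq_iou: SeqIoUResult
    wrong_as_dr_from_healthy_patients: int
    wrong_as_dr_from_dr_patients: int
    wrong_as_healthy: int


def reduce_to_dr(
    probs: Probs, threshold: float = DEFAULT_THRESHOLD
) -> bool:
    """Binary reduction of a multilabel prediction: DR iff any biomarker is
    predicted present.  Used when predictions carry no dedicated DR
    probability; an artifact convenience, flagged as such in reports."""
    return bool(binarize(probs, threshold) & BIOMARKERS)


def binary_report(
    sequences: TSequence[Sequence],
    preds: Predictions,
    threshold: float = DEFAULT_THRESHOLD,
) -> BinaryReport:
    """Healthy-vs-DR evaluation of sequences.

    A prediction record carrying a ``DR`` probability key is used directly;
    otherwise the multilabel prediction is reduced via :func:`reduce_to_dr`.
    Truth: a scan is DR iff its true label set contains a biomarker.  The
    per-scan IoU of the induced singleton label sets is 0/1, so SeqIoU here
    is the per-sequence fraction of correctly classified scans.
    """
    if not sequences:
        raise ValueError("no sequences")
    scans = [s for seq in sequences for s in seq.scans]
    ptype = patient_types(scans)

    def pred_dr(key: ScanKey) -> bool:
        probs = _probs_for(preds, key)
        if "DR" in probs:
            return probs["DR"] >= threshold  # type: ignore[index]
        return reduce_to_dr(probs, threshold)

    truth = np.array([s.is_dr for s in scans], dtype=bool)
    pred = np.array([pred_dr(s.key) for s in scans], dtype=bool)
    p_dr, r_dr, _, p_h, r_h, _ = _binary_rates(truth, pred)
    accuracy = float((truth == pred).mean())

    wrong_as_dr_h = wrong_as_dr_dr = wrong_as_h = 0
    for s, t, p in zip(scans, truth, pred):
        if not t and p:
            if ptype[s.patient_id] == "healthy":
                wrong_as_dr_h += 1
            else:
                wrong_as_dr_dr += 1
        elif t and not p:
            wrong_as_h += 1

    # Binary SeqIoU via singleton label sets {DR} / {HEALTHY}.
    binary_truth = {
        s.key: frozenset({Label.DME if t else Label.HEALTHY}) for s, t in zip(scans, truth)
    }
    per_seq: dict[tuple[str, str, str], float] = {}
    strata: dict[str, list[float]] = {"healthy": [], "dr": []}
    pred_map = {s.key: p for s, p in zip(scans, pred)}
    for seq in sequences:
        value = sum(
            scan_iou(
                binary_truth[s.key],
                frozenset({Label.DME if pred_map[s.key] else Label.HEALTHY}),
            )
            for s in seq.scans
        ) / len(seq)
        per_seq[seq.key] = value
        strata[ptype[seq.patient_id]].append(value)
    overall_mean, overall_std = _mean_std(list(per_seq.values()))
    healthy_mean, healthy_std = _mean_std(strata["healthy"])
    dr_mean, dr_std = _mean_std(strata["dr"])
    iou = SeqIoUResult(
        overall_mean=overall_mean,
        overall_std=overall_std,
        healthy_mean=healthy_mean,
        healthy_std=healthy_std,
        dr_mean=dr_mean,
        dr_std=dr_std,
        per_sequence=per_seq,
        n_healthy_sequences=len(strata["healthy"]),
        n_dr_sequences=len(strata["dr"]),
    )
    return BinaryReport(
        threshold=threshold,
        n_scans=len(scans),
        n_sequences=len(sequences),
        precision_dr=p_dr,
        recall_dr=r_dr,
        precision_healthy=p_h,
        recall_healthy=r_h,
        accuracy=accuracy,
        seq_iou=iou,
        wrong_as_dr_from_healthy_patients=wrong_as_dr_h,
        wrong_as_dr_from_dr_patients=wrong_as_dr_dr,
        wrong_as_healthy=wrong_as_h,
    )
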