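"""Intra- vs inter-patient cosine similarity of scan embeddings.

For each patient, *intra-patient similarity* is the mean cosine similarity
over all (left-eye scan, right-eye scan) pairs of that patient — a measure
of bilateral coherence — and *inter-patient similarity* is the mean cosine
over all pairs formed by the patient's scans with every other patient's
scans.  Cohort-level means and standard deviations are taken across
patients (each patient contributes one intra mean and one inter mean);
raw-pair aggregation is available behind ``aggregate="pairs"``.

Patients whose intra-patient mean falls below an alert threshold (default
0.6) are flagged: low bilateral coherence may indicate acquisition problems
or strongly asymmetric disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

import numpy as np
import pandas as pd

from .records import ScanKey, ScanRecord

DEFAULT_ALERT_THRESHOLD = 0.6


@dataclass
class EmbeddingMatrix:
    """Scan-aligned dense embedding vectors.

    One row per scan key; all rows share the same dimension and contain only
    finite values.
    """

    keys: list[ScanKey]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding values must be a 2-D array")
        if len(self.keys) != self.values.shape[0]:
            raise ValueError("one embedding row per scan key required")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate scan keys in embedding matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def index_of(self, keys: Iterable[ScanKey]) -> np.ndarray:
        lookup = {k: i for i, k in enumerate(self.keys)}
        try:
            return np.array([lookup[k] for k in keys], dtype=int)
        except KeyError as err:
            raise ValueError(f"no embedding for scan {err.args[0]}") from None


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity ``dot(u, v) / (‖u‖ ‖v‖)``, clipped to [−1, 1].

    Raises ``ValueError`` on zero vectors or mismatched dimensions.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors have different dimensions")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _unit_rows(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    if (norms == 0.0).any():
        raise ValueError("embedding matrix contains a zero vector")
    return values / norms


def intra_patient_similarity(
    emb: EmbeddingMatrix,
    scans: TSequence[ScanRecord],
    patient_id: str,
) -> tuple[float, np.ndarray]:
    """Mean cosine over the full left-eye x right-eye pair set of one patient.

    Returns ``(mean, pair_similarities)``; the mean is NaN (and the pair
    array empty) when the patient has scans from only one eye.
    """
    od = [s.key for s in scans if s.patient_id == patient_id and s.eye == "OD"]
    os_ = [s.key for s in scans if s.patient_id == patient_id and s.eye == "OS"]
    if not od or not os_:
        return math.nan, np.empty(0)
    unit = _unit_rows(emb.values)
    sims = unit[emb.index_of(os_)] @ unit[emb.index_of(od)].T
    sims = np.clip(sims, -1.0, 1.0).ravel()
    return float(sims.mean()), sims


def inter_patient_similarity(
    emb: EmbeddingMatrix,
    scans: TSequence[ScanRecord],
    patient_id: str,
) -> tuple[float, np.ndarray]:
    """Mean cosine over all pairs (scan of the patient, scan of any other
    patient), both eyes included.  Raises on a single-patient cohort."""
    own = [s.key for s in scans if s.patient_id == patient_id]
    others = [s.key for s in scans if s.patient_id != patient_id]
    if not others:
        raise ValueError("inter-patient similarity requires at least 2 patients")
    if not own:
        raise ValueError(f"patient {patient_id!r} has no scans")
    unit = _unit_rows(emb.values)
    sims = unit[emb.index_of(own)] @ unit[emb.index_of(others)].T
    sims = np.clip(sims, -1.0, 1.0).ravel()
    return float(sims.mean()), sims


@dataclass
class SimilarityReport:
    """Cohort-level similarity summary with per-patient detail."""

    per_patient: pd.DataFrame  # patient_id, intra_mean, inter_mean, pair counts
    intra_mean: float
    intra_std: float
    inter_mean: float
    inter_std: float
    flagged_patients: list[str] = field(default_factory=list)
    alert_threshold: float = DEFAULT_ALERT_THRESHOLD
    aggregate: str = "patients"
    histograms: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def similarity_report(
    emb: EmbeddingMatrix,
    scans: TSequence[ScanRecord],
    alert_threshold: float = DEFAULT_ALERT_THRESHOLD,
    aggregate: str = "patients",
    histogram_bins: int = 20,
) -> SimilarityReport:
    """Per-patient intra/inter similarity with cohort aggregation.

    ``aggregate="patients"`` (default) averages the per-patient means (each
    patient weighs equally); ``"pairs"`` pools raw pair similarities.
    Patients with a single represented eye contribute no intra mean and are
    excluded from the cohort intra aggregate.
    """
    if aggregate not in ("patients", "pairs"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    patients = sorted({s.patient_id for s in scans})
    if len(patients) < 2:
        raise ValueError("similarity report requires at least 2 patients")
    rows = []
    intra_pairs_all: list[np.ndarray] = []
    inter_pairs_all: list[np.ndarray] = []
    histograms: dict[str, dict[str, np.ndarray]] = {}
    bin_edges = np.linspace(-1.0, 1.0, histogram_bins + 1)
    for pid in patients:
        intra_mean, intra_pairs = intra_patient_similarity(emb, scans, pid)
        inter_mean, inter_pairs = inter_patient_similarity(emb, scans, pid)
        rows.append(
            {
                "patient_id": pid,
                "intra_mean": intra_mean,
                "inter_mean": inter_mean,
                "n_intra_pairs": len(intra_pairs),
                "n_inter_pairs": len(inter_pairs),
            }
        )
        intra_pairs_all.append(intra_pairs)
        inter_pairs_all.append(inter_pairs)
        histograms[pid] = {
            "bin_edges": bin_edges,
            "intra_counts": np.histogram(intra_pairs, bins=bin_edges)[0],
            "inter_counts": np.histogram(inter_pairs, bins=bin_edges)[0],
        }
    per_patient = pd.DataFrame(rows).set_index("patient_id")
    if aggregate == "patients":
        intra = per_patient["intra_mean"].dropna()
        inter = per_patient["inter_mean"].dropna()
    else:
        intra = pd.Series(np.concatenate(intra_pairs_all)) if intra_pairs_all else pd.Series(dtype=float)
        inter = pd.Series(np.concatenate(inter_pairs_all))
    flagged = sorted(
        per_patient.index[per_patient["intra_mean"] < alert_threshold].tolist()
    )
    return SimilarityReport(
        per_patient=per_patient,
        intra_mean=float(intra.mean()) if len(intra) else math.nan,
        intra_std=float(intra.std(ddof=1)) if len(intra) > 1 else math.nan,
        inter_mean=float(inter.mean()) if len(inter) else math.nan,
        inter_std=float(inter.std(ddof=1)) if len(inter) > 1 else math.nan,
        flagged_patients=flagged,
        alert_threshold=alert_threshold,
        aggregate=aggregate,
        histograms=histograms,
    )
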