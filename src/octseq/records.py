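"""Core data model for annotated OCT B-scans.

A *scan* is one cross-sectional B-scan of one eye, annotated with a set of
labels drawn from three diabetic-macular-edema biomarkers (DME — intraretinal
cystoid edema, ND — subfoveal neurosensory detachment, HF — hyperreflective
foci) plus HEALTHY.  Scans showing non-DR-specific pathology (CNV, epiretinal
membrane, hemorrhage) or acquisition artifacts carry an *excluded* category
and are dropped before any analysis.

Consecutive scans of one eye from one acquisition form a *sequence* (the
volumes are possibly incomplete, hence not "volume").  Sequence membership is
what the sequence-level metrics in :mod:`octseq.metrics` aggregate over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable


class Label(str, Enum):
    """A scan-level annotation label (three biomarkers + healthy)."""

    DME = "DME"
    ND = "ND"
    HF = "HF"
    HEALTHY = "HEALTHY"


#: The three DR-specific biomarkers; a scan carrying any of these is a "DR scan".
BIOMARKERS: frozenset[Label] = frozenset({Label.DME, Label.ND, Label.HF})

#: Canonical label ordering used for CSV columns and report rows.
LABEL_ORDER: tuple[Label, ...] = (Label.DME, Label.ND, Label.HF, Label.HEALTHY)


class ExcludedCategory(str, Enum):
    """Reasons a scan is removed before analysis (non-DR-specific lesions, artifacts)."""

    CNV_DR = "CNV_DR"
    ERM_DR = "ERM_DR"
    HEMORRHAGE_DR = "HEMORRHAGE_DR"
    ARTIFACT = "ARTIFACT"


EYES = ("OD", "OS")  # right eye, left eye

ScanKey = tuple[str, str, str, int]
SequenceKey = tuple[str, str, str]


@dataclass(frozen=True)
class ScanRecord:
    """One annotated B-scan.

    Parameters
    ----------
    patient_id, eye, sequence_id, slice_index
        Identity of the scan; the 4-tuple must be unique within a dataset and
        ``slice_index`` (0-based) orders scans within their sequence.
    labels
        True label set.  Non-empty for retained scans; HEALTHY never
        co-occurs with a biomarker.
    excluded
        Set when the scan belongs to an excluded category; such scans may
        carry an empty label set and are removed by :func:`filter_retained`.
    """

    patient_id: str
    eye: str
    sequence_id: str
    slice_index: int
    labels: frozenset[Label]
    excluded: ExcludedCategory | None = None

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.slice_index < 0:
            raise ValueError(f"slice_index must be >= 0, got {self.slice_index}")
        labels = frozenset(Label(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if Label.HEALTHY in labels and labels & BIOMARKERS:
            raise ValueError(
                f"HEALTHY co-occurs with a biomarker in true labels of scan {self.key}"
            )
        if self.excluded is None and not labels:
            raise ValueError(f"retained scan {self.key} has an empty label set")

    @property
    def key(self) -> ScanKey:
        return (self.patient_id, self.eye, self.sequence_id, self.slice_index)

    @property
    def sequence_key(self) -> SequenceKey:
        return (self.patient_id, self.eye, self.sequence_id)

    @property
    def is_dr(self) -> bool:
        """True when the scan carries at least one biomarker."""
        return bool(self.labels & BIOMARKERS)


@dataclass
class Sequence:
    """An ordered, non-empty run of scans from one eye of one patient."""

    key: SequenceKey
    scans: list[ScanRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError(f"sequence {self.key} is empty")
        if any(s.sequence_key != self.key for s in self.scans):
            raise ValueError(f"sequence {self.key} contains scans with a foreign key")
        self.scans = sorted(self.scans, key=lambda s: s.slice_index)

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def patient_id(self) -> str:
        return self.key[0]


def check_unique_keys(scans: Iterable[ScanRecord]) -> None:
    """Raise ``ValueError`` naming the first duplicated scan key, if any."""
    seen: set[ScanKey] = set()
    for s in scans:
        if s.key in seen:
            raise ValueError(f"duplicate scan key {s.key}")
        seen.add(s.key)


def group_sequences(scans: Iterable[ScanRecord]) -> list[Sequence]:
    """Group scans into sequences, ordered by (patient, eye, sequence id)."""
    by_key: dict[SequenceKey, list[ScanRecord]] = {}
    for s in scans:
        by_key.setdefault(s.sequence_key, []).append(s)
    return [Sequence(key=k, scans=v) for k, v in sorted(by_key.items())]


def filter_retained(scans: Iterable[ScanRecord]) -> list[ScanRecord]:
    """Drop every scan carrying an excluded category.

    Surviving scans are returned unaltered (same objects, same label sets);
    they carry only labels from {DME, ND, HF, HEALTHY}.
    """
    return [s for s in scans if s.excluded is None]


def patient_types(scans: Iterable[ScanRecord]) -> dict[str, str]:
    """Classify each patient as ``"healthy"`` or ``"dr"``.

    A DR patient has at least one retained scan carrying a biomarker; a
    healthy patient has only HEALTHY scans.
    """
    types: dict[str, str] = {}
    for s in scans:
        if s.excluded is not None:
            continue
        if s.is_dr:
            types[s.patient_id] = "dr"
        else:
            types.setdefault(s.patient_id, "healthy")
    return types
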