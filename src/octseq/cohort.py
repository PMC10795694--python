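"""The packaged study cohort: per-patient scan counts and their expansion.

The study's cohort of 52 patients is published only as a per-patient table of
B-scan counts in ten annotation categories — six retained label combinations
(ND+HF, DME+HF, DME+HF+ND, DME+ND, HF alone, healthy) and four excluded ones
(CNV, epiretinal membrane, hemorrhage — each combined with DR — and artifact).
That table ships with the package and is validated on load against the
study's printed aggregate counts (the *consistency oracle*): 2660 retained
scans of which 1615 carry DME, 330 ND, 2096 HF and 510 are healthy.

Because the table carries no volume structure, :func:`expand_cohort` packs
the counted scans into synthetic sequences of at most ``seq_len`` consecutive
slices.  This is a modelling convenience for exercising the pipeline;
sequence-level conclusions about real data rest on annotation CSVs and the
synthetic-cohort generator, not on this expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .records import EYES, ExcludedCategory, Label, ScanRecord

#: Retained categories and the label set each expands to.
CATEGORY_LABELS: dict[str, frozenset[Label]] = {
    "ND_HF": frozenset({Label.ND, Label.HF}),
    "DME_HF": frozenset({Label.DME, Label.HF}),
    "DME_HF_ND": frozenset({Label.DME, Label.HF, Label.ND}),
    "DME_ND": frozenset({Label.DME, Label.ND}),
    "HF": frozenset({Label.HF}),
    "HEALTHY": frozenset({Label.HEALTHY}),
}

#: Excluded categories, mapped to their marker.
EXCLUDED_CATEGORIES: dict[str, ExcludedCategory] = {
    "CNV_DR": ExcludedCategory.CNV_DR,
    "ERM_DR": ExcludedCategory.ERM_DR,
    "HEMORRHAGE_DR": ExcludedCategory.HEMORRHAGE_DR,
    "ARTIFACT": ExcludedCategory.ARTIFACT,
}

#: Column order of the cohort table.
CATEGORY_ORDER: tuple[str, ...] = (
    "ND_HF",
    "ERM_DR",
    "DME_HF",
    "DME_HF_ND",
    "DME_ND",
    "CNV_DR",
    "HF",
    "HEMORRHAGE_DR",
    "ARTIFACT",
    "HEALTHY",
)

_LABELSET_TO_CATEGORY = {v: k for k, v in CATEGORY_LABELS.items()}

# Printed aggregates of the study cohort, used by the consistency oracle.
_EXPECTED_TOTALS = {
    "ND_HF": 2,
    "ERM_DR": 229,
    "DME_HF": 1287,
    "DME_HF_ND": 274,
    "DME_ND": 54,
    "CNV_DR": 23,
    "HF": 533,
    "HEMORRHAGE_DR": 43,
    "ARTIFACT": 27,
    "HEALTHY": 510,
}
_EXPECTED_RETAINED = 2660
_EXPECTED_BIOMARKER_SCANS = {Label.DME: 1615, Label.ND: 330, Label.HF: 2096, Label.HEALTHY: 510}


@dataclass
class CohortCountsTable:
    """Per-patient B-scan counts by annotation category.

    Wraps a DataFrame indexed by ``patient_id`` with one non-negative integer
    column per category in :data:`CATEGORY_ORDER`.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORY_ORDER if c not in self.counts.columns]
        if missing:
            raise ValueError(f"cohort table missing category columns {missing}")
        self.counts = self.counts[list(CATEGORY_ORDER)].astype(int)
        if (self.counts < 0).any().any():
            raise ValueError("cohort table contains negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError("cohort table contains duplicated patient ids")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_scans(self) -> int:
        return int(self.counts.to_numpy().sum())

    def category_totals(self) -> dict[str, int]:
        return {c: int(self.counts[c].sum()) for c in CATEGORY_ORDER}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortCountsTable):
            return NotImplemented
        a = self.counts.sort_index()
        b = other.counts.sort_index()
        return a.equals(b)


def load_cohort_fixture() -> CohortCountsTable:
    """Load the packaged 52-patient cohort table and verify its aggregates.

    Raises
    ------
    RuntimeError
        If the shipped table fails the consistency oracle (corrupted fixture).
    """
    with resources.files("octseq.data").joinpath("table1_cohort.csv").open("r") as fh:
        df = pd.read_csv(fh, index_col="patient_id")
    table = CohortCountsTable(df)
    check_fixture_consistency(table)
    return table


def check_fixture_consistency(table: CohortCountsTable) -> None:
    """The consistency oracle: category totals must match the study's printed aggregates.

    Checks the per-category totals, the derived per-biomarker scan counts
    (DME 1615 = DME_HF + DME_HF_ND + DME_ND, ND 330, HF 2096, healthy 510),
    the retained total 2660 and the excluded total (grand total − 2660).
    """
    totals = table.category_totals()
    if totals != _EXPECTED_TOTALS:
        raise RuntimeError(
            f"cohort fixture failed consistency oracle: category totals {totals} "
            f"!= expected {_EXPECTED_TOTALS}"
        )
    derived = {
        Label.DME: totals["DME_HF"] + totals["DME_HF_ND"] + totals["DME_ND"],
        Label.ND: totals["ND_HF"] + totals["DME_HF_ND"] + totals["DME_ND"],
        Label.HF: totals["ND_HF"] + totals["DME_HF"] + totals["DME_HF_ND"] + totals["HF"],
        Label.HEALTHY: totals["HEALTHY"],
    }
    if derived != _EXPECTED_BIOMARKER_SCANS:
        raise RuntimeError(
            f"cohort fixture failed consistency oracle: biomarker sums {derived}"
        )
    retained = sum(totals[c] for c in CATEGORY_LABELS)
    if retained != _EXPECTED_RETAINED:
        raise RuntimeError(
            f"cohort fixture failed consistency oracle: retained total {retained} != "
            f"{_EXPECTED_RETAINED}"
        )
    excluded = sum(totals[c] for c in EXCLUDED_CATEGORIES)
    if excluded != table.n_scans - _EXPECTED_RETAINED:
        raise RuntimeError("cohort fixture failed consistency oracle: excluded total")


def expand_cohort(
    table: CohortCountsTable, seq_len: int = 25, seed: int = 0
) -> list[ScanRecord]:
    """Expand per-category counts into per-scan records with synthetic sequences.

    For each (patient, category, count) cell, emits ``count`` records carrying
    that category's label set.  Each patient's scans are shuffled once under
    ``seed`` and packed into sequences of at most ``seq_len`` consecutive
    slices, alternating eyes OD/OS per sequence.  Per-patient per-category
    counts of the output equal the input table exactly, so
    ``tabulate(expand_cohort(t)) == t``.
    """
    if seq_len < 1:
        raise ValueError(f"seq_len must be >= 1, got {seq_len}")
    rng = np.random.default_rng(seed)
    records: list[ScanRecord] = []
    for patient_id, row in table.counts.iterrows():
        cells: list[tuple[frozenset[Label], ExcludedCategory | None]] = []
        for category in CATEGORY_ORDER:
            n = int(row[category])
            if category in CATEGORY_LABELS:
                payload = (CATEGORY_LABELS[category], None)
            else:
                payload = (frozenset(), EXCLUDED_CATEGORIES[category])
            cells.extend([payload] * n)
        order = rng.permutation(len(cells))
        for position, idx in enumerate(order):
            labels, excluded = cells[idx]
            seq_number, slice_index = divmod(position, seq_len)
            records.append(
                ScanRecord(
                    patient_id=str(patient_id),
                    eye=EYES[seq_number % 2],
                    sequence_id=f"s{seq_number:03d}",
                    slice_index=slice_index,
                    labels=labels,
                    excluded=excluded,
                )
            )
    return records


def tabulate(scans: Iterable[ScanRecord]) -> CohortCountsTable:
    """Re-tabulate scan records into a cohort counts table (inverse of expansion).

    Raises ``ValueError`` for a retained label set that is not one of the six
    cohort categories.
    """
    rows: dict[str, dict[str, int]] = {}
    for s in scans:
        if s.excluded is not None:
            category = s.excluded.value
        else:
            category = _LABELSET_TO_CATEGORY.get(s.labels)
            if category is None:
                raise ValueError(
                    f"label set {sorted(l.value for l in s.labels)} of scan {s.key} "
                    "is not a cohort category"
                )
        row = rows.setdefault(s.patient_id, {c: 0 for c in CATEGORY_ORDER})
        row[category] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    df.index.name = "patient_id"
    return CohortCountsTable(df)
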