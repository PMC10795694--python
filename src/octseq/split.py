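"""Patient-disjoint train/test splitting by multilabel iterative stratification.

Scans from one patient are never split across sides: the unit of allocation
is the patient, characterized by the 4-bit feature vector F_patients (at
least one DME / ND / HF / healthy scan).  Because feature combinations vary
widely across patients, a uniformly random patient split tends to
misrepresent rare combinations in the test set; iterative stratification
allocates patients label-by-label, rarest label first, to preserve
per-feature proportions on both sides.

The algorithm (greedy rarest-label-first): repeatedly pick the unallocated
feature with the fewest remaining carriers, and assign each of its carriers
to the side with the greatest remaining demand for that feature; ties break
by overall remaining capacity, then by a seeded random draw.  Patients with
no active features are allocated last by capacity.  Side capacities are
enforced, so the test side receives floor or ceil of
``test_fraction * n_patients`` patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

import numpy as np

from .records import LABEL_ORDER, Label
from .summary import PatientFeatures

#: Feature combinations reported by default: the study's table shows the four
#: single features and six of the pairs.
DEFAULT_COMBINATIONS: tuple[tuple[Label, ...], ...] = (
    (Label.DME,),
    (Label.DME, Label.HEALTHY),
    (Label.HF, Label.HEALTHY),
    (Label.DME, Label.HF),
    (Label.HEALTHY,),
    (Label.HF,),
    (Label.DME, Label.ND),
    (Label.ND, Label.HF),
    (Label.ND,),
    (Label.ND, Label.HEALTHY),
)


@dataclass
class CombinationRow:
    """One row of the combination-ratio report."""

    combination: tuple[Label, ...]
    n_train: int
    n_test: int
    ratio: float  # n_test / n_train; NaN when n_train == 0


@dataclass
class SplitResult:
    """A patient-disjoint split with its feature matrix and report."""

    train_patients: set[str]
    test_patients: set[str]
    features: list[PatientFeatures]
    seed: int
    test_fraction: float
    combination_rows: list[CombinationRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = self.train_patients & self.test_patients
        if overlap:
            raise ValueError(f"patients on both sides of the split: {sorted(overlap)}")
        allp = {f.patient_id for f in self.features}
        if self.train_patients | self.test_patients != allp:
            raise ValueError("split does not cover all patients exactly")

    def side_of(self, patient_id: str) -> str:
        return "test" if patient_id in self.test_patients else "train"


def stratified_patient_split(
    features: TSequence[PatientFeatures],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitResult:
    """Split patients into train/test by iterative multilabel stratification.

    Deterministic given ``(features, test_fraction, seed)``.
    """
    n = len(features)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    if not (0.0 < test_fraction < 1.0) or test_fraction * n < 1:
        raise ValueError(
            f"degenerate test_fraction {test_fraction} for {n} patients"
        )

    rng = np.random.default_rng(seed)
    sides = ("train", "test")
    fraction = {"train": 1.0 - test_fraction, "test": test_fraction}
    # Remaining overall capacity per side.
    capacity = {s: fraction[s] * n for s in sides}
    # Remaining desired carriers per (side, feature).
    label_count = {
        l: sum(f.has(l) for f in features) for l in LABEL_ORDER
    }
    demand = {s: {l: fraction[s] * label_count[l] for l in LABEL_ORDER} for s in sides}

    unallocated: dict[str, PatientFeatures] = {f.patient_id: f for f in features}
    if len(unallocated) != n:
        raise ValueError("duplicate patient ids in feature list")
    assigned: dict[str, str] = {}

    def eligible_sides() -> tuple[str, ...]:
        with_room = tuple(s for s in sides if capacity[s] > 1e-9)
        return with_room if with_room else sides

    def assign(pid: str, side: str) -> None:
        f = unallocated.pop(pid)
        assigned[pid] = side
        capacity[side] -= 1
        for l in LABEL_ORDER:
            if f.has(l):
                demand[side][l] -= 1

    def pick_side(scores: dict[str, float]) -> str:
        cand = eligible_sides()
        best = max(scores[s] for s in cand)
        cand = tuple(s for s in cand if scores[s] >= best - 1e-12)
        if len(cand) > 1:
            best_cap = max(capacity[s] for s in cand)
            cand = tuple(s for s in cand if capacity[s] >= best_cap - 1e-12)
        if len(cand) > 1:
            return cand[int(rng.integers(len(cand)))]
        return cand[0]

    while True:
        remaining_per_label = {
            l: [pid for pid, f in unallocated.items() if f.has(l)] for l in LABEL_ORDER
        }
        remaining_per_label = {l: p for l, p in remaining_per_label.items() if p}
        if not remaining_per_label:
            break
        rare = min(remaining_per_label, key=lambda l: (len(remaining_per_label[l]), l.value))
        pids = sorted(remaining_per_label[rare])
        rng.shuffle(pids)
        for pid in pids:
            assign(pid, pick_side({s: demand[s][rare] for s in sides}))

    # Featureless patients (cannot occur for retained scans, but be defensive).
    leftovers = sorted(unallocated)
    rng.shuffle(leftovers)
    for pid in leftovers:
        assign(pid, pick_side({s: capacity[s] for s in sides}))

    result = SplitResult(
        train_patients={p for p, s in assigned.items() if s == "train"},
        test_patients={p for p, s in assigned.items() if s == "test"},
        features=list(features),
        seed=seed,
        test_fraction=test_fraction,
    )
    result.combination_rows = combination_report(result)
    return result


def combination_report(
    split: SplitResult,
    combinations: Iterable[tuple[Label, ...]] = DEFAULT_COMBINATIONS,
) -> list[CombinationRow]:
    """Count, per side, patients carrying ALL features of each combination.

    ``ratio`` is ``n_test / n_train`` (0 when the test side is empty for the
    combination; NaN when the train side is).
    """
    rows = []
    for combo in combinations:
        n_train = n_test = 0
        for f in split.features:
            if all(f.has(l) for l in combo):
                if f.patient_id in split.test_patients:
                    n_test += 1
                else:
                    n_train += 1
        ratio = n_test / n_train if n_train else math.nan
        rows.append(CombinationRow(tuple(combo), n_train, n_test, ratio))
    return rows


def uniform_patient_split(
    features: TSequence[PatientFeatures],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitResult:
    """Uniformly random patient split of the same size — the baseline the
    stratified splitter is compared against."""
    n = len(features)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_test = max(1, int(round(test_fraction * n)))
    rng = np.random.default_rng(seed)
    pids = [f.patient_id for f in features]
    test = set(rng.choice(pids, size=n_test, replace=False).tolist())
    return SplitResult(
        train_patients=set(pids) - test,
        test_patients=test,
        features=list(features),
        seed=seed,
        test_fraction=test_fraction,
    )
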