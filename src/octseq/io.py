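"""CSV readers/writers for annotations, predictions and embeddings.

All files are UTF-8 CSV with a mandatory header.  The scan key columns are
``patient_id,eye,sequence_id,slice_index`` throughout, so annotation,
prediction and embedding tables align row-for-row on the same key.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import (
    LABEL_ORDER,
    ExcludedCategory,
    Label,
    ScanKey,
    ScanRecord,
    check_unique_keys,
)

KEY_COLUMNS = ["patient_id", "eye", "sequence_id", "slice_index"]
DEFAULT_LABEL_DELIMITER = "|"

_LABEL_TOKENS = {l.value for l in Label}
_EXCLUDED_TOKENS = {e.value for e in ExcludedCategory}


def load_annotations(
    path: str | os.PathLike,
    label_delimiter: str = DEFAULT_LABEL_DELIMITER,
) -> list[ScanRecord]:
    """Read an annotation CSV into validated :class:`ScanRecord` objects.

    Expected columns: ``patient_id,eye,sequence_id,slice_index,labels`` and
    optionally ``excluded``.  The ``labels`` cell is a delimiter-separated
    list of label tokens; it may be empty only when ``excluded`` is set.

    Raises
    ------
    ValueError
        On a missing column, an unknown label or excluded token, a duplicate
        scan key, or an empty label set on a retained scan — each naming the
        offending row.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "sequence_id": str})
    missing = [c for c in KEY_COLUMNS + ["labels"] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} is missing columns {missing}")
    has_excluded = "excluded" in df.columns
    records: list[ScanRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        raw = getattr(row, "labels")
        tokens = [] if pd.isna(raw) or raw == "" else str(raw).split(label_delimiter)
        labels = set()
        for tok in tokens:
            tok = tok.strip()
            if not tok:
                continue
            if tok not in _LABEL_TOKENS:
                raise ValueError(
                    f"unknown label {tok!r} at row {row_number} of {path}"
                )
            labels.add(Label(tok))
        excluded = None
        if has_excluded:
            raw_exc = getattr(row, "excluded")
            if not (pd.isna(raw_exc) or raw_exc == ""):
                if str(raw_exc) not in _EXCLUDED_TOKENS:
                    raise ValueError(
                        f"unknown excluded category {raw_exc!r} at row {row_number} of {path}"
                    )
                excluded = ExcludedCategory(str(raw_exc))
        try:
            records.append(
                ScanRecord(
                    patient_id=str(row.patient_id),
                    eye=str(row.eye),
                    sequence_id=str(row.sequence_id),
                    slice_index=int(row.slice_index),
                    labels=frozenset(labels),
                    excluded=excluded,
                )
            )
        except ValueError as err:
            raise ValueError(f"row {row_number} of {path}: {err}") from err
    check_unique_keys(records)
    return records


def annotations_to_frame(
    scans: Iterable[ScanRecord],
    label_delimiter: str = DEFAULT_LABEL_DELIMITER,
) -> pd.DataFrame:
    rows = []
    for s in scans:
        rows.append(
            {
                "patient_id": s.patient_id,
                "eye": s.eye,
                "sequence_id": s.sequence_id,
                "slice_index": s.slice_index,
                "labels": label_delimiter.join(
                    l.value for l in LABEL_ORDER if l in s.labels
                ),
                "excluded": "" if s.excluded is None else s.excluded.value,
            }
        )
    return pd.DataFrame(rows, columns=KEY_COLUMNS + ["labels", "excluded"])


def write_annotations(
    scans: Iterable[ScanRecord],
    path: str | os.PathLike,
    label_delimiter: str = DEFAULT_LABEL_DELIMITER,
) -> None:
    annotations_to_frame(scans, label_delimiter).to_csv(path, index=False)


def load_predictions(path: str | os.PathLike) -> dict[ScanKey, dict[Label, float]]:
    """Read a prediction CSV: scan key columns + one probability column per label."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sequence_id": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction file {path} is missing columns {missing}")
    label_cols = [l for l in LABEL_ORDER if l.value in df.columns]
    if not label_cols:
        raise ValueError(f"prediction file {path} has no label probability columns")
    preds: dict[ScanKey, dict[Label, float]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.patient_id), str(row.eye), str(row.sequence_id), int(row.slice_index))
        if key in preds:
            raise ValueError(f"duplicate prediction for scan {key} in {path}")
        probs = {l: float(getattr(row, l.value)) for l in label_cols}
        for l, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} for {l.value} of scan {key} outside [0, 1]")
        preds[key] = probs
    return preds


def write_predictions(
    preds: Mapping[ScanKey, Mapping[Label, float]],
    path: str | os.PathLike,
) -> None:
    rows = []
    for key in sorted(preds):
        probs = preds[key]
        row = dict(zip(KEY_COLUMNS, key))
        for l in LABEL_ORDER:
            if l in probs:
                row[l.value] = probs[l]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_embeddings(path: str | os.PathLike) -> tuple[list[ScanKey], np.ndarray]:
    """Read an embedding CSV (scan key columns + d numeric columns e0..e{d-1})."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sequence_id": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"embedding file {path} is missing columns {missing}")
    value_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    keys = [
        (str(r.patient_id), str(r.eye), str(r.sequence_id), int(r.slice_index))
        for r in df.itertuples(index=False)
    ]
    values = df[value_cols].to_numpy(dtype=float)
    return keys, values


def write_embeddings(
    keys: Iterable[ScanKey],
    values: np.ndarray,
    path: str | os.PathLike,
) -> None:
    keys = list(keys)
    values = np.asarray(values, dtype=float)
    if len(keys) != values.shape[0]:
        raise ValueError("number of keys does not match number of embedding rows")
    df = pd.concat(
        [
            pd.DataFrame(keys, columns=KEY_COLUMNS),
            pd.DataFrame(values, columns=[f"e{j}" for j in range(values.shape[1])]),
        ],
        axis=1,
    )
    df.to_csv(path, index=False)
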