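import pytest

from octseq import (
    Label,
    ScanRecord,
    Sequence,
    expand_cohort,
    filter_retained,
    load_cohort_fixture,
)


def make_scan(pid="P1", eye="OD", seq="v1", idx=0, labels=("HEALTHY",), excluded=None):
    return ScanRecord(
        patient_id=pid,
        eye=eye,
        sequence_id=seq,
        slice_index=idx,
        labels=frozenset(Label(l) for l in labels),
        excluded=excluded,
    )


def make_sequence(truths, pid="P1", eye="OD", seq="v1"):
    """Build a Sequence from a list of label-name tuples, slice-indexed 0..n."""
    scans = [make_scan(pid, eye, seq, i, labels) for i, labels in enumerate(truths)]
    return Sequence(key=(pid, eye, seq), scans=scans)


@pytest.fixture(scope="session")
def cohort_table():
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def expanded_scans(cohort_table):
    return expand_cohort(cohort_table, seq_len=25, seed=0)


@pytest.fixture(scope="session")
def retained_scans(expanded_scans):
    return filter_retained(expanded_scans)
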