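"""Synthetic cohorts, predictions and embeddings with the study's structure.

The study's OCT images are private, so every pipeline stage is exercised on
generated data that reproduces the statistical features the analyses assume:

* **Cohorts** — patients are healthy-type or DR-type; each eye contributes
  sequences of ~25 consecutive slices.  Within a DR sequence each biomarker
  occupies one contiguous run of slices (lesions fade in and out at run
  edges rather than flickering scan-by-scan), and HF accompanies DME on a
  configurable fraction of DME scans (default 0.95, the strong DME–HF
  co-occurrence seen in the study cohort).  Scans covered by no run are
  healthy.
* **Predictions** — a stand-in for a trained classifier: per scan and label
  the detection outcome is flipped according to configured sensitivity /
  specificity, then a score is drawn from a bounded Beta distribution on the
  corresponding side of 0.5, so thresholding at 0.5 recovers the configured
  rates in expectation and scores are valid probabilities without clipping.
* **Embeddings** — unit-norm vectors ``normalize(g + a·u_patient +
  b·v_class + σ·ε)`` sharing a global direction ``g``, a per-patient
  direction ``u`` common to both eyes (raising intra-patient cosine), a
  per-label-combination direction ``v`` and white noise.

All generators are fully deterministic under an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .records import EYES, Label, ScanKey, ScanRecord
from .similarity import EmbeddingMatrix


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study cohort where it states a value (25-slice
    sequences; 16 of 52 patients fully healthy ≈ 0.31; P(HF | DME) = 0.95)
    and plausible choices elsewhere (documented free parameters).
    """

    n_patients: int = 52
    fraction_healthy_patients: float = 16 / 52
    sequences_per_patient_eye: int = 2
    sequence_length: int = 25
    p_dr_sequence: float = 0.8  # P(a DR patient's sequence contains lesions)
    p_dme_sequence: float = 0.85  # P(DME present | DR sequence)
    p_nd_given_dme: float = 0.3  # P(an ND run occurs | DME run present)
    p_hf_given_dme: float = 0.95  # per-DME-scan HF coverage probability
    mean_run_length: float = 12.0  # mean lesion run length in slices
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_healthy_patients",
            "p_dr_sequence",
            "p_dme_sequence",
            "p_nd_given_dme",
            "p_hf_given_dme",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1 or self.sequences_per_patient_eye < 1:
            raise ValueError("counts must be >= 1")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if not (1.0 <= self.mean_run_length <= self.sequence_length):
            raise ValueError("mean_run_length must lie in [1, sequence_length]")
        n_healthy = int(round(self.fraction_healthy_patients * self.n_patients))
        if self.fraction_healthy_patients > 0 and n_healthy < 1:
            raise ValueError(
                "infeasible config: fraction_healthy_patients > 0 but no healthy "
                "patient fits the cohort size"
            )


def _run(rng: np.random.Generator, seq_len: int, mean_len: float) -> tuple[int, int]:
    """A contiguous run (start, length) with E[length] = mean_len, length >= 1."""
    length = 1 + rng.binomial(seq_len - 1, (mean_len - 1) / max(seq_len - 1, 1))
    start = int(rng.integers(0, seq_len - length + 1))
    return start, length


def _dr_sequence_labels(
    rng: np.random.Generator, cfg: CohortConfig
) -> list[frozenset[Label]]:
    """Label sets for one DR sequence; guaranteed to contain >= 1 biomarker scan."""
    n = cfg.sequence_length
    dme = np.zeros(n, dtype=bool)
    nd = np.zeros(n, dtype=bool)
    hf = np.zeros(n, dtype=bool)
    has_dme = rng.random() < cfg.p_dme_sequence
    if has_dme:
        d0, dlen = _run(rng, n, cfg.mean_run_length)
        dme[d0 : d0 + dlen] = True
        if rng.random() < cfg.p_nd_given_dme:
            # ND occupies a contiguous sub-run of the DME run (ND essentially
            # always co-occurs with DME in the study cohort).
            nlen = 1 + int(rng.integers(0, dlen))
            n0 = d0 + int(rng.integers(0, dlen - nlen + 1))
            nd[n0 : n0 + nlen] = True
        # HF covers Binomial(dlen, p) DME scans as one contiguous sub-run
        # anchored at a DME-run edge: the scan-level count of HF-covered DME
        # scans is then an exact binomial draw while the lesion stays
        # contiguous.  Anchoring at an edge lets the run extend outward past
        # the DME run without touching uncovered DME scans.
        k = int(rng.binomial(dlen, cfg.p_hf_given_dme))
        if k > 0:
            if rng.random() < 0.5:  # prefix of the DME run, may extend left
                hf[d0 : d0 + k] = True
                left = int(rng.integers(0, d0 + 1))
                hf[d0 - left : d0] = True
            else:  # suffix, may extend right
                hf[d0 + dlen - k : d0 + dlen] = True
                right = int(rng.integers(0, n - (d0 + dlen) + 1))
                hf[d0 + dlen : d0 + dlen + right] = True
    else:
        # No DME: the sequence is DR through an HF-only run.
        h0, hlen = _run(rng, n, cfg.mean_run_length)
        hf[h0 : h0 + hlen] = True
    out = []
    for i in range(n):
        labels = set()
        if dme[i]:
            labels.add(Label.DME)
        if nd[i]:
            labels.add(Label.ND)
        if hf[i]:
            labels.add(Label.HF)
        out.append(frozenset(labels) if labels else frozenset({Label.HEALTHY}))
    return out


def generate_cohort(cfg: CohortConfig) -> list[ScanRecord]:
    """Generate a full synthetic cohort of annotated scans.

    Healthy-type patients carry only HEALTHY scans; DR-type patients mix DR
    sequences (contiguous biomarker runs, healthy margins) with entirely
    healthy sequences.  Output always satisfies the scan-record invariants.
    """
    rng = np.random.default_rng(cfg.seed)
    n_healthy = int(round(cfg.fraction_healthy_patients * cfg.n_patients))
    records: list[ScanRecord] = []
    for i in range(cfg.n_patients):
        healthy_patient = i < n_healthy
        pid = f"{'H' if healthy_patient else 'D'}{i:03d}"
        forced_dr: tuple[str, int] | None = None
        if not healthy_patient:
            # Guarantee the DR type: one designated sequence is always DR.
            eye = EYES[int(rng.integers(2))]
            forced_dr = (eye, int(rng.integers(cfg.sequences_per_patient_eye)))
        for eye in EYES:
            for j in range(cfg.sequences_per_patient_eye):
                if healthy_patient:
                    is_dr = False
                else:
                    is_dr = (eye, j) == forced_dr or rng.random() < cfg.p_dr_sequence
                if is_dr:
                    labels = _dr_sequence_labels(rng, cfg)
                else:
                    labels = [frozenset({Label.HEALTHY})] * cfg.sequence_length
                for k, lab in enumerate(labels):
                    records.append(
                        ScanRecord(
                            patient_id=pid,
                            eye=eye,
                            sequence_id=f"s{j:03d}",
                            slice_index=k,
                            labels=lab,
                        )
                    )
    return records


@dataclass
class LabelNoise:
    """Per-label detection noise: error rates + bounded score shapes.

    ``alpha``/``beta`` parameterize the Beta draw mapped onto [0.5, 1] for a
    positive detection and mirrored onto [0, 0.5) for a negative one; larger
    ``alpha/beta`` pushes scores away from the threshold.
    """

    sensitivity: float = 0.9
    specificity: float = 0.9
    alpha: float = 4.0
    beta: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must be in [0, 1]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")


@dataclass
class PredictionNoiseConfig:
    """Noise model standing in for a trained multilabel classifier.

    ``healthy_mode="coupled"`` (default) sets the healthy probability to
    ``1 − max(biomarker scores)``, mimicking a model that never predicts
    healthy together with a biomarker; ``"independent"`` treats HEALTHY as a
    fourth independent label with its own noise.
    """

    per_label: dict[Label, LabelNoise] = field(
        default_factory=lambda: {l: LabelNoise() for l in Label}
    )
    healthy_mode: str = "coupled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.healthy_mode not in ("coupled", "independent"):
            raise ValueError(f"unknown healthy_mode {self.healthy_mode!r}")
        for l in Label:
            self.per_label.setdefault(l, LabelNoise())


def _draw_score(rng: np.random.Generator, noise: LabelNoise, positive: bool) -> float:
    u = rng.beta(noise.alpha, noise.beta)
    return 0.5 + 0.5 * u if positive else 0.5 * (1.0 - u)


def simulate_predictions(
    scans: list[ScanRecord],
    cfg: PredictionNoiseConfig,
) -> dict[ScanKey, dict[Label, float]]:
    """Draw per-scan label probabilities with configured error rates.

    For each scan and biomarker, the thresholded outcome is a Bernoulli draw
    with success probability ``sensitivity`` (label truly present) or
    ``1 − specificity`` (absent); the score is then drawn from the Beta
    distribution on the matching side of 0.5.
    """
    rng = np.random.default_rng(cfg.seed)
    biomarkers = (Label.DME, Label.ND, Label.HF)
    preds: dict[ScanKey, dict[Label, float]] = {}
    for s in scans:
        probs: dict[Label, float] = {}
        for label in biomarkers:
            noise = cfg.per_label[label]
            present = label in s.labels
            positive = rng.random() < (
                noise.sensitivity if present else 1.0 - noise.specificity
            )
            probs[label] = _draw_score(rng, noise, positive)
        if cfg.healthy_mode == "coupled":
            probs[Label.HEALTHY] = 1.0 - max(probs[l] for l in biomarkers)
        else:
            noise = cfg.per_label[Label.HEALTHY]
            present = Label.HEALTHY in s.labels
            positive = rng.random() < (
                noise.sensitivity if present else 1.0 - noise.specificity
            )
            probs[Label.HEALTHY] = _draw_score(rng, noise, positive)
        preds[s.key] = probs
    return preds


@dataclass
class EmbeddingConfig:
    """Parameters of the structured embedding generator.

    ``patient_effect`` scales the per-patient shared direction (drives the
    intra-patient > inter-patient similarity gap); ``disease_effect`` scales
    the per-label-combination direction; ``noise_scale`` the white noise.
    Dimension defaults to 768, a typical backbone feature size.
    """

    dimension: int = 768
    patient_effect: float = 0.6
    disease_effect: float = 0.4
    noise_scale: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.patient_effect < 0 or self.disease_effect < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")


def _unit(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def generate_embeddings(scans: list[ScanRecord], cfg: EmbeddingConfig) -> EmbeddingMatrix:
    """Unit-norm embeddings with global, patient, disease-class and noise terms."""
    rng = np.random.default_rng(cfg.seed)
    d = cfg.dimension
    g = _unit(rng, d)
    patient_dirs: dict[str, np.ndarray] = {}
    class_dirs: dict[frozenset[Label], np.ndarray] = {}
    for pid in sorted({s.patient_id for s in scans}):
        patient_dirs[pid] = _unit(rng, d)
    for combo in sorted({s.labels for s in scans}, key=lambda c: sorted(l.value for l in c)):
        class_dirs[combo] = _unit(rng, d)
    rows = np.empty((len(scans), d))
    for i, s in enumerate(scans):
        v = (
            g
            + cfg.patient_effect * patient_dirs[s.patient_id]
            + cfg.disease_effect * class_dirs[s.labels]
            + cfg.noise_scale * rng.standard_normal(d) / math.sqrt(d)
        )
        rows[i] = v / np.linalg.norm(v)
    return EmbeddingMatrix(keys=[s.key for s in scans], values=rows)
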