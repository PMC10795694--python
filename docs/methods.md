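# Methods

## Data model

A `ScanRecord` identifies one B-scan by `(patient_id, eye, sequence_id,
slice_index)` and carries a set of true labels over {DME, ND, HF, HEALTHY}.
Invariants enforced at construction: the key 4-tuple is unique in a dataset,
HEALTHY never co-occurs with a biomarker in a *true* label set, and a
retained scan's label set is non-empty.  Scans with non-DR-specific
pathology (CNV, epiretinal membrane, hemorrhage, each combined with DR) or
acquisition artifacts carry an `ExcludedCategory` and are removed by
`filter_retained` before every analysis.  A `Sequence` is the ordered,
non-empty list of scans sharing `(patient_id, eye, sequence_id)`; eyes are
encoded OD (right) / OS (left), slice indices are 0-based, and the CSV label
delimiter is `|` (configurable).

## The packaged cohort table

The study cohort is available only as a per-patient table of scan counts in
ten categories.  The published rendering of that table has internally
inconsistent column headers, so the packaged fixture adopts the unique
category assignment whose column totals (2, 229, 1287, 274, 54, 23, 533,
43, 27, 510) simultaneously reproduce *all* published aggregates: 2660
retained scans, per-biomarker counts DME 1615 = 1287 + 274 + 54, ND 330 =
2 + 274 + 54, HF 2096 = 2 + 1287 + 274 + 533, 510 healthy scans, and the
per-patient narratives (C06: 240 DME+HF, 141 HF, 13 healthy; M17: 164
DME+HF, 99 HF).  A consistency oracle re-derives these aggregates on every
load and hard-errors on any mismatch.  Two published numbers disagree with
the table itself: a stated total of 2980 images (the table sums to 2982)
and a claim of 54 HF-only scans (consistent reading: 533 HF-only, 54
DME+ND); the table is taken as ground truth and the discrepancy is left
visible rather than patched.

`expand_cohort` turns counts into per-scan records by shuffling each
patient's category cells under a seed and packing them into synthetic
sequences of at most 25 slices (the acquisition's slices-per-retina),
alternating eyes per sequence.  The expansion conserves counts exactly
(`tabulate ∘ expand_cohort` is the identity) and is deterministic under the
seed.  Sequence structure in the expansion is a modelling convenience — the
count table carries none — so sequence-level metric behaviour is exercised
on synthetic cohorts and annotation CSVs, not on the fixture.

## Cohort summary

`summarize` reports scan counts per label, patient counts per feature
(≥1 scan with the label), fully-healthy and mixed patient counts, the mean
biomarker multiplicity over DR scans (Σ |biomarkers(s)| / #DR scans) and
P(HF | DME) = #(DME ∧ HF scans) / #(DME scans).  On the packaged cohort
these compute to 1.8795... and 0.96656...; the source tables round them to
1.87 and "95 %".  Values are kept at full precision internally and rounded
to two decimals only in display output.  A cohort with no DR scans reports
the multiplicity as NaN (missing), never 0.

## Patient split

The splitter operates on patients, never scans, so no patient's scans leak
across sides.  Patients are described by the 4-bit feature vector
F_patients and allocated by iterative stratification (greedy
rarest-label-first): repeatedly take the feature with the fewest remaining
unallocated carriers, and assign each carrier to the side with the greater
remaining demand for that feature; ties break by remaining overall
capacity, then by a seeded draw.  Side capacities (`test_fraction · n` and
its complement) are enforced, which pins the test-side size to the floor or
ceiling of the target.  Defaults: `test_fraction = 0.2`, matching the
0.13–0.21 test/train ratios the study reports for its own split.  That
split itself is not reproducible (unknown seed and algorithm), so published
per-side counts are used only as combination *totals* (train + test) and as
the report layout: the combination report counts, per side, patients
carrying all features of each requested combination (default: the four
single features and six pairs) with ratio `n_test / n_train` (0 when the
test side is empty, missing when the train side is).

## Sequence metrics

SeqAcc, exact-match SeqAcc and SeqIoU are implemented as documented in the
README.  Numerical and convention choices:

* Threshold boundary: `p >= threshold` counts as present (fixed for
  determinism; the convention at exactly 0.5 is otherwise arbitrary).
* `scan_iou(∅, ∅) = 1` — vacuous agreement.  True label sets are non-empty
  for retained scans, so this is purely defensive.
* Standard deviations use sequences as the sample unit with the n−1
  denominator; a stratum with one sequence reports NaN, a stratum with none
  reports missing means.
* Strata are defined by *patient* type (healthy-type patients have only
  HEALTHY scans dataset-wide), not by sequence content.
* HEALTHY is a fourth independent label in multilabel mode; predicted sets
  combining HEALTHY with a biomarker are legal but logged as warnings.
* The binary (healthy-vs-DR) report accepts a dedicated `DR` probability
  column, or reduces multilabel predictions by "DR iff any biomarker
  predicted" — an artifact convenience, since the study trained a separate
  binary model.  Binary per-scan IoU is 0/1, so binary SeqIoU is the
  per-sequence fraction of correctly classified scans.
* ROC AUC is computed from raw per-scan probabilities (no sequence
  averaging) as the tie-corrected rank statistic, delegated to
  scikit-learn; labels with single-class support report NaN.  Tests verify
  it against an independent brute-force pairwise oracle.

All metric implementations are verified against naive double-loop
recomputation on random micro-datasets to 1e-12, and satisfy: correcting
any single wrong scan never decreases any sequence metric; stratum means
recombine (weighted by sequence counts) to the overall mean.

## Embedding similarity

Embeddings are consumed from file, one fixed-dimension vector per scan
(extracting them from images is out of scope).  For each patient, the
intra-patient mean is the average cosine over the full OS × OD Cartesian
product of the patient's scans — patients with one represented eye report
missing and are excluded from the cohort intra aggregate — and the
inter-patient mean averages over all pairs with other patients' scans, both
eyes included.  Cohort mean and std are taken *across patients* (each
patient contributes one intra and one inter mean); the source analysis
reports per-patient histograms and its inter-patient std (0.03) is
consistent with across-patient aggregation, but since the aggregation unit
is not stated, pooled raw-pair aggregation is available behind
`aggregate="pairs"`.  Patients with intra-patient mean below an alert
threshold (default 0.6, the level the study flags) are listed in the
report.  Cosine values are clipped to [−1, 1] against rounding.

## Synthetic data

The generators make every pipeline stage testable without the private
images; their defaults are the study's stated conditions where it states
any, and documented free choices elsewhere.

**Cohorts.**  Defaults: 52 patients, 16/52 fully healthy, 25-slice
sequences, 2 sequences per eye, P(HF | DME) = 0.95.  Free parameters
(plausible choices, no published values exist): P(DR sequence | DR patient)
= 0.8, P(DME | DR sequence) = 0.85, P(ND run | DME run) = 0.3 (ND
essentially always co-occurs with DME in the cohort table), mean lesion run
length 12 slices.  Within a DR sequence each biomarker occupies one
contiguous run — lesions appear and fade along neighbouring slices rather
than flickering — which is the simplest structure that makes sequence-level
metrics behave differently from pooled per-scan metrics.  HF coverage of a
DME run of length L is drawn as Binomial(L, p) scans placed as one
contiguous sub-run anchored at a run edge (extensions grow outward past the
edge), so the scan-level empirical P(HF | DME) is an exact binomial
proportion with n = total DME scans — the recovery tests' binomial
standard-error oracle is therefore exact, not approximate.  Scans covered
by no run are HEALTHY; a DR patient always has at least one DR sequence; a
sequence without DME is made DR by an HF-only run.

**Predictions.**  Per scan and label, the thresholded outcome is a
Bernoulli draw at the configured sensitivity (label present) or
1 − specificity (absent); the score is then drawn from a two-parameter Beta
distribution mapped onto [0.5, 1] (positive) or mirrored onto [0, 0.5)
(negative), guaranteeing valid probabilities without clipping and exact
rate recovery in expectation at threshold 0.5.  The healthy score defaults
to `1 − max(biomarker scores)` ("coupled" mode), mimicking the observed
behaviour that a trained model never predicts healthy together with a
biomarker; an "independent" mode treats HEALTHY as a fourth noisy label for
stress testing.  In coupled mode the healthy label's error rates are
implied (≈ specificity³ for sensitivity on healthy scans), not configured.

**Embeddings.**  `normalize(g + a·u_patient + b·v_class + σ·ε)` with a
global direction g, a per-patient unit direction u shared by both eyes, a
per-label-combination direction v, and white noise ε scaled by σ/√d.
Defaults d = 768 (a typical backbone feature size), a = 0.6, b = 0.4,
σ = 0.8, giving a clear intra > inter ordering without saturating cosines.
With a = b = 0 the scans are exchangeable across patients and intra ≈ inter
(null check); the intra − inter gap is monotone in a.

All generators use a single integer-seeded NumPy `default_rng`; no
time-based entropy anywhere.

## What passing tests do and do not show

The synthetic cohort reproduces the *statistical* structure the analyses
assume — patient types, contiguous lesion runs, DME–HF co-occurrence,
patient-coherent embeddings — not the optics of OCT: no pixel data, no
acquisition artifacts, no annotation disagreement, no within-patient
disease progression across visits.  Parameter-recovery results validate the
pipeline's arithmetic end to end; they say nothing about any real
classifier's performance, and the published performance tables of the
source study are not reproducible without its private images and trained
models.

## Problem sizes

The test suite and the acceptance script run on the 52-patient packaged
cohort (2982 scans), simulation cohorts of 50 patients / 5000 scans for
rate recovery, 250 patients for co-occurrence recovery, and 15–20 patients
at embedding dimension 64–128 for similarity checks — sizes at which the
binomial oracles are tight (3 SE ≈ 1–3 percentage points) while the whole
suite completes in seconds.
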