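# octseq

Sequence-level evaluation of multilabel OCT B-scan biomarker annotations.

Optical coherence tomography (OCT) screening for diabetic macular edema (DME)
produces *sequences* of consecutive cross-sectional B-scans per eye
(incomplete volumes, typically 25 slices).  Each scan is annotated with a set
of labels drawn from three DME biomarkers — intraretinal cystoid edema (DME),
subfoveal neurosensory detachment (ND), hyperreflective foci (HF) — plus
HEALTHY.  Classical per-scan metrics ignore the volume structure, yet
clinically a classifier that flags a biomarker *somewhere* in every affected
sequence is preferable to one that is perfect on some volumes and blind on
others.  `octseq` is a library and CLI for analysts working with such
annotations: cohort characterization, patient-disjoint stratified splitting,
sequence-level evaluation metrics, embedding-similarity analysis, and a
synthetic-data generator so the whole pipeline is testable without private
images.

## The metrics

Predictions are per-scan label probabilities, binarized at a threshold
(default 0.5, a probability exactly at the threshold counts as present).
With sequences `seq` and labels `l`:

* **SeqAcc** — per-label accuracy aggregated first within each sequence,
  then across sequences:

      SeqAcc_l(seq) = (TP_l + TN_l) / (TP_l + TN_l + FP_l + FN_l)   over scans of seq
      SeqAcc_l      = mean over sequences of SeqAcc_l(seq)

  An *exact-match* variant counts a scan as correct only when its entire
  predicted label set equals the truth.

* **SeqIoU** — the Jaccard index between the true set `c_s` and the
  predicted set `ĉ_s` of each scan, averaged within and then across
  sequences:

      IoU(s)      = |c_s ∩ ĉ_s| / |c_s ∪ ĉ_s|
      SeqIoU(seq) = mean over scans s of IoU(s)
      SeqIoU      = mean over sequences of SeqIoU(seq)

  reported overall and stratified into `SeqIoU_H` / `SeqIoU_DR` by patient
  type (a DR patient has at least one biomarker-bearing scan).  With
  singleton label sets IoU is 0/1 and SeqIoU reduces to exact-match SeqAcc;
  with all sequences of length 1, SeqAcc is classical accuracy.

Supporting analyses: per-label precision/recall/F1/sensitivity/specificity
and ROC AUC; patient-disjoint train/test splitting by iterative multilabel
stratification over the 4-bit patient feature vector `F_patients` (≥1 DME /
ND / HF / healthy scan); and intra-patient (left × right eye) vs
inter-patient cosine similarity of scan embeddings.

The package ships the study cohort as a per-patient count table (52
patients, 2982 scans, 2660 retained after excluding CNV/ERM/hemorrhage/
artifact scans), validated on load against its published aggregates.

## Worked example

```python
import octseq

table = octseq.load_cohort_fixture()          # 52-patient count table
scans = octseq.expand_cohort(table, seed=0)   # per-scan records
retained = octseq.filter_retained(scans)
s = octseq.summarize(retained)
print(s.n_scans_retained)                     # 2660
print(s.per_biomarker_scan_counts)            # DME 1615, ND 330, HF 2096, HEALTHY 510
print(round(s.mean_biomarkers_per_dr_scan, 4))# 1.8795
print(round(s.p_hf_given_dme, 4))             # 0.9666
```

2660 scans survive exclusion; 1615 carry DME, 330 ND, 2096 HF and 510 are
healthy.  DR scans carry on average 1.8795 biomarkers, and 96.66 % of scans
with DME also show HF — the strong DME–HF co-occurrence that motivates
set-valued (Jaccard) evaluation.  The metric itself:

```python
from octseq import Label, scan_iou
scan_iou({Label.DME, Label.ND}, {Label.DME, Label.HF})   # 0.3333...
```

One correctly predicted label out of a three-label union gives IoU = 1/3.

The same pipeline runs from a shell:

```sh
octseq summarize --out-dir reports/
octseq simulate --n-patients 20 --out-dir sim/
octseq evaluate --annotations sim/annotations.csv --predictions sim/predictions.csv --out-dir reports/
octseq similarity --annotations sim/annotations.csv --embeddings sim/embeddings.csv --out-dir reports/
```

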