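# l3muscle

Validation toolkit for automated skeletal-muscle segmentation on axial CT at
the third lumbar vertebra (L3) — the standard single-slice level for
whole-body muscle-mass estimation in sarcopenia and cancer-cachexia research.

Automated L3 muscle models (typically nnU-Net-style networks trained on
public datasets) produce raw masks that need post-processing before muscle
area can be quantified: arm muscles must be excluded for subjects scanned
arms-down, and adipose tissue/fascia wrongly included by coarse training
annotations must be removed by Hounsfield-unit (HU) thresholding.  This
package implements that post-processing, the agreement metrics used to
validate it, and the subgroup statistics that probe where the model fails —
plus a synthetic L3 phantom generator so the whole pipeline can be exercised
and tested without clinical data.

## What it computes

For a reference mask and a model mask with pixel area `A` (cm²/pixel):

- **Dice similarity coefficient** — `DSC = 2·TP / (2·TP + FP + FN)`,
  equivalently `1 − (FP+FN)/(2·TP+FP+FN)`.
- **Segmentation surface error** — `SSE = (FP + FN) · A` in cm², the
  physical area of the disagreement region.
- **Muscle surface area** — foreground count × `A`, summarised as
  median (IQR) over a cohort.
- **Bland–Altman agreement** — mean of paired area differences with limits
  of agreement at mean ± 1.96 SD.

Mask post-processing follows the two-step scheme used in external-validation
studies: DBSCAN over foreground pixel coordinates (ε = 10 px, minimum
cluster size 5) with selection of the centrally located cluster to discard
arm muscles, followed by removal of pixels below an HU threshold.  The
operating threshold is selected by sweeping integer cuts over −60…0 HU and
maximising the cohort median DSC.

Subgroup analysis runs the usual nonparametric battery over subject
covariates: Spearman rank correlations (age, BMI; |ρ| < 0.40 weak,
0.40–0.69 moderate, ≥ 0.70 strong), Mann–Whitney U (sex, IV contrast,
arm position, GLIM underweight status), Kruskal–Wallis with pairwise
follow-up (cancer type, grade, comorbidity index), and Fisher exact tests
on error-class prevalence, all at p < 0.05.

## Worked example

```python
import numpy as np
from l3muscle import (ErrorProfile, SegmentationPair, generate_cohort,
                      generate_phantom, simulate_model_mask, sweep_threshold,
                      postprocess)
from l3muscle.metrics import evaluate_pair, bland_altman

subjects = generate_cohort(30, seed=7)
pairs, phantoms, raws = [], [], []
for i, s in enumerate(subjects):
    ph = generate_phantom(s, seed=100 + i)
    raw = simulate_model_mask(ph, ErrorProfile(), seed=200 + i)
    phantoms.append(ph); raws.append(raw)
    pairs.append((ph.reference_mask, raw, ph.slice))

sweep = sweep_threshold(pairs)          # derive the operating HU cut
print(f"optimal threshold: {sweep.optimal_threshold} HU")

metrics = []
for ph, raw in zip(phantoms, raws):
    pred = postprocess(raw, ph.slice, threshold=sweep.optimal_threshold)
    metrics.append(evaluate_pair(
        SegmentationPair(ph.reference_mask, pred, ph.slice.pixel_area_cm2)))

dsc = np.median([m.dsc for m in metrics])
sse = np.median([m.sse for m in metrics])
ba = bland_altman([m.ref_area for m in metrics], [m.pred_area for m in metrics])
print(f"median DSC: {dsc:.3f}   median SSE: {sse:.3f} cm^2")
print(f"Bland-Altman mean difference {ba.mean_difference:.3f} cm^2 "
      f"(LoA {ba.loa_lower:.3f} to {ba.loa_upper:.3f})")
```

Output:

```
optimal threshold: 0 HU
median DSC: 0.986   median SSE: 3.667 cm^2
Bland-Altman mean difference -2.654 cm^2 (LoA -4.021 to -1.287)
```

The sweep lands at 0 HU because the synthetic fascia fringe sits entirely
below −30 HU while muscle sits above +20 HU: every cut inside that gap
removes the full fringe, and ties resolve toward the most aggressive
adipose exclusion.  The median DSC ≈ 0.99 after thresholding reflects the
residual boundary jitter; the small negative mean area difference says the
post-processed model slightly under-calls muscle on this cohort.

## Command line

```sh
l3muscle simulate --n 50 --seed 1 --out cohort/          # synthetic bundle
l3muscle run --manifest cohort/manifest.csv --sweep --out results/
l3muscle report --bundle results/ --out report.md
```

`run` writes `metrics.csv` (per-subject TP/FP/FN, DSC, SSE, areas),
`sweep.csv`, `subgroups.csv` (the statistical battery), `review.csv`
(lowest-DSC-quartile error attribution), `exclusions.csv` and
`report.json`; identical inputs and seed reproduce the bundle byte for
byte.  `postprocess`, `sweep`, `evaluate` and `subgroups` expose the
individual stages.

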