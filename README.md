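# hepquant

Volumetric quantification of hepatobiliary contrast-agent (Gd-EOB-DTPA /
gadoxetate) uptake in liver lesions, built around T1 relaxometry rather than
signal-intensity ratios.

Functioning hepatocytes import gadoxetate through the OATP1B1/B3 transporters,
and the accumulated gadolinium shortens the tissue's T1 relaxation time. As
hepatocellular carcinoma (HCC) dedifferentiates, OATP1B3 expression falls and
uptake drops, so the fractional T1 change between the native scan and the
hepatobiliary phase (HBP, ~20 min post-injection),

```
RR = (T1_plain − T1_HBP) / T1_plain,
```

carries information about tumor grade (G1 well, G2 moderately, G3 poorly
differentiated). `hepquant` implements the whole measurement chain and the
statistics used to turn it into a grade discriminator:

* **relaxometry** — steady-state spoiled-gradient-echo (SPGR) signal model and
  the DESPOT1 variable-flip-angle T1 fit (flips 1°/7°/14°, TR 5.79 ms by
  default), voxelwise with relative-B1 transmit-field correction; NIfTI I/O.
* **segmentation** — lesion contours drawn on every second axial slice,
  shape-based interpolation of the missing slices via signed distance
  transforms, center-in-polygon rasterization, volumetry (area × slice
  thickness) and masked mean-T1 extraction with invalid-voxel accounting.
* **quantify** — the reduction rate, computed on masked per-phase means.
* **irs** — the semiquantitative OATP1B3 immunoreactive score: percent-positive
  category (0–4) × staining-intensity category (0–3), binned
  negative/low/medium/high.
* **stats** — grouped summaries (mean ± SD, median [q1; q3] with the
  weighted-average quantile convention), Kruskal–Wallis with rank-based
  post-hoc pairwise comparisons, Mann–Whitney and Wilcoxon signed-rank tests
  with exact small-sample enumeration, ROC analysis with the Youden-index
  optimal cutoff and sensitivity/specificity/PPV/NPV.
* **cohort** — an embedded 33-lesion HCC reference cohort (grade, pathology
  reads, reduction rate, volume, Ishak fibrosis stage) plus the study's
  eligibility filter.
* **synthetic** — seeded generators for grade-conditional cohorts and digital
  SPGR phantoms (smooth B1 field, Gaussian/Rician noise) so every stage is
  testable end to end without patient data.

## Worked example

```python
import numpy as np
import hepquant as hq

cohort = hq.reference_cohort()
rr = np.array([r.reduction_rate for r in cohort])
grades = np.array([r.grade for r in cohort], dtype=object)

for grade, s in hq.group_summary(rr, grades).items():
    print(f"{grade}: n={s.n}  RR {s.mean:.2f} +/- {s.sd:.2f}")

roc = hq.roc_analysis(rr, grades == "G1")
print(f"AUC {roc.auc:.3f}, cutoff {roc.cutoff:.3f} -> "
      f"sens {roc.sensitivity:.0f}%, spec {roc.specificity:.0f}%")
```

prints

```
G1: n=14  RR 0.40 +/- 0.15
G2: n=14  RR 0.26 +/- 0.07
G3: n=5  RR 0.25 +/- 0.07
AUC 0.791, cutoff 0.385 -> sens 50%, spec 100%
```

Well-differentiated lesions take up substantially more contrast (higher RR);
calling a lesion G1 whenever its reduction rate reaches 0.385 catches half of
the G1 lesions with no false positives (PPV 100%, NPV 73%). The `examples/`
directory holds one short script per capability (cohort analysis, T1 mapping
on a phantom, segmentation/volumetry, IRS scoring, simulation + recovery),
each printing the numbers it computes.

A thin CLI mirrors the stages:

```sh
hepquant fit-t1 --flip plain_1.nii:1 --flip plain_7.nii:7 --flip plain_14.nii:14 \
         --b1 b1.nii --tr 5.79 --out t1_plain.nii
hepquant rr --plain t1_plain.nii --hbp t1_hbp.nii --mask contours.json
hepquant roc            # ROC on the embedded cohort
hepquant simulate cohort --seed 7 --out cohort.csv
hepquant run --out report.json
```

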