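# glenovol

Glenohumeral joint volumetry from CT arthrography, with the statistics that
typically accompany it in clinical shoulder research.

After arthroscopic rotator cuff repair, capsular contracture can shrink the
joint capsule and limit passive range of motion (ROM).  CT arthrography (CTA)
fills the capsule with a standardized contrast volume, so the segmented
contrast measures the joint volume — overall, and per anatomical compartment.
`glenovol` implements that measurement chain and its downstream analysis for
researchers who have segmented (or segmentable) CTA volumes, three scapular
landmarks, and per-patient ROM tables:

1. **Scapular frame** — the plane through the angulus inferior, trigonum
   scapulae, and glenoid center is the scapular (coronal) plane; its unit
   normal â points anteriorly, the in-plane medial-border direction ŝ points
   superiorly, and l̂ = â × ŝ.  The glenoid center is the origin.
2. **Segmentation and volumetry** — seeded, thresholded region growing
   (voxels ≥ threshold, 26-connected to a seed) labels the intra-articular
   contrast; the total joint volume is `Vol.TJ = N·Δx·Δy·Δz / 1000` mL.
3. **Clock-face quadrants** — each labeled voxel is classified by the sign of
   its (a, s) frame coordinates into the anteroinferior (AIQ, 6–9 h),
   anterosuperior (ASQ, 9–12 h), posterosuperior (PSQ, 12–3 h), and
   posteroinferior (PIQ, 3–6 h) compartments, with half-open clock sectors so
   AIQ + ASQ + PSQ + PIQ = Vol.TJ exactly.
4. **Statistics** — Table-style descriptives (mean ± SD, range); Pearson
   correlations r with two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df for
   each motion (scaption Sc, external rotation at side ERs and at 90° ER90,
   internal rotation on back IRb as the vertebral-level score buttock = 1,
   L5..L1 = 2..6, T12..T1 = 7..18) against each volume column; reliability as
   ICC(2,1) (two-way random effects, absolute agreement, single measures)
   with the 0.5 / 0.75 / 0.9 category thresholds.
5. **Synthetic data** — capsule phantoms with analytically known volumes
   (spheres, shells, offset spheres cut by the coronal plane into spherical
   caps) and Gaussian-copula cohort/rater simulators, so the whole pipeline
   is testable without patient data.

Volumes and masks are read/written as NIfTI/NRRD, landmarks as Slicer
markups (`.mrk.json`, `.fcsv`) or plain CSV, cohorts as CSV; all geometry is
handled internally in the LPS patient-space convention.

## Worked example

```python
from glenovol import VolumeROMModel, ReliabilityModel
from glenovol.simulate import (CohortSimConfig, RaterSimConfig,
                               simulate_cohort, simulate_raters)

cohort = simulate_cohort(CohortSimConfig(n=83, seed=7))
print(VolumeROMModel(cohort).fit().summary())
print(ReliabilityModel(simulate_raters(
    RaterSimConfig(n_subjects=83, error_sd=1.0, seed=8))).fit().summary())
```

prints

```
Joint volume vs range of motion
==========================================================
patients: 83

Cohort summary (mean +/- SD, range)
----------------------------------------------------------
      Vol.TJ     10.24 +/-   3.20  (4.13-19.40)  n=83
     Vol.AIQ      2.08 +/-   1.04  (0.01-4.66)  n=83
     Vol.ASQ      2.23 +/-   0.82  (0.51-4.47)  n=83
     Vol.PSQ      2.66 +/-   1.21  (0.35-5.47)  n=83
     Vol.PIQ      3.27 +/-   1.23  (0.48-6.22)  n=83
          Sc    161.05 +/-  17.72  (103.60-180.00)  n=83
         ERs     46.48 +/-  16.56  (5.07-87.56)  n=83
        ER90     82.15 +/-  14.39  (46.99-117.16)  n=83
         IRb      7.20 +/-   3.57  (1.00-18.00)  n=83

Pearson correlations, motion x volume (* p < 0.05)
----------------------------------------------------------
              Vol.TJ     Vol.AIQ     Vol.ASQ     Vol.PSQ     Vol.PIQ
      Sc     0.42*       0.38*       0.21        0.36*       0.28*
     ERs     0.23*       0.28*       0.15        0.19        0.08
    ER90     0.36*       0.27*       0.15        0.37*       0.25*
     IRb     0.42*       0.37*       0.18        0.37*       0.30*

p-values are two-sided and unadjusted for multiplicity.
Measurement reliability
========================================
subjects: 83   raters: 2 (rater1, rater2)
ICC model: two-way random effects, absolute agreement, single measures (ICC(2,1))
ICC = 0.932  ->  excellent reliability
```

The summary reads like a clinical demographics table: each volume compartment
in mL, each motion in degrees (IRb in scale points), and the correlation grid
showing which compartment volumes track which motions in this simulated
83-patient cohort (starred cells are significant at p < 0.05).  The ICC block
reports how reproducibly two raters would recover the same volumes given a
1 mL measurement error on a cohort with ≈3.2 mL between-patient SD.

The same analysis runs from the shell on real or simulated data:

```sh
glenovol phantom --seed 1 --out ph/                       # synthetic CTA + landmarks
glenovol measure --volume ph/phantom.nii \
    --fiducials ph/phantom.mrk.json --seed-point 0,-10,0 \
    --threshold 150 --out cohort_volumes.csv              # one volume row
glenovol simulate --n 200 --seed 2 --out cohort.csv       # simulated cohort
glenovol analyze --cohort cohort.csv --out report.json    # summary + correlation report
glenovol run --seed 7 --out demo/                         # full chain, one command
```

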