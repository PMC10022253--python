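# Methods

## The measurement model

CT arthrography outlines the glenohumeral capsule with contrast injected to a
standardized 20 mL total (12.5 mL saline + 6 mL iopromide + 1.5 mL
mepivacaine); equal filling makes post-operative joint volume comparable
across patients and interpretable as a proxy for capsular contracture.
`glenovol` treats volumetry as label-map counting: a segmentation assigns
each voxel to contrast or background, and volume is the labeled-voxel count
times the voxel volume.  No partial-volume weighting or mesh estimation is
used; this matches label-map "segment statistics" practice, and it is what
makes the quadrant partition conserve volume exactly.

### Scapular coordinate frame

Three fiducials define the frame: angulus inferior (AI), trigonum scapulae
(TS), glenoid center (GC).  The plane through them is the scapular (coronal)
plane.  In LPS patient coordinates:

- anterior axis â = unit normal of the plane, signed so its y component is
  negative (anterior).  Valid while the scapula is in a roughly anatomical
  pose; the sign rule is what anchors "anterior" without a fourth landmark.
- superior axis ŝ = direction AI→TS (the medial border, in-plane by
  construction) orthogonalized against â, signed so its z component is
  positive.  If |ŝ_z| < 0.1 the pose is implausible and an
  `OrientationWarning` is issued (the frame is still returned).
- lateral axis l̂ = â × ŝ; origin = GC.

Landmarks with triangle area ≤ 1 mm² are treated as collinear and rejected —
a deterministic degeneracy rule rather than a numerical-noise cliff.
For **left** shoulders the stored triad stays right-handed (det = +1); the
mirror is applied to the *l coordinate* when transforming points, so that
positive l means lateral on both sides.  Quadrant labels use only (a, s), so
left/right cohorts are automatically label-symmetric.

### Segmentation

Intra-articular contrast is segmented by seeded, thresholded region growing:
voxels with intensity ≥ threshold that are 26-connected to the seed voxel.
This is a transparent, parameterized stand-in for interactive
workstation segmentation ("grow from seeds" plus manual edits): with contrast
objects hundreds of intensity units above background, the exact algorithm
matters less than the connectivity and threshold, which are both explicit
here.  A seed below the threshold raises `EmptySegmentationError` with
advice; the default threshold in phantom work is the mid-contrast intensity
(halfway between background and contrast).

### Clock-face quadrants

In the scapular sagittal view, with GC as the clock center (12 h superior,
3 h posterior, 6 h inferior, 9 h anterior), the compartments are AIQ (6–9 h),
ASQ (9–12 h), PSQ (12–3 h), PIQ (3–6 h).  Voxel centers are classified by
the signs of (a, s); the sectors are half-open in clock order so each
boundary ray belongs to the sector it starts (6 h→AIQ, 9 h→ASQ, 12 h→PSQ,
3 h→PIQ; the origin lands in PSQ).  These ties have measure zero
physically but fixing them makes the partition exhaustive and disjoint, so

    Vol.AIQ + Vol.ASQ + Vol.PSQ + Vol.PIQ = Vol.TJ

holds bit-exactly (the total is computed as the same floating-point sum).

## Statistics

- **Descriptives**: mean, sample SD (n−1), min, max per numeric column; sex
  as counts.  A single-row cohort reports SD 0 with a degenerate-sample
  warning.
- **Pearson correlation**: product-moment r with two-sided p from
  t = r·√((n−2)/(1−r²)) on n−2 df.  Missing values are deleted listwise per
  pair and the per-pair n is reported.  p-values are deliberately not
  adjusted for multiplicity (the reports say so); the 4×5 motion × volume
  grid is the unit of output.
- **IRb**: internal rotation on back is ordinal — the highest vertebral level
  reached by the thumb — converted as buttock = 1, L5..L1 = 2..6,
  T12..T1 = 7..18.  Unknown labels (e.g. "S1") raise a vocabulary error
  listing the accepted levels.
- **Reliability**: ICC(2,1), i.e. two-way random effects, absolute agreement,
  single measures, computed from the two-way ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`.  This form treats raters
  as interchangeable and penalizes systematic rater bias, which is the
  appropriate convention for "would another surgeon measure the same
  volume?".  Categories: < 0.5 poor, [0.5, 0.75) fair, [0.75, 0.9) good,
  ≥ 0.9 excellent — half-open with the upper category winning at the knots,
  since prose definitions are ambiguous exactly there.

## Synthetic data

### Phantoms

`make_phantom` builds a bright shape (solid sphere, spherical shell, offset
sphere, or two disjoint blobs) in scapular-frame coordinates on a noisy
background, with landmarks placed so the derived frame reproduces the
requested origin/axes exactly.  Defaults: isotropic 1 mm voxels (CTA slice
thickness is 1 mm; in-plane resolution is a choice), contrast 300 over
background 0 (HU-like), Gaussian noise SD 20 — a conservative CT-like noise
level that leaves ≈7.5σ between background and the mid-contrast threshold,
so the noiseless ground-truth mask is recovered at Dice ≥ 0.99.

Analytic volumes: 4/3·πR³ (sphere), 4/3·π(R³−r³) (shell); a sphere whose
center sits at signed distance d from a cutting plane splits as
V⁺ = π(R+d)²(2R−d)/3 (spherical cap complement).  Quadrant closed forms
exist when the offset is along a single frame axis; otherwise a 0.25 mm
brute-force voxel count is returned as the oracle value.

What the phantoms do **not** model: CT physics (beam hardening, scatter,
partial-volume blur), anatomically shaped capsules, leakage into tendon
sheaths, or the nonlinear pressure–volume behavior of a real capsule.
Passing phantom tests therefore demonstrates the geometry and accounting of
the pipeline, not segmentation robustness on clinical CTA.

### Cohorts and raters

`simulate_cohort` draws a latent multivariate normal with a target 8×8
correlation matrix over (Vol.AIQ, Vol.ASQ, Vol.PSQ, Vol.PIQ, Sc, ERs, ER90,
IRb), scales each margin to its configured mean/SD, then applies the
physical constraints: volumes floored at 0.01 mL, Sc ∈ [0, 180]°, ERs/ER90 ∈
[0, 120]°, IRb rounded and clamped to 1..18.  `Vol.TJ` is always the sum of
the four quadrants, keeping simulated tables consistent with the volumetry
invariant; its moments are emergent (mean ≈ 10.19 mL under the default
margins) rather than enforced.  Default margins are the published cohort
values (volumes 2.17±1.10 / 2.28±0.85 / 2.60±1.23 / 3.14±1.34 mL; Sc
159.71±25.23°, ERs 47.21±17.35°, ER90 76.58±16.14°, IRb 7.07±3.67); the
default cross-correlation block is the published volume × motion grid, with
within-block correlations set once to 0.3 (smallest eigenvalue 0.47).

Truncation caveat: the 180° scaption ceiling sits only 0.8 SD above the Sc
mean, so ~21% of latent mass is clipped and Sc's realized mean/SD and its
correlations are attenuated relative to their targets.  This mirrors real
goniometry (the instrument cannot read past 180°) and is left in place;
moment- and correlation-recovery guarantees apply to variables whose bounds
clip < 0.5% of mass (Vol.ASQ, ERs, ER90), with mild (< 5%) SD attenuation
for the quadrant volumes whose zero floor sits ≈2 SD below the mean.  IRb
rounding attenuates its correlations by ≤ 0.02.

`simulate_raters` uses the variance-component model
rating = true + bias_rater + noise, so the implied ICC(2,1) in the unbiased
case is σ²_true/(σ²_true + σ²_err); a config with true SD 3 and error SD 1
implies ICC 0.9 and is recovered within ±0.02 at 5,000 subjects.

## Pipeline and determinism

The CLI (`phantom`, `simulate`, `measure`, `analyze`, `reliability`, `run`)
is a thin layer over the library; the cohort CSV (columns `patient_id`,
`Vol.TJ`, `Vol.AIQ`, `Vol.ASQ`, `Vol.PSQ`, `Vol.PIQ`, `Sc`, `ERs`, `ER90`,
`IRb`) is the interchange hub, so externally measured volumes can enter the
statistics without images.  All randomness derives from one seed via keyed
sub-streams; reports carry a provenance block (seed, config hash, version)
and no timestamps, so reruns are byte-identical.  Reports print volumes and
descriptives to 2 decimals, r to 2 and p to 4 decimals, ICC to 3.

## Problem sizes used in validation

Phantom accuracy is checked at 0.5 mm spacing (88³ grid) for the 20 mm
sphere (< 1% error vs 33.51 mL), 1 mm for the shell and offset-sphere cap
comparisons (1–2%); conservation and invariance batteries use 100 random
small masks/frames and 10 random rigid transforms; statistical recovery uses
n = 10,000 cohorts, 5,000 rater pairs, and 1,000 null replicates.  These
sizes make the whole suite run in well under a minute while leaving the
sampling error far below the asserted tolerances.

## Known limitations

- The anterior/superior sign rules assume a near-anatomical scapula pose;
  frames built from grossly rotated data need user review (warnings, not
  errors).
- Region growing has no leak protection beyond the threshold; real CTA with
  contrast touching bone at similar intensity would need manual editing,
  which is out of scope.
- The "glenoid center" is taken as a given fiducial; no glenoid-surface fit
  is attempted.
- DICOM series are not read; convert to NIfTI/NRRD first.
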