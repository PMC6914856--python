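# Methods

This note documents the models, defaults and design choices behind
`aptw-pipeline`, in the order the pipeline runs.

## Z-spectrum model and the synthetic phantom

Per voxel, the normalised Z-spectrum is modelled as unity minus a sum of
Lorentzian saturation pools:

```
Z(Δω) = 1 − L_water(Δω − δB0) − L_MT(Δω − δB0) − L_amide(Δω − δB0) − L_NOE(Δω − δB0) + ε
```

with each `L` a peak-normalised Lorentzian `A · (w/2)² / ((Δω−c)² + (w/2)²)`
(amplitude `A` as a fraction of S0, FWHM `w` in ppm, centre `c` in ppm).
Defaults: water `A=0.80, w=1.4` and semisolid MT `A=0.12, w=30`, both centred
at 0 ppm; amide at +3.5 ppm with `w=2.0`; relayed NOE at −3.5 ppm with
`w=4.0` and amplitude 2% of S0.  Design points:

- **Symmetric baseline.**  Water and MT are centred at 0 ppm, so the entire
  designed asymmetry at 3.5 ppm is carried by the amide-minus-NOE amplitude
  difference.  Real semisolid MT is slightly asymmetric, but the analysis
  treats MTR_asym as the signal of interest, not its physical decomposition.
- **Construction identity.**  The amide amplitude is solved per voxel so that
  the noise-free, zero-shift MTR_asym — normalised by the *measured*
  reference signal at −1560 ppm, which sits slightly below S0 because of pool
  tails — equals the voxel's target APTw exactly (machine precision).  This
  also fixes a feasibility floor near −1.9% APTw (amide amplitude cannot go
  negative); cohort voxel values are clipped there and the clip count logged.
- **Pool widths vs offset sampling.**  Widths were chosen so the spectrum is
  smooth at the 0.4-ppm offset spacing; substantially narrower pools would
  make three-point interpolation (below) systematically inaccurate, which is
  a property of the correction scheme, not of the data.
- **Noise.**  Additive Gaussian noise on the normalised signal (default SD
  0.002 of S0 per offset image).  The acquisition noise level of APTw imaging
  is not specified by the study conditions; this default is an assumption,
  chosen so that per-voxel APTw noise (~0.3% after asymmetry) is comparable
  to the within-lesion spread.  Rician effects are negligible at this SNR and
  an additive model keeps the zero-noise limit unbiased.
- **B0 field.**  A random low-order polynomial in the three normalised
  coordinates, rescaled so its maximum absolute value equals `b0_amplitude`
  (default 0.15 ppm; up to 0.4 ppm is correctable by design).
- **Lesion geometry.**  Ellipsoids on the 0.9×0.9×3.85 mm reconstruction
  grid with uniformly drawn half-axes (defaults 1.8–4.5 voxels in-plane,
  1.0–2.2 slices), placed disjointly with a one-voxel gap and a minimum of
  10 voxels; typical sizes are a few dozen voxels, matching the scale of the
  analysed lesions.
- **Cohort hierarchy.**  Group APTw means/SDs describe the across-patient
  distribution of per-patient mean lesion APTw.  Per patient, a target is
  drawn at the group mean with the between-patient SD (default: the full
  group SD); per lesion, a target around the patient's (between-lesion SD,
  default 0.10%); per voxel, Gaussian spread (within-lesion SD, default
  0.33%, the scale implied by the reported 10th–90th percentile spans).  The
  variance split is a free parameter, but the default puts the group SD at
  the patient level because that is the quantity the group statistics
  operate on; a 50/50 patient/voxel split would make the across-patient SD
  converge to ~0.71× the configured value.  Healthy subjects get a uniform
  white-matter APTw at their subject-level draw and no lesions; lesion-group
  backgrounds sit at the healthy mean (0.47%).
- **FLAIR-like volume.**  Background 100, lesion contrast +50, Gaussian noise
  SD 5 — a 10:1 contrast-to-noise ratio, comfortably above the 3:1 the
  segmentation assumes.
- **Determinism.**  One `numpy` Generator seeded from `CohortSpec.seed`
  drives every draw; identical specs give byte-identical cohorts.

Healthy-WM ROIs are three mirrored bilateral pairs (frontal, centrum
semiovale, parietal) on one slice; each ROI is the `round(area / voxel_area)`
voxel centers nearest its centre (area default 85 mm², protocol range
80–90 mm²), with the right mask the mirror image of the left so pairs have
identical counts.

## B0 correction and mapping

Normalisation divides each saturation image by the reference; voxels with
non-positive S0 are flagged invalid.  Z values are deliberately *not* clamped
to [0, 1]: noise can push them slightly above 1 and clamping would bias the
asymmetry.  A field offset δB0 means saturation nominally at Δω landed at
Δω − δB0 from water, so the three measured samples per side are placed at
their shifted offsets and the spectrum at ±3.5 ppm is evaluated by quadratic
Lagrange interpolation through them — exact for locally quadratic spectra,
no oscillation risk with three points.  Evaluation outside the shifted sample
span is clamped to the nearest sample; |δB0| beyond `max_b0` (default
0.4 ppm, the sampled half-span) marks the voxel uncorrectable (NaN, excluded
from all lesion statistics, counted in the run report).  On noise-free
phantoms with |δB0| ≤ 0.3 ppm the corrected map's RMSE is about 0.01% against
ground truth, versus ~0.4% uncorrected.  If several acquisitions of one
offset are supplied they are averaged before normalisation.

## Segmentation

The committed interpretation of "manual outline, then automatic threshold +
edge growth" is: rasterise the closed polygon (voxel centers inside, even-odd
rule) on its slice; admit voxels with intensity ≥ mean(seed) − k·sd(seed)
(k default 2) whose Gaussian-smoothed (σ = 1 voxel) gradient magnitude stays
at or below the q-th percentile (default 90) of the gradient over
lesion-candidate voxels within a bounding box around the seed (margin
12×12×3 voxels); the lesion is the seed's 26-connected component of that set.
26-connectivity is used because 3.85-mm slices make 6-connectivity overly
strict across slices.  Two details matter:

- The barrier percentile is computed over *supra-threshold* voxels of the
  box, not the whole box: small lesions occupy a few percent of any box, so a
  whole-box percentile lands at the background-noise gradient level and
  classifies the entire lesion as edge.
- The candidate set for the barrier uses a fixed multiplier (`barrier_k` = 2)
  independent of the admission `k`, so relaxing the admission threshold can
  only grow the mask (monotonicity), and the leak guard stays meaningful.

There is no interactive correction: growth beyond `max_voxels` (default
10 000) raises a diagnostic error (threshold and barrier values included) and
the lesion is re-run with different parameters or dropped, which replaces the
manual post-hoc adjustment step.  Lesions under 10 voxels are excluded
afterwards.  On phantom cohorts at the default contrast/noise the mean Dice
against ground truth is ~0.94.

Seeds used by the automated pipeline are derived from ground truth the way a
reader would outline: the convex hull of the lesion's voxel centers on its
maximum-area slice, expanded by 0.2 voxel so boundary centers fall strictly
inside the polygon.

## Features and group statistics

Percentiles use linear interpolation between order statistics at rank
1 + p·(n−1) (the numpy default); the definition is stated because percentile
conventions differ across software.  Patient aggregation averages each
parameter across lesions with equal weight per lesion, not voxel-weighted.
Healthy subjects contribute the mean of their six ROI means as one
subject-level value by default (the alternative — treating the 6 ROI means
per subject as separate observations — is exposed but not default, since the
group comparisons operate per subject).

Wilcoxon rank-sum tests are two-sided with midranks for ties; the null is
enumerated exactly for combined samples of ≤ 12 without ties, otherwise the
tie-corrected normal approximation with continuity correction is used (the
study's group sizes always take the asymptotic branch).  Benjamini–Hochberg
adjustment is the step-up procedure (via statsmodels), rejecting at adjusted
p ≤ 0.10 by default.

The ROC operates at lesion level with the patient as cluster — pooled lesion
counts, not per-patient means — with the positive class the MS-lesion group
and larger APTw indicating it.  The AUC is the Mann–Whitney probability with
ties counted ½ (identical to the trapezoidal area under the empirical ROC
curve).  Its variance uses placement-value components: per-cluster sums of
centred placement values, with small-sample factors I1/(I1−1) and I2/(I2−1)
on the two variance components and I12/(I12−1) on the cross covariance
(I1, I2, I12 = clusters containing positives, negatives, both; the factor is
1 when I12 ≤ 1).  With one lesion per cluster this reduces algebraically to
the classic iid placement-value (DeLong-type) variance.  The 95% CI is
AUC ± 1.96·SE on the AUC scale, truncated to [0, 1] — no logit transform,
matching symmetric reporting conventions.  Monte-Carlo calibration at the
study's cluster structure (27 vs 35 patients, 5–20 correlated lesions each,
2000 replicates) gives empirical coverage close to 94%.

The Youden operating point scans the observed values as cutoffs, classifies
positive at value ≥ cutoff, maximises J = sensitivity + specificity − 1 and
breaks ties at the lowest cutoff (whether the original analysis used ≥ or >
is not stated; ≥ is committed here).  Accuracy is pooled over lesions:
(sens·n_pos + spec·n_neg)/(n_pos + n_neg).

## What the phantom does and does not show

The generator reproduces the statistical structure the analysis assumes —
nested variance, group separations, B0 fields, lesion geometry and FLAIR
contrast — so passing tests demonstrate that the pipeline recovers known
ground truth under those assumptions.  It does not reproduce real brain
anatomy, partial-volume mixing at lesion rims, spatially correlated noise,
B1 inhomogeneity, T1 effects on the APTw signal, non-Gaussian lesion-value
distributions, or confluent/periventricular lesion morphology; agreement on
phantoms therefore validates the computation, not the biology.  Gaussian
group models also mean the phantom's lesion-level AUC (~0.67 by the
generating model for the mean parameter) need not match AUCs measured on
real, non-Gaussian data.  Full Bloch–McConnell simulation is out of scope.

## Numerical and degenerate-input conventions

Uncorrectable or invalid voxels are NaN and excluded everywhere, with counts
logged and reported.  Empty lesion records, empty classes, and groups with
fewer than two patients raise errors rather than returning degenerate
statistics.  All-identical pooled samples give p = 1.  The clustered variance
is floored at 0 before the square root.  Pipeline runs write their resolved
configuration next to their outputs, and two runs with equal configurations
produce identical tables.

## Problem sizes

Default test and reproduction scales: phantom mapping on 64×64×14 grids,
segmentation cohorts of 6–8 patients with 3–6 lesions each, CI calibration
at 2000 replicates, and cohort recovery at the full study size (27/35/20
subjects, ~750–900 lesions), which completes in seconds to a few minutes on
one CPU.
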