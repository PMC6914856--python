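# aptw-pipeline

Amide proton transfer weighted (APTw) MRI lesion analysis: a tested,
reproducible pipeline for asking whether the APTw signal distinguishes
demyelinating multiple sclerosis lesions (MSL) from white matter
hyperintensities of presumed vascular origin (WMH), and how both compare with
healthy white matter.  It is written for researchers working with CEST
(chemical exchange saturation transfer) brain imaging who need the complete
chain from Z-spectrum volumes to group statistics, together with a synthetic
cohort generator so every stage can be exercised and validated without
patient data.

## What it computes

**APTw mapping.**  The APTw metric is the magnetization transfer ratio
asymmetry at 3.5 ppm from water,

```
MTR_asym(%) = 100 x (S(-3.5 ppm) - S(+3.5 ppm)) / S0
```

where `S(±Δω)` are saturation images acquired at ±3.1, ±3.5, ±3.9 ppm and
`S0` is the unsaturated reference (acquired far off-resonance at −1560 ppm).
Before the asymmetry is taken, each voxel's Z-spectrum `Z(Δω) = S(Δω)/S0` is
re-centred on its true water resonance using a per-voxel B0 offset map: the
three samples on each side are treated as samples of the spectrum at the
shifted offsets and the value at ±3.5 ppm is recovered by quadratic Lagrange
interpolation (voxels with |δB0| beyond a configurable bound, default
0.4 ppm, are flagged uncorrectable and excluded).

**Lesion analysis.**  Lesions are delineated from a single 2D outline drawn
on the slice of maximal diameter of a FLAIR-like volume; a combined
intensity-threshold + gradient-edge region growing recovers the 3D extent,
and lesions under 10 voxels are excluded.  Per lesion, six first-order
histogram parameters of the voxel APTw values are computed (mean, median,
10th/25th/75th/90th percentile), then averaged per patient with equal weight
per lesion.

**Group statistics.**  Per-patient parameters are compared between groups
with two-sided Wilcoxon rank-sum tests, corrected by the Benjamini–Hochberg
step-up procedure at a false discovery rate of 0.10.  Diagnostic performance
is quantified at lesion level by the pooled Mann–Whitney AUC with a
clustered (patient-level) variance from placement-value components —
lesions within a patient are correlated, and ignoring that understates the
AUC's uncertainty — plus the Youden-index operating point (cutoff,
sensitivity, specificity, pooled accuracy).

**Synthetic cohorts.**  The `phantom` module builds per-subject Z-spectrum
volumes from a multi-pool Lorentzian model (water and semisolid MT baseline,
amide pool at +3.5 ppm, relayed-NOE pool at −3.5 ppm), smooth B0 offset
fields, FLAIR-like anatomy with ellipsoidal lesions on the 0.9×0.9×3.85 mm
reconstruction grid, and a nested patient/lesion/voxel hierarchy whose group
means and SDs default to the study conditions (MSL 0.72 ± 0.24%, WMH
0.52 ± 0.35%, healthy WM 0.47 ± 0.32%; 27/35/20 subjects).

## Worked example

Run the full pipeline on a small synthetic cohort (8 MSL patients, 8 WMH
patients, 4 healthy subjects):

```python
from aptw import RunConfig, run_pipeline

cfg = RunConfig(seed=7, cohort=dict(
    n_patients={"MSL": 8, "WMH": 8, "HealthyWM": 4},
    lesions_per_patient=(4, 8), grid_shape=(48, 48, 12)))
report = run_pipeline(cfg, outdir="example_run")
print(report["counts"])
```

prints the stage accounting

```
{"seeded": 101, "leaks": 0, "filtered_small": 0, "segmented": 101, "uncorrectable_voxels": 0}
```

meaning all 101 simulated lesions were seeded, grown without runaway leaks,
and retained by the 10-voxel size filter, and no voxel's B0 offset exceeded
the correctable bound.  `example_run/group_tests.csv` then holds the
per-parameter comparisons:

```
parameter  statistic  p_raw  p_adjusted  rejected
     mean       79.0 0.2701       0.372     False
   median       80.0 0.2271       0.372     False
      p10       77.0 0.3720       0.372     False
      p25       81.0 0.1893       0.372     False
      p75       78.0 0.3184       0.372     False
      p90       80.0 0.2271       0.372     False
```

(at 8 patients per group the true group difference — recovered per-patient
means 0.695 vs 0.615% here — is not yet separable from between-patient
spread), and `example_run/roc.csv` the clustered lesion-level ROC:

```
parameter   auc  ci_low  ci_high  cutoff  sensitivity  specificity  accuracy
     mean 0.621   0.342    0.900   0.416        0.893        0.378     0.663
   median 0.633   0.360    0.906   0.482        0.804        0.511     0.673
```

The AUC near 0.62 with a wide patient-clustered CI is the expected picture
for overlapping lesion distributions; the CI shrinks as patients (clusters),
not just lesions, are added.

The same stages are exposed on the command line (`aptw simulate`, `aptw map`,
`aptw segment`, `aptw extract`, `aptw analyze`, `aptw run-all`); volumes move
as NIfTI-1, tables as CSV, configuration as YAML.  A deposited per-lesion
voxel-value table can be ingested directly with
`aptw analyze --lesions <file> --out <dir>`, which sniffs the column layout
and normalises it to the internal schema.

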