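# holoquant

Quantification-accuracy analysis for holmium-166 (¹⁶⁶Ho) SPECT/CT, built
for radionuclide-therapy dosimetry QA. ¹⁶⁶Ho microspheres (used in
transarterial radioembolization) are imaged with SPECT/CT to verify
absorbed doses; the images are only quantitative after a calibration
step, and that calibration degrades at high count rates because of
detector dead time. `holoquant` reproduces, on synthetic phantom data,
the full accuracy analysis a physics group would run: phantom and VOI
construction, a scanner stand-in simulator, conversion-factor
quantification, and the recovery metrics used to judge it.

## The model

A reconstructed SPECT volume in counts is converted to activity
concentration with a conversion factor

```
CF = ( μ / (t · n · V_voxel) ) / ( A / V_VOI )      [(cps/mL) / (MBq/mL)]
```

where μ is the mean counts in a calibration VOI, t the projection time
(s), n the number of projections, V_voxel the voxel volume (mL), A the
true activity in the VOI (MBq) and V_VOI its volume (mL). Two
calibration choices are implemented:

* **scanner-specific** (`CF_homogeneous`): measured once on a separately
  scanned homogeneous cylinder (Ø20 cm × 20 cm, 6283 mL) with a ~2 L
  central VOI;
* **self-calibration** (`CF_self`): derived from the imaged object
  itself, using a whole-phantom VOI and the known total activity at scan
  start. By construction this method always recovers exactly 100% of the
  total activity.

Quantified volumes are decay-corrected to the injection time point
(T½ = 26.8 h). Accuracy is evaluated with whole-phantom recovered
activity, activity concentration recovery coefficients
(ACRC = AC_measured / AC_true per VOI), axial activity-concentration
profiles, cumulative activity-volume histograms (cAVH), and recovery
curves — a 3-parameter logistic in sphere diameter d,

```
ACRC(d) = a · (1 − 1 / (1 + (d/b)^c)),
```

whose asymptote `a` is the best achievable ACRC and which supports
region-based partial-volume correction (divide a region mean by
ACRC(d); never valid voxel-wise).

The scanner stand-in operates in reconstructed-volume space: an
isotropic Gaussian PSF (default FWHM 15 mm), Poisson counting noise,
and a camera-level paralyzable dead-time efficiency
`g = exp(−R·τ)` evaluated at the whole-field true count rate R. The
default phantoms and 22-scan decay schedule (14 time points, four in
triplicate, spanning ~3.3 GBq down to ~62 MBq) match the study
conditions the package analyses.

## Worked example

```python
from holoquant import StudyConfig, run_study

report = run_study(StudyConfig(seed=1, metrics_spacing_mm=2.0))
print(f"CF_homogeneous = {report.cf_homogeneous.value:.2f} cps/MBq")
print(report.recovery_table.query("method=='homogeneous'")
      [["dt_h", "true_total_mbq", "recovery_percent"]]
      .iloc[[0, 9, 16, 21]].round(2).to_string(index=False))
print(report.fit_table.query("method=='self'").round(4).to_string(index=False))
```

prints

```
CF_homogeneous = 18.96 cps/MBq
 dt_h  true_total_mbq  recovery_percent
  1.5         3221.05             58.40
 58.0          747.07             86.71
104.8          222.68             94.27
154.2           62.06             96.63
method group      a       b      c     r2
  self  tp10 0.9595 23.5790 1.8737 0.9984
  self  tp12 0.9546 23.4343 1.8975 0.9979
  self  tp13 0.9488 23.2567 1.9292 0.9983
  self  tp14 0.9468 23.1893 1.9292 0.9975
```

Reading this: the scanner-specific method under-recovers badly at high
activity (58% at ~3.2 GBq, where dead-time losses are ~40%) and
approaches truth as the phantom decays — the bias direction that makes
a single-activity calibration unsafe for ¹⁶⁶Ho dosimetry. The
self-calibration recovery column (not shown) is identically 100%. The
logistic recovery-curve fits have r² ≈ 0.998; their asymptote `a` ≈ 0.95
is the ACRC ceiling imposed by the 15 mm PSF, and `b` ≈ 23 mm is the
sphere diameter recovering half of that.

The same pipeline is scriptable from the shell:

```
holoquant run-study --out out/ --seed 1
holoquant simulate --phantom jaszczak --dt 58 --seed 7 --out counts.nii.gz
holoquant fit-recovery --csv acrc.csv --out fit.json
```

## Layout

* `holoquant.phantom_geometry` — voxelized phantoms, VOIs, ground truth
* `holoquant.synthetic_spect` — decay, PSF, dead time, acquisition simulator
* `holoquant.resampling` — nearest-neighbor grid transfer
* `holoquant.quantification` — conversion factors and decay correction
* `holoquant.recovery_metrics` — ACRC, profiles, cAVH, recovery curves, PVC
* `holoquant.config` / `holoquant.study` / `holoquant.cli` / `holoquant.io`
  — configuration, the end-to-end pipeline, CLI, NIfTI/CSV I/O

See `docs/methods.md` for the modelling assumptions and numerical
choices.
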