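# Methods

## Scope and model

`holoquant` analyses the accuracy of conversion-factor–based ¹⁶⁶Ho
SPECT/CT quantification on synthetic phantom data. The physical chain —
collimator, projections, scatter, attenuation, vendor reconstruction —
is deliberately not modelled. Instead the simulator operates directly in
reconstructed-volume space with the three phenomena the accuracy
analysis actually measures:

1. **Finite resolution**: isotropic Gaussian PSF, σ = FWHM/2√(2 ln 2)
   per axis, applied to the true activity-concentration map. Default
   FWHM 15 mm, matching the post-reconstruction filtering level typical
   for ¹⁶⁶Ho imaging. The convolution is zero-padded; totals are
   conserved to <0.1% provided ≥3σ of empty grid surrounds the phantom
   (the default grids leave 60 mm).
2. **Counting noise**: expected counts per voxel are
   `AC_blurred · V_voxel · sensitivity · g · t · n`; realized counts are
   Poisson draws from a seeded generator. Identical inputs and seed give
   bit-identical volumes.
3. **Rate-dependent efficiency loss**: a paralyzable dead-time model,
   observed = true · exp(−true·τ), applied as a *single camera-level*
   efficiency g evaluated at the whole-field true count rate. Dead time
   is a detector-level effect, so a global factor (rather than per-voxel
   attenuation) reproduces the whole-image under-recovery seen at high
   activities.

Decay bookkeeping uses T½ = 26.8 h throughout; activities are MBq,
concentrations MBq/mL, lengths mm, schedule times hours and acquisition
sub-times seconds, enforced at config parse time.

## Phantoms and study conditions

The generator's defaults are the study conditions, not tuning knobs:

* Homogeneous cylinder: inner Ø200 × 200 mm (6283 mL), 0.049 MBq/mL at
  injection, scanned once at Δt = 8.5 h (~250 MBq) to calibrate the
  scanner-specific CF from a 2.0 L central cylindrical VOI (radius
  70 mm × height 130 mm; the exact split is not physically constrained
  and is configurable).
* Jaszczak phantom: body Ø216 × 186 mm (background ≈ 6.67 L), six
  fillable spheres of inner diameter 9.9–60 mm at 4.10 MBq/mL over a
  0.41 MBq/mL background (10:1). Sphere mounts follow the standard
  six-sphere flanged insert: centers evenly spaced 60° apart on a 70 mm
  ring in one axial plane, ordered by size. This keeps every
  edge-to-edge gap ≥ 24 mm (≈1.6 PSF FWHM) so inter-sphere spill-in
  stays second-order; with tighter packings the 15.4 mm sphere sits in
  the 60 mm sphere's spill-in field and its ACRC overtakes the next
  larger sphere's, which no physical insert exhibits. Positions are
  configurable.
* Schedule: 22 Jaszczak scans at 14 decay time points from Δt = 1.5 h
  (~3.2 GBq) to 154.2 h (~62 MBq), the 10th, 12th, 13th and 14th in
  triplicate. Per-scan seeds are `root_seed + index`, so triplicates
  differ but runs reproduce exactly.
* Acquisition: 2 × 60 projections × 20 s. System sensitivity defaults
  to 19.7 cps/MBq, chosen so that sensitivity × efficiency at the
  cylinder-scan rate lands at the scanner-specific conversion factor a
  clinical ¹⁶⁶Ho system reports (≈19.3 cps/MBq).
* Dead time: τ is calibrated in closed form, τ = −ln(1−f)/R, so the
  loss fraction f at the highest scheduled rate equals 40% (the
  midpoint of the 34–45% readout range at ~3.1 GBq); the same τ then
  yields ~1% at 61 MBq, consistent with the low end of the readouts.

## Geometry and voxelization

World coordinates are mm with the origin at the phantom's geometric
center; a `VoxelGrid` places voxel *centers* at
`origin + spacing · index`. Simulation runs on a 4.8 mm isotropic grid
(the OSEM reconstruction voxel); metrics run on a 1 mm "CT-like" grid
(2 mm in the faster configurations), bridged by nearest-neighbor
resampling under an affine world map, as an anatomical-delineation
workflow would. Nearest-neighbor ties (a point exactly halfway between
source centers) resolve to the lower index; this is reachable with
half-voxel-commensurate grids and is pinned by tests. Because
nearest-neighbor upsampling does not conserve sums, every activity
total in the package is computed as VOI mean × VOI volume, which is
stable under this resampling.

Masks are binary and built by a supersampled majority vote: a voxel
belongs to a shape iff ≥ half of its s³ sub-centers (default s = 3) lie
inside the analytic surface. Two documented edge behaviours:

* A sphere too small to win the vote anywhere still yields the single
  voxel containing its center, so positive-diameter VOIs are never
  empty.
* Binary masks quantize. A Ø9.9 mm sphere spans ~508 voxels at 1 mm, and
  which boundary voxels round in or out depends on grid alignment; the
  resulting volume error has sd ≈ 1.2% with worst cases near 5%, and is
  *not* reduced by deeper supersampling (it is a property of the binary
  decision, not of the coverage estimate). The error falls quadratically
  with spacing (Ø9.9 mm is within 1% at 0.5 mm, 0.14% at 0.25 mm), and
  spheres ≥ 24.8 mm are within 1% at 1 mm. Flat surfaces aligned with
  voxel-center planes (the cylinder's end caps on a centered grid)
  carry a half-voxel-layer bias, ≤0.5% for the 6283 mL cylinder.

The Jaszczak VOI set is constructed as a partition by definition: sphere
masks are clipped to the whole-phantom mask and to each other,
background = whole ∖ (∪ spheres), so spheres + background tile the whole
mask voxel-for-voxel. Overlapping sphere specifications are rejected
naming the offending pair.

## Quantification

`CF = (μ/(t·n·V_voxel)) / (A/V_VOI)` with μ the mean counts over the
calibration VOI. Self-calibration uses the whole-phantom VOI and the
activity at scan start; activity during the ~20 min scan changes <1%
over a 26.8 h half-life, so no mid-scan decay integration is applied.
Quantified voxels are `(counts/(t·n·V_voxel))/CF`, decay-corrected to
injection by `2^(+Δt/T½)`. The self-calibration closure — whole-phantom
recovery ≡ 100% regardless of noise, blur or dead time — is an algebraic
identity of these definitions and is enforced to 10⁻⁶ relative in
tests over the full schedule. Poisson counts cannot be negative, so no
clipping rule exists; externally supplied absolute-calibrated volumes
(the third quantification route, ingested as already-quantified Bq/mL
data) keep any negative values and report them rather than clipping.

## Metrics

* **ACRC**: VOI mean over true concentration, with the truth taken at
  injection since quantified volumes are decay-corrected there. The
  background VOI is used exactly like sphere VOIs (no erosion).
* **Profiles**: per-slice values along the symmetry axis, either single
  voxel rows at (x, y) or disk averages within a radius; summaries
  exclude slices within 30 mm of the phantom ends, where edge blur
  dominates.
* **cAVH**: the empirical survival function of VOI voxel values;
  default threshold grid 256 levels from 0 to 1.05 × the VOI maximum
  (binning is not physically constrained; configurable).
* **Recovery curve**: unweighted least squares of
  `a(1 − 1/(1+(d/b)^c))` on ACRC vs sphere diameter, initialized at
  a₀ = max ACRC, b₀ = median diameter, c₀ = 2, with 5 jittered restarts
  and bounds a ∈ (0, 1.5], b ∈ (0, 200] mm, c ∈ (0, 10]. Optional 1/sd
  weighting is available since triplicate standard deviations exist,
  but the unweighted fit is the default. r² = 1 − SSres/SStot about the
  mean (stated because conventions differ). Non-convergence after all
  restarts raises an error carrying the best attempt.
* **PVC**: region-based only — a region mean divided by ACRC(d); the
  correction refuses recoveries below 0.05 (default floor) as
  unstable, and corrected values must not be evaluated voxel-wise.

## Verification strategy and what it shows

Oracles are independent of the paths they check: blurred-sphere ACRC
against an explicit-kernel FFT convolution; the resampler against a
brute-force nearest-center search; simulator count algebra against the
closed-form expectation; decay totals against hand-computed half-life
arithmetic; the logistic fit against data generated from known
parameters (exact recovery to 10⁻⁶ noiseless; asymptote bias <0.1% over
200 replicates at sd 0.02).

Problem sizes are chosen for fast, deterministic runs: the default test
and acceptance paths use the 4.8 mm simulation grid with 2 mm metrics
grids where sphere-level resolution is needed; the full 22-scan
schedule simulates in under a minute.

The synthetic data reproduce the *mechanisms* — partial-volume loss,
Poisson noise, rate-dependent efficiency — not a specific scanner.
Real acquisitions add effects absent here: spatially varying collimator
response, residual scatter and attenuation errors, reconstruction
non-linearity and noise correlation, lead x-ray contamination of the
81 keV window, and motion. Consequently, passing tests demonstrate the
correctness of the analysis pipeline and the qualitative bias
structure (self-calibration closure is exact; a single-rate calibration
under-recovers at high rate and recovers toward truth at low rate;
ACRC grows sigmoidally with sphere size), but absolute recovery numbers
on real scanners will differ. The simulator's scanner-specific method
cannot overshoot 100% at low activity, whereas a real system calibrated
on a different phantom can; only the sign and monotonicity of the bias
are claimed.

## Known limitations

* Volume-space simulation: no projection-domain effects, no
  reconstruction artifacts (Gibbs, positivity bias at low counts).
* Global dead-time factor: no per-region rate dependence or pulse
  pile-up spectrum distortion.
* Nearest-neighbor-only resampling; no registration estimation.
* Binary VOIs with the quantization floor described above; fractional
  (partial-volume) masks are out of scope.
* The absolute-quantification route is ingested, not emulated: no
  vendor calibration procedure is modelled.
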