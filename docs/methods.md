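# Methods

## Measurement model

PS-OCT records two complex detection channels per voxel. The package
assumes channel data are already reconstructed (spectral-domain
processing and fiber-mismatch compensation are upstream of this
pipeline) and starts from amplitude and phase. Stokes vectors follow the
standard two-channel relations; the phase difference enters only U and
V, so a global phase offset between channels rotates (U, V) but leaves
DOPU invariant — DOPU is invariant under any global rotation of the
normalized Stokes directions, which is covered by a property test.

DOPU is the length of the window-averaged, per-voxel-normalized Stokes
vector. Two conventions exist for the averaging; both are implemented:

* **per-voxel normalization** (default): normalize (Q, U, V) by that
  voxel's I, then average. This is the classical definition and is what
  the synthetic ground truth is calibrated against.
* **intensity-weighted** (`intensity_weighted=True`): average raw
  (Q, U, V) and normalize by the summed I. Brighter voxels dominate.

Windows are 10 × 10 px (axial × lateral) by default and slide within a
single B-scan; with the default pixel spacings (2 μm axial, 8 mm/1024
lateral) that is ≈ 20 × 78 μm. The even kernel is anchored with the
output voxel at index ⌊k/2⌋; border windows are truncated rather than
invalidated. A window yields a value only if at least 25% of its full
kernel area consists of valid (above-threshold) voxels; the threshold is
inclusive (I ≥ 2 × noise level counts as valid). The noise level is
carried as acquisition metadata, not re-estimated from the data.

### Estimator properties

For a window of n independent directions with population resultant
length ρ, E[DOPU²] = ρ² + (1 − ρ²)/n: the finite window biases DOPU
upward, by ≈ +0.015 at ρ = 0.2 with n = 100 and negligibly at ρ ≥ 0.5.
Additive unpolarized detection noise biases it downward by roughly
I_s/(I_s + I_n). At the phantom's default tissue SNR (see below) the two
effects nearly cancel; recovery tests bound the net deviation at ±0.02.
These are properties of the DOPU statistic itself, not artifacts of the
implementation.

## RPE line refinement

Strictly per A-scan: maximal runs ("batches") of consecutive valid
pixels with DOPU strictly below 0.6 are enumerated; the batch closest to
the initial intensity-based line index is selected (distance 0 if the
index lies inside a batch, else the gap to the nearest batch end) and
the corrected index is the batch's DOPU argmin. Deterministic
tie-breaks: equidistant batches → the shallower one; tied minima → the
smallest index. No cross-A-scan smoothness constraint is imposed.

A-scans with no sub-threshold batch (e.g. inside the optic nerve head)
are flagged invalid and excluded from en-face maps; the initial index is
retained as a fallback value, and `keep_unmatched=True` switches to the
alternative behavior of trusting the initial line. The refinement is
idempotent, and the production path is a vectorized run-length
implementation verified against a direct per-A-scan restatement of the
rule.

## En-face maps, mosaicking, ONH exclusion

Repeats are averaged pixel-wise (invalid only where all repeats are
invalid); they are assumed pre-aligned by the instrument's retinal
tracker, with an optional translation registration for robustness.
Sub-fields are resampled to an isotropic grid at the native lateral
spacing (8/1024 mm/px by default) with invalid-aware bilinear
interpolation, then placed at their nominal scan offsets, refined by
masked phase correlation against the growing mosaic (fovea outward).
A refinement is rejected — falling back to the nominal offset with a
warning — if the implied shift exceeds `max_shift_px` (default 40 px) or
the post-shift overlap correlation is below `corr_floor` (default 0.3).
Overlaps are fused with distance-to-edge feathering capped at 40 px;
where only one map contributes the weights normalize away exactly, so
single-source values are conserved. Rotation and scale are not
registered: at these sub-field offsets translation is the dominant
misalignment, and full fundus-reference registration is out of scope.

The optic nerve head is excluded as a disc of 140 native pixels
(≈ 1.09 mm) around a supplied center; on synthetic data the center is
known, on real data it is an input. Fovea localization likewise uses the
phantom ground truth (the mosaic origin); real data would require a
manual seed point.

## Sectoral grid

Diameters 0.5, 1, 2, 3, 6, 9, 12 mm; half-open annuli [inner, outer) so
each position belongs to exactly one of the 49 fields. Sector numbering
is a chart convention, not a physical fact: the default anchors sector 1
at the positive-x horizontal advancing counterclockwise with boundaries
at multiples of 45°, and both the anchor angle and direction are
configurable (`GridSpec(anchor_deg=..., clockwise=...)`). No left/right
eye mirroring is applied by default. Fields with no usable pixel are
reported as missing (NaN, n = 0), never as zero.

## Cohort statistics

Group contrasts are two-sample Student's t-tests with pooled variance
(Welch by flag) at α = 0.05 per field, without multiplicity correction
(a Benjamini–Hochberg helper exists but is off by default, matching the
per-field 5% convention). Age matching is expressed as a minimum-age
filter applicable to selected groups. Neighboring-ring contrasts default
to *paired* t-tests, since the same subjects contribute both rings; the
unpaired reading is available via `paired=False`. Degenerate
zero-variance inputs return t = 0, p = 1 (identical) rather than NaN.
Age trends are ordinary least squares of ring DOPU on age via
`scipy.stats.linregress`, reporting slope (DOPU/year), intercept, R², p
and the t-based slope CI; results are cross-checked against statsmodels
OLS in the tests.

## Synthetic data

The phantom emulates, per A-scan: background noise above the retina, a
polarization-preserving neural retina (fixed Stokes direction, default
circular (0, 0, 1)), a depolarizing RPE band of 14 px (28 μm at 2 μm/px
— thicker than a real RPE so that the 10-px kernel fits inside the
band), and a short polarization-preserving tail below it. Channel fields
are synthesized so the noise-free Stokes vector is fully polarized, then
independent complex Gaussian noise is added per channel.

Depolarization is modeled as per-voxel random polarization directions
drawn from a von Mises–Fisher distribution on the Poincaré sphere — not
amplitude decorrelation — because DOPU measures exactly the mean
resultant length of normalized Stokes vectors: choosing the
concentration κ with coth κ − 1/κ = target makes the expected
large-window DOPU equal the target by construction. The inverse Langevin
function is computed by Newton refinement of a Banerjee-type starting
guess (vectorized, ~1e-12 accurate); targets of exactly 1 and 0 map to a
point mass and the uniform distribution.

Defaults and their reasoning:

* **tissue SNR** = 100 in intensity (20 dB, amplitude SNR 10), typical
  of retinal OCT tissue signal over the noise floor. Much lower SNR
  physically depresses measured DOPU (see estimator properties) — that
  is a property of DOPU in noise, which the phantom reproduces rather
  than hides.
* **spatial pattern**: strongest depolarization (0.33) in a perifoveal
  annulus, cosine-tapered relief to 0.42 at the foveal center, smooth
  rise to 0.52 by 5 mm eccentricity — the qualitative healthy pattern —
  plus a small deterministic sinusoidal texture (amplitude 0.02) that
  gives translation registration local contrast.
* **ONH**: within 0.95 mm of (4, 0) mm the depolarizing band is replaced
  by preserving tissue, so no low-DOPU batch exists there and the
  refinement correctly reports those A-scans as unmatched.
* **sub-field layout**: macula-centered tile plus six on a 9° hexagon;
  every adjacent tile pair overlaps by well over 15% and the seven
  28° × 21° tiles span ~46°, comparable to fundus photography. The
  hexagon radius is the single overlap knob.
* **cohort**: 105 healthy (ages 21–79) + 48 glaucoma (40–78) subjects,
  ring baselines A 0.42, B 0.35, C 0.36, D 0.42, E 0.47, F 0.50, G 0.52
  at a reference age of 60, age slope −0.0015 DOPU/yr, group effect
  −0.01, sex effect +0.005, between-subject noise sd 0.03, values
  clipped to [0, 1]. Cohorts carry per-ring values (the quantities the
  age/group analyses consume); per-field tables from `grid.field_means`
  plug into the same statistics functions.

What the phantom does **not** emulate: OCT speckle statistics, signal
attenuation and shadowing, axial PSF, motion artifacts, real layer
morphology, or fundus imagery. Passing recovery tests therefore
demonstrates correctness of the computations under the stated tissue
model, not clinical performance on real tomograms.

## Problem sizes in the tests

The full protocol raster (250 × 1024 × 512 voxels × 2 channels × 21
acquisitions) is supported but far exceeds what routine testing needs;
the recovery tests use reduced rasters (e.g. 48 B-scans × 256 A-scans ×
160 depth px) that keep every physical constant (extent in mm, kernel
size, thresholds) unchanged, so per-window statistics are identical to
the full-size case. Mosaicking tests run at 8/256 mm/px for the same
reason. Monte-Carlo checks use 10⁴–10⁵ draws, sized so their standard
errors are several times tighter than the asserted tolerances.

## Numerical choices

* DOPU windows use float64 cumulative sums (exact truncated-window
  sums, verified to 1e-9 against a per-window loop) and the result is
  clipped to [0, 1] to absorb float rounding at the boundaries.
* Windows with fewer than 25% valid kernel pixels are invalid (NaN);
  empty windows never raise.
* vMF sampling uses the inverse-CDF construction for the coordinate
  along the mean direction, stable for κ from 1e-8 to ∞.
* All generators take explicit integer seeds and are bit-for-bit
  reproducible; acquisition repeats use caller-supplied distinct seeds.

## Known limitations

Translation-only mosaicking cannot correct rotation or torsion between
sub-fields. The intensity-based initial segmentation is an input, not
reproduced here. DOPU values depend on the incident polarization state
and the kernel size; comparisons across instruments or kernel choices
require care. Cohort analyses are cross-sectional OLS/t-tests only — no
mixed-effects or longitudinal modeling.
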