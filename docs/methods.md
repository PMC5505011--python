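# Methods

## Scope and data model

`callusct` operates on reconstructed, isotropic grey-value volumes (TIFF
slice stacks or NIfTI-1; axis order z, y, x, 0-based). It does not perform
tomographic reconstruction, scanner-format import, or beam-hardening physics
beyond a linear density calibration. All defaults assume the acquisition
regime the package targets: ~10 µm isotropic voxels over a ~6 mm
mid-diaphyseal window centred on the fracture gap (620 slices at 10 µm).

## Volume of interest

The VOI is a cylinder defined by two circles drawn on the first and last
slice; centre coordinates and radius are interpolated *linearly* across the
stack (the simplest scheme consistent with two drawn end circles; vendor
software does not document its interpolation). A voxel is inside if its
centre is within (≤) the slice's circle. The VOI may generously enclose
air/marrow: every downstream quantity is either restricted to labelled
voxels or normalised per voxel, so the panel is insensitive to loose
contouring. That is the reason the panel excludes BV/TV and BMD, which
divide by the contour-dependent total volume.

## Segmentation

The "constrained" Gaussian filter is implemented as a separable truncated
kernel: radius = `support` voxels, weights ∝ exp(−i²/2σ²), renormalised to
unit sum, mirror boundaries. Support 0 (or σ 0) is exactly the identity;
constants are preserved; the operator is linear. Mirror boundaries avoid
darkening at the volume faces, which would bias the global thresholds.

Classification thresholds the two filtered copies with ≥ comparisons
(callus 150, cortex 370 on the stored grey scale, taken at face value —
the native bit depth is not rescaled). Cortex takes precedence where both
tests fire, so the three classes partition the VOI. Raising a threshold can
only shrink its class (monotonicity), matching the over-/under-estimation
behaviour seen when thresholds are mis-set.

The histogram module bins *raw* in-VOI values (the filtered copies are used
only for thresholding). Automated threshold suggestion smooths the
histogram with a moving average, takes the three tallest local maxima, and
returns the minimum-frequency bin between modes 1–2 and 2–3; with fewer
than three detectable modes it returns a failure flag and the caller keeps
the defaults.

Known behaviour at interfaces: with plateau greys (50, 250, 600) a marrow
voxel face-adjacent to flat cortex filters to ≈181 ≥ 150 and reads as
callus, and a densely-backed callus voxel adjacent to cortex filters to
≈378 ≥ 370 and reads as cortex. Segmentation errors on the phantom are
therefore confined to a one-voxel shell around true tissue interfaces
(asserted in the tests); on the 256³ phantom this puts per-class Dice at
≈0.98–0.996 rather than 1.0 even without noise. This mirrors the
partial-volume rims visible in real scans.

## Morphometry

* **BV** — voxel count × voxel volume.
* **BS / surface meshing** — marching cubes at level 0.5 on the binary
  field smoothed with a σ = 1 voxel Gaussian. Meshing the raw binary field
  overestimates curved surfaces by the staircase effect (≈ +9% on digitized
  spheres); with smoothing the error is < 0.5% for radii ≥ 15 voxels.
  Surfaces are left open where the structure meets the volume boundary, so
  VOI cut planes are not counted as bone surface.
* **Local thickness / Tb.Th.** — Euclidean distance transform gives each
  voxel its inscribed-sphere radius; radii are visited in descending order
  (binned, ≤ 50 passes) and each sphere paints its diameter over the voxels
  it covers, yielding the largest-inscribed-sphere thickness. Diameters use
  the half-voxel boundary convention `2·EDT − 1` voxels, which calibrates a
  single isolated voxel to exactly one voxel size; structures whose width
  parity places the optimal sphere centre between lattice planes (e.g. an
  even-width slab) read up to one voxel thin. Digitized cylinders at
  20 voxels diameter are recovered within 5%.
* **SMI** — 6·BV·S′/S² with BV the voxel count and S′ a *central*
  difference of mesh areas. Near an interface the σ-smoothed binary field
  approximates Φ(d/σ) of the signed boundary distance d, so meshing at
  levels Φ(∓δ/σ) displaces the surface by ±δ voxels; curvature-induced
  level shifts are equal at both offsets and cancel in the difference.
  Defaults σ = 1.2, δ = 1.25 voxels were fixed against the analytic
  references (sphere 4, rod 3, plate 0; measured 4.19 / 3.22 / 0.00). A
  one-sided difference or a direct EDT-based dilation both proved unstable
  (biases up to −50% on spheres) because discrete dilation moves the
  surface by less than its nominal offset. SMI of structures thinner than
  ~4 voxels is unreliable (the offset surfaces merge).
* **DA / MIL** — directions are a deterministic Fibonacci hemisphere
  (n ≥ 30, default 64). Per direction, a raster of parallel lines (default
  ≈1600, offsets jittered by a seeded RNG to break lattice aliasing) is
  sampled at 0.5-voxel steps by nearest-neighbour lookup; MIL = total
  in-phase length / entry crossings. The fabric tensor H is fitted by least
  squares on u′Hu = 1/MIL², axis lengths are eigenvalue^(−1/2), DA =
  longest/shortest ≥ 1. The `anisotropy_axis` is the eigen-direction most
  separated from the other two, which tracks the symmetry axis for both
  plate normals and rod axes. Results are deterministic given the seed;
  repeat-seed scatter on a 96³ structure is ~1%.
* **TMD** — mean calibrated density over the compartment eroded twice with
  the 6-connected structuring element ("two-voxel peeling", read as two
  single-voxel erosions); an explicit error names the peel depth if the
  compartment vanishes. Requires a density-calibrated volume.
* **BMC** — BV·TMD/1000 exactly (mm³ → cm³). Note that a *median* BMC over
  specimens is a median of per-specimen products, not the product of the
  BV and TMD medians.

## Density calibration

A linear least-squares map grey → mg HA/cm³ (exactly interpolating when
two pairs are given, e.g. air and the 1200 mg HA/cm³ phantom). Vendor
beam-hardening corrections are proprietary; only this linear hook is
exposed, a documented limitation when comparing absolute TMD across
scanners.

## Statistics

Median = middle order statistic (mean of the middle two for even n); IQR =
Q3 − Q1 with linear interpolation of order statistics. Pearson r with a
two-sided p from t = r·√((n−2)/(1−r²)), df = n−2. Association is computed
across group medians (the two modality cohorts are disjoint animals), so n
equals the number of groups — with four groups the p-values are exploratory
by construction. Regression lines are reported with the morphometric
parameter as the dependent variable, matching the convention of the
reference panel this module reproduces. The packaged reference table is a
verbatim transcription of published four-group medians and IQRs; these
absolute per-group values are *inputs* to the statistics stage, not
quantities the imaging pipeline claims to regenerate — they derive from
destructive animal experiments and undisclosed vendor algorithm details.

## Fracture phantom

The generator emulates a scaled rat mid-diaphysis inside a 2.56 mm
field of view (256³ at 10 µm): cortical outer radius 0.62 mm, wall
0.18 mm, fracture gap 0.5 mm, three wedge fragments of the cortical ring
rigidly displaced 0.12 mm, periosteal collar 0.50 mm. Trabecular callus is
a seeded Gaussian random field smoothed at a 0.05 mm correlation length and
thresholded at the quantile giving the requested fill fraction (default
0.5); the correlation length is set so callus local thickness lands near
0.1 mm, the magnitude reported for 21-day rat callus. Grey plateaus
(50, 250, 600) straddle the default thresholds; default noise sd is 30
grey values. Ground truth is the noise-free region assignment; the optional
intramedullary wire is brighter than cortex and is merged into the
cortical-bone class in the ground truth, because thresholding necessarily
classifies it as dense bone — a documented behaviour, not a claim about
metal artefacts.

What the phantom does **not** model: beam hardening, scatter, ring/streak
reconstruction artefacts, anatomically curved cortices, cartilage, and
grey-level gradients within a tissue. Passing the phantom tests therefore
demonstrates correctness of the geometry/filter/threshold pipeline under
idealised plateau contrast, not robustness to scanner physics.

## Problem sizes

The test suite uses 96–128³ phantoms and 33–120-voxel primitives; the
acceptance script runs the full 256³ phantom twice (noise-free and noisy)
plus the primitive oracles, completing in about a minute on one CPU.

## Known limitations

* Thresholds are interpreted on the stored grey scale; data acquired at a
  different dynamic range must be rescaled or re-thresholded.
* Tb.Th. parity: even-width slabs read one voxel thin (half-voxel
  convention above).
* SMI on sub-4-voxel structures and DA on structures without crossings in
  some direction (flagged by an explicit error) are out of the reliable
  regime.
* Absolute agreement with proprietary scanner software is not claimed; the
  published-literature definitions implemented here differ in undisclosed
  details (ridge handling, dilation steps).
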