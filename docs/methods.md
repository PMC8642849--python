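# Methods

This note documents the model implemented by `epidpredict`, the
choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about real data.

## Forward model

The package predicts the integrated EPID transmission image of an
IMRT/VMAT delivery in detector grayscale units; no absolute-dose (Gy)
calibration is attempted anywhere. The chain per control point:

1. **Fluence rasterization.** The MLC/jaw aperture is a union of
   axis-aligned rectangles (Millennium-120 leaf geometry: 10 outer
   1 cm pairs, 40 central 0.5 cm pairs, 10 outer 1 cm pairs, bank B on
   the negative-x side), projected to the detector plane by
   SDD/SAD = 1.5. Pixels straddling an edge get exact area fractions
   (the coverage factorizes into x- and y-overlaps). The aperture over
   a control-point interval is the mean of the two endpoint apertures,
   scaled by the interval's MU fraction; fluence carries MU units
   (ψ = 1 per MU in the open beam). Edges are ideal steps: all
   penumbra physics is deliberately deferred to the kernels.
   Leaf transmission defaults to 0 and is a configurable scalar added
   under closed leaves inside the jaw rectangle.
2. **Control-point up-sampling** (default factor 5) linearly
   interpolates leaves, jaws and MU fraction; gantry angles
   interpolate along the shortest arc so arcs crossing 360°/0°
   behave. N control points become 5(N−1)+1.
3. **Open image.** G₀ = (A·(ψ⊗k₁⊗k₂) + B)·HCM(r). Both kernels are
   sampled at pixel centres and normalized to unit sum, so the fitted
   response line (A, B) keeps its absolute meaning and only kernel
   *shapes* matter (the amplitudes c, aᵢ set relative weight within
   each kernel). Convolution is FFT-based with zero padding to linear
   size; equivalence with a direct double loop is a test, not an
   option. Default supports: 4σ for k₁ and 8/min(bᵢ) for k₂ — the
   latter captures ≥ 99.9% of the analytic kernel mass (a narrower
   support triggers a warning); supports are additionally capped at
   the map half-extent, since mass beyond the panel cannot register.
4. **Primary extraction.** Division by GFO(fs, r), with fs the
   Sterling equivalent square 4·Area/Perimeter of *that control
   point's* aperture at the isocenter scale (the per-control-point
   choice is the finer variant consistent with per-field commissioning
   of modulated deliveries).
5. **Attenuation.** Multiplication by exp(−a(r)·t/(1+b(r)·t)), with t
   the per-pixel water-equivalent thickness from ray tracing at the
   control point's gantry angle. Thickness maps are cached per 0.5°
   gantry bin.
6. **Scatter restoration.** Multiplication by (1 + SPR(L, fs, t, r))
   with per-pixel exit air gap L. The SPR was measured with per-setup
   air gaps; querying it per pixel strictly generalizes that geometry.
7. **Superposition.** Control-point images sum into the integrated
   image; the detector offset B is applied once per integrated
   acquisition (an integrated-mode readout has one offset, not one per
   control point). Negative grayscale is clipped to zero and counted.

Table lookups are multilinear on the stored grids; out-of-grid
coordinates clamp to the boundary (measurements extend to r = 10 cm
off-axis, L = 50 cm air gap), with the off-axis coordinate
r = √(x²+y²) evaluated per pixel in the detector plane.

## Commissioned parameters

| Parameter | Units | Source measurement |
|---|---|---|
| c, σ | –, cm | open 5/10/15/20 cm square fields |
| aᵢ, bᵢ | –, cm⁻¹ | same fields (penumbra + tails) |
| A, B | grayscale/MU, grayscale | 10×10 fields, 1–600 MU |
| HCM(r) | – | open 20×20 field, diagonal profile |
| GFO(fs, r) | – | open 3–20 cm fields, on/off axis |
| a(r), b(r) | cm⁻¹, cm⁻¹ | 0–40 cm solid water, 0–10 cm off-axis |
| SPR(L, fs, t, r) | – | full grid: 9 fs × 13 t × 11 r × 7 L |

Numerical choices:

* **Zero-field extrapolation.** The primary grayscale is the fs → 0
  limit of a quadratic least-squares fit of grayscale versus field
  size over all available field sizes. A quadratic is exact for any
  scatter contribution smooth in fs near zero; the polynomial order is
  a function argument for sensitivity studies.
* **Kernel fit.** Nonlinear least squares over
  (σ, w₂, w₃, log₁₀b₁, log₁₀b₂, log₁₀b₃), where wᵢ are the relative
  2-D *mass fractions* of the k₂ exponential components
  (aᵢ = wᵢ·bᵢ²·scale). Raw amplitudes span four orders of magnitude
  and make the objective's gradient vanish along the tail directions —
  fitting masses keeps every parameter O(0.1–1). Residuals are
  normalized per field to the central value and restricted to pixels
  within the commissioned horn profile's radial range (beyond it the
  clamped profile is not a model of the measurement). Two generic
  starts guard against local minima; on noiseless synthetic fields σ
  is recovered to 0.2% and the field RMS is 0.08% of the central
  value.
* **Horn extraction.** The 20×20 image is sampled bilinearly along
  both diagonals (averaged), normalized to the bilinear value at the
  exact central axis (an even grid has no pixel on the axis), pinned
  to exactly 1 at r = 0, sampled every 0.5 cm to 14 cm.
* **Attenuation fit.** Per off-axis bin, primaries at each thickness
  (extrapolated per air gap and averaged — the primary does not depend
  on the gap) are normalized to t = 0 and fitted with the saturated
  exponential; T(0) = 1 is enforced by the functional form. The
  saturation coefficient can be pinned (`fix_b=0` reduces the model to
  a pure exponential).
* **Monotonicity.** Commissioned tables are checked against the
  physically expected orderings (GFO ↑ fs, ↓ r; SPR ↑ fs, t, ↓ r, L;
  a(r) ↑ r). Violations are *reported*, never silently repaired;
  commissioned data is not altered.

## Ray tracing

Machine-frame coordinates: x lateral, y up, z along the couch,
isocenter at the origin; the gantry rotates the source (SAD 100 cm)
about z, the detector plane sits normal to the central axis at SDD
150 cm. The radiological path is the exact parametric voxel traversal
(all axis-plane crossings merged and sorted; each segment attributed
to the voxel containing its midpoint) — equivalent to Siddon's
incremental scheme and exact for piecewise-constant volumes. The exit
air gap is the distance from the far boundary of the last segment with
RED > 0.05 (excludes air, keeps lung; configurable) to the ray's end;
rays meeting no such material use L = SDD by convention, and t = 0
pixels query the SPR at t = 0, where the table reduces to open-beam
scatter. HU volumes convert to RED by piecewise-linear interpolation
of a monotone calibration table, clamped at the ends.

## Gamma comparison

Global gamma with dose difference as a percentage of the reference
image maximum, DTA in mm, and a low-dose threshold applied to the
reference only; excluded pixels are NaN, never 0. The search
interpolates the evaluated image bilinearly over a disc of radius
3·DTA in two stages: a coarse global pass at DTA/10 steps (with an
early exit once the pure distance term exceeds every pixel's current
best), then a vectorized local refinement at DTA/100 steps in a
±1.5-coarse-step box around each pixel's coarse optimum. The
refinement matters: the distance-term quantization of a DTA/10-only
search is itself ~0.05 in gamma near zero. Against an exhaustive
DTA/100 dense search the two-stage result agrees to < 0.01 for image
pairs in the clinically relevant range (disagreements up to a few
percent of the normalization); for pathological pairs with gamma ≫ 1
the basin found by the coarse pass may differ harmlessly.

## Synthetic truth model

The generator stands in for the Linac + detector. Its tables are
smooth closed forms chosen to reproduce the qualitative behaviour of
measured data (all constants are this package's choices):

* GFO(fs, r) = 1 + (0.004·fs + 10⁻⁴·fs²)·exp(−r/30 cm) — head/detector
  scatter grows with field size (GFO ≈ 1.05 at 10 cm, 1.12 at 20 cm)
  and decays off-axis. Polynomial in fs, so the quadratic zero-field
  extrapolation is *exact* and the commissioning round-trip isolates
  implementation error rather than model mismatch.
* a(r), b(r): measured-beam attenuation rows at 1 cm off-axis spacing,
  a rising from 0.0575 to 0.0640 cm⁻¹ (off-axis softening).
* SPR(L, fs, t, r) = (GFO−1)·(1 + 0.05·t)·(50 cm/L) — rises with field
  size and thickness, falls off-axis and with air gap, spans ~0–0.9
  over the measurement grid, and reduces to the open-beam scatter
  GFO − 1 at t = 0 and the reference gap (queries beyond L = 50 cm
  clamp there, preserving open-beam consistency).
* HCM(r) = 1 + 3·10⁻⁴·r² (≈ 3% horn at 10 cm); response A = 2.67·10⁵
  grayscale/MU, B = −168.
* Noise: multiplicative Gaussian, σ = 0.5% of the local signal,
  seeded; commissioning readings are noiseless by default.

Commissioning *table* measurements are stored as field-centre ROI
readings (small uniform patches with setup metadata), which is what
the GFO/attenuation/SPR fitters consume; kernel, horn and response
commissioning uses full 2-D images generated through the forward
model. The `offset_r` metadata is the detector-plane off-axis distance
of the reading (realized by moving the MLC laterally by r/1.5 at the
isocenter plane).

The stylized thorax phantom is an elliptical body (semi-axes 15 × 10
cm, 28 cm long, RED 1.0) with two RED 0.2 ellipsoid lungs (semi-axes
4 × 6 × 10 cm at x = ±9.5 cm). The lungs sit lateral to the central
mediastinal channel so a central anterior field sees smoothly varying
thickness — the property of the physical thorax phantom that makes
small setup shifts nearly invisible in the transmission image. All
chords are hand-computable from the analytic geometry.

Error catalogue (e1–e17): MU scalings of +1/+3/+5/+10/−5%; phantom
shifts of 5/10/20 mm laterally and anteriorly; MLC apertures opened
5 mm (interpreted as total widening, 2.5 mm per bank), both banks
shifted 5 mm, in-field bank-B leaves shifted 5 mm, central four pairs
opened 10 mm; gantry offsets of +5°/+10°.

**What passing tests do not show.** The generator's measurements are
produced by the same forward-model family that is being fitted, with
idealized noise; real EPIDs add glare, lag, backscatter structure,
beam-spectrum effects and acquisition artifacts that are absent here.
Round-trip recoveries and the ≥ 99% closed-loop gamma pass rate
demonstrate internal consistency and correct implementation of the
calibration algebra — not clinical accuracy. Only the *directions* of
the error-sensitivity results (MLC-opening worst, MU errors graded by
magnitude, small setup shifts benign) are claimed transferable.

## Problem sizes

Tests and the acceptance script run on a 128 × 96 detector grid (8×
binning of the 1024 × 768 panel, 0.3125 cm pitch), 0.5 cm phantom
voxels, and 8–11-control-point plans up-sampled ×5; these are the
package's default study scale, chosen so the full loop stays
interactive. Production use at 2× binning is a configuration change
(`RunConfig.binning`), not a code path change.

## Known limitations

* Collimator rotation, couch modelling, within-interval dose-rate and
  gantry-speed dynamics are out of scope; rounded-leaf-end and
  tongue-and-groove effects are absorbed into k₁ rather than modelled.
* The response offset B is treated as a single per-acquisition
  constant; detectors with MU-rate-dependent offsets would need a
  per-control-point treatment.
* Whether head-scatter fluence belongs in ψ or in GFO is not
  observable from the measurements used here; ψ is pure aperture
  fluence and commissioning absorbs the residual.
* The gamma search is exact only up to its refinement resolution
  (DTA/100) and, for gamma ≫ 1, up to coarse-pass basin selection.
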