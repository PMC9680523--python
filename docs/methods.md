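# Methods

This note documents the models, algorithmic choices and defaults behind
`octlayers`, and what the synthetic-phantom evaluation does and does not
demonstrate.

## Coordinate conventions

All processing happens in polar coordinates: a frame is indexed
(angle bin, radial bin) with angle bin 0 at θ = 0 increasing
counterclockwise and radius measured from the catheter center; a pullback
stacks frames along the slice axis. The radius attached to radial bin j is
the bin center (j + 0.5)·Δr. The default radial pixel pitch Δr is
0.0045 mm, matching the ~4.5 µm resolution of contemporary intravascular
OCT systems, and is configurable because device pixel pitch may differ
from optical resolution. Cartesian input frames are converted by bilinear
resampling about a configurable center.

## Synthetic phantom

The phantom emulates the features of a diseased coronary OCT pullback that
drive segmentation difficulty, with exact ground truth:

* **Geometry.** Each boundary (lumen, IEM, EEM, ADV) is a mean radius plus
  low-order Fourier terms in angle plus a single-period sinusoidal drift
  along the pullback. Defaults: lumen 0.85 mm with ±0.06/±0.03 mm Fourier
  terms; layer thicknesses ≈ 0.65 mm (thickened intima), 0.24 mm (media),
  0.22 mm (adventitia) — values typical of diseased segments where the
  plaque-bearing intima dominates the wall. The drift is band-limited by
  construction so the slice-to-slice continuity assumption behind edge
  propagation holds, with a drift rate of well under one radial bin per
  slice at the default 60 slices.
* **Intensity.** Region means 8 (lumen), 185 (intima), 70 (media), 150
  (adventitia), 30 (periadventitia) on the 0–255 scale produce the
  light–dark–light radial signature: the noise-free profile rises and
  falls exactly twice. An exponential decay of 0.5 mm⁻¹ beyond the lumen
  boundary emulates depth attenuation while preserving the pattern.
* **Speckle** is multiplicative mean-one log-normal noise
  (σ = 0.15 by default) followed by clipping to [0, 255]; this is the
  simplest model reproducing OCT's intensity-proportional grain, chosen
  over a physically detailed coherent-speckle simulation (out of scope).
  Because the noise is mean-one, per-region sample means estimate the
  attenuated noise-free means; tests compare against a noise-free render
  of the same spec, excluding near-clip pixels where the truncation biases
  the mean.
* **Occlusions.** Lipid-shadow sectors multiply all pixels beyond a stated
  depth by a small suppression factor over a (slice range × angle range)
  block; defaults are two sectors of 110° and 100° over 20 slices each,
  sized so that more than half the wall remains visible on every slice —
  consistent with the reported visibility of the external elastic lamina
  over >180° in the large majority of OCT slices. A guidewire sector
  (15°, suppression 0.05, all slices) darkens whole A-lines.

What passing phantom tests does **not** show: performance on real OCT with
layered plaque patterns, calcification, side branches, motion artifacts or
non-monotone attenuation. The phantom's boundaries are smooth and
band-limited by design, which flatters the spline repair relative to
focally irregular disease.

## Lumen segmentation

Otsu's threshold is computed over all 256 integer gray levels with ties
broken toward the lowest level; the binary tissue mask is cleaned by
opening then closing with a 4-pixel square element (the order is a
package choice; only "successive" application is prescribed by the
method), restricted to the largest connected component with the angular
axis treated as circular (components touching across the 0°/360° seam are
merged — without this the guidewire gap severs the wall ring), and the
first tissue pixel per A-line gives the radius. Contours are smoothed by a
circular 50-bin moving average; the 50-pixel bandwidth is read as angular
bins, the contour's sampling axis. Invalid bins (guidewire, no tissue) are
pre-filled by periodic linear interpolation. The boxcar preserves the
circular mean exactly and attenuates high angular orders; at 360 bins the
order-1 and order-2 attenuation is 3% and 12%, the dominant contributor to
the residual sub-bin lumen error.

## Layer detection

Frames are flattened to the detected lumen (integer circular shifts,
recorded for exact inversion). On the flattened frame the radial first
derivative exhibits valley–peak–valley at IEM–EEM–ADV. Candidates come
from `skimage.feature.canny` with angular wrap padding of 3× the Gaussian
radius; contiguous same-sign edge-pixel runs along an A-line are collapsed
to the strongest pixel. Candidates are confined to a whole-wall band: from
just past the lumen-entry gradient to the end of the contiguous
above-floor run of smoothed intensity (floor 20/255) plus a margin. Using
the contiguous run (rather than the last bright pixel anywhere) excludes
both the signal-free interior of full-suppression shadows and the data
wrapped to the deep end of the A-line by the circular flattening shift.
Valleys are split into valley1/valley2 by position relative to the
strongest peak on that A-line. Guidewire A-lines, dilated by twice the
Gaussian radius (the shadow border itself reads as an edge), produce no
candidates.

Seeding generalizes "pick the true edges on the first slice" to any seed
slice with bidirectional propagation, so users can seed on the clearest
frame; batch runs select per-bin candidates nearest to a supplied
reference contour (ties toward the smaller depth). Propagation accepts,
per boundary and angle bin, the nearest same-label candidate within a
tolerance of 10 radial bins (≈45 µm) of the last accepted depth at that
bin; misses leave a gap and the reference carries forward. Bins whose
accepted depths violate IEM < EEM < ADV are demoted to gaps entirely —
the minimal deterministic repair. The Canny defaults (σ = 5 px, low/high
thresholds 0.03/0.06 on the 0–1 image) were fixed by running the provided
grid search (`tune_canny`; objective = mean absolute depth error plus a
10-bin penalty per unmatched reference bin, ties broken lexicographically)
against phantom ground truth; real-device data should be re-tuned against
a few manually annotated slices.

## Surface repair

Accepted contours are reverse-flattened and stacked into radius surfaces
r(θ, z), one per boundary (the lumen surface carries the guidewire holes
through the same machinery for uniformity). Completion fits a
tensor-product cubic B-spline — uniform periodic in angle (10
coefficients, i.e. 36° knot spacing), clamped uniform along the pullback
(n/10 + 2 coefficients) — by least squares on the known samples with a
second-difference coefficient penalty. The smoothing weight is selected
per surface by generalized cross-validation over λ ∈ 10⁻⁴…10. The basis
is deliberately coarse: every tensor coefficient then keeps data support
even under a 120°×20-slice hole, which keeps the GCV solution stable;
a vessel boundary is smooth at this scale, and angular detail is restored
by the known samples themselves because **known bins keep their measured
values** — only holes take the spline value. This makes repairing a
complete surface a no-op and the fit exactly idempotent, and yields exact
(≤1e-6 mm) recovery of surfaces lying inside the spline space from 70% of
their samples at smoothing 0.

Finalization smooths each completed boundary with the same circular
moving-average operator (window 15 bins), enforces
lumen < IEM < EEM < ADV by minimal outward projection (logged; a hard
error if more than 5% of bins need projection), and converts to Cartesian
x = r cosθ + cx, y = r sinθ + cy.

## Thickness metrics

Quarters are bounded by the four axis-aligned rays from the lumen
centroid (a deterministic, rotation-reportable choice; the quarter
definition is otherwise unconstrained). Each quarter carries 25 nodal
points at arc-length fractions (m+0.5)/25, avoiding nodes exactly on the
rays. The piecewise equal-step correspondence marches from each lumen node
along the local outward normal of the current boundary to the nearest
intersection with the next boundary (lumen → IEM → EEM → ADV); if the
normal ray misses, the nearest point on the next boundary is used and the
node is logged. Layer thicknesses are the segment lengths, so
intima + media + adventitia equals the lumen→ADV connecting-path length by
construction.

The thickness tensor T_q(i, j, k) supports three aggregation levels:
per-slice point means; per-pullback slice means; and an overall mean
reported both pooled (every sample weighted equally, i.e. pullbacks
weighted by slice count) and with equal pullback weights, since either
reading of a multi-patient average is defensible. Signed relative errors
are 100 × mean(auto − manual)/mean(manual) per slice (negative ⇒
automatic thinner), averaged over slices and then patients; slices with
zero manual mean are excluded and counted. Percentiles use numpy's linear
interpolation between order statistics. Point-to-point contour distances
are signed per-angle radial differences (auto − manual) about the shared
center, with periodic linear resampling on grid mismatch.

## Constitutive model

The strain-energy density is the modified Mooney–Rivlin form with an
exponential isotropic stiffening term and one fiber family at angle φ
from the circumferential direction in the θ–z plane (I₄-based). Shipped
parameter sets (kPa / dimensionless):

| tissue | c₁ | c₂ | D₁ | D₂ | K₁ | K₂ | φ |
|---|---|---|---|---|---|---|---|
| lipid (isotropic) | 0.5 | 0 | 0.5 | 1.5 | – | – | – |
| intima | −262.76 | 22.9 | 125.9 | 2.0 | 7.19 | 23.5 | 0° (assumed) |
| media | −5 | −20 | 20 | 2.8 | 168 | 57 | 24.9° |
| adventitia | 6.16 | 0 | 0.03 | 30 | 10 | 54 | 75.3° |

The intima set carries fiber moduli but no published fiber angle; the
package assumes circumferential fibers (φ = 0), the conservative choice
for a ring-shaped layer, and exposes the field for override. Uniaxial
response assumes incompressibility with traction-free lateral directions:
the free in-plane stretch solves ∂W/∂λ_lateral = 0 (root-bracketing with
continuation along the stretch grid, which keeps a continuous branch
despite the non-convex isotropic parts with negative c₁), and Cauchy
stress follows from the envelope theorem, σ = λ·∂W/∂λ at the equilibrium
lateral stretch. The default stretch grid [1.0, 1.5] is a pragmatic
range; convexity outside it is not asserted. W(identity) = 0 and σ(1) = 0
hold exactly because every term vanishes at I₁ = I₂ = 3, I₄ = 1.

The geometry pre-shrink divides slice spacing by the axial stretch
(default 1.05) and scales contour radii by (1 − circumferential shrink).
Scaling about the polar center equals scaling about the lumen centroid up
to a rigid in-plane translation, so layer thicknesses, perimeters and
areas are unaffected by the choice. The circumferential shrink has no
published default and is a required user input. Finite-element stress
analysis is explicitly out of scope.

## Problem sizes and numerical checks

The end-to-end evaluation uses the default phantom suite — 60 slices ×
360 A-lines × 500 radial bins, speckle σ = 0.15, two lipid-shadow sectors
(110°/100° over 20 slices each) and a 15° guidewire sector — which a
single CPU processes in well under a minute; unit fixtures use 6–12-slice
variants with the drift rate scaled to the shorter pullback. Oracle
checks (Otsu vs exhaustive search, thickness statistics vs nested-loop
evaluation, percentile vs sort-and-interpolate) agree to ≤1e-10 relative;
analytic uniaxial stress matches central-difference differentiation of
the reduced energy to ≤1e-4 relative; spline recovery of in-space
surfaces is exact to ≤1e-6 mm; two runs with the same config and seed
produce byte-identical contour CSVs.

## Known limitations

* No automatic plaque-component classification (lipid/calcium) and no
  layered-plaque disambiguation; those phenomena are also absent from the
  phantom.
* Guidewire detection assumes a near-total radial shadow over a
  contiguous angular run; partial or split shadows need manual masking.
* The repair's coarse angular basis (36° knots) smooths away focal
  boundary irregularity sharper than ~20°; reduce the knot spacing (and
  expect to need stronger smoothing) for focally irregular vessels.
* Seed selection in batch mode requires a reference contour on the seed
  slice; fully unsupervised seeding is not attempted.
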