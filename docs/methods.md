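# Methods

This note documents the models, conventions and design choices behind
fiberdiam, in the spirit of a software methods section: what each stage
computes, which knobs matter, and what the synthetic validation does and
does not demonstrate.

## Segmentation

Three histogram-shape thresholding criteria are implemented from their
published definitions (scikit-image provides none of the latter two, and
a single code path serves both global and windowed use):

* **Otsu** — maximize between-class variance ω₀ω₁(μ₀ − μ₁)².
* **Huang** — minimize the fuzzy Shannon entropy Σ h(g)·S(u_g) with
  membership u_g = 1/(1 + |g − μ_class|/C).
* **Minimum error (Kittler–Illingworth)** — minimize
  1 + 2(P₁ln σ₁ + P₂ln σ₂) − 2(P₁ln P₁ + P₂ln P₂), both classes
  modelled as Gaussians (variances floored at 1e-8 to keep the
  criterion finite on near-empty classes).

A pixel is foreground iff its intensity is strictly greater than the
threshold; ties go to background. Fibers are assumed brighter than
background (`invert` handles the opposite). The test suite checks each
criterion against an exhaustive 256-point scan; agreement is asserted on
the *attained criterion value* because runs of empty histogram bins make
the arg-optimum a tie.

**Local mode** evaluates the chosen criterion on window-sized
neighbourhoods centred on a half-window grid (image reflected at the
borders) and classifies each pixel against the bilinearly interpolated
threshold surface (plus a 1e-6 epsilon so interpolation noise cannot
break the tie rule). Exact per-pixel window histograms would cost
O(H·W·window²) and are not worth it: the threshold field of a real
micrograph varies on the illumination scale, far coarser than a half
window. A window at least as large as the image reproduces the global
result exactly; constant windows threshold at their single value, which
the strict-> rule sends to background. The conventional window size is
the mean fiber diameter plus 10 %, rounded odd. Because that diameter is
only known after measurement, the pipeline bootstraps: global segment →
measure the mean fiber diameter → derive the window → local re-segment.

**Mask refinement** is a 3×3 median filter iterated to a fixed point
(capped at 100 rounds with a warning; convergence is byte equality),
then one erosion–dilation–erosion round with a 3×3 square element.
Erosion treats beyond-the-border as foreground so strokes crossing the
field of view are not eaten from outside; the round thins strokes by at
most two pixels and removes isolated pixels. Refinement can split a
pinched component in pathological masks, so the "component count never
increases" property is only claimed (and tested) for fiber-like inputs.
Binary inputs bypass the whole segmentation stage, including refinement
— they are taken as already clean.

## Centerline and diameters

The centerline is the axial-thinning skeleton of the mask
(`skimage.morphology.skeletonize`) with endpoint spurs pruned when a
branch runs into a junction in fewer pixels than 1.5× the junction's
EDT radius — thinning grows such artifacts at stroke ends and crossings.
Skeleton pixels with ≥3 neighbours (8-connectivity) are crossing pixels,
clustered 8-connectedly into intersection sites; the remaining pixels
form segments whose length is counted as axial links + √2·diagonal
links, skipping diagonal links that shortcut an L-corner.

**Diameter convention.** The local diameter at a centerline pixel is
2×EDT with no ±1 pixel-width correction. The EDT is evaluated on a
4-fold supersampled grid (per coarse pixel, the maximum over its 4×4
block plus half a fine pixel): this measures distance to the background
*region* from the best-centred subpixel position, which removes two
biases that dominate at small diameters — the lattice quantization of
pixel-center distances (a 3 px stroke has no pixel-distance near 1.5)
and the up-to-half-pixel offset of the thinned centerline from the true
one. On mixed-angle 1280×960 phantoms this keeps the mean error within
about 2 % from 3 px to 250 px strokes. `supersample=1` recovers the
plain pixel EDT and `edge_correction=True` the 2×EDT − 1 reading (exact
for axis-aligned strokes only).

**Sample exclusion.** Centerline pixels are dropped when they lie
within one local radius of a crossing pixel (the radius is the EDT at
the crossing pixel itself, which is inflated there and so covers the
merged blob), within 1.5× the segment's maximum radius of a centerline
endpoint (stroke caps and border clipping taper the EDT), or closer to
the image border than their own radius (partially clipped fibers read
thin). If exclusion would remove everything, all pixels are kept rather
than failing.

Retained diameters are binned at 1 px by default, bins centred on
integer multiples of the bin width. All computation is in pixels; a
µm/px scale converts bin centers and summary values at output time only.

**Super-pixel estimate** = foreground area ÷ total centerline length,
with n_crossings × d̂² subtracted from the area (d̂ = 2× the median
centerline EDT, robust to crossing-blob inflation), floored at half the
raw area. It is accurate on sparse straight phantoms (≤5 % on bars with
length ≫ width) but reads low on dense curly mats, where the per-crossing
d̂² undercounts shallow-angle overlaps and thinning shortens the
centerline slightly; the histogram mean is the primary estimator.

**Local thickness** assigns every foreground pixel the diameter of the
largest inscribed circle containing it. A circle centred at c has radius
EDT(c) and contains pixel p when |p − c| ≤ EDT(c) − 1; the reported
value is 2·EDT(c) − 1 by default so a 25 px bar reads 25 across its
interior. Centers whose circle is wholly contained in a neighbour's
(EDT(n) ≥ EDT(c) + |n − c|) are pruned before painting — an exact
reduction to roughly the distance ridge. The implementation equals an
exhaustive inscribed-circle enumeration on arbitrary masks (tested on
randomized suites up to 64×64).

## Pore and network statistics

Porosity is the background fraction. Mean mesh hole size is the mean
area of 4-connected background components not touching the image border
(border pores have unknown true extent; `include_border_pores=True`
keeps them). Intersection density is crossing sites per unit area;
characteristic fiber length is total centerline length ÷ number of
segments. These four definitions are this package's interpretations of
the conventional summary-table names; none has a canonical formula in
the literature.

## Orientation and NOI

Orientation is measured on the centerline, not the filled mask, so thick
fibers do not dominate by area: the skeleton is dilated by 2 px (disk),
gradients are taken spectrally (FFT derivative — the Fourier-gradient
flavour of structure-tensor analysis), and the tensor is smoothed with a
Gaussian window of σ = 7/6 px, truncated so the kernel is exactly 7×7
(±3σ). The fiber direction is the minor eigenvector; angles use the
screen convention (counter-clockwise positive, x-axis zero) on
[−90°, 90°) with 1° bins, counted per enlarged-centerline pixel (not
weighted by segment length). On rasterized straight-line phantoms the
modal angle lands within ~2° of the drawn angle; the residual comes from
staircase rasterization, which locally favours axis-aligned runs.

NOI = (90 − x)/90 × 100: find the modal bin (ties → smallest angle),
grow the window one bin per side with wraparound on the 180° circle
until it holds ≥ half the total counts, and read x as the half-width in
degrees from bin centers. A uniform histogram needs x = 45 (NOI = 50),
a single occupied bin x = 0 (NOI = 100). With the ≥ rule, a histogram
whose modal bin alone holds exactly half the mass (e.g. two equal
spikes) stops at x = 0; a strict > rule would instead run to the second
spike. The ≥ reading is used because the expansion is defined to
*capture* half the mass, not to exceed it.

## Peak fitting and error metrics

Multi-modal diameter histograms are fit with a sum of Gaussians plus a
constant baseline (lmfit, ordinary least squares on counts — no Poisson
weighting). Initial centers come from the strongest well-separated local
maxima; sigmas are bounded below by a quarter bin. Peaks are returned
sorted by center and matched to ground-truth diameters in that order.
FWHM ↔ σ conversion is exact: σ = FWHM/(2√(2 ln 2)).

The pooled diameter standard deviation across peaks and images is
computed as √(Σσᵢ²)·N/T (N peaks, T images) behind a named strategy
("rss_scaled"), with plain root-sum-of-squares and mean-σ alternatives —
the conventional printed formula for this quantity is typographically
ambiguous, so the reading is swappable without touching callers.

## Synthetic calibration images

The generator emulates hand-drawn validation sets: 8-bit 1280×960
canvases, white strokes on black, five families (ordered/disordered ×
one/three diameters, plus multi-diameter disordered sets with 2, 3, 4 or
6 distinct diameters). A stroke of diameter d is the set of pixels whose
centers lie strictly inside the continuous capsule of half-width d/2
around the center path; odd diameters center on a pixel row, even ones
on a half-pixel line, so axis-aligned widths are exact and 2×EDT at the
centerline reads d to within a pixel at any angle. Straight strokes use
exact point-to-segment distances; curved strokes cubic-spline-resample a
curvature-bounded random heading walk (minimum bend radius 2× the
diameter) and rasterize via a KD-tree on a 0.25 px path sampling, whose
one-sided error means borderline pixels are dropped, never added.

Free parameters the source material does not constrain, chosen once:

* **Coverage** ≈ 30 % foreground by default (realistic for scaffold
  micrographs); line count (single-diameter families) or per-line length
  (multi-diameter families) is derived from it.
* **Random diameter plans** draw distinct diameters from 5–60 px with a
  minimum gap of 8 px (so that multi-peak histograms remain resolvable)
  and frequencies uniform on [0, 25] with zeros promoted to 1.
* **Placement rejection**: a straight-line placement is redrawn when it
  would cross an earlier stroke so shallowly that the d₁d₂/sin α overlap
  patch exceeds 8 % of its own area, or run near-parallel closer than
  the summed radii — merged strokes measure as one thick fiber and have
  no hand-drawn counterpart.

`verify_manual_width` automates the classic manual check: at random
centerline sites it counts contiguous foreground along the local
perpendicular in quarter-pixel steps.

**What the phantoms do not show.** They are noise-free, perfectly
bimodal, unshaded and exactly binary; passing on them validates the
geometry of the measurement chain (skeleton, EDT, exclusion rules,
peak fitting), not robustness to SEM noise, charging artifacts, depth
blur or segmentation error on real micrographs. The gradient-phantom
test covers only smooth multiplicative-style illumination drift.

## Numerical choices and degenerate inputs

* Thresholding a constant image raises a degenerate-histogram error in
  global mode; constant local windows threshold at their value.
* Empty masks raise empty-input errors in skeleton/diameter/thickness
  paths; pore statistics report porosity 1 with NaN elsewhere.
* Skeletons reduced to nothing by pruning fall back to the unpruned
  thinning; exclusion rules that would drop every sample keep all.
* Histogram mode ties resolve to the smallest bin; modal-angle ties to
  the smallest angle.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); rendering, measurement and the pipeline
  are deterministic given their inputs, and CSV output uses a fixed
  float format so reruns are byte-identical.

## Problem sizes used in the validation suite

The packaged tests exercise full 1280×960 phantoms for the diameter
sweep (3–250 px), multi-peak recovery on four multi-diameter phantoms
(2, 3, 4, 6 peaks), thickness-oracle equivalence on fifty masks up to
64×64, and threshold-oracle equivalence on twenty synthetic bimodal
histograms; smaller canvases (≤640×480) serve the per-module unit tests.
These sizes were chosen to keep the whole suite comfortably fast while
covering the full diameter range the phantom families span.
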