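# Methods

## Segmentation

Nuclei are detected on the Hoechst channel after Gaussian smoothing
(σ = 1 px): Otsu's threshold separates nuclei from background by default,
with a fixed-value override for non-bimodal material. Because Otsu always
returns *some* threshold, a guard rejects the split when the foreground
mean exceeds the background mean by less than 4 background standard
deviations — this is what makes a cell-free noise field segment to zero
nuclei instead of one giant artifact. Components smaller than
`min_nucleus_area_px` (default 20 px) are discarded.

Fragmenting apoptotic nuclei pose a labeling dilemma: their sub-lobes are
separate connected components but one biological object. We close gaps up
to `fragment_merge_radius_px` (default 4 px) *for labeling connectivity
only* — the region keeps its original, possibly disconnected pixels, and
the number of connected components becomes the `nucleus_fragment_count`
feature. The converse ambiguity (two distinct nuclei bridged by the
closing) is resolved by component size: pieces larger than
`fragment_max_component_px` (default 100 px) are whole nuclei and are
separated; smaller pieces are fragments and stay together. At default
geometry fragments are ≤ ~90 px and whole nuclei ≥ ~200 px, so the two
regimes do not overlap.

Stuck (touching) nuclei are split by a watershed on the smoothed distance
transform; h-maxima suppression with depth `(1 − sensitivity) × max
distance` realizes a scalar "splitting value": sensitivity 1 splits at
every local maximum, sensitivity → 0 never splits, and the label count is
monotone in the sensitivity. The default of 0.5 is conservative; visibly
clumped material calls for 0.7–0.9.

Cell bodies are grown from nuclear seeds over the dim cytoplasmic Hoechst
halo (pixels above `cytoplasm_threshold_factor` × nuclear threshold,
default 0.5); competing seeds partition shared halo by geodesic proximity
(watershed of the distance-to-nucleus map restricted to the halo). The
four regions are then: nucleus; cell (nucleus + halo territory);
cytoplasm = cell \ nucleus; eroded nucleus = per-nucleus disc erosion of
radius `round(0.05 × equivalent_radius)`, minimum 1 px. We read the "5%
erosion from the outer border" as a radius fraction per nucleus rather
than a fixed pixel count so the operation is scale-invariant across
magnifications; a 1-px nucleus erodes to the empty set, in which case the
cell is kept and eroded-region features are missing. Cells whose *nucleus*
touches the frame border are removed entirely; a cell whose cytoplasm
alone reaches the border is kept.

Background is the per-field, per-channel median intensity of pixels
outside every cell region (computed before border-cell removal so bright
discarded cells cannot leak into it). The assay's "n-fold above
background" rules are expressed in units of this estimate. At least 1% of
the field must be background; denser fields must configure a fixed value.

## Features

For each region × channel we record mean, population SD, max, integrated
intensity, and the background ratio (region mean ÷ field background).
Morphology: areas, perimeters (boundary-step with diagonal correction, via
`skimage.regionprops`), circularity `4πA/P²` (clipped to 1 against
rasterization excess), roundness `4A/(π·major_axis²)`, equivalent radius,
nuclear/cytoplasm area ratio, and fragment count.

Texture follows the spots/edges/ridges semantics at one Gaussian scale
(default 2 px at 10×): edges = gradient magnitude; spots = √|det H| of the
Hessian (large only where both principal curvatures are large — blobs);
ridges = |λ_hi| − |λ_lo| (curvature anisotropy — large on lines, zero on
blobs and flat areas). The vendor formulas behind commercial "SER"
features are proprietary; these open definitions reproduce the intended
ordering (a dot scores spots > ridges, a line ridges > spots). The input
is mean-subtracted before filtering, so constant regions score exactly
zero and additive offsets cancel; region means of the responses are then
divided by the region mean intensity, giving invariance to illumination
scaling.

The supervised backend consumes a fixed 22-feature vector (16 nucleus + 6
cell body) spanning every feature family; it is isolated behind a named
tuple (`SUPERVISED_FEATURES`) so an alternative realization can be swapped
in without touching the model code.

## Classification

Gating is a two-step tree on two ratios, both compared strictly (`>`,
so a ratio of exactly 2.0 falls in the negative branch): nuclear Yo-Pro-3
ratio > 2 → late/necrotic branch, else healthy/initial; then whole-cell
annexin V ratio > 2 splits each branch (late vs necrotic; initial vs
healthy). The Yo-Pro readout uses the eroded-nucleus region whenever
erosion is enabled (falling back to the plain nucleus for degenerate
erosions), matching the practice of reading the dye away from the nuclear
rim. Cells missing a required ratio are excluded with a logged reason,
never dropped silently. Morphology cues used when annotating by eye
(circularity < 0.8, collapsed nuclear/cytoplasm ratio, blebbing) are
exposed as features to the trained backends rather than hard-coded into
the gate, which as defined consumes only the two dye ratios.

The linear backend is a shrinkage-regularized linear discriminant
(`lsqr` solver) on standardized features; prediction is the argmax of the
per-class linear scores with ties resolved to the first class in canonical
order. Training requires at least 40 annotated cells per class — a hard
contract, not a warning. The supervised backend is
`HistGradientBoostingClassifier` on the 22-feature vector; NaNs are
handled natively. Both backends sort training rows canonically before
fitting so row order cannot change the model.

Post-classification morphology flags catch "healthy-but-not-normal"
cells: a healthy-classified cell is `senescent_like` when both nucleus
and cell area exceed the vehicle-control 95th percentiles (expected false
positive rate ≤ 5% by construction); a well is `enlarged` when its median
cell area exceeds 1.5× the control median. Fewer than 50 reference cells
skips flagging with a warning.

## Dose–response

Cells are pooled across the fields of a well; wells are the replicate
unit. The response for IC₅₀ is the percentage of healthy cells by default
(normalized healthy count optional). The 4PL is fitted on log₁₀
concentration by Levenberg–Marquardt from a 20-point multi-start grid
(5 log-spaced inflection guesses × 4 slopes including a negative one);
the bottom ≤ top convention is restored post hoc via the 4PL's
(bottom↔top, h→−h) symmetry. Convergence is honest: flat responses
(SD below tolerance), non-finite parameters, or an IC₅₀ more than 3
decades outside the tested range report `converged=False` with no IC₅₀.
Vehicle wells (concentration 0) are excluded from the fit and reported
alongside. Replicate CV% is `100·sd/mean` with the sample SD (n−1).

## Synthetic data

The generator emulates what the classifiers actually consume, not optics:
nuclei are flat-top (super-Gaussian, exponent 6) blobs with low-order
Fourier boundary irregularity; the cytoplasm halo is a larger dim blob in
the Hoechst channel (amplitude 0.5× background over a 100-count offset);
annexin V positivity is a Gaussian ring (σ = 2 px) at the cell boundary;
blebs are satellite blobs on the boundary; fragmentation splits the
nucleus into 2–5 sub-blobs offset by 0.85 radii. Dye amplitudes are
quoted as fold-over-background (healthy/initial Yo-Pro 0.3×, late/necrotic
3×; annexin ring 5× where present) so each class's rendered region-mean
ratios satisfy its defining inequalities before noise — at high SNR,
gating accuracy approaches 100% by construction. Gaussian read noise
(SD 5 counts) is added per channel; Poisson shot noise is optional.
Stuck-pair rendering places a partner nucleus at 2.0 radii: close enough
that thresholded footprints touch, far enough that a distance-transform
saddle exists for the splitter (flat-top profiles closer than ~2 radii
merge into a single saddle-free blob, which no intensity-based splitter
can divide).

Annotation sets emulate reference wells treated with death-mode inducers:
each field is *predominantly* (70%) one phenotype with the remainder
spread across the others, because inducer compounds drive a predominant,
not exclusive, death mode — and because training on phenotype-pure,
contamination-free wells was observed to make tree models brittle to the
neighbor-contaminated feature distributions of mixed wells. Labels come
from per-cell ground truth matched by nucleus centroid (≤ 10 px). The
fragmented dye-negative phenotype (intensely stained, 3–5 lobes, both
dyes negative) is annotated as initial apoptotic when included, mirroring
the by-eye call for that morphology; the gate, by definition, calls those
cells healthy.

What the generator does **not** emulate: point-spread functions, chromatic
shift, uneven illumination, debris, confluent monolayers, mitotic figures
and cell-cycle intensity variation. Passing tests therefore demonstrate
the pipeline's internal consistency and statistical behavior under the
stated noise model, not robustness to real microscope artifacts.

## Problem sizes and numerical choices

End-to-end accuracy is evaluated on one 500-cell well (4 fields × 125
cells, 512×512 px, balanced phenotypes) against a 60-cell-per-class
annotation set. Segmentation recall uses 100 seeded 256×256 fields of 15
well-separated cells (center separation ≥ 26 px ≈ 3 nuclear radii).
IC₅₀ recovery statistics run at the counting level — multinomial class
draws from the Hill model plus a 2% symmetric misclassification channel
standing in for imaging noise (a rate at or above what the imaging
pipeline's measured per-cell accuracy implies) — because the estimator's
statistical behavior is a property of the counts, and rendering ~2000
fields per repetition would add nothing but runtime; the full
image-to-IC₅₀ path is exercised separately on a rendered plate. Recovery
of shallow curves (h = 0.5) to ±20% requires a dose design spanning the
curve (12-point 1:2.5); steeper curves are covered by 7-point designs.

Ties in cytoplasm seed competition follow the watershed's deterministic
flooding order; label ids are assigned in scan order, and all randomness
flows through a single seeded generator, so identical inputs give
bit-identical masks and tables.

## Known limitations

* The gate cannot see morphology: dye-negative phenotypes (fragmentation,
  senescence-like enlargement) are "healthy" to it by definition; the
  trained backends and the post-classification flags exist for exactly
  those cases.
* Early apoptotic vs early necrotic cells are not distinguishable from
  these dyes at a single time point; no early-necrotic class is attempted.
* Label-free (brightfield) segmentation is out of scope; the brightfield
  channel is carried but never computed on.
* The linear backend assumes standardized features are linearly separable
  enough; heavily overlapping phenotypes require the supervised backend.
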