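# Methods

## Problem and model

Retinal vessels appear in the green channel of a fundus photograph as dark
curvilinear structures, 1–10 px wide at DRIVE-like resolution, on a bright
but unevenly illuminated background.  The pipeline treats segmentation as
the conjunction of two weak detectors — a *geometric* one (vessels are
ridges of the intensity surface) and a *photometric* one (vessel pixels
occupy the bright tail of the top-hat image) — cleaned up by morphological
constraints that adapt to the local background texture.

### Preprocessing

The green channel is contrast-enhanced with a **black top-hat**
(closing − image) using a disc of radius 10–60 px (default 30).  Vessels
are dark in the green channel, so this polarity renders them bright on a
near-zero background while cancelling smooth illumination gradients.  The
closing also raises a bright ring just *outside* the field-of-view rim
(the dark surround near the disc edge gets filled); the pipeline therefore
clips the preprocessed image to the FOV eroded by 2 px and renormalizes
inside it.  Without this clip the rim ring dominates the vesselness
normalization and the entropy statistics — it is the rim artefact the
dedicated Sobel-based FOV mask exists to remove.

### Ridge enhancement

A Gaussian-derivative Hessian at a single scale σ (default 1.5 px, chosen
for the 1–10 px calibre range) is γ-normalized by σ² and decomposed in
closed form.  The sampled second-derivative kernel has a small DC gain
(its weights do not sum exactly to zero); it is subtracted so constant
images have an exactly zero Hessian.  The vesselness is the standard
two-term bright-ridge response with β = 0.5 and `c` set automatically to
half the maximum Frobenius norm of the Hessian over the image; the
response is zeroed where λ₂ ≥ 0 and rescaled to [0, 1] by its maximum.
No scale-space maximum is taken: a single scale responds adequately across
the calibre range and keeps the filter cheap.

### Co-occurrence entropy thresholding

The quantized top-hat image (L = 255 levels by default) yields a
co-occurrence matrix of ordered right/below gray-level transitions
(`Σt_ij = M(N−1) + (M−1)N`).  For each candidate threshold t, the
within-object (levels > t on both axes) and within-background quadrants
are renormalized and their transition entropies, `−½Σp̂log₂p̂`, summed;
the optimal threshold maximises the sum, ties to the smallest t.  The
½ factor and the base-2 logarithm are fixed conventions — the argmax is
invariant to both, but fixing them makes curves bit-reproducible.  Cross
quadrants (object↔background transitions) are computed and exposed but
excluded from the total; a configuration hook can include them.  The
object quadrant is the bright one because top-hat vessels are bright.  The
implementation uses 2-D cumulative sums of p and p·log₂p so each
threshold's quadrant sums cost O(1); a naive quadrant-loop oracle is kept
in the test suite and agrees to < 1e-9.

The same `t*` drives two regimes: the **mask regime** (scale 0.3–0.8,
default 0.5) extracts a generous vessel mask that gates the vesselness
image, and the **reflex regime** (scale 0.8–3, default 1.5) keeps only
strongly bright pixels, recovering the vessel cores the curvature detector
misses where the central light reflex splits a vessel.  The reflex-regime
mask is further restricted to a dilated halo (default 4 px) of the
curvature segmentation: the strict threshold is meant for pixels near
reflex-affected vessel centrelines, and the halo keeps it from
resurrecting isolated background clutter far from any detected vessel.
The pixel-true rule is `level ≥ scale·t*`; a per-pixel spatial rule is
deliberately not attempted since the regimes' ranges already encode the
edge-versus-core distinction.

### Texture partition

Background clutter is not homogeneous, so a single component-size cut
cannot serve the whole image.  The partition chain: stationary
(undecimated) wavelet transform, 3 levels of 3 oriented subbands (`db2`);
magnitudes median-filtered (3×3) and then diffused by a Gaussian of scale
8 px.  The diffusion step matters: texture is a neighbourhood property,
and without it the inter-granule background of both textures is
identically zero and the watershed cannot see the texture boundary.  The
Sobel gradient of the summed subband magnitudes, closed with a disc of
radius 4 and H-minima-suppressed (h = 0.05 on the [0,1] gradient), is
flooded by a marker-based watershed restricted to the FOV.  A region
similarity graph over the resulting atomic regions carries per-region mean
subband magnitudes, mean intensity and log-area as node features; edge
weights are `exp(−‖f_a−f_b‖²/2σ_f²)` with σ_f the median pairwise feature
distance over edges (scale-free).  Normalized-cut spectral clustering
(row-normalized eigenvectors of the symmetric normalized Laplacian,
k-means with a fixed seed, k = 8 by default, apportioned per connected
component) groups the regions; clusters are finally merged into exactly
two macro-labels by each cluster's bright-granule size — the area-weighted
median area of connected components above half the cluster's 99th
percentile intensity — with smaller-granule clusters labelled *fine*.
A manual cluster→label override map is accepted.

Two numerical choices here deviate from the obvious defaults and are worth
recording.  The pre-watershed disc closing uses radius 4, not 8: radius 8
collapses the over-segmentation to one or two regions on 256² images,
leaving the spectral step nothing to cluster (radius 4 yields ~20–30
atomic regions).  The granule statistic is pixel-weighted and uses a
per-cluster adaptive threshold: a pooled Otsu threshold sits above the
faint-but-large coarse granules (they never register), and an unweighted
median is swamped by 1-px dust components.

Known limitation: a cluster of coarse-half background *between* granules
contains no granules of its own and is labelled fine.  The functional harm
is nil — where there are no granules there is nothing for the
connectivity filter to remove — but pixelwise agreement with a half/half
ground truth varies with the granule layout (≈0.55–0.90 across phantom
seeds; ≈0.90 on the standard two-texture fixture).  The underlying manual
merge protocol is not reproducible; the automatic criterion is an explicit
stand-in and the override map is the escape hatch.

### Class routing and cleanup

Images fall into three classes — uniform illumination with well-localised
reflex (class 1), uniform illumination with reflex-broken vessels
(class 2), non-uniform illumination and/or pathology (class 3) — and run
steps {2,5}, {2,3,5} and {1–5} respectively.  Class assignment is manual
(CLI flag), as the class characteristics are judged by eye.  The
connectivity filter assigns each 8-connected component to the texture
label covering the majority of its pixels and removes it if its pixel
count is ≤ the label's threshold (fine 5, coarse 16; a single global
threshold when no partition exists).  Recovery step: class 1 closes the
curvature segmentation with a radius-2 disc; classes 2–3 first OR in the
reflex-regime segmentation.  For class 2 the reflex segmentation is
produced globally (no partition exists); a config switch can disable it.

### Width measurement

The mask is thinned to a 1-px skeleton; spurs shorter than 3 px that end
at a branch point are pruned (plain open lines are never shortened, so
8-connected component count is preserved).  At each centreline pixel with
exactly two line neighbours forming one of the **14 valid window
configurations** — neighbour pairs whose 3-pixel path is
coordinate-distinct along exactly one image axis — the direction is the
unit vector between the outer pixels; when both orientation groups match,
the pair with larger y-coordinates wins.  Branch pixels (≥3 neighbours)
are rejected.  Pure-diagonal continuations (opposite diagonal neighbours)
are coordinate-distinct along *both* axes and thus outside the window
family, but their tangent is unambiguous; they are accepted as a
documented fallback, otherwise perfectly diagonal vessels would go
unmeasured.  The direction is rotated 90° CCW ((dx,dy) → (dy,−dx) with y
down), the perpendicular profile is rasterized by largest-component
stepping with zero gap tolerance (configurable), and the width is the
Euclidean distance between the outermost foreground pixels plus 1 — the
pixel-extent convention that makes an axis-aligned bar of height h
measure exactly h.  Diagonal profiles sample perpendicular distance on a
√2 grid, giving a ≤ ~1.5 px bias at 45°, consistent with the method's
pixel-scale error elsewhere.

### Width-evaluation protocol

Expert-style ground truth arrives as edge-point pairs.  Points are
rendered and closed with a square element whose side starts at s = 3 and
auto-escalates (cap 15) until the declared number of vessels each form one
component — the smallest element that connects all points.  A ground-truth
location scores as a success when its nearest predicted centre lies within
the local true width and sits inside the closed ground-truth segment
(nearest-first, smallest-index tie-break).  Mean width is the closed
predicted segment's area divided by its thinned centreline length, with
the closing's rounded end-caps (radius s+1 around centreline endpoints)
excluded from both counts so the ratio estimates calibre rather than
cap geometry.  The error standard deviation is the RMS, over ground-truth
cross-sections, of the pixel disagreement between the two closed segments
along the full straight line through each edge-point pair, extended s+2 px
beyond each point so over-segmentation outside the true band is counted.

## Phantom generator

The phantom emulates the image features the pipeline actually exercises,
at 256×256 with an FOV disc of radius 0.45·min(H,W):

- **Vessels** (default 4, widths 2–8 px): smooth random curves entering
  from the rim, with a Gaussian cross-section of FWHM equal to the stated
  width — the smooth, approximately Gaussian profile used throughout the
  matched-filter vessel literature (narrow vessels keep a minimal flat
  core so they survive the sampling grid).  Contrast 0.25 below a 0.65
  background green level.  The gold mask is the band within width/2 of
  the centreline.
- **Central reflex** (optional): a brighter 1-px core line restoring half
  the vessel contrast.
- **Illumination**: multiplicative left-to-right ramp, amplitude 0.2.
- **Noise**: dark granules with dip amplitudes of 10–20 % of the vessel
  contrast — the ratio of background mottle to vessel contrast seen in
  fundus camera images; fine granules (≤3 px, density 0.08) on the left
  half and coarse granules (8–16 px, density 0.04) on the right, so the
  texture partition has an unambiguous half/half ground truth.
- **Pathology** (class-3 phantoms): 2 bright Gaussian blobs, radius
  6–12 px.

All randomness flows from one seed; the truth tables (centreline/width
list, edge-point pairs every second path sample at the outermost band
pixel, partition map, FOV disc) are generated alongside the image.

What the phantom does **not** emulate: the optic disc and macula, JPEG
artefacts, camera vignetting beyond a linear ramp, vessel branching
topology (curves may cross but do not bifurcate) and calibre variation
along a single vessel.  Passing the phantom suite therefore demonstrates
the pipeline's mechanics — polarity handling, threshold selection,
texture-adaptive filtering, reflex recovery, width accounting — not
clinical-grade performance on real fundus images.

## Default parameters

| key | default | range | meaning |
|---|---|---|---|
| preprocess.tophat_radius | 30 | 10–60 | disc radius of the black top-hat, px |
| texture.levels | 3 | 2–5 | wavelet decomposition depth |
| texture.k | 8 | 1–64 | spectral clusters before the two-label merge |
| texture.hminima | 0.05 | >0 | basin-depth suppression on the [0,1] gradient |
| texture.presmooth_radius | 4 | 0–16 | disc closing of the gradient before H-minima |
| enhance.sigma | 1.5 | ≥0.5 | Hessian scale, px |
| enhance.beta | 0.5 | >0 | anisotropy-ratio sensitivity |
| enhance.c | auto | >0 | structure-norm scale (auto = half max Frobenius norm) |
| entropy.L | 255 | 15–255 | quantization levels |
| entropy.mask_scale | 0.5 | 0.3–0.8 | threshold scale, mask regime |
| entropy.reflex_scale | 1.5 | 0.8–3 | threshold scale, reflex regime |
| segment.global_threshold | 0.1 | 0.04–0.2 | cut on vesselness × entropy mask |
| segment.min_fine / min_coarse | 5 / 16 | 5–16 | connectivity constraints, px |
| segment.reflex_dilation | 4 | 0–16 | halo radius restricting the reflex mask |

Problem sizes used by the test suite and the acceptance script — 256²
phantoms, three seeds for the end-to-end check, 50 random 32² images for
the entropy oracle, a 5-width × 5-angle bar grid — were chosen so the
whole suite completes in well under a minute per module while each check
still exercises the full code path.

## Degenerate inputs and tie-breaks

Blank images yield an all-true FOV with a warning; a flat entropy profile
returns threshold 0 with a warning; a threshold exceeding L gives an empty
mask with a warning; watershed with h above the gradient range yields a
single region; clustering of a single region or a disconnected graph is
handled per component; entropy quadrants that are empty contribute zero
(0·log 0 := 0).  Argmax ties always break to the smallest index.
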