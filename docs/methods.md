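# Methods

## The localization model

The detector treats optic-disc localization as bright-blob candidate
screening followed by texture classification. Its assumptions: the disc is
the largest locally bright, roughly circular structure inside the field of
view (FOV); dark vessels converge on it and may cut it into fragments under
thresholding; exudates are bright but smaller and texturally smoother; and
illumination varies smoothly, so locally bright structure is better defined
against a large-scale background estimate than against a global threshold.

### Bright-structure map

Analysis runs on the green channel (highest vessel/disc contrast in fundus
photographs; whether to use a luminance combination instead was an open
choice — green is ours). CLAHE (clip factor 2.0 relative to a uniform
256-bin tile histogram, 8×8 tiles — standard values) normalizes local
contrast; a median filter whose window defaults to 1/8 of the FOV diameter
estimates background; the clamped difference, rescaled to [0, 255] inside
the FOV, is the bright map. The window must sit well above the expected
disc diameter (1/6 of the FOV diameter by default) so the disc survives the
subtraction. The FOV itself is estimated as the largest connected component
of pixels with max-channel intensity above 10, so frame borders can never
produce candidates.

### Thresholding and keypoint evidence

Otsu's threshold on the bright map is computed on the 256-bin histogram by
exact integer arithmetic: the between-class variance ratio
(S₀W − SW₀)²/(W₀W₁) is compared across thresholds by cross-multiplication,
and the smallest threshold attaining the maximum wins. This removes
floating-point sensitivity in near-tie splits and makes the tie-break
deterministic and testable.

Keypoints are scale-normalized determinant-of-Hessian extrema: σ⁴·det(H)
computed with Gaussian-derivative filters on the [0, 1]-scaled bright map
over a geometric σ ladder (2–16 in 6 steps, covering blob radii ≈ 3–23 px at
the default phantom scale), thresholded at 0.002 and extracted as 3×3×3
local maxima. Both defaults were fixed from the phantom geometry (a disc of
radius r responds near σ = r/√2 with response well above 0.002 at the
contrast the bright map delivers). A thresholded component survives only if
some keypoint lies within `radius_factor × scale` (default factor 1.0) of
one of its pixels; survival is decided per component, not per pixel, since
the keypoints serve as evidence for a region, not as a segmentation.

### Texture features and classification

The LBP operator uses the original 3×3 kernel with s(x) = 1 for x ≥ 0
(ties count as "not darker", so a flat patch codes to 255) and neighbor
bits ordered clockwise from the top-left corner. The ordering is a frozen
convention: any fixed ordering yields histograms equivalent up to bin
permutation. Candidate and template patches all pass one normalization
function — CLAHE, photometric inversion, resize to 64×64 — so LBP
histograms and SSIM comparisons are always commensurate.

The visual dictionary is k-means (k-means++ init, seeded, ≤ 300 iterations)
over LBP histograms with k = 8 by default: forty training patches cannot
support a large vocabulary. Quantization is the exact squared-Euclidean
argmin with smallest-index tie-break. Whether the classifier should consume
the word assignment or the raw histogram is ambiguous in principle; the
default feeds the random forest the concatenation of the 256-bin histogram
and the one-hot word (`feature_mode="both"`), so both the quantization and
the raw texture contribute, and the alternatives remain one flag away. The
forest uses 100 trees, bootstrap sampling, √d features per split, unlimited
depth, seeded.

SSIM follows the Wang et al. formulation (Gaussian window σ = 1.5,
K₁ = 0.01, K₂ = 0.03, L = 255, population covariances). The SSIM templates
are the disc training patches themselves — the only disc exemplars the
method possesses — and a candidate's score is the maximum over templates.

### Decision and the dilation fallback

A candidate passes when the convex fusion `0.4·SSIM + 0.6·P(disc)` reaches
0.5 (both weight and threshold configurable; `fusion="and"` instead
requires P(disc) ≥ 0.5 and SSIM ≥ 0.3 separately, covering the stricter
reading of "both scores must agree"). If no first-pass candidate passes,
the thresholded mask is dilated with a disk of radius 2 and relabeled,
repeatedly, stopping when a component reaches 2× the expected disc area,
when the component count stops decreasing, or after 5 rounds (an explicit
cap guaranteeing termination). Dilation decides *grouping only*: the chosen
merged component is measured — bbox, centroid, area — on the pre-dilation
foreground pixels it contains, a closing-like reading of "making fragmented
regions whole" that keeps the reported geometry free of structuring-element
inflation. The area floor (0.25× expected disc area) is applied to that
pre-dilation pixel count, which also suppresses dilated exudates.

The winner is refined to a square ("quadratic") region of side
max(bbox height, width) centered on the centroid, shifted toward the image
interior when the disc sits near the frame edge on its (left/right) side;
the side determination affects crop placement only. Coordinates are 0-based
(row, col) and bounding boxes half-open throughout.

### Evaluation protocol

The overlap score S = Area(T∩D)/Area(T∪D) (Jaccard) compares the true disc
mask with the refined square region rasterized; S ≥ 0.5 is a success. The
dataset summary reports image-level accuracy (successes/total) and the
pixel-basis rate (mean S), both as percentages to two decimals; by default
the mean includes missed images as S = 0, with a flag for averaging over
detections only. Scoring the refined square rather than the raw component
is a protocol choice: it matches what the detector actually reports.

## The synthetic phantom

`PhantomSpec` defaults define the study conditions: 256×256 images, FOV
radius 120 px, disc radius 20 px (the 1/6-of-FOV proportion the detector
assumes), brightness lift 70 counts, 4 vessels of width 3 and darkness 60
converging on the disc center as quadratic Bézier tracks, 2 exudates of
radius 3–7 at lift 45 placed ≥ 1 disc radius from the disc rim, a ±15 %
linear illumination gradient, and Gaussian noise σ = 3. The easy battery
varies position, brightness (60–90), vessel count (3–5), exudate count
(0–3) and noise (σ 2–4) while keeping exudates at 0.6× disc brightness;
the hard battery pushes exudates to 0.95× disc brightness, radius up to
10 px, and heavier noise and gradients.

What the phantom does *not* model: photoreceptor and nerve-fiber texture,
hemorrhages and drusen, vessel branching and caliber variation, camera
optics (vignetting beyond a linear gradient, chromatic effects, blur), and
inter-subject anatomy. Passing the phantom battery therefore demonstrates
that the pipeline's logic is sound — fragments re-merge, exudates are
rejected by texture and size, geometry is recovered to sub-pixel accuracy —
not that any particular accuracy transfers to clinical images; on real data
the classifier should be retrained with real labeled patches through the
same `fit` interface.

Training patches (20 disc, 20 non-disc by default) are cropped from fresh
phantoms: disc patches at 1.1× the disc radius around the true center,
negatives alternating between flat background and exudate-centered crops at
the exudate's own scale. The exudate negatives matter: resized to 64×64 an
exudate looks like a smooth disc, and only its lack of vessel texture —
which LBP captures — separates the classes.

## Numerical choices and degenerate inputs

- Otsu: exact integer comparison, smallest threshold on ties; constant
  images raise (no threshold exists), which the detector maps to an empty
  candidate list.
- Quantization ties: smallest word index.
- k-means: `n_init=10` under a fixed seed; byte-identical centroids across
  runs.
- Empty keypoint set: the whole mask is cleared with a logged warning — no
  blob evidence means no candidates, not an error.
- Both-empty masks score S = 0 (an empty union has no overlap to measure).
- Region bounding boxes with an extent below 2 px are rejected before
  CLAHE/resize.
- Full-pipeline determinism: with fixed seeds the serialized result JSON is
  byte-identical across runs.

## Problem sizes

The shipped experiments use 256×256 phantoms, 40 training patches, a
40-patch held-out batch, and 50-image batteries — sizes at which the full
acceptance run completes in well under a minute on one CPU while leaving
every code path (fragmentation, fallback, exudate rejection, refinement)
exercised.

## Known limitations

- The keypoint detector threshold is calibrated for the bright map's
  contrast; images normalized differently may need `KeypointConfig`
  adjustments.
- The SSIM template set is the training disc patches; with few templates
  the SSIM term is noisy, which is why the fusion weights the forest higher
  (0.6 vs 0.4).
- The refined square is axis-aligned; a tilted elliptical disc loses a few
  points of overlap by construction.
- `summarize` is deliberately simple accounting; no confidence intervals
  are attached to battery-level rates.
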