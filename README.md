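# odlocate — optic-disc localization in retinal fundus images

The optic disc (OD) is the bright, roughly circular exit point of the optic
nerve in a color fundus photograph. Locating it automatically is a
prerequisite for most retinal-screening pipelines (vessel tracing,
cup-to-disc measurement, lesion triage), but brightness alone is a poor cue:
hard exudates — the bright lipid lesions of diabetic retinopathy — mimic the
disc, uneven illumination creates spurious bright patches, and the dark
vessels converging on the disc often split it into fragments under
thresholding.

`odlocate` implements a multi-stage localization pipeline for researchers
and engineers working on fundus image analysis:

1. **Candidate generation.** The CLAHE-enhanced green channel minus a
   large-window median background gives a bright-structure map; Otsu's
   threshold binarizes it; connected components without nearby scale-space
   blob keypoints (determinant-of-Hessian extrema) are discarded; components
   smaller than a fraction of the expected disc area are not processed.
2. **Region analysis.** Each candidate's bounding box is cropped,
   CLAHE-enhanced, inverted, and resized to 64×64. Its texture is summarized
   by the 256-bin local-binary-pattern histogram

   LBP(x_c, y_c) = Σ_{n=0..7} s(i_n − i_c)·2ⁿ,  s(x) = 1 if x ≥ 0 else 0,

   which feeds a visual dictionary (k-means words over LBP space; a query is
   quantized to the word minimizing D = Σ_j (X_j − Y_ij)²) and a random
   forest that outputs the probability the patch is the disc. In parallel
   the patch is compared against the disc training patches with the
   structural similarity index (SSIM).
3. **Decision with recursive dilation.** Candidates are ranked by the fused
   score `w·SSIM + (1−w)·P(disc)`. If nothing clears the threshold —
   typically because vessels fragmented the disc — the mask is dilated
   recursively with a disk element until the fragments merge (or a size
   bound is hit), and analysis repeats. The winning region is refined to a
   square crop centered on its centroid.

Detections are scored against ground truth with the overlap score
S = Area(T ∩ D) / Area(T ∪ D); S ≥ 0.5 counts as a successful localization.

Because public fundus datasets cannot be redistributed, the package ships a
**synthetic fundus-phantom generator** (bright disc crossed by dark Bézier
vessels, textured reddish background, exudate confusers, illumination
gradients) that provides training patches, SSIM templates, and fully
labeled evaluation batteries with zero downloads. Real images and
user-supplied training patches plug into the identical API.

## Worked example

```python
from odlocate import (OpticDiscDetector, generate_training_patches,
                      generate_phantom, PhantomSpec, overlap_score)
from odlocate.segmentation import region_bbox_mask

patches, labels = generate_training_patches(seed=7)   # 20 disc + 20 non-disc
detector = OpticDiscDetector(random_state=7).fit(patches, labels)

image, truth = generate_phantom(PhantomSpec(seed=3))
result = detector.detect(image)

S = overlap_score(truth.disc_mask,
                  region_bbox_mask(result.disc_region, image.shape))
```

prints (via the obvious `print` statements):

```
found=True rounds_used=2
detected center (row, col) = (118.0, 189.0)
true center (row, col)     = (118.5, 189.4)
candidate area=815 ssim=0.352 model_prob=0.780 round=2
overlap score S = 0.683  (success: True)
```

On this phantom the vessels split the disc into fragments below the
candidate area floor, so the first pass found nothing; two dilation rounds
re-merged the fragments (`rounds_used=2`), the merged region scored
P(disc) = 0.78 with SSIM 0.35 against the templates, and the refined square
overlaps the true disc at S = 0.68 — a successful localization with the
center off by half a pixel.

The same workflow is available from the shell:

```bash
odlocate simulate --n 50 --seed 7 --difficulty easy --out sim/
odlocate train --seed 7 --out model/
odlocate detect --image sim/phantom_000.png --model model/ --out result.json
odlocate evaluate --images sim/ --model model/ --out eval.csv
```

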