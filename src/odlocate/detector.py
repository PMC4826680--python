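"""End-to-end optic-disc localization.

Three stages:

1. *Candidate generation* — bright-structure map -> Otsu threshold ->
   blob-keypoint filtering -> connected components; components smaller than
   a fraction of the expected disc area are dropped.
2. *Per-region analysis* — each candidate's bounding box is cropped from the
   green channel, CLAHE-enhanced, inverted and resized to the feature size;
   its LBP histogram goes through the visual-dictionary/random-forest model
   (disc probability) and the patch is compared by SSIM against the disc
   template patches (max over templates).
3. *Decision with dilation fallback* — candidates are scored by a convex
   fusion of SSIM and model probability.  If nothing clears the decision
   threshold (typically because dark vessels fragmented the disc below the
   area floor), the binary mask is dilated recursively to re-merge the
   fragments and analysis is repeated.  Dilation decides the *grouping*
   only: the chosen component's geometry (bbox, centroid, area) is measured
   on the pre-dilation foreground pixels it contains, so the reported region
   is not inflated by the structuring element.

The winning region is refined to a square ("quadratic") crop centered on
its centroid, shifted toward the image interior where it would overrun the
frame on the disc's (left/right) side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.transform import resize
from sklearn.base import BaseEstimator

from .dictionary_model import POSITIVE, DiscPatchClassifier, VisualDictionary
from .keypoints import KeypointConfig, detect_keypoints, mask_by_keypoints
from .preprocess import BrightConfig, RetinalImage, clahe, extract_bright_regions, invert
from .segmentation import Region, dilate, label_components, otsu_threshold
from .texture import SSIMConfig, lbp_histogram, ssim

__all__ = [
    "DetectorConfig",
    "CandidateRegion",
    "DetectionResult",
    "OpticDiscDetector",
    "prepare_patch",
    "expected_disc_area",
    "generate_candidates",
    "analyze_region",
    "recursive_dilation_pass",
    "refine_disc_region",
    "detect_optic_disc",
]


@dataclass
class DetectorConfig:
    """Tunables of the three-stage detector.

    ``expected_disc_diameter`` is in pixels, or None to derive it as 1/6 of
    the field-of-view diameter (a typical fundus proportion).  Area floors
    and ceilings are fractions of the expected disc area.  ``fusion`` is
    "weighted" (convex combination, default) or "and" (both scores must
    clear their thresholds).
    """

    min_area_fraction: float = 0.25
    max_area_fraction: float = 2.0
    dilation_radius: int = 2
    max_dilation_rounds: int = 5
    ssim_weight: float = 0.4
    decision_threshold: float = 0.5
    ssim_threshold: float = 0.3  # used by fusion="and" only
    expected_disc_diameter: float | None = None
    fusion: str = "weighted"
    feature_size: int = 64
    keypoint_radius_factor: float = 1.0
    bright: BrightConfig = field(default_factory=BrightConfig)
    keypoint: KeypointConfig = field(default_factory=KeypointConfig)
    ssim_cfg: SSIMConfig = field(default_factory=SSIMConfig)

    def __post_init__(self) -> None:
        if not (0 < self.min_area_fraction < self.max_area_fraction):
            raise ValueError("need 0 < min_area_fraction < max_area_fraction")
        if self.max_dilation_rounds < 1:
            raise ValueError("max_dilation_rounds must be >= 1")
        if not (0 <= self.ssim_weight <= 1):
            raise ValueError("ssim_weight must be in [0, 1]")
        if self.fusion not in ("weighted", "and"):
            raise ValueError(f"fusion must be 'weighted' or 'and', got {self.fusion!r}")


@dataclass
class CandidateRegion:
    """One analyzed candidate with its scores and the round it came from."""

    region: Region
    patch: np.ndarray
    ssim_score: float
    model_prob: float
    dilation_round: int = 0

    def fused_score(self, cfg: DetectorConfig) -> float:
        return cfg.ssim_weight * self.ssim_score + (1 - cfg.ssim_weight) * self.model_prob

    def passes(self, cfg: DetectorConfig) -> bool:
        if cfg.fusion == "and":
            return (
                self.model_prob >= cfg.decision_threshold
                and self.ssim_score >= cfg.ssim_threshold
            )
        return self.fused_score(cfg) >= cfg.decision_threshold


@dataclass
class DetectionResult:
    found: bool
    disc_region: Region | None
    disc_center: tuple[float, float] | None
    candidates: list[CandidateRegion]
    rounds_used: int

    def __post_init__(self) -> None:
        if self.found:
            r0, c0, r1, c1 = self.disc_region.bbox
            cr, cc = self.disc_center
            if not (r0 <= cr < r1 and c0 <= cc < c1):
                raise ValueError("disc_center must lie inside disc_region bbox")

    def to_json(self, cfg: DetectorConfig | None = None) -> str:
        cfg = cfg or DetectorConfig()
        payload = {
            "found": self.found,
            "disc_center": list(self.disc_center) if self.found else None,
            "disc_bbox": list(self.disc_region.bbox) if self.found else None,
            "disc_area": self.disc_region.pixel_count if self.found else None,
            "rounds_used": self.rounds_used,
            "candidates": [
                {
                    "label": c.region.label,
                    "bbox": list(c.region.bbox),
                    "area": c.region.pixel_count,
                    "ssim": round(c.ssim_score, 6),
                    "model_prob": round(c.model_prob, 6),
                    "fused": round(c.fused_score(cfg), 6),
                    "dilation_round": c.dilation_round,
                }
                for c in self.candidates
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def expected_disc_area(img: RetinalImage, cfg: DetectorConfig) -> float:
    """Expected disc area in pixels (pi r^2 from the configured diameter)."""
    if cfg.expected_disc_diameter is not None:
        d = float(cfg.expected_disc_diameter)
    else:
        fov = img.fov()
        fov_diam = 2.0 * np.sqrt(fov.sum() / np.pi) if fov.any() else min(img.shape)
        d = fov_diam / 6.0
    return np.pi * (d / 2.0) ** 2


def prepare_patch(gray_crop: np.ndarray, feature_size: int = 64) -> np.ndarray:
    """Analysis normalization of a grayscale crop: CLAHE -> invert -> resize.

    All candidate and template patches pass through this one function, so
    LBP features and SSIM comparisons are always computed on commensurate
    inputs (inverted, contrast-normalized squares of the feature size).
    """
    crop = np.asarray(gray_crop, dtype=np.uint8)
    if crop.shape[0] < 2 or crop.shape[1] < 2:
        raise ValueError(f"degenerate patch of shape {crop.shape}")
    tiles = (min(8, crop.shape[0]), min(8, crop.shape[1]))
    enhanced = invert(clahe(crop, tile_grid=tiles))
    out = resize(
        enhanced, (feature_size, feature_size), preserve_range=True, anti_aliasing=True
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _threshold_bright(bright: np.ndarray) -> np.ndarray:
    """Otsu on the bright map; a structureless map yields an empty mask."""
    try:
        _, mask = otsu_threshold(bright)
    except ValueError:
        return np.zeros(bright.shape, dtype=bool)
    return mask


def _candidate_mask(img: RetinalImage, cfg: DetectorConfig):
    bright = extract_bright_regions(img, cfg.bright)
    mask = _threshold_bright(bright)
    if mask.any():
        kps = detect_keypoints(bright, cfg.keypoint)
        mask = mask_by_keypoints(mask, kps, cfg.keypoint_radius_factor)
    return mask, bright


def _regions_above_floor(
    regions: list[Region], floor: float
) -> list[Region]:
    return [r for r in regions if r.pixel_count >= floor]


def generate_candidates(
    img: RetinalImage, cfg: DetectorConfig | None = None
) -> tuple[list[Region], np.ndarray]:
    """First-pass candidate regions and the bright-structure map.

    Regions smaller than ``min_area_fraction`` x expected disc area are not
    processed further; an empty list is a valid outcome.
    """
    cfg = cfg or DetectorConfig()
    mask, bright = _candidate_mask(img, cfg)
    floor = cfg.min_area_fraction * expected_disc_area(img, cfg)
    return _regions_above_floor(label_components(mask), floor), bright


def analyze_region(
    img: RetinalImage,
    region: Region,
    model: DiscPatchClassifier,
    dictionary: VisualDictionary | None,
    templates: list[np.ndarray],
    cfg: DetectorConfig | None = None,
    dilation_round: int = 0,
) -> CandidateRegion:
    """Score one candidate region: model probability and max template SSIM."""
    cfg = cfg or DetectorConfig()
    r0, c0, r1, c1 = region.bbox
    if r1 - r0 < 2 or c1 - c0 < 2:
        raise ValueError(f"degenerate region bbox {region.bbox}")
    crop = img.green()[r0:r1, c0:c1]
    patch = prepare_patch(crop, cfg.feature_size)
    hist = lbp_histogram(patch)
    prob = float(model.disc_probability([hist])[0])
    score = max(
        (ssim(patch, t, cfg.ssim_cfg) for t in templates), default=0.0
    )
    return CandidateRegion(
        region=region,
        patch=patch,
        ssim_score=float(score),
        model_prob=prob,
        dilation_round=dilation_round,
    )


def recursive_dilation_pass(
    mask: np.ndarray,
    cfg: DetectorConfig | None = None,
    expected_area: float | None = None,
) -> tuple[np.ndarray, int]:
    """Recursive disk dilation until fragments merge or a size bound is hit.

    Stops immediately (0 rounds) when a component already reaches
    ``max_area_fraction`` x expected area; otherwise dilates and relabels
    until that ceiling is reached, the component count stops decreasing, or
    ``max_dilation_rounds`` rounds have run.
    """
    cfg = cfg or DetectorConfig()
    mask = np.asarray(mask, dtype=bool)
    if expected_area is None:
        expected_area = np.pi * (min(mask.shape) / 12.0) ** 2
    ceiling = cfg.max_area_fraction * expected_area

    def max_area_and_count(m):
        regs = label_components(m)
        return (regs[0].pixel_count if regs else 0), len(regs)

    area, count = max_area_and_count(mask)
    rounds = 0
    while rounds < cfg.max_dilation_rounds:
        if area >= ceiling or count == 0:
            break
        new = dilate(mask, cfg.dilation_radius)
        rounds += 1
        new_area, new_count = max_area_and_count(new)
        mask = new
        if new_area >= ceiling:
            break
        if new_count >= count:  # merging has stalled
            break
        area, count = new_area, new_count
    return mask, rounds


def refine_disc_region(img: RetinalImage, region: Region) -> Region:
    """Square ("quadratic") crop of side max(bbox h, w) around the centroid.

    The square is clamped to the image; when the disc sits near the left or
    right frame edge the crop is shifted toward the image interior rather
    than shrunk.
    """
    h, w = img.shape
    r0, c0, r1, c1 = region.bbox
    side = max(r1 - r0, c1 - c0)
    side = min(side, h, w)
    cr, cc = region.centroid
    nr0 = int(round(cr - side / 2.0))
    nc0 = int(round(cc - side / 2.0))
    nr0 = min(max(nr0, 0), h - side)
    nc0 = min(max(nc0, 0), w - side)
    bbox = (nr0, nc0, nr0 + side, nc0 + side)
    return Region(
        label=region.label,
        pixel_count=side * side,
        bbox=bbox,
        centroid=(nr0 + (side - 1) / 2.0, nc0 + (side - 1) / 2.0),
    )


def _merged_regions(
    dilated: np.ndarray, original: np.ndarray, floor: float
) -> list[Region]:
    """Regions grouped by dilated components but measured on original pixels."""
    labeled = measure.label(dilated, connectivity=2)
    grouped = np.where(original, labeled, 0)
    out = []
    for p in measure.regionprops(grouped):
        reg = Region(
            label=int(p.label),
            pixel_count=int(p.area),
            bbox=tuple(int(v) for v in p.bbox),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
        )
        if reg.pixel_count >= floor:
            out.append(reg)
    out.sort(key=lambda r: (-r.pixel_count, r.label))
    return out


def _select_best(cands: list[CandidateRegion], cfg: DetectorConfig):
    passing = [c for c in cands if c.passes(cfg)]
    if not passing:
        return None
    return max(passing, key=lambda c: c.fused_score(cfg))


def detect_optic_disc(
    img: RetinalImage,
    model: DiscPatchClassifier,
    dictionary: VisualDictionary | None,
    templates: list[np.ndarray],
    cfg: DetectorConfig | None = None,
) -> DetectionResult:
    """Run the full three-stage pipeline on one image."""
    cfg = cfg or DetectorConfig()
    exp_area = expected_disc_area(img, cfg)
    floor = cfg.min_area_fraction * exp_area
    mask, _bright = _candidate_mask(img, cfg)

    regions = _regions_above_floor(label_components(mask), floor)
    candidates = [
        analyze_region(img, r, model, dictionary, templates, cfg, 0) for r in regions
    ]
    best = _select_best(candidates, cfg)
    rounds_used = 0

    if best is None and mask.any():
        dilated, rounds_used = recursive_dilation_pass(mask, cfg, exp_area)
        if rounds_used > 0:
            merged = _merged_regions(dilated, mask, floor)
            late = [
                analyze_region(img, r, model, dictionary, templates, cfg, rounds_used)
                for r in merged
            ]
            candidates.extend(late)
            best = _select_best(late, cfg)

    if best is None:
        return DetectionResult(False, None, None, candidates, rounds_used)

    refined = refine_disc_region(img, best.region)
    return DetectionResult(
        found=True,
        disc_region=refined,
        disc_center=refined.centroid,
        candidates=candidates,
        rounds_used=rounds_used,
    )


class OpticDiscDetector(BaseEstimator):
    """Trainable end-to-end optic-disc detector (scikit-learn style).

    ``fit`` takes labeled grayscale patches (optic disc vs not); it trains
    the visual-dictionary/random-forest patch classifier and retains the
    normalized disc patches as SSIM templates.  ``detect`` localizes the
    disc in one :class:`RetinalImage`; ``predict`` maps over a sequence.

    Parameters mirror :class:`DiscPatchClassifier` plus the stage
    configuration; ``config=None`` uses :class:`DetectorConfig` defaults.
    """

    def __init__(
        self,
        k: int = 8,
        n_trees: int = 100,
        feature_mode: str = "both",
        config: DetectorConfig | None = None,
        random_state: int = 0,
    ):
        self.k = k
        self.n_trees = n_trees
        self.feature_mode = feature_mode
        self.config = config
        self.random_state = random_state

    def _cfg(self) -> DetectorConfig:
        return self.config if self.config is not None else DetectorConfig()

    def fit(self, patches, y):
        cfg = self._cfg()
        y = np.asarray(y)
        prepared = [prepare_patch(p, cfg.feature_size) for p in patches]
        feats = [lbp_histogram(p) for p in prepared]
        self.classifier_ = DiscPatchClassifier(
            k=self.k,
            n_trees=self.n_trees,
            feature_mode=self.feature_mode,
            random_state=self.random_state,
        ).fit(feats, y)
        self.templates_ = [p for p, lab in zip(prepared, y) if lab == POSITIVE]
        if not self.templates_:
            raise ValueError(f"no patches labeled {POSITIVE!r}; cannot build templates")
        return self

    def detect(self, img: RetinalImage) -> DetectionResult:
        return detect_optic_disc(
            img,
            self.classifier_,
            self.classifier_.dictionary_,
            self.templates_,
            self._cfg(),
        )

    def predict(self, imgs) -> list[DetectionResult]:
        return [self.detect(im) for im in imgs]
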