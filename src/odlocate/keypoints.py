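"""Scale-space blob keypoints and the keypoint-evidence candidate filter.

Bright-region extraction alone keeps every locally bright patch, including
uneven-illumination artifacts.  The optic disc and exudates, by contrast,
are genuine blobs: the vessel/disc junction produces strong scale-space
extrema.  Candidate components lacking any nearby blob keypoint are
therefore discarded.

The detector is a determinant-of-Hessian (fast-Hessian family) scale-space
extremum detector: scale-normalized det(H) responses are computed with
Gaussian-derivative filters over a geometric sigma ladder and local 3x3x3
maxima above a threshold become keypoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

__all__ = ["Keypoint", "KeypointConfig", "detect_keypoints", "mask_by_keypoints"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Keypoint:
    """A blob interest point: (row, col) position, characteristic radius
    ``scale`` (sigma * sqrt(2)) and non-negative detector ``response``."""

    row: float
    col: float
    scale: float
    response: float


@dataclass
class KeypointConfig:
    """Determinant-of-Hessian detector parameters.

    The sigma ladder spans ``min_sigma``..``max_sigma`` geometrically in
    ``n_scales`` steps; a blob of radius r responds strongest near
    sigma = r / sqrt(2), so the defaults cover radii of roughly 3-23 px.
    ``threshold`` applies to the sigma^4-normalized det(H) of the [0, 1]
    scaled image.
    """

    min_sigma: float = 2.0
    max_sigma: float = 16.0
    n_scales: int = 6
    threshold: float = 0.002


def detect_keypoints(
    img: np.ndarray, cfg: KeypointConfig | None = None
) -> list[Keypoint]:
    """Blob keypoints of a grayscale image, sorted by descending response."""
    cfg = cfg or KeypointConfig()
    img = np.asarray(img, dtype=np.float64) / 255.0
    sigmas = np.geomspace(cfg.min_sigma, cfg.max_sigma, cfg.n_scales)

    stack = np.empty((len(sigmas),) + img.shape)
    for i, s in enumerate(sigmas):
        hrr = ndi.gaussian_filter(img, s, order=(2, 0))
        hcc = ndi.gaussian_filter(img, s, order=(0, 2))
        hrc = ndi.gaussian_filter(img, s, order=(1, 1))
        stack[i] = (s**4) * (hrr * hcc - hrc**2)

    local_max = ndi.maximum_filter(stack, size=(3, 3, 3), mode="nearest")
    peaks = (stack == local_max) & (stack > cfg.threshold)
    kps = [
        Keypoint(
            row=float(r),
            col=float(c),
            scale=float(sigmas[i] * np.sqrt(2.0)),
            response=float(stack[i, r, c]),
        )
        for i, r, c in zip(*np.nonzero(peaks))
    ]
    kps.sort(key=lambda k: (-k.response, k.row, k.col))
    return kps


def mask_by_keypoints(
    mask: np.ndarray, kps: list[Keypoint], radius_factor: float = 1.0
) -> np.ndarray:
    """Keep only components with blob evidence.

    A foreground connected component survives iff at least one keypoint lies
    within ``radius_factor * scale`` (Euclidean) of any of its pixels; every
    other foreground pixel is cleared.  An empty keypoint list clears the
    whole mask (with a logged warning).
    """
    if radius_factor <= 0:
        raise ValueError("radius_factor must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not kps:
        logger.warning("mask_by_keypoints: no keypoints; clearing mask")
        return np.zeros_like(mask)
    if not mask.any():
        return mask.copy()

    # A keypoint is within d of some component pixel iff the disk of radius
    # d around the keypoint intersects the component.
    h, w = mask.shape
    kp_disks = np.zeros((h, w), dtype=bool)
    for kp in kps:
        d = radius_factor * kp.scale
        r0 = max(0, int(np.floor(kp.row - d)))
        r1 = min(h, int(np.ceil(kp.row + d)) + 1)
        c0 = max(0, int(np.floor(kp.col - d)))
        c1 = min(w, int(np.ceil(kp.col + d)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.ogrid[r0:r1, c0:c1]
        kp_disks[r0:r1, c0:c1] |= (rr - kp.row) ** 2 + (cc - kp.col) ** 2 <= d**2

    labeled = measure.label(mask, connectivity=2)
    hit = np.unique(labeled[kp_disks & mask])
    hit = hit[hit > 0]
    return np.isin(labeled, hit)


def keypoints_to_frame(kps: list[Keypoint]) -> pd.DataFrame:
    """Keypoint table (row, col, scale, response) for CSV export."""
    return pd.DataFrame(
        {
            "row": [k.row for k in kps],
            "col": [k.col for k in kps],
            "scale": [k.scale for k in kps],
            "response": [k.response for k in kps],
        }
    )
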