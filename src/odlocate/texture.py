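"""Local binary patterns and the structural similarity index.

The LBP operator encodes each pixel's 3x3 neighborhood as an 8-bit code:
each neighbor contributes a bit s(i_n - i_c), with s(x) = 1 for x >= 0,
weighted 2^n.  The 256-bin histogram of codes over a patch is the texture
feature used throughout the classifier.  Note s(0) = 1, so a perfectly flat
patch codes to 255 everywhere.

SSIM follows the Wang et al. formulation: the mean over Gaussian-weighted
sliding windows (sigma 1.5) of the luminance * contrast * structure product
with stabilizers C1 = (K1 L)^2, C2 = (K2 L)^2, K1 = 0.01, K2 = 0.03,
L = 255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "LBPHistogram",
    "SSIMConfig",
    "lbp_code",
    "lbp_image",
    "lbp_histogram",
    "ssim",
]

# Neighbor offsets for bit n = 0..7: clockwise from the top-left corner.
# Any fixed ordering yields histograms equivalent up to bin permutation;
# this one is frozen for reproducibility.
_OFFSETS = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


@dataclass
class LBPHistogram:
    """Normalized 256-bin histogram of LBP codes over a patch."""

    bins: np.ndarray
    patch_id: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=np.float64)
        if b.shape != (256,):
            raise ValueError(f"bins must have shape (256,), got {b.shape}")
        if (b < 0).any():
            raise ValueError("bins must be non-negative")
        total = b.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"bins must sum to 1 (or 0), got {total}")
        self.bins = b


@dataclass
class SSIMConfig:
    k1: float = 0.01
    k2: float = 0.03
    sigma: float = 1.5
    data_range: float = 255.0


def lbp_code(neighborhood: np.ndarray) -> int:
    """LBP code of a single 3x3 patch (int in [0, 255])."""
    patch = np.asarray(neighborhood)
    if patch.shape != (3, 3):
        raise ValueError(f"neighborhood must be 3x3, got {patch.shape}")
    patch = patch.astype(np.int64)
    center = patch[1, 1]
    code = 0
    for n, (dr, dc) in enumerate(_OFFSETS):
        if patch[1 + dr, 1 + dc] - center >= 0:
            code |= 1 << n
    return code


def lbp_image(img: np.ndarray) -> np.ndarray:
    """LBP codes at every interior pixel; shape (H-2, W-2), dtype uint8."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got {img.shape}")
    x = img.astype(np.int64)
    center = x[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.uint8)
    for n, (dr, dc) in enumerate(_OFFSETS):
        neigh = x[1 + dr : x.shape[0] - 1 + dr, 1 + dc : x.shape[1] - 1 + dc]
        codes |= ((neigh - center >= 0).astype(np.uint8)) << n
    return codes


def lbp_histogram(patch: np.ndarray, patch_id: str = "") -> LBPHistogram:
    """Normalized histogram of LBP codes over a patch (border pixels skipped)."""
    codes = lbp_image(patch)
    counts = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    return LBPHistogram(bins=counts / counts.sum(), patch_id=patch_id)


def ssim(a: np.ndarray, b: np.ndarray, cfg: SSIMConfig | None = None) -> float:
    """Mean structural similarity between two equally-sized gray images."""
    cfg = cfg or SSIMConfig()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"size mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a,
            b,
            data_range=cfg.data_range,
            gaussian_weights=True,
            sigma=cfg.sigma,
            use_sample_covariance=False,
            K1=cfg.k1,
            K2=cfg.k2,
        )
    )
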