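"""Image loading and the intensity-domain operators feeding candidate generation.

A fundus photograph shows the retina inside a roughly circular illuminated
field of view (FOV) surrounded by a black border.  The optic disc is the
brightest large structure inside the FOV; hard exudates are smaller bright
lesions that confound brightness-based detectors.  The operators here work on
the green channel, which carries the highest vessel/disc contrast in fundus
imagery, and every map they produce is zeroed outside the FOV so border
artifacts can never become candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_adapthist
from skimage.filters import rank
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "RetinalImage",
    "BrightConfig",
    "load_image",
    "save_gray",
    "estimate_fov",
    "invert",
    "clahe",
    "extract_bright_regions",
]


@dataclass
class RetinalImage:
    """An 8-bit color fundus image with an optional field-of-view mask.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    fov_mask : (H, W) bool array or None
        True inside the circular illuminated area.
    source_id : str
        Identifier used in reports and file names.
    """

    pixels: np.ndarray
    fov_mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"image too small: {px.shape[:2]} (need >= 64x64)")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.fov_mask is not None:
            fov = np.asarray(self.fov_mask, dtype=bool)
            if fov.shape != px.shape[:2]:
                raise ValueError("fov_mask shape does not match image")
            self.fov_mask = fov

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def green(self) -> np.ndarray:
        """Green channel as a uint8 grayscale image."""
        return self.pixels[:, :, 1]

    def fov(self) -> np.ndarray:
        """The FOV mask, estimating it on first use if absent."""
        if self.fov_mask is None:
            self.fov_mask = estimate_fov(self.pixels)
        return self.fov_mask


@dataclass
class BrightConfig:
    """Parameters of bright-structure extraction.

    ``window_fraction`` sets the background-median window as a fraction of
    the FOV diameter; it must be large relative to the disc so the disc
    itself is not flattened into the background estimate.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    window_fraction: float = 1.0 / 8.0
    fov_floor: int = 10


def load_image(path, fov_floor: int = 10) -> RetinalImage:
    """Read an 8-bit raster file as a :class:`RetinalImage`.

    Grayscale inputs are accepted and replicated to three channels (with a
    logged warning).  The FOV mask is estimated as the largest connected
    component of pixels whose max-channel intensity exceeds ``fov_floor``.
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        logger.warning("grayscale input %s replicated to 3 channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        raise IOError(f"{path!r} is not an 8-bit image (dtype {arr.dtype})")
    img = RetinalImage(arr, source_id=str(path))
    img.fov_mask = estimate_fov(arr, floor=fov_floor)
    return img


def save_gray(path, img: np.ndarray) -> None:
    """Write a grayscale uint8 array as PNG (debug intermediates)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def estimate_fov(pixels: np.ndarray, floor: int = 10) -> np.ndarray:
    """Field-of-view mask: largest connected bright-enough component."""
    bright = np.asarray(pixels).max(axis=2) > floor
    if not bright.any():
        return np.zeros(bright.shape, dtype=bool)
    labels, n = ndi.label(bright)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def invert(img: np.ndarray) -> np.ndarray:
    """Photometric inversion: out = 255 - in, elementwise."""
    img = np.asarray(img)
    return (255 - img.astype(np.int16)).clip(0, 255).astype(np.uint8)


def clahe(
    img: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` follows the conventional per-tile histogram clip factor
    (relative to a uniform 256-bin histogram); it is normalized by the bin
    count for the backend. Output is uint8 in [0, 255], same shape as input.
    """
    if clip_limit <= 0:
        raise ValueError(f"clip_limit must be positive, got {clip_limit}")
    img = np.asarray(img, dtype=np.uint8)
    h, w = img.shape
    tr, tc = tile_grid
    if tr <= 0 or tc <= 0:
        raise ValueError(f"tile_grid entries must be positive, got {tile_grid}")
    if tr > h or tc > w:
        raise ValueError(f"tile grid {tile_grid} exceeds image size {(h, w)}")
    kernel = (max(1, h // tr), max(1, w // tc))
    out = equalize_adapthist(img, kernel_size=kernel, clip_limit=clip_limit / 256.0)
    return np.round(out * 255.0).astype(np.uint8)


def extract_bright_regions(
    img: RetinalImage, cfg: BrightConfig | None = None
) -> np.ndarray:
    """Map of locally bright structures (disc, exudates) on the green channel.

    CLAHE-enhanced green channel minus a large-scale median background
    estimate, negatives clamped, rescaled to [0, 255] inside the FOV and
    zero outside it.  A constant image yields an all-zero map.
    """
    cfg = cfg or BrightConfig()
    fov = img.fov()
    green = img.green()
    enhanced = clahe(green, cfg.clip_limit, cfg.tile_grid)

    if fov.any():
        fov_diam = 2.0 * np.sqrt(fov.sum() / np.pi)
    else:
        fov_diam = float(min(img.shape))
    radius = max(3, int(round(fov_diam * cfg.window_fraction / 2.0)))
    background = rank.median(enhanced, footprint=disk(radius), mask=fov)

    diff = enhanced.astype(np.int16) - background.astype(np.int16)
    diff = np.clip(diff, 0, None).astype(np.float64)
    diff[~fov] = 0.0
    peak = diff.max()
    if peak > 0:
        diff = diff * (255.0 / peak)
    return np.round(diff).astype(np.uint8)
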