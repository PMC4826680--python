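"""Synthetic fundus phantoms with ground truth.

The phantom reproduces the image properties the detector relies on, and only
those: a reddish background inside a circular field of view, a smooth
multiplicative illumination gradient, a bright roughly circular optic disc
crossed by dark curvilinear vessels converging on it (so that thresholding
fragments the disc, exercising the recursive-dilation recovery), optional
smaller bright exudate blobs placed well away from the disc, and additive
Gaussian noise.  Everything is deterministic under the spec seed.

Vessels are quadratic Bezier tracks through the disc center — the minimal
model that reproduces the fragmentation phenomenon.  Exudate centers are
kept at least one disc radius away from the disc rim so ground truth stays
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import RetinalImage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_training_patches",
    "generate_battery",
]

_BACKGROUND_RGB = np.array([170.0, 82.0, 38.0])  # reddish fundus tone


@dataclass
class PhantomSpec:
    """Parameters of one synthetic fundus image.

    ``disc_center`` of None places the disc at a typical nasal position
    (left or right of center, chosen from the seed).  ``disc_brightness``
    and ``vessel_darkness`` are intensity lifts/drops in 8-bit counts.
    """

    image_size: tuple[int, int] = (256, 256)
    disc_center: tuple[float, float] | None = None
    disc_radius: float = 20.0
    disc_brightness: float = 70.0
    n_vessels: int = 4
    vessel_width: float = 3.0
    vessel_darkness: float = 60.0
    n_exudates: int = 2
    exudate_radius_range: tuple[float, float] = (3.0, 7.0)
    exudate_brightness: float = 45.0
    illumination_gradient: float = 0.15
    noise_sigma: float = 3.0
    seed: int = 0

    def fov_radius(self) -> float:
        return 0.47 * min(self.image_size)

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.exudate_radius_range
        if not (0 < lo <= hi):
            raise ValueError("exudate_radius_range must be 0 < min <= max")
        if hi >= self.disc_radius:
            raise ValueError("exudate radii must be smaller than disc_radius")
        if self.disc_center is not None:
            h, w = self.image_size
            cy, cx = h / 2.0, w / 2.0
            r, c = self.disc_center
            if np.hypot(r - cy, c - cx) + self.disc_radius > self.fov_radius():
                raise ValueError("disc must lie fully inside the field of view")


@dataclass
class GroundTruth:
    """True disc geometry and masks for one phantom."""

    disc_mask: np.ndarray
    disc_center: tuple[float, float]
    disc_radius: float
    exudate_mask: np.ndarray


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _bezier_track(p0, p1, p2, n=400) -> np.ndarray:
    """Sampled quadratic Bezier curve; (n, 2) array of (row, col)."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _paint_track(mask, track, width) -> None:
    """Mark a curvilinear track of the given full width on a bool mask."""
    h, w = mask.shape
    half = width / 2.0
    for r, c in track:
        r0, r1 = int(np.floor(r - half)), int(np.ceil(r + half)) + 1
        c0, c1 = int(np.floor(c - half)), int(np.ceil(c + half)) + 1
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(h, r1), min(w, c1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.ogrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= half**2


def generate_phantom(spec: PhantomSpec) -> tuple[RetinalImage, GroundTruth]:
    """Render one phantom and its ground truth, deterministically per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = h / 2.0, w / 2.0
    fov_r = spec.fov_radius()
    fov = _disk_mask((h, w), (cy, cx), fov_r)

    if spec.disc_center is None:
        side = rng.choice([-1.0, 1.0])
        dc = (
            cy + rng.uniform(-0.15, 0.15) * fov_r,
            cx + side * rng.uniform(0.35, 0.55) * fov_r,
        )
    else:
        dc = spec.disc_center

    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.empty((h, w, 3))
    img[:] = _BACKGROUND_RGB

    # smooth multiplicative illumination gradient in a random direction
    theta = rng.uniform(0, 2 * np.pi)
    proj = ((rr - cy) * np.sin(theta) + (cc - cx) * np.cos(theta)) / fov_r
    img *= (1.0 + spec.illumination_gradient * proj)[..., None]

    # bright disc with a soft rim (~1.5 px falloff), slightly yellowish
    dist = np.hypot(rr - dc[0], cc - dc[1])
    soft = 1.0 / (1.0 + np.exp((dist - spec.disc_radius) / 1.5))
    lift = spec.disc_brightness * soft
    img[..., 0] += lift
    img[..., 1] += lift
    img[..., 2] += 0.7 * lift

    # dark vessels: Bezier tracks from the disc center out to the FOV rim
    vessel = np.zeros((h, w), dtype=bool)
    angles = rng.uniform(0, 2 * np.pi) + np.arange(spec.n_vessels) * (
        2 * np.pi / max(spec.n_vessels, 1)
    ) + rng.uniform(-0.25, 0.25, size=spec.n_vessels)
    for ang in angles[: spec.n_vessels]:
        p0 = np.array(dc)
        end = np.array(
            [cy + fov_r * np.sin(ang) * 1.05, cx + fov_r * np.cos(ang) * 1.05]
        )
        mid = (p0 + end) / 2.0
        normal = np.array([np.cos(ang), -np.sin(ang)])
        ctrl = mid + normal * rng.uniform(-0.25, 0.25) * fov_r
        _paint_track(vessel, _bezier_track(p0, ctrl, end), spec.vessel_width)
    img[vessel] -= spec.vessel_darkness

    # exudates: small bright blobs >= 1 disc radius away from the disc rim
    exudate = np.zeros((h, w), dtype=bool)
    placed = 0
    guard = 0
    while placed < spec.n_exudates and guard < 200:
        guard += 1
        er = rng.uniform(*spec.exudate_radius_range)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.15, 0.85) * (fov_r - 2 * er)
        center = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
        if np.hypot(center[0] - dc[0], center[1] - dc[1]) < 2 * spec.disc_radius + er:
            continue
        blob = _disk_mask((h, w), center, er)
        img[blob] += spec.exudate_brightness
        exudate |= blob
        placed += 1

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img[~fov] = 4.0  # near-black border outside the field of view
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        disc_mask=_disk_mask((h, w), dc, spec.disc_radius),
        disc_center=(float(dc[0]), float(dc[1])),
        disc_radius=float(spec.disc_radius),
        exudate_mask=exudate,
    )
    return RetinalImage(pixels, fov_mask=fov, source_id=f"phantom-{spec.seed}"), gt


def _crop_square(gray: np.ndarray, center, half: int) -> np.ndarray:
    """Square crop clamped inside the image (shifted, not shrunk)."""
    h, w = gray.shape
    side = 2 * half
    r0 = int(round(center[0])) - half
    c0 = int(round(center[1])) - half
    r0 = min(max(r0, 0), h - side)
    c0 = min(max(c0, 0), w - side)
    return gray[r0 : r0 + side, c0 : c0 + side]


def generate_training_patches(
    n_disc: int = 20, n_background: int = 20, seed: int = 0
) -> tuple[list[np.ndarray], list[str]]:
    """Labeled green-channel training patches cropped from fresh phantoms.

    Disc patches are centered on the true disc at roughly its bounding-box
    scale; negatives alternate between flat background crops and
    exudate-centered crops at the exudate's own scale (the confuser the
    classifier must reject).  Returns (patches, labels) with labels in
    {"optic_disc", "non_optic_disc"}; the disc patches double as SSIM
    templates.
    """
    if n_disc < 2 or n_background < 2:
        raise ValueError("need at least 2 patches per class")
    rng = np.random.default_rng(seed)
    patches: list[np.ndarray] = []
    labels: list[str] = []

    n_phantoms = max(n_disc, n_background)
    for i in range(n_phantoms):
        sub = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            seed=sub,
            disc_brightness=rng.uniform(55, 85),
            n_vessels=int(rng.integers(3, 6)),
            n_exudates=int(rng.integers(1, 4)),
            noise_sigma=rng.uniform(2, 4),
        )
        img, gt = generate_phantom(spec)
        gray = img.green()

        if len([l for l in labels if l == "optic_disc"]) < n_disc:
            half = int(round(1.1 * gt.disc_radius))
            patches.append(_crop_square(gray, gt.disc_center, half))
            labels.append("optic_disc")

        if len([l for l in labels if l == "non_optic_disc"]) < n_background:
            if i % 2 == 0 and gt.exudate_mask.any():
                # exudate-centered negative at the exudate's scale
                rows, cols = np.nonzero(gt.exudate_mask)
                j = int(rng.integers(0, rows.size))
                er = max(4, int(np.sqrt(gt.exudate_mask.sum() / np.pi / 2)))
                patches.append(
                    _crop_square(gray, (rows[j], cols[j]), int(1.5 * er))
                )
            else:
                # flat background inside the FOV, away from the disc
                fov = img.fov()
                for _ in range(100):
                    r = rng.uniform(0.2, 0.8) * gray.shape[0]
                    c = rng.uniform(0.2, 0.8) * gray.shape[1]
                    far = np.hypot(r - gt.disc_center[0], c - gt.disc_center[1])
                    if fov[int(r), int(c)] and far > 2.5 * gt.disc_radius:
                        break
                patches.append(
                    _crop_square(gray, (r, c), int(round(1.1 * gt.disc_radius)))
                )
            labels.append("non_optic_disc")

    return patches, labels


def generate_battery(
    n_images: int, seed: int = 0, difficulty: str = "easy"
) -> list[tuple[RetinalImage, GroundTruth]]:
    """A reproducible battery of varied phantoms for end-to-end evaluation.

    Easy batteries keep exudates small and dimmer than the disc, so the
    true disc is always the brightest connected structure; hard batteries
    add more and larger exudates at near-disc brightness.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if difficulty not in ("easy", "hard"):
        raise ValueError(f"difficulty must be 'easy' or 'hard', got {difficulty!r}")
    rng = np.random.default_rng(seed)
    battery = []
    for _ in range(n_images):
        sub = int(rng.integers(0, 2**31 - 1))
        brightness = rng.uniform(60, 90)
        if difficulty == "easy":
            spec = PhantomSpec(
                seed=sub,
                disc_brightness=brightness,
                exudate_brightness=0.6 * brightness,
                n_vessels=int(rng.integers(3, 6)),
                n_exudates=int(rng.integers(0, 4)),
                exudate_radius_range=(3.0, 7.0),
                noise_sigma=rng.uniform(2, 4),
                illumination_gradient=rng.uniform(0.08, 0.2),
            )
        else:
            spec = PhantomSpec(
                seed=sub,
                disc_brightness=brightness,
                exudate_brightness=0.95 * brightness,
                n_vessels=int(rng.integers(3, 7)),
                n_exudates=int(rng.integers(3, 7)),
                exudate_radius_range=(4.0, 10.0),
                noise_sigma=rng.uniform(3, 5),
                illumination_gradient=rng.uniform(0.12, 0.25),
            )
        battery.append(generate_phantom(spec))
    return battery
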