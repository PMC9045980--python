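"""Synthetic breast-phantom slices with ROI and tumor ground truth.

Clinical DCE-MRI breast data are private, so the package ships a phantom
generator that reproduces the *properties* the segmentation task depends on:
a bright breast region (two half-disks bulging from a chest band) against a
dark background, heavy foreground/background class imbalance (the lesion is
well under 10% of the breast area), and the two lesion morphologies seen in
breast MRI — "mass" lesions with sharp margins and high contrast, and
"nonmass" lesions with irregular support, blurred boundaries and lower
effective contrast.  Optional bright distractor blobs outside the breast
emulate confounding background tissue and motivate the two-stage cascade.

A case is an ordered stack of slices sharing one anatomy; the lesion radius
is modulated along the stack like a cut ellipsoid.  Cases are the unit of
train/test splitting and of metric averaging.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter, map_coordinates

__all__ = [
    "CaseRecord",
    "PhantomConfig",
    "augment",
    "expand_with_augmentation",
    "generate_case",
    "generate_cases",
    "load_cases",
    "save_cases",
    "split_cases",
    "zscore_normalize",
]

_BACKGROUND = 0.08
_BREAST = 0.45
_CHEST = 0.60
_TEXTURE_AMPLITUDE = 0.03
_PNG_SCALE = 2.0  # stored pixel = intensity / _PNG_SCALE * 65535


class PhantomConfigError(ValueError):
    """A phantom configuration field violates its invariant."""


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic data.

    Parameters
    ----------
    image_size:
        Pixels per side; must be >= 32 and divisible by 16 (four pooling
        levels).  128 is the desk-scale default; 512 mirrors clinical slices.
    n_slices_per_case:
        Slices in one synthetic "patient".
    lesion_type:
        "mass", "nonmass", or "mixed" (type drawn per case).
    lesion_radius_range:
        (min, max) semi-major axis in pixels; defaults scale with image size
        as (0.04, 0.08) * image_size.
    lesion_contrast:
        Intensity offset of the lesion over breast tissue, in [0, 1].
    nonmass_blur_sigma:
        Gaussian sigma (pixels) blurring the rendered nonmass intensity.
    noise_sigma:
        Additive white-noise sigma in intensity units.
    n_distractors:
        Bright lesion-like blobs placed outside the breast region.
    """

    image_size: int = 128
    n_slices_per_case: int = 3
    lesion_type: str = "mixed"
    lesion_radius_range: tuple | None = None
    lesion_contrast: float = 0.4
    nonmass_blur_sigma: float = 2.0
    noise_sigma: float = 0.04
    n_distractors: int = 0
    seed: int = 0

    def __post_init__(self):
        s = self.image_size
        if s < 32 or s % 16:
            raise PhantomConfigError(
                f"image_size must be >= 32 and divisible by 16, got {s}"
            )
        if self.n_slices_per_case < 1:
            raise PhantomConfigError("n_slices_per_case must be >= 1")
        if self.lesion_type not in ("mass", "nonmass", "mixed"):
            raise PhantomConfigError(f"lesion_type {self.lesion_type!r} unknown")
        if self.lesion_radius_range is None:
            self.lesion_radius_range = (max(3, round(0.04 * s)), round(0.08 * s))
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise PhantomConfigError("lesion_radius_range must satisfy 0 < min <= max")
        if hi > 0.15 * s:
            raise PhantomConfigError(
                "lesion_radius_range too large to fit inside the breast region"
            )
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise PhantomConfigError("lesion_contrast must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise PhantomConfigError("noise_sigma must be >= 0")
        if self.nonmass_blur_sigma < 0:
            raise PhantomConfigError("nonmass_blur_sigma must be >= 0")


@dataclass
class CaseRecord:
    """One synthetic patient: aligned image, ROI-mask and tumor-mask stacks."""

    case_id: str
    slices: list  # list of (H, W) float32 arrays
    roi_masks: list  # list of (H, W) uint8 {0,1} arrays
    tumor_masks: list  # list of (H, W) uint8 {0,1} arrays
    lesion_type: str = "mass"

    def validate(self):
        if not (len(self.slices) == len(self.roi_masks) == len(self.tumor_masks)):
            raise ValueError("slice/mask stacks differ in length")
        for img, roi, tum in zip(self.slices, self.roi_masks, self.tumor_masks):
            for m in (roi, tum):
                vals = np.unique(m)
                if not np.all(np.isin(vals, (0, 1))):
                    raise ValueError("masks must be strictly {0,1}-valued")
            if np.any(tum & ~roi):
                raise ValueError("tumor mask leaves the ROI mask")
        return self

    @property
    def n_slices(self):
        return len(self.slices)


def _grid(size):
    return np.meshgrid(np.arange(size), np.arange(size), indexing="ij")


def _breast_geometry(size, rng):
    """Breast union mask and per-breast (center_row, center_col, radius)."""
    chest_top = int(round(0.80 * size))
    rows, cols = _grid(size)
    for _ in range(20):
        radii = rng.uniform(0.28, 0.32, size=2) * size
        centers = [(chest_top, 0.28 * size), (chest_top, 0.72 * size)]
        mask = np.zeros((size, size), dtype=bool)
        for (cr, cc), r in zip(centers, radii):
            mask |= ((rows - cr) ** 2 + (cols - cc) ** 2 <= r**2) & (rows < chest_top)
        frac = mask.mean()
        if 0.20 < frac < 0.60:
            return mask, chest_top, centers, radii
    raise RuntimeError("could not place a breast region in the 20-60% band")


def _ellipse_mask(size, center, axes, angle):
    rows, cols = _grid(size)
    dr, dc = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_case(config: PhantomConfig, seed: int | None = None) -> CaseRecord:
    """Generate one deterministic phantom case.

    Given the same ``(config, seed)`` the output is bit-identical.  The
    breast occupies 20-60% of the image, the lesion under 10% of the breast,
    and the tumor mask is a subset of the ROI mask on every slice.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    s = config.image_size
    breast, chest_top, centers, radii = _breast_geometry(s, rng)

    lesion_type = config.lesion_type
    if lesion_type == "mixed":
        lesion_type = "mass" if rng.random() < 0.5 else "nonmass"

    # Lesion placement: fully inside one breast half-disk, above the chest.
    lo, hi = config.lesion_radius_range
    a = rng.uniform(lo, hi)
    b = a * rng.uniform(0.6, 1.0)
    angle = rng.uniform(0, np.pi)
    side = int(rng.integers(2))
    (cr0, cc0), rb = centers[side], radii[side]
    for _ in range(100):
        rad = rng.uniform(0, max(rb - a - 3.0, 1.0))
        theta = rng.uniform(np.pi, 2 * np.pi)  # upper half of the disk
        lr = cr0 + rad * np.sin(theta)
        lc = cc0 + rad * np.cos(theta)
        if lr < chest_top - a - 2 and a + 2 < lc < s - a - 2:
            full = _ellipse_mask(s, (lr, lc), (a + 1, b + 1), angle)
            if not np.any(full & ~breast):
                break
    else:  # pragma: no cover - extremely unlikely with valid configs
        raise RuntimeError("failed to place a lesion inside the breast")

    # Nonmass support: thresholded smoothed noise inside the ellipse.
    support_noise = gaussian_filter(rng.standard_normal((s, s)), 0.06 * s)

    # Distractor geometry is shared across slices.
    distractors = np.zeros((s, s), dtype=bool)
    rows, cols = _grid(s)
    placed = 0
    for _ in range(200):
        if placed >= config.n_distractors:
            break
        dr_c = rng.uniform(0.05 * s, 0.95 * s)
        dc_c = rng.uniform(0.05 * s, 0.95 * s)
        drad = rng.uniform(0.025 * s, 0.05 * s)
        blob = (rows - dr_c) ** 2 + (cols - dc_c) ** 2 <= drad**2
        if not np.any(blob & breast):
            distractors |= blob
            placed += 1

    n = config.n_slices_per_case
    images, roi_masks, tumor_masks = [], [], []
    for z in range(n):
        t = 0.0 if n == 1 else (z - (n - 1) / 2) / ((n - 1) / 2)
        zscale = np.sqrt(1.0 - 0.5 * t * t)  # ellipsoid cross-section
        ell = _ellipse_mask(s, (lr, lc), (a * zscale, b * zscale), angle)
        if lesion_type == "nonmass":
            thr = np.quantile(support_noise[ell], 0.35) if ell.any() else 0.0
            lesion = ell & (support_noise > thr)
            if not lesion.any():
                lesion = ell
        else:
            lesion = ell

        img = np.full((s, s), _BACKGROUND, dtype=np.float64)
        img[chest_top:] = _CHEST
        img[breast] = _BREAST
        img += distractors * (_BREAST + config.lesion_contrast - img)
        texture = gaussian_filter(rng.standard_normal((s, s)), 2.0)
        img += _TEXTURE_AMPLITUDE * texture * (breast | (rows >= chest_top))
        if lesion_type == "nonmass":
            bump = lesion * config.lesion_contrast
            if config.nonmass_blur_sigma > 0:
                bump = gaussian_filter(bump, config.nonmass_blur_sigma)
            img += bump
        else:
            img += lesion * config.lesion_contrast
        if config.noise_sigma > 0:
            img += rng.normal(0.0, config.noise_sigma, size=(s, s))

        images.append(img.astype(np.float32))
        roi_masks.append(breast.astype(np.uint8))
        tumor_masks.append(lesion.astype(np.uint8))

    return CaseRecord(
        case_id=f"case_{seed:06d}",
        slices=images,
        roi_masks=roi_masks,
        tumor_masks=tumor_masks,
        lesion_type=lesion_type,
    ).validate()


def generate_cases(config: PhantomConfig, n_cases: int, seed: int = 0) -> list:
    """Generate ``n_cases`` phantoms with per-case seeds derived from ``seed``."""
    root = np.random.default_rng(seed)
    case_seeds = root.integers(0, 2**31 - 1, size=n_cases)
    return [generate_case(config, int(cs)) for cs in case_seeds]


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Standardize one slice to zero mean / unit variance.

    A constant slice has no scale to normalize by; it maps to all zeros with
    a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    mu = image.mean()
    sd = image.std()
    if sd < 1e-12:
        warnings.warn("constant image: z-score normalization returns zeros", stacklevel=2)
        return np.zeros_like(image, dtype=np.float32)
    return ((image - mu) / sd).astype(np.float32)


def augment(image, masks, op: str, params: dict | None = None, seed: int = 0):
    """Apply one geometric augmentation identically to an image and its masks.

    Supported ops: ``mirror`` (left-right flip), ``scale`` (central zoom by
    ``params['factor']``), ``elastic`` (Gaussian-smoothed random displacement
    field with ``params['amplitude']`` and ``params['sigma']``, both pixels).
    The image is warped bilinearly, masks by nearest neighbour, and the
    output size equals the input size.
    """
    params = params or {}
    image = np.asarray(image)
    masks = [np.asarray(m) for m in masks]
    for m in masks:
        if m.shape != image.shape:
            raise ValueError("image and masks must share dimensions")

    if op == "mirror":
        return np.flip(image, axis=1).copy(), [np.flip(m, axis=1).copy() for m in masks]

    if op == "scale":
        f = float(params.get("factor", 1.25))
        if f <= 0:
            raise ValueError(f"scale factor must be > 0, got {f}")
        c = (np.asarray(image.shape) - 1) / 2.0
        matrix = np.eye(2) / f
        offset = c - matrix @ c
        bg = float(image[0, 0])
        out_img = affine_transform(
            image.astype(np.float64), matrix, offset=offset, order=1, cval=bg
        ).astype(image.dtype)
        out_masks = [
            (affine_transform(m.astype(np.float64), matrix, offset=offset, order=0, cval=0.0) > 0.5).astype(m.dtype)
            for m in masks
        ]
        return out_img, out_masks

    if op == "elastic":
        amp = float(params.get("amplitude", 4.0))
        sig = float(params.get("sigma", 8.0))
        if amp == 0:
            return image.copy(), [m.copy() for m in masks]
        rng = np.random.default_rng(seed)
        disp = [gaussian_filter(rng.uniform(-1, 1, image.shape), sig) for _ in range(2)]
        peak = max(np.abs(d).max() for d in disp)
        disp = [d / peak * amp for d in disp]
        rows, cols = _grid(image.shape[0])
        coords = [rows + disp[0], cols + disp[1]]
        out_img = map_coordinates(
            image.astype(np.float64), coords, order=1, mode="reflect"
        ).astype(image.dtype)
        out_masks = [
            (map_coordinates(m.astype(np.float64), coords, order=0, mode="constant") > 0.5).astype(m.dtype)
            for m in masks
        ]
        return out_img, out_masks

    raise ValueError(f"unknown augmentation op {op!r}")


def expand_with_augmentation(cases: list, multiplier: int = 4, seed: int = 0) -> list:
    """Expand a training set: originals plus ``multiplier - 1`` warped copies.

    Each copy applies one randomly drawn op with random parameters, the same
    transform for every slice of a case so stacks stay coherent.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    out = list(cases)
    for k in range(multiplier - 1):
        for case in cases:
            op = rng.choice(["mirror", "scale", "elastic"])
            params = {}
            if op == "scale":
                params = {"factor": float(rng.uniform(0.85, 1.2))}
            elif op == "elastic":
                params = {"amplitude": float(rng.uniform(1.0, 4.0)), "sigma": 8.0}
            tseed = int(rng.integers(0, 2**31 - 1))
            slices, rois, tums = [], [], []
            for img, roi, tum in zip(case.slices, case.roi_masks, case.tumor_masks):
                aimg, (aroi, atum) = augment(img, [roi, tum], op, params, seed=tseed)
                atum &= aroi  # warping can nudge a boundary pixel outside
                slices.append(aimg)
                rois.append(aroi)
                tums.append(atum)
            out.append(
                CaseRecord(
                    case_id=f"{case.case_id}_aug{k}_{op}",
                    slices=slices,
                    roi_masks=rois,
                    tumor_masks=tums,
                    lesion_type=case.lesion_type,
                ).validate()
            )
    return out


def split_cases(cases: list, train_fraction: float, seed: int = 0):
    """Split by case (never by slice) into disjoint, exhaustive partitions."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    n = len(cases)
    n_train = int(np.clip(round(n * train_fraction), 1, n - 1))
    order = np.random.default_rng(seed).permutation(n)
    train = [cases[i] for i in sorted(order[:n_train])]
    test = [cases[i] for i in sorted(order[n_train:])]
    return train, test


# -- on-disk dataset layout ----------------------------------------------------


def save_cases(cases: list, out_dir) -> None:
    """Write one directory per case: 16-bit gray PNGs, binary mask PNGs, manifest."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        cdir = out_dir / case.case_id
        cdir.mkdir(exist_ok=True)
        for i, (img, roi, tum) in enumerate(zip(case.slices, case.roi_masks, case.tumor_masks)):
            img16 = np.clip(img / _PNG_SCALE, 0, 1) * 65535
            iio.imwrite(cdir / f"image_{i:04d}.png", img16.astype(np.uint16))
            iio.imwrite(cdir / f"roi_{i:04d}.png", (roi * 255).astype(np.uint8))
            iio.imwrite(cdir / f"tumor_{i:04d}.png", (tum * 255).astype(np.uint8))
        manifest = {
            "case_id": case.case_id,
            "n_slices": case.n_slices,
            "lesion_type": case.lesion_type,
            "intensity_scale": _PNG_SCALE,
        }
        (cdir / "case.json").write_text(json.dumps(manifest, indent=2))


def load_cases(in_dir) -> list:
    """Load a dataset written by :func:`save_cases`."""
    import imageio.v3 as iio

    cases = []
    for cdir in sorted(Path(in_dir).iterdir()):
        mpath = cdir / "case.json"
        if not mpath.exists():
            continue
        manifest = json.loads(mpath.read_text())
        scale = manifest.get("intensity_scale", _PNG_SCALE)
        slices, rois, tums = [], [], []
        for i in range(manifest["n_slices"]):
            img16 = iio.imread(cdir / f"image_{i:04d}.png")
            slices.append((img16.astype(np.float32) / 65535.0 * scale))
            rois.append((iio.imread(cdir / f"roi_{i:04d}.png") > 127).astype(np.uint8))
            tums.append((iio.imread(cdir / f"tumor_{i:04d}.png") > 127).astype(np.uint8))
        cases.append(
            CaseRecord(
                case_id=manifest["case_id"],
                slices=slices,
                roi_masks=rois,
                tumor_masks=tums,
                lesion_type=manifest.get("lesion_type", "mass"),
            ).validate()
        )
    return cases
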