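"""Image-quality and motion perturbations for robustness testing.

The robustness harness perturbs the *images* entering registration — Gaussian
noise, thicker slices, bulk rigid motion — while the ground-truth field and
meshes stay untouched, then reruns the full VDM analysis and compares the
growth-metric errors with and without the perturbation.

Noise levels are characterized by the contrast-to-noise ratio
CNR = (μ_aorta − μ_bg) / sqrt(σ²_aorta + σ²_bg), with the aortic ROI taken as
the segmentation mask eroded by three voxels and the background ROI drawn in
the surrounding tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import ImageGrid, ImageVolume
from .registration.stages import RigidTransform

__all__ = [
    "PerturbationSpec",
    "add_gaussian_noise",
    "compute_cnr",
    "default_background_roi",
    "sigma_for_cnr",
    "resample_slice_thickness",
    "apply_bulk_motion",
]

NOISE_LEVELS_HU = (50.0, 100.0, 150.0)
SLICE_THICKNESSES_MM = (1.0, 1.5, 2.0)
TRANSLATION_LEVELS_MM = (20.0, 40.0, 60.0)
ROTATION_BOUND_DEG = 5.0


@dataclass
class PerturbationSpec:
    """One perturbation arm: kind, level and seed.

    Levels come from the standard menus (noise sigma 50/100/150 HU, slice
    thickness 1.0/1.5/2.0 mm, translation magnitude 20/40/60 mm with per-axis
    rotations uniform in ±5°) unless explicitly overridden.
    """

    kind: str
    level: float
    seed: int = 0
    rotation_bound_deg: float = ROTATION_BOUND_DEG
    allow_custom_level: bool = False

    _MENUS = {
        "noise": NOISE_LEVELS_HU,
        "slice_thickness": SLICE_THICKNESSES_MM,
        "bulk_motion": TRANSLATION_LEVELS_MM,
        "respiratory": None,
    }

    def __post_init__(self) -> None:
        if self.kind not in self._MENUS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        menu = self._MENUS[self.kind]
        if menu is not None and not self.allow_custom_level and self.level not in menu:
            raise ValueError(
                f"{self.kind} level {self.level} not in standard menu {menu}; "
                "pass allow_custom_level=True to override"
            )


def add_gaussian_noise(img: ImageVolume, sigma: float, seed: int = 0) -> ImageVolume:
    """Add i.i.d. zero-mean Gaussian noise (HU); deterministic for a given seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(img.grid.shape) * sigma
    return ImageVolume((img.data + noise).astype(np.float32), img.grid)


def default_background_roi(aorta_mask: ImageVolume, margin_vox: int = 6,
                           width_vox: int = 6) -> ImageVolume:
    """Background ROI adjacent to the aorta: a shell well clear of the wall.

    Mirrors the role of the manually drawn mediastinal-fat ROIs: tissue near
    the aorta but free of lumen partial-volume voxels.
    """
    m = aorta_mask.data.astype(bool)
    inner = ndimage.binary_dilation(m, iterations=margin_vox)
    outer = ndimage.binary_dilation(inner, iterations=width_vox)
    roi = outer & ~inner
    return ImageVolume(roi.astype(np.uint8), aorta_mask.grid)


def compute_cnr(
    img: ImageVolume,
    aorta_mask: ImageVolume,
    bg_roi: Optional[ImageVolume] = None,
    erosion: int = 3,
) -> float:
    """Contrast-to-noise ratio with the aortic ROI eroded by 3 voxels."""
    eroded = ndimage.binary_erosion(aorta_mask.data.astype(bool), iterations=erosion)
    if not eroded.any():
        raise ValueError("aortic ROI empty after erosion")
    if bg_roi is None:
        bg_roi = default_background_roi(aorta_mask)
    bg = bg_roi.data.astype(bool)
    if not bg.any():
        raise ValueError("background ROI empty")
    a = img.data[eroded].astype(float)
    b = img.data[bg].astype(float)
    denom = np.sqrt(a.var() + b.var())
    if denom == 0:
        raise ZeroDivisionError("noise-free ROIs: CNR undefined (zero variance)")
    return float((a.mean() - b.mean()) / denom)


def sigma_for_cnr(
    img: ImageVolume,
    aorta_mask: ImageVolume,
    target_cnr: float,
    bg_roi: Optional[ImageVolume] = None,
    erosion: int = 3,
) -> float:
    """Noise sigma (HU) that brings this image's CNR to ``target_cnr``.

    With equal i.i.d. noise σ added to both ROIs,
    CNR(σ) = Δμ / sqrt(v_a + v_b + 2σ²); solve for σ.  Raises if the image is
    already below the target.
    """
    eroded = ndimage.binary_erosion(aorta_mask.data.astype(bool), iterations=erosion)
    if bg_roi is None:
        bg_roi = default_background_roi(aorta_mask)
    a = img.data[eroded].astype(float)
    b = img.data[bg_roi.data.astype(bool)].astype(float)
    dmu = a.mean() - b.mean()
    v0 = a.var() + b.var()
    need = (dmu / target_cnr) ** 2 - v0
    if need <= 0:
        raise ValueError(
            f"image CNR already at/below target {target_cnr}; cannot reach it by adding noise"
        )
    return float(np.sqrt(need / 2.0))


def resample_slice_thickness(img: ImageVolume, thickness: float) -> ImageVolume:
    """Box-average the z axis to a thicker slice profile; in-plane unchanged.

    Each output slice averages the (linearly interpolated) intensity over a
    ``thickness``-wide axial window — the simplest slice-sensitivity-profile
    model; intensity mass is conserved up to the volume ends.
    """
    sz = img.grid.spacing[2]
    if thickness < sz - 1e-9:
        raise ValueError(f"target thickness {thickness} < native z-spacing {sz}")
    if abs(thickness - sz) < 1e-9:
        return img.copy()
    nz = img.grid.shape[2]
    z0 = img.grid.origin[2]
    z_extent = (nz - 1) * sz
    nz_new = max(2, int(np.floor(z_extent / thickness)) + 1)
    z_new = z0 + np.arange(nz_new) * thickness
    # integrate the linear interpolant of each z-profile over the slab window
    # via its antiderivative on the fine grid
    data = img.data.astype(float)
    csum = np.concatenate(
        [np.zeros(data.shape[:2] + (1,)), np.cumsum(
            0.5 * (data[:, :, 1:] + data[:, :, :-1]) * sz, axis=2)], axis=2
    )  # antiderivative sampled at fine z nodes

    def integral_at(z):
        """∫ profile dz from z0 to z, per (x, y)."""
        t = np.clip((z - z0) / sz, 0.0, nz - 1.0)
        k = np.floor(t).astype(int)
        k = np.minimum(k, nz - 2)
        frac = t - k
        f0 = data[:, :, k]
        f1 = data[:, :, k + 1]
        partial = sz * (f0 * frac + 0.5 * (f1 - f0) * frac**2)
        return csum[:, :, k] + partial

    out = np.empty(data.shape[:2] + (nz_new,), dtype=np.float32)
    half = 0.5 * thickness
    for j, zc in enumerate(z_new):
        lo = max(zc - half, z0)
        hi = min(zc + half, z0 + z_extent)
        out[:, :, j] = (integral_at(hi) - integral_at(lo)) / (hi - lo)
    new_grid = ImageGrid(
        (img.grid.shape[0], img.grid.shape[1], nz_new),
        (img.grid.spacing[0], img.grid.spacing[1], thickness),
        img.grid.origin,
        img.grid.direction,
    )
    return ImageVolume(out, new_grid)


def apply_bulk_motion(
    img: ImageVolume,
    mask: ImageVolume,
    translation_level: float,
    rotation_bound_deg: float = ROTATION_BOUND_DEG,
    seed: int = 0,
    pad_mm: float = 8.0,
) -> tuple[ImageVolume, ImageVolume, RigidTransform]:
    """Apply one random bulk rigid motion to an image/mask pair.

    Rotations are drawn uniformly in ±``rotation_bound_deg`` per axis; the
    translation has magnitude ``translation_level`` with random per-axis sign
    (equal components along the three axes).  The output grid's origin follows
    the translation and is padded for the rotation, so the anatomy never
    leaves the field of view; the generating transform is returned for
    verification.
    """
    rng = np.random.default_rng(seed)
    if translation_level == 0 and rotation_bound_deg == 0:
        return img.copy(), mask.copy(), RigidTransform.identity()
    angles = np.deg2rad(rng.uniform(-rotation_bound_deg, rotation_bound_deg, 3))
    signs = rng.choice([-1.0, 1.0], 3)
    t = signs * translation_level / np.sqrt(3.0)
    center = np.asarray(img.grid.origin) + 0.5 * img.grid.extent
    motion = RigidTransform.from_euler(angles, t, center)

    pad = int(np.ceil(pad_mm / min(img.grid.spacing)))
    shape = tuple(n + 2 * pad for n in img.grid.shape)
    origin = tuple(
        img.grid.origin[a] - pad * img.grid.spacing[a] + t[a] for a in range(3)
    )
    out_grid = ImageGrid(shape, img.grid.spacing, origin, img.grid.direction)
    pts = out_grid.meshgrid_world().reshape(-1, 3)
    src = motion.inverse().apply(pts)
    idx = img.grid.world_to_index(src).T
    bg = float(np.percentile(img.data, 1))
    vals = ndimage.map_coordinates(img.data.astype(float), idx, order=1,
                                   mode="constant", cval=bg)
    mvals = ndimage.map_coordinates(mask.data.astype(float), idx, order=1,
                                    mode="constant", cval=0.0)
    new_mask = (mvals >= 0.5).astype(np.uint8).reshape(shape)
    if mask.data.any() and new_mask.sum() < 0.8 * mask.data.sum():
        raise ValueError("bulk motion pushed the mask outside the padded FOV")
    return (
        ImageVolume(vals.reshape(shape).astype(np.float32), out_grid),
        ImageVolume(new_mask, out_grid),
        motion,
    )
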