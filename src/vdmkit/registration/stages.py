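"""The three-stage VDM registration pipeline.

Stage 1 rigidly aligns the scans by maximizing normalized cross-correlation
over the dilated aortic mask.  Stage 2 ("centerline alignment") is a coarse
B-spline registration driven by mutual information with bending-energy
(weight 10) and rigidity (weight 20) regularization: surrounding tissue may
deform but the aorta itself moves near-rigidly, which implicitly aligns the
aortic centerlines.  Stage 3 is a finer B-spline registration with MI and a
stronger bending-energy term (weight 100) that captures wall growth.

The returned field composes all three stages (fixed-space x ↦ moving-space
x + u(x)); the rigid transform and the deformable-only part are also kept
separately, so bulk patient repositioning can be distinguished from tissue
deformation.  Growth metrics are invariant under a rigid motion shared by
both meshes, so including the rigid stage keeps them comparable across
moved scan pairs while still capturing drag absorbed by any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from ..core import DisplacementField, ImageGrid, ImageVolume, compose_fields
from .bspline import BSplineModel
from .penalties import bending_energy_and_grad, make_rigidity_map, rigidity_and_grad
from .similarity import mi_and_grad, ncc_and_grad, ssd_and_grad

__all__ = [
    "RigidTransform",
    "StageConfig",
    "VdmConfig",
    "VdmResult",
    "clamp_negative",
    "rigid_stage",
    "bspline_stage",
    "centerline_alignment_stage",
    "final_dir_stage",
    "run_vdm",
]


# ---------------------------------------------------------------------------
# rigid transform


@dataclass
class RigidTransform:
    """x ↦ R (x − c) + c + t with R orthonormal (det +1)."""

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, dtype=float))

    @classmethod
    def from_euler(cls, angles_rad, translation, center) -> "RigidTransform":
        ax, ay, az = angles_rad
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(Rz @ Ry @ Rx, np.asarray(translation, float), np.asarray(center, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ self.rotation.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, self.center)

    def euler_angles(self) -> np.ndarray:
        """ZYX-convention Euler angles (radians) of the rotation."""
        R = self.rotation
        ay = np.arcsin(np.clip(-R[2, 0], -1, 1))
        ax = np.arctan2(R[2, 1], R[2, 2])
        az = np.arctan2(R[1, 0], R[0, 0])
        return np.array([ax, ay, az])


def clamp_negative(img: ImageVolume) -> ImageVolume:
    """Clamp negative HU to zero (removes the influence of aerated lung)."""
    return ImageVolume(np.maximum(img.data, 0), img.grid)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StageConfig:
    """Parameters for one registration stage."""

    similarity: str = "MI"            # MI | NCC | SSD
    bending_weight: float = 0.0
    rigidity_weight: float = 0.0
    control_spacing: float = 10.0     # B-spline control-point spacing, mm
    strides: tuple[int, ...] = (3, 2) # sample-grid stride per resolution level
    iterations: "int | tuple" = 60    # optimizer iterations: int, or tuple per level
    mi_bins: int = 32
    max_samples: int = 30000
    displacement_weight: float = 0.0  # Tikhonov pull toward zero displacement
    transverse_weight: float = 0.0    # pull-to-zero restricted to directions
                                      # transverse to the intensity gradient
                                      # (suppresses sliding along level sets
                                      # without shrinking genuine motion)
    total_transverse_weight: float = 0.0  # same, but applied to the TOTAL
                                      # displacement (outer ∘ current) at the
                                      # similarity samples: pins the sliding
                                      # null space of the composed map so two
                                      # registrations of the same anatomy
                                      # agree on correspondence
    transverse_highpass_mm: float = 0.0   # if > 0, the dense transverse
                                      # penalty sees only displacement
                                      # variation below this scale: smooth
                                      # bulk motion (e.g. respiratory drag)
                                      # passes free, oscillatory sliding is
                                      # still pinned
    smoothing_floor_vox: float = 0.0  # minimum pyramid smoothing at every
                                      # level (voxels); denoises the full-
                                      # resolution level at a small cost in
                                      # boundary sharpness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bending_weight < 0 or self.rigidity_weight < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.control_spacing <= 0:
            raise ValueError("control spacing must be > 0")


@dataclass
class VdmConfig:
    """Full three-stage pipeline configuration."""

    rigid: StageConfig = dc_field(
        default_factory=lambda: StageConfig(similarity="NCC", strides=(4, 2, 1))
    )
    coarse: StageConfig = dc_field(
        default_factory=lambda: StageConfig(
            similarity="MI", bending_weight=10.0, rigidity_weight=20.0,
            control_spacing=14.0, strides=(3, 2), iterations=(40, 20),
            mi_bins=48, transverse_weight=1e-3, transverse_highpass_mm=25.0,
            smoothing_floor_vox=1.0,
        )
    )
    fine: StageConfig = dc_field(
        default_factory=lambda: StageConfig(
            similarity="MI", bending_weight=100.0, rigidity_weight=0.0,
            control_spacing=7.0, strides=(4, 2, 1), iterations=(40, 30, 15),
            mi_bins=48, transverse_weight=1e-3, transverse_highpass_mm=25.0,
            smoothing_floor_vox=1.0,
        )
    )
    mask_dilation: int = 5
    clamp_hu: bool = True
    seed: int = 0

    @classmethod
    def fast(cls) -> "VdmConfig":
        """Reduced-effort settings for smoke tests."""
        cfg = cls()
        cfg.rigid = replace(cfg.rigid, strides=(4,))
        cfg.coarse = replace(cfg.coarse, strides=(3,), iterations=30)
        cfg.fine = replace(cfg.fine, strides=(2,), iterations=40)
        return cfg


@dataclass
class VdmResult:
    """Output of the full pipeline.

    ``field`` is the total fixed→moving displacement (rigid ∘ deformable) on
    the fixed grid; ``deformable`` excludes the rigid stage (the growth part);
    ``rigid`` is the stage-1 transform alone.
    """

    field: DisplacementField
    deformable: DisplacementField
    rigid: RigidTransform
    meta: dict


# ---------------------------------------------------------------------------
# stage 1: rigid


def _mask_points(mask: ImageVolume, stride: int, cap: int = 40000):
    idx = np.argwhere(mask.data[::stride, ::stride, ::stride].astype(bool)) * stride
    if len(idx) > cap:
        idx = idx[:: int(np.ceil(len(idx) / cap))]
    pts = mask.grid.index_to_world(idx)
    return idx, pts


def _centroid(mask: ImageVolume) -> np.ndarray:
    idx = np.argwhere(mask.data.astype(bool))
    return mask.grid.index_to_world(idx).mean(axis=0)


def rigid_stage(
    fixed: ImageVolume,
    moving: ImageVolume,
    fixed_mask: ImageVolume,
    moving_mask: ImageVolume,
    cfg: Optional[StageConfig] = None,
    mask_dilation: int = 5,
) -> RigidTransform:
    """NCC-optimal rigid alignment over the dilated fixed mask.

    Translation is initialized from the mask centroid offset (a large capture
    range without multistart); Powell refines 3 Euler angles + 3 translations.
    """
    cfg = cfg or StageConfig(similarity="NCC", strides=(4, 2, 1))
    if not fixed_mask.data.any() or not moving_mask.data.any():
        raise ValueError("rigid stage requires nonempty masks")
    domain = make_rigidity_map(fixed_mask, mask_dilation)
    center = _centroid(fixed_mask)
    t0 = _centroid(moving_mask) - center

    def build(p):
        return RigidTransform.from_euler(p[:3] * 0.01, p[3:] + t0, center)

    p_opt = np.zeros(6)
    for stride in cfg.strides:
        _, pts = _mask_points(domain, stride, cap=cfg.max_samples)
        fv = fixed.sample(pts, order=1)

        def cost(p):
            mv = moving.sample(build(p).apply(pts), order=1)
            try:
                s, _ = ncc_and_grad(fv, mv)
            except ValueError:
                return 1.0
            return -s

        res = optimize.minimize(
            cost, p_opt, method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 12},
        )
        p_opt = res.x
    return build(p_opt)


# ---------------------------------------------------------------------------
# B-spline deformable stage


def _lowpass(vol: np.ndarray, sigma_vox) -> np.ndarray:
    """Fast large-kernel smoother: triple box filter ≈ Gaussian of sigma.

    Cost is independent of sigma (unlike a direct Gaussian), and the operator
    is symmetric, so it serves as its own adjoint in penalty gradients.
    """
    sizes = [max(1, int(round(np.sqrt(12.0 * s * s / 3.0 + 1.0)))) for s in sigma_vox]
    out = vol
    for _ in range(3):
        out = ndimage.uniform_filter(out, size=sizes, mode="nearest")
    return out


class _Outer:
    """Map applied after the current displacement when sampling the moving image."""

    def __init__(self, rigid: Optional[RigidTransform] = None,
                 prior: Optional[DisplacementField] = None):
        self.rigid = rigid
        self.prior = prior

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        out = pts
        if self.prior is not None:
            out = out + self.prior.sample(out, order=1)
        if self.rigid is not None:
            out = self.rigid.apply(out)
        return out

    def rotation(self) -> np.ndarray:
        return np.eye(3) if self.rigid is None else self.rigid.rotation


def _crop_grid(mask: ImageVolume, margin_vox: int) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask.data.astype(bool))
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + margin_vox + 1, mask.grid.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def bspline_stage(
    fixed: ImageVolume,
    moving: ImageVolume,
    domain: ImageVolume,
    cfg: StageConfig,
    rigidity: Optional[ImageVolume] = None,
    outer: Optional[_Outer] = None,
    initial_coef: Optional[np.ndarray] = None,
    anchor_to_initial: bool = False,
) -> tuple[DisplacementField, dict]:
    """One multiresolution B-spline registration stage.

    Returns the displacement field evaluated on the full fixed grid (zero
    outside the optimized region) plus a metadata dict with per-level cost
    traces.
    """
    outer = outer or _Outer()
    crop = _crop_grid(domain, margin_vox=6)
    sub_origin = fixed.grid.index_to_world([s.start for s in crop])[0]
    ctrl_extent = tuple(
        (sub_origin[a], sub_origin[a] + (crop[a].stop - crop[a].start - 1)
         * fixed.grid.spacing[a])
        for a in range(3)
    )

    fixed_crop = fixed.data[crop].astype(float)
    f_dom = fixed_crop[domain.data[crop].astype(bool)]
    f_range = (float(f_dom.min()), float(f_dom.max()))
    m_range = (float(moving.data.min()), float(moving.data.max()))
    if f_range[1] <= f_range[0]:
        raise ValueError("fixed image constant over registration domain")

    iters = (
        tuple(cfg.iterations)
        if isinstance(cfg.iterations, (tuple, list))
        else (int(cfg.iterations),) * len(cfg.strides)
    )
    coef = None
    model = None
    trace = []
    for stride, lv_iters in zip(cfg.strides, iters):
        lv_shape = tuple(len(range(s.start, s.stop, stride)) for s in crop)
        lv_spacing = tuple(sp * stride for sp in fixed.grid.spacing)
        lv_grid = ImageGrid(lv_shape, lv_spacing, tuple(sub_origin))
        lv_slices = tuple(slice(None, None, stride) for _ in crop)
        # Gaussian pyramid: smoothing proportional to the subsampling widens
        # the capture basin at coarse levels (boundary shifts of several mm
        # are otherwise outside the gradient support of a sharp wall)
        sig_lvl = max(0.5 * (stride - 1), cfg.smoothing_floor_vox)
        if sig_lvl > 0:
            lv_fixed_full = ndimage.gaussian_filter(fixed_crop, sig_lvl)
            sig_mov = [sig_lvl * fixed.grid.spacing[a] / moving.grid.spacing[a]
                       for a in range(3)]
            mov_data = ndimage.gaussian_filter(moving.data.astype(float), sig_mov)
        else:
            lv_fixed_full = fixed_crop
            mov_data = moving.data.astype(float)
        grad_mov = np.gradient(mov_data, *moving.grid.spacing)
        lv_fixed = lv_fixed_full[lv_slices]
        lv_domain = domain.data[crop][lv_slices].astype(bool)
        lv_rigid = (rigidity.data[crop][lv_slices].astype(bool)
                    if rigidity is not None else None)

        model = BSplineModel(lv_grid, cfg.control_spacing, extent=ctrl_extent)
        if coef is None:
            coef = model.zero_coefficients() if initial_coef is None else initial_coef.copy()
        u_ref = model.dense(initial_coef) if (anchor_to_initial and initial_coef is not None) else None

        sel = np.argwhere(lv_domain)
        if len(sel) > cfg.max_samples:
            sel = sel[:: int(np.ceil(len(sel) / cfg.max_samples))]
        sel_t = tuple(sel.T)
        pts = lv_grid.index_to_world(sel)
        fv = lv_fixed[sel_t]
        if fv.max() <= fv.min():
            raise ValueError("fixed image constant over level domain")
        mask_w = lv_domain
        rot = outer.rotation()

        nhat_s = conf_s = None
        if cfg.total_transverse_weight > 0:
            gfx = np.gradient(lv_fixed, *lv_spacing)
            gf = np.stack([g[sel_t] for g in gfx], axis=1)
            gmag2_s = np.sum(gf * gf, axis=1)
            tau2_s = (0.1 * np.sqrt(gmag2_s.max())) ** 2 if len(gf) else 1.0
            conf_s = gmag2_s / (gmag2_s + tau2_s)
            nhat_s = gf / np.sqrt(np.maximum(gmag2_s, 1e-300))[:, None]

        nhat = conf = None
        if cfg.transverse_weight > 0:
            # combined fixed+moving gradient direction spans both shell
            # positions; where the gradient is weak the penalty becomes
            # isotropic (confidence → 0 keeps the full |u|² term)
            mv_lv = moving.sample(lv_grid.meshgrid_world().reshape(-1, 3), order=1)
            both = lv_fixed + mv_lv.reshape(lv_shape)
            gv = np.stack(np.gradient(both, *lv_spacing), axis=-1)
            gmag2 = np.sum(gv * gv, axis=-1)
            tau2 = (0.1 * np.sqrt(gmag2[lv_domain].max())) ** 2 if lv_domain.any() else 1.0
            conf = gmag2 / (gmag2 + tau2)
            nhat = gv / np.sqrt(np.maximum(gmag2, 1e-300))[..., None]

        def cost_and_grad(x):
            c = x.reshape(coef.shape)
            u = model.dense(c)
            warped = outer(pts + u[sel_t])
            widx = moving.grid.world_to_index(warped).T
            mv = ndimage.map_coordinates(mov_data, widx, order=1, mode="nearest")
            if cfg.similarity == "MI":
                sim, dsim = mi_and_grad(fv, mv, cfg.mi_bins, f_range, m_range)
                sim, dsim = -sim, -dsim
            elif cfg.similarity == "SSD":
                sim, dsim = ssd_and_grad(fv, mv)
            else:
                s, g = ncc_and_grad(fv, mv)
                sim, dsim = -s, -g
            gm = np.stack([
                ndimage.map_coordinates(grad_mov[a], widx, order=1, mode="nearest")
                for a in range(3)
            ], axis=1)
            # chain: d(mv)/du_a = Σ_d ∂M/∂x_d · R_da (outer rotation)
            g_samples = dsim[:, None] * (gm @ rot)  # (n, 3) in world frame
            if cfg.total_transverse_weight > 0:
                # penalize only the displacement component transverse to the
                # local gradient, and only where that direction is reliable;
                # flat regions are left to the smoothness terms
                d_tot = warped - pts
                un_s = np.einsum("ij,ij->i", d_tot, nhat_s)
                val_tt = np.sum(conf_s * (np.einsum("ij,ij->i", d_tot, d_tot)
                                          - un_s * un_s))
                sim += cfg.total_transverse_weight * val_tt / len(pts)
                gw = (2.0 * cfg.total_transverse_weight / len(pts)) * (
                    conf_s[:, None] * (d_tot - un_s[:, None] * nhat_s)
                )
                g_samples += gw @ rot
            g_dense = np.zeros_like(u)
            for a in range(3):
                np.add.at(g_dense[..., a], sel_t, g_samples[:, a])
            val = sim
            if cfg.bending_weight > 0:
                be, gbe = bending_energy_and_grad(u, lv_spacing, mask_w)
                val += cfg.bending_weight * be
                g_dense += cfg.bending_weight * gbe
            if cfg.rigidity_weight > 0 and lv_rigid is not None:
                rg, grg = rigidity_and_grad(u, lv_spacing, lv_rigid)
                val += cfg.rigidity_weight * rg
                g_dense += cfg.rigidity_weight * grg
            if cfg.displacement_weight > 0:
                nw = mask_w.sum()
                w3 = mask_w[..., None]
                du = u if u_ref is None else u - u_ref
                val += cfg.displacement_weight * float(np.sum(w3 * du * du)) / nw
                g_dense += (2.0 * cfg.displacement_weight / nw) * w3 * du
            if cfg.transverse_weight > 0:
                nw = mask_w.sum()
                wm = mask_w.astype(float)
                if cfg.transverse_highpass_mm > 0:
                    sig_hp = [cfg.transverse_highpass_mm / sp for sp in lv_spacing]
                    low = np.stack([_lowpass(u[..., c], sig_hp)
                                    for c in range(3)], axis=-1)
                    r = u - low
                else:
                    r = u
                un = np.einsum("...c,...c->...", r, nhat)
                # |r|² − conf·(r·n̂)²: transverse part where gradient is strong
                val += cfg.transverse_weight * float(
                    np.sum(wm * (np.sum(r * r, axis=-1) - conf * un * un))
                ) / nw
                g_pen = (2.0 * cfg.transverse_weight / nw) * (
                    wm[..., None] * (r - (conf * un)[..., None] * nhat)
                )
                if cfg.transverse_highpass_mm > 0:
                    g_pen = g_pen - np.stack(
                        [_lowpass(g_pen[..., c], sig_hp) for c in range(3)],
                        axis=-1)
                g_dense += g_pen
            return val, model.adjoint(g_dense).ravel()

        res = optimize.minimize(
            cost_and_grad, coef.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": lv_iters, "ftol": 1e-9, "gtol": 1e-8},
        )
        coef = res.x.reshape(coef.shape)
        trace.append({
            "stride": stride, "cost_final": float(res.fun),
            "n_iter": int(res.nit), "n_samples": int(len(pts)),
        })

    fld = model.resample_coef_field(coef, fixed.grid)
    meta = {"trace": trace, "control_spacing": cfg.control_spacing,
            "similarity": cfg.similarity, "coef": coef}
    fld.meta.update(meta)
    return fld, meta


def centerline_alignment_stage(
    fixed: ImageVolume,
    moving: ImageVolume,
    rigidity: ImageVolume,
    cfg: Optional[StageConfig] = None,
    outer_rigid: Optional[RigidTransform] = None,
) -> DisplacementField:
    """MI-driven coarse DIR with bending (10) and rigidity (20) penalties.

    The rigidity map keeps the aorta locally rigid while surrounding tissue
    deforms, implicitly registering the aortic centerlines.
    """
    cfg = cfg or VdmConfig().coarse
    fld, _ = bspline_stage(
        fixed, moving, domain=rigidity, cfg=cfg, rigidity=rigidity,
        outer=_Outer(rigid=outer_rigid),
    )
    return fld


def final_dir_stage(
    fixed: ImageVolume,
    moving: ImageVolume,
    domain: ImageVolume,
    cfg: Optional[StageConfig] = None,
    outer_rigid: Optional[RigidTransform] = None,
    prior: Optional[DisplacementField] = None,
) -> DisplacementField:
    """Finer-grid MI B-spline registration with a stronger bending term (100)."""
    cfg = cfg or VdmConfig().fine
    fld, _ = bspline_stage(
        fixed, moving, domain=domain, cfg=cfg, rigidity=None,
        outer=_Outer(rigid=outer_rigid, prior=prior),
    )
    return fld


def run_vdm(
    fixed: ImageVolume,
    moving: ImageVolume,
    fixed_mask: ImageVolume,
    moving_mask: ImageVolume,
    cfg: Optional[VdmConfig] = None,
) -> VdmResult:
    """Full VDM pipeline: clamp → rigid → centerline alignment → final DIR.

    The returned ``field`` composes the two deformable stages on the fixed
    grid (fixed-space x ↦ x + u(x) in the rigid-aligned moving frame); the
    rigid stage is reported separately in ``rigid``.  Deterministic for fixed
    inputs and configuration.
    """
    cfg = cfg or VdmConfig()
    f = clamp_negative(fixed) if cfg.clamp_hu else fixed
    m = clamp_negative(moving) if cfg.clamp_hu else moving
    rigidity = make_rigidity_map(fixed_mask, cfg.mask_dilation)

    rigid = rigid_stage(f, m, fixed_mask, moving_mask, cfg.rigid, cfg.mask_dilation)
    u_coarse = centerline_alignment_stage(f, m, rigidity, cfg.coarse, outer_rigid=rigid)
    u_fine = final_dir_stage(
        f, m, rigidity, cfg.fine, outer_rigid=rigid, prior=u_coarse
    )
    deformable = compose_fields(u_coarse, u_fine)
    # total map: x ↦ T_rigid(x + u_def(x)); stored as a displacement field
    pts = deformable.grid.meshgrid_world().reshape(-1, 3)
    warped = rigid.apply(pts + deformable.data.reshape(-1, 3))
    total = DisplacementField(
        (warped - pts).reshape(deformable.grid.shape + (3,)), deformable.grid
    )

    jac = deformable.jacobian_determinant()
    dil = rigidity.data.astype(bool)
    meta = {
        "jacobian_min_on_mask": float(jac[dil].min()),
        "rigid_translation": rigid.translation.tolist(),
        "coarse_trace": u_coarse.meta.get("trace"),
        "fine_trace": u_fine.meta.get("trace"),
    }
    total.meta.update(meta)
    return VdmResult(field=total, deformable=deformable, rigid=rigid, meta=meta)
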