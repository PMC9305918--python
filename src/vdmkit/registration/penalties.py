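"""Regularization penalties on displacement fields.

*Bending energy* — mean squared Frobenius norm of the transform's second
spatial derivatives; zero exactly for affine transforms.  Penalizes
high-frequency changes of the field and discourages folding.

*Rigidity penalty* — coefficient-weighted mean of LN² + OC² + PC² where, with
J the transform Jacobian, LN collects second derivatives (linearity), OC is
‖JᵀJ − I‖_F (orthonormality) and PC is det J − 1 (properness).  Zero exactly
for globally rigid motion.  The coefficient map is 1 on rigid tissue (the
dilated aortic mask) and 0 elsewhere.

Both are evaluated with central finite differences on the field grid; the
weight mask is zeroed on a 2-voxel border so boundary stencils never enter.
Gradient counterparts (w.r.t. the dense field) feed the B-spline optimizer.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from ..core import DisplacementField, ImageVolume

__all__ = [
    "bending_energy",
    "rigidity_penalty",
    "make_rigidity_map",
    "bending_energy_and_grad",
    "rigidity_and_grad",
]


def _d1(u: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Central first difference via roll (wrap rows are masked out by weights)."""
    return (np.roll(u, -1, axis=axis) - np.roll(u, 1, axis=axis)) / (2.0 * h)


def _d1_adj(g: np.ndarray, axis: int, h: float) -> np.ndarray:
    return (np.roll(g, 1, axis=axis) - np.roll(g, -1, axis=axis)) / (2.0 * h)


def _d2(u: np.ndarray, axis: int, h: float) -> np.ndarray:
    return (np.roll(u, -1, axis=axis) - 2.0 * u + np.roll(u, 1, axis=axis)) / (h * h)


def _interior_weight(shape: tuple[int, ...], domain: Optional[np.ndarray]) -> np.ndarray:
    w = np.ones(shape) if domain is None else domain.astype(float).copy()
    for a in range(3):
        sl = [slice(None)] * 3
        sl[a] = slice(0, 2)
        w[tuple(sl)] = 0.0
        sl[a] = slice(-2, None)
        w[tuple(sl)] = 0.0
    return w


def _second_derivs(u: np.ndarray, sp) -> list[tuple[np.ndarray, float, tuple]]:
    """All (∂²u_c/∂x_a∂x_b, multiplicity) for a (..., 3) field."""
    out = []
    for a in range(3):
        for b in range(a, 3):
            mult = 1.0 if a == b else 2.0  # symmetric off-diagonal pairs
            if a == b:
                d = _d2(u, a, sp[a])
            else:
                d = _d1(_d1(u, a, sp[a]), b, sp[b])
            out.append((d, mult, (a, b)))
    return out


def bending_energy(field: DisplacementField, domain: Optional[ImageVolume] = None) -> float:
    """Mean over the domain of ‖∂²T/∂x∂xᵀ‖²_F (T = identity + field)."""
    val, _ = bending_energy_and_grad(
        field.data, field.grid.spacing,
        None if domain is None else domain.data.astype(bool), want_grad=False,
    )
    return val


def bending_energy_and_grad(
    u: np.ndarray, spacing, domain: Optional[np.ndarray] = None, want_grad: bool = True
) -> tuple[float, Optional[np.ndarray]]:
    w = _interior_weight(u.shape[:3], domain)
    n = w.sum()
    if n == 0:
        raise ValueError("empty bending-energy domain")
    w3 = w[..., None]
    val = 0.0
    grad = np.zeros_like(u) if want_grad else None
    for d, mult, (a, b) in _second_derivs(u, spacing):
        val += mult * float(np.sum(w3 * d * d))
        if want_grad:
            g = 2.0 * mult * w3 * d
            if a == b:
                grad += _d2(g, a, spacing[a])  # self-adjoint with zero border
            else:
                grad += _d1_adj(_d1_adj(g, b, spacing[b]), a, spacing[a])
    return val / n, (grad / n if want_grad else None)


def make_rigidity_map(mask: ImageVolume, dilation: int = 5) -> ImageVolume:
    """Binary rigidity-coefficient map: the aortic mask dilated by ``dilation`` voxels.

    Dilation uses the 6-connected structuring element applied ``dilation``
    times, the morphological reading of "dilated by N voxels".
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    if dilation > 0:
        m = ndimage.binary_dilation(m, iterations=int(dilation))
    return ImageVolume(m.astype(np.uint8), mask.grid)


def _jacobian(u: np.ndarray, sp) -> np.ndarray:
    """J = I + grad u, shape (..., 3, 3) with J[c, a] = δ_ca + ∂u_c/∂x_a."""
    J = np.empty(u.shape[:3] + (3, 3))
    for c in range(3):
        for a in range(3):
            J[..., c, a] = _d1(u[..., c], a, sp[a])
        J[..., c, c] += 1.0
    return J


def rigidity_and_grad(
    u: np.ndarray, spacing, coeffs: np.ndarray, want_grad: bool = True
) -> tuple[float, Optional[np.ndarray]]:
    """Eq-style rigidity penalty (LN² + OC² + PC² weighted mean) and gradient."""
    w = _interior_weight(u.shape[:3], coeffs.astype(bool))
    n = w.sum()
    if n == 0:
        return 0.0, (np.zeros_like(u) if want_grad else None)
    w3 = w[..., None]
    grad = np.zeros_like(u) if want_grad else None

    # LN: squared second derivatives (same stencils as bending energy)
    ln_val = 0.0
    for d, mult, (a, b) in _second_derivs(u, spacing):
        ln_val += mult * float(np.sum(w3 * d * d))
        if want_grad:
            g = 2.0 * mult * w3 * d
            if a == b:
                grad += _d2(g, a, spacing[a])
            else:
                grad += _d1_adj(_d1_adj(g, b, spacing[b]), a, spacing[a])

    # OC and PC act on the Jacobian
    J = _jacobian(u, sp=spacing)
    JtJ = np.einsum("...ca,...cb->...ab", J, J)
    E = JtJ - np.eye(3)
    oc_val = float(np.sum(w * np.einsum("...ab,...ab->...", E, E)))
    # cofactor matrix: det J = Σ_a J[0,a]·C[0,a] and d(det J)/dJ = C
    C = np.empty_like(J)
    for c in range(3):
        c1, c2 = (c + 1) % 3, (c + 2) % 3
        for a in range(3):
            a1, a2 = (a + 1) % 3, (a + 2) % 3
            C[..., c, a] = (J[..., c1, a1] * J[..., c2, a2]
                            - J[..., c1, a2] * J[..., c2, a1])
    detJ = np.einsum("...a,...a->...", J[..., 0, :], C[..., 0, :])
    pc_val = float(np.sum(w * (detJ - 1.0) ** 2))

    if want_grad:
        # d(OC²)/dJ = 4 J E ;  d(PC²)/dJ = 2 (det J − 1) · C
        gJ = 4.0 * w[..., None, None] * np.einsum("...ca,...ab->...cb", J, E)
        gJ += (2.0 * w * (detJ - 1.0))[..., None, None] * C
        # chain through the central-difference Jacobian: J[c,a] = δ + D_a u_c
        for c in range(3):
            for a in range(3):
                grad[..., c] += _d1_adj(gJ[..., c, a], a, spacing[a])

    val = (ln_val + oc_val + pc_val) / n
    return val, (grad / n if want_grad else None)


def rigidity_penalty(field: DisplacementField, coeffs: ImageVolume) -> float:
    """Coefficient-weighted mean of LN² + OC² + PC² over the rigidity map."""
    if coeffs.data.shape != field.grid.shape:
        raise ValueError("rigidity map grid does not match field grid")
    val, _ = rigidity_and_grad(
        field.data, field.grid.spacing, coeffs.data.astype(bool), want_grad=False
    )
    return val
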