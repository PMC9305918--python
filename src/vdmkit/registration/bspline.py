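"""Cubic B-spline free-form deformation on a regular control grid.

The displacement is u(x) = Σ_k c_k β³((x − x_k)/δ) with separable cubic
B-spline basis functions on control points spaced δ mm apart.  On a regular
sample grid the evaluation is a chain of three small dense matrix products
(one per axis), and the adjoint (needed for cost gradients) is the same chain
with transposed matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import DisplacementField, ImageGrid

__all__ = ["bspline3", "bspline3_deriv", "BSplineModel"]


def bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2, unit integral and partition of unity."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = 2.0 / 3.0 - t[m1] ** 2 + 0.5 * t[m1] ** 3
    out[m2] = ((2.0 - t[m2]) ** 3) / 6.0
    return out


def bspline3_deriv(t: np.ndarray) -> np.ndarray:
    ta = np.abs(np.asarray(t, dtype=float))
    sgn = np.sign(t)
    out = np.zeros_like(ta)
    m1 = ta < 1
    m2 = (ta >= 1) & (ta < 2)
    out[m1] = -2.0 * ta[m1] + 1.5 * ta[m1] ** 2
    out[m2] = -0.5 * (2.0 - ta[m2]) ** 2
    return out * sgn


@dataclass
class BSplineModel:
    """Maps control-point coefficients to dense displacements on a sample grid."""

    grid: ImageGrid          # sample grid (level grid)
    spacing: float           # control-point spacing, mm (isotropic)
    extent: tuple = None     # optional ((x0,x1),(y0,y1),(z0,z1)) the controls must span
    basis: tuple[np.ndarray, np.ndarray, np.ndarray] = None
    ctrl_shape: tuple[int, int, int] = None
    ctrl_origin: tuple[float, float, float] = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("control spacing must be > 0")
        basis = []
        ctrl_shape = []
        ctrl_origin = []
        for a in range(3):
            if self.extent is not None:
                x0, x1 = self.extent[a]
            else:
                x0 = self.grid.origin[a]
                x1 = x0 + (self.grid.shape[a] - 1) * self.grid.spacing[a]
            # control points must cover [x0, x1] with a one-point margin for
            # the cubic support
            c0 = x0 - 2.0 * self.spacing
            nc = int(np.ceil((x1 - c0) / self.spacing)) + 3
            xs = self.grid.origin[a] + np.arange(self.grid.shape[a]) * self.grid.spacing[a]
            cx = c0 + np.arange(nc) * self.spacing
            B = bspline3((xs[:, None] - cx[None, :]) / self.spacing)
            basis.append(B)
            ctrl_shape.append(nc)
            ctrl_origin.append(c0)
        self.basis = tuple(basis)
        self.ctrl_shape = tuple(ctrl_shape)
        self.ctrl_origin = tuple(ctrl_origin)

    @property
    def n_params(self) -> int:
        return int(np.prod(self.ctrl_shape)) * 3

    def zero_coefficients(self) -> np.ndarray:
        return np.zeros(self.ctrl_shape + (3,))

    def dense(self, coef: np.ndarray) -> np.ndarray:
        """Displacement (nx, ny, nz, 3) on the sample grid."""
        Bx, By, Bz = self.basis
        t = np.einsum("Ii,ijkc->Ijkc", Bx, coef, optimize=True)
        t = np.einsum("Jj,Ijkc->IJkc", By, t, optimize=True)
        t = np.einsum("Kk,IJkc->IJKc", Bz, t, optimize=True)
        return t

    def adjoint(self, g_dense: np.ndarray) -> np.ndarray:
        """Chain a gradient w.r.t. the dense field back to the coefficients."""
        Bx, By, Bz = self.basis
        t = np.einsum("Kk,IJKc->IJkc", Bz, g_dense, optimize=True)
        t = np.einsum("Jj,IJkc->Ijkc", By, t, optimize=True)
        t = np.einsum("Ii,Ijkc->ijkc", Bx, t, optimize=True)
        return t

    def resample_coef_field(self, coef: np.ndarray, grid: ImageGrid) -> DisplacementField:
        """Evaluate the spline analytically on an arbitrary grid."""
        out = np.zeros(grid.shape + (3,))
        Bs = []
        for a in range(3):
            xs = grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a]
            cx = self.ctrl_origin[a] + np.arange(self.ctrl_shape[a]) * self.spacing
            Bs.append(bspline3((xs[:, None] - cx[None, :]) / self.spacing))
        t = np.einsum("Ii,ijkc->Ijkc", Bs[0], coef, optimize=True)
        t = np.einsum("Jj,Ijkc->IJkc", Bs[1], t, optimize=True)
        t = np.einsum("Kk,IJkc->IJKc", Bs[2], t, optimize=True)
        return DisplacementField(t, grid)
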