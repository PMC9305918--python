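"""Core spatial containers: image grids, scalar volumes, displacement fields, meshes.

All public coordinates are world-space millimeters.  Voxel indices appear only
inside conversion helpers; arrays are indexed ``[ix, iy, iz]`` so that axis
order matches the (x, y, z) world axes under an identity direction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3D sampling grid: shape, spacing (mm), origin (mm), direction."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", tuple(float(d) for d in self.direction))

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def extent(self) -> np.ndarray:
        """Physical size along each axis (mm), from first to last voxel center."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (…, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - np.asarray(self.origin)) @ self.direction_matrix  # D^T on rows
        return rel / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction_matrix.T

    def axes_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinate of voxel centers along each axis (identity direction)."""
        o = np.asarray(self.origin)
        return tuple(o[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3))

    def meshgrid_world(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of all voxel centers."""
        ii = np.meshgrid(*(np.arange(n, dtype=float) for n in self.shape), indexing="ij")
        idx = np.stack(ii, axis=-1).reshape(-1, 3)
        return self.index_to_world(idx).reshape(self.shape + (3,))

    def contains_points(self, points: np.ndarray, margin_vox: float = 0.0) -> np.ndarray:
        idx = self.world_to_index(points)
        lo = -0.5 + margin_vox
        hi = np.asarray(self.shape) - 0.5 - margin_vox
        return np.all((idx >= lo) & (idx <= hi), axis=-1)


@dataclass
class ImageVolume:
    """Scalar 3D image with grid metadata (HU or arbitrary units)."""

    data: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.grid)

    def astype(self, dtype) -> "ImageVolume":
        return ImageVolume(self.data.astype(dtype), self.grid)

    def sample(self, points: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate at world points (N, 3)."""
        idx = self.grid.world_to_index(points)
        return ndimage.map_coordinates(
            self.data.astype(float, copy=False), idx.T, order=order, mode="constant", cval=cval
        )


@dataclass
class DisplacementField:
    """Dense displacement u on a grid; maps fixed-space x to moving-space x + u(x).

    ``data`` has shape (nx, ny, nz, 3), in millimeters, world axes.
    """

    data: np.ndarray
    grid: ImageGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape + (3,):
            raise ValueError(
                f"field shape {self.data.shape} incompatible with grid {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "DisplacementField":
        return cls(np.zeros(grid.shape + (3,)), grid)

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolated displacement vectors at world points (N, 3)."""
        idx = self.grid.world_to_index(points).T
        out = np.empty((idx.shape[1], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.data[..., c], idx, order=order, mode="nearest"
            )
        return out

    def transform_points(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self.sample(pts, order=order)

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + grad u) by central differences on the field grid."""
        sp = self.grid.spacing
        J = np.zeros(self.grid.shape + (3, 3))
        for c in range(3):
            for a in range(3):
                J[..., c, a] = np.gradient(self.data[..., c], sp[a], axis=a)
            J[..., c, c] += 1.0
        return np.linalg.det(J)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Field of x ↦ outer(inner(x)), sampled on the inner field's grid."""
    pts = inner.grid.meshgrid_world().reshape(-1, 3)
    warped = pts + inner.data.reshape(-1, 3)
    total = outer.sample(warped, order=1) + inner.data.reshape(-1, 3)
    return DisplacementField(total.reshape(inner.grid.shape + (3,)), inner.grid)


def invert_field(
    fld: DisplacementField,
    grid: Optional[ImageGrid] = None,
    n_iter: int = 30,
    tol: float = 1e-3,
) -> DisplacementField:
    """Fixed-point inverse: find v with v(y) = -u(y + v(y)).

    Converges for smooth fields without folding (Jacobian determinant > 0).
    The inverse is evaluated on ``grid`` (default: the field's own grid).
    """
    grid = grid or fld.grid
    pts = grid.meshgrid_world().reshape(-1, 3)
    v = -fld.sample(pts, order=1)
    for _ in range(n_iter):
        v_new = -fld.sample(pts + v, order=1)
        err = np.max(np.abs(v_new - v))
        v = v_new
        if err < tol:
            break
    return DisplacementField(v.reshape(grid.shape + (3,)), grid)


@dataclass
class SurfaceMesh:
    """Indexed triangle mesh in world millimeters with stable vertex order.

    Deformed copies of a mesh keep identical vertex count and index order, so
    vertex-wise correspondence v_i ↔ ṽ_i holds across deformations.
    ``attrs`` carries per-vertex arrays (e.g. the generating (s, θ) parameters
    or analytic displacements) that travel with the mesh.
    """

    vertices: np.ndarray
    faces: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3) triangles")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray, **extra_attrs) -> "SurfaceMesh":
        """Same connectivity and attrs, new vertex positions (correspondence kept)."""
        attrs = dict(self.attrs)
        attrs.update(extra_attrs)
        return SurfaceMesh(np.asarray(vertices, dtype=float), self.faces.copy(), attrs)

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(cross, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("degenerate (zero-area) face encountered")
        return cross / norms

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def bounds(self) -> np.ndarray:
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass
class CenterlineCurve:
    """Ordered polyline through the lumen center, arc-length parameterized."""

    points: np.ndarray
    arc_length: np.ndarray = None
    tangents: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs >= 2 points of shape (N, 3)")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline points must be strictly ordered (no repeats)")
        if self.arc_length is None:
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=float)
            if np.any(np.diff(self.arc_length) <= 0):
                raise ValueError("arc_length must be strictly increasing")
        if self.tangents is None:
            t = np.gradient(self.points, self.arc_length, axis=0)
            self.tangents = t / np.linalg.norm(t, axis=1, keepdims=True)
        else:
            self.tangents = np.asarray(self.tangents, dtype=float)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1] - self.arc_length[0])

    def point_at(self, s) -> np.ndarray:
        """Linear interpolation of position at arc length s (scalar or array)."""
        s = np.asarray(s, dtype=float)
        out = np.stack(
            [np.interp(s, self.arc_length, self.points[:, c]) for c in range(3)], axis=-1
        )
        return out

    def tangent_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        t = np.stack(
            [np.interp(s, self.arc_length, self.tangents[:, c]) for c in range(3)], axis=-1
        )
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def resample(self, step: float) -> "CenterlineCurve":
        n = max(2, int(np.ceil(self.length / step)) + 1)
        s = np.linspace(self.arc_length[0], self.arc_length[-1], n)
        return CenterlineCurve(self.point_at(s))
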