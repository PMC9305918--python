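"""Mesh-based aortic growth metrics.

Two metrics quantify wall deformation between corresponding surface meshes
with identical connectivity:

* **Area ratio (AR)** — per triangular face, the deformed-to-fixed face area
  ratio S(f̂)/S(f).  AR = 1 means no areal change; a fusiform bulge raises AR
  circumferentially.
* **Deformation in normal direction (DiN)** — per vertex, the signed
  projection of the displacement v̂ᵢ − vᵢ onto the outward unit normal of the
  fixed surface, in mm.  Outward growth is positive.

Error summaries restrict to the *deformed region* — elements whose
ground-truth deformation magnitude exceeds a small threshold — so that the
vast undeformed portion of the surface does not dilute the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SurfaceMesh

__all__ = [
    "GrowthMetrics",
    "ErrorSummary",
    "area_ratio",
    "vertex_normals",
    "din",
    "interpolate_face_to_vertex",
    "compute_growth_metrics",
    "absolute_error",
    "relative_error",
]


@dataclass
class GrowthMetrics:
    """Per-element growth measurements for one fixed/deformed mesh pair."""

    ar: np.ndarray  # per-face, dimensionless
    din: np.ndarray  # per-vertex, mm, outward positive
    ar_on_vertices: np.ndarray  # per-vertex area-weighted interpolation of ar


@dataclass
class ErrorSummary:
    """Summary statistics of absolute element-wise error within a region."""

    p99: float
    p95: float
    median: float
    mean: float
    std: float
    threshold: float
    n_elements: int


def _check_correspondence(fixed: SurfaceMesh, deformed: SurfaceMesh) -> None:
    if fixed.n_vertices != deformed.n_vertices or not np.array_equal(
        fixed.faces, deformed.faces
    ):
        raise ValueError("meshes must share vertex count and identical face connectivity")


def area_ratio(fixed: SurfaceMesh, deformed: SurfaceMesh) -> np.ndarray:
    """Per-face deformed/fixed triangle area ratio."""
    _check_correspondence(fixed, deformed)
    a_fixed = fixed.face_areas()
    bad = np.flatnonzero(a_fixed <= 0)
    if bad.size:
        raise ValueError(f"zero-area fixed faces: {bad[:10].tolist()}")
    return deformed.face_areas() / a_fixed


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Outward per-vertex unit normals, angle-weighted over incident faces.

    Angle weighting makes the normal independent of how the local surface is
    triangulated, unlike simple face averaging.
    """
    tri = mesh.vertices[mesh.faces]
    fn = mesh.face_normals()
    normals = np.zeros_like(mesh.vertices)
    counts = np.zeros(mesh.n_vertices)
    for corner in range(3):
        a = tri[:, corner]
        b = tri[:, (corner + 1) % 3]
        c = tri[:, (corner + 2) % 3]
        u = b - a
        v = c - a
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(normals, mesh.faces[:, corner], ang[:, None] * fn)
        np.add.at(counts, mesh.faces[:, corner], 1)
    if np.any(counts == 0):
        raise ValueError("isolated vertices present (no incident faces)")
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate vertex normal (incident normals cancel)")
    return normals / norms


def din(fixed: SurfaceMesh, deformed: SurfaceMesh) -> np.ndarray:
    """Signed per-vertex deformation along the fixed-surface outward normal (mm).

    Positive values indicate outward growth; tangential sliding projects to
    (near) zero.
    """
    _check_correspondence(fixed, deformed)
    n = vertex_normals(fixed)
    return np.einsum("ij,ij->i", n, deformed.vertices - fixed.vertices)


def interpolate_face_to_vertex(face_values: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted mean of incident face values at each vertex."""
    face_values = np.asarray(face_values, dtype=float)
    if face_values.shape[0] != mesh.n_faces:
        raise ValueError("need one value per face")
    areas = mesh.face_areas()
    acc = np.zeros(mesh.n_vertices)
    wsum = np.zeros(mesh.n_vertices)
    for corner in range(3):
        np.add.at(acc, mesh.faces[:, corner], areas * face_values)
        np.add.at(wsum, mesh.faces[:, corner], areas)
    return acc / wsum


def compute_growth_metrics(fixed: SurfaceMesh, deformed: SurfaceMesh) -> GrowthMetrics:
    ar = area_ratio(fixed, deformed)
    return GrowthMetrics(
        ar=ar,
        din=din(fixed, deformed),
        ar_on_vertices=interpolate_face_to_vertex(ar, fixed),
    )


def _region_masks(
    gt: GrowthMetrics, fixed: SurfaceMesh, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deformed-region membership: vertices by |GT DiN|, faces by incident vertices."""
    vert_mask = np.abs(gt.din) > threshold
    face_mask = vert_mask[fixed.faces].any(axis=1)
    return face_mask, vert_mask


def _summary(err: np.ndarray, threshold: float) -> ErrorSummary:
    if err.size == 0:
        raise ValueError("deformed region is empty at this threshold")
    return ErrorSummary(
        p99=float(np.percentile(err, 99)),
        p95=float(np.percentile(err, 95)),
        median=float(np.median(err)),
        mean=float(np.mean(err)),
        std=float(np.std(err)),
        threshold=threshold,
        n_elements=int(err.size),
    )


def absolute_error(
    gt: GrowthMetrics,
    measured: GrowthMetrics,
    fixed: SurfaceMesh,
    threshold: float = 1e-3,
) -> tuple[ErrorSummary, ErrorSummary]:
    """(AR, DiN) summaries of |GT − measured| within the deformed region.

    The region contains vertices whose ground-truth |DiN| exceeds
    ``threshold`` mm, and faces touching such a vertex.
    """
    face_mask, vert_mask = _region_masks(gt, fixed, threshold)
    ar_err = np.abs(gt.ar - measured.ar)[face_mask]
    din_err = np.abs(gt.din - measured.din)[vert_mask]
    return _summary(ar_err, threshold), _summary(din_err, threshold)


def relative_error(
    err_perturbed: float, err_original: float, gt_p99: float
) -> float:
    """Perturbation-attributable error, percent of the GT 99th percentile."""
    if gt_p99 == 0:
        raise ValueError("GT 99th percentile is zero; relative error undefined")
    return 100.0 * (err_perturbed - err_original) / gt_p99


def gt_percentile(
    gt: GrowthMetrics, fixed: SurfaceMesh, threshold: float = 0.01, q: float = 99.0
) -> tuple[float, float]:
    """(AR, |DiN|) percentiles of the GT deformation within its region.

    AR is summarized on its raw scale (1 = no change), matching how the
    deformation-magnitude distributions are reported; DiN as |DiN| in mm.
    These are the denominators of the perturbation relative errors.
    """
    face_mask, vert_mask = _region_masks(gt, fixed, threshold)
    if not vert_mask.any():
        raise ValueError("deformed region is empty")
    ar_p = float(np.percentile(gt.ar[face_mask], q))
    din_p = float(np.percentile(np.abs(gt.din[vert_mask]), q))
    return ar_p, din_p
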