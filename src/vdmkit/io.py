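"""Readers and writers for volumes (NIfTI/MetaImage), meshes (PLY/STL),
displacement fields, and YAML experiment configuration.

All on-disk volumes use the usual medical-imaging conventions (SimpleITK
handles header parsing); in memory everything is world-space millimeters with
arrays indexed ``[ix, iy, iz]``.  Vertex order is preserved through PLY round
trips because mesh correspondence depends on it; STL cannot preserve it
(facet soup with duplicated vertices), which ``write_mesh`` warns about.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import SimpleITK as sitk
import trimesh
import yaml

from .core import DisplacementField, ImageGrid, ImageVolume, SurfaceMesh

__all__ = [
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_field",
    "write_field",
    "load_config",
    "save_config",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(f"unsupported volume format: {path.name} "
                         f"(expected one of {_VOLUME_SUFFIXES})")


def _sitk_to_grid(img: sitk.Image) -> ImageGrid:
    return ImageGrid(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def read_volume(path: Union[str, Path]) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume."""
    path = Path(path)
    _check_volume_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValueError(f"malformed volume {path.name}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return ImageVolume(data, _sitk_to_grid(img))


def write_volume(vol: ImageVolume, path: Union[str, Path]) -> None:
    """Write a volume; float32 for images, uint8 for masks survive losslessly."""
    path = Path(path)
    _check_volume_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.grid.spacing)
    img.SetOrigin(vol.grid.origin)
    img.SetDirection(vol.grid.direction)
    sitk.WriteImage(img, str(path))


def read_field(path: Union[str, Path]) -> DisplacementField:
    """Read a 3-component vector volume as a fixed→moving displacement field."""
    path = Path(path)
    _check_volume_path(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # [z, y, x, 3]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{path.name} is not a 3-component vector volume")
    data = np.ascontiguousarray(arr.transpose(2, 1, 0, 3)).astype(float)
    return DisplacementField(data, _sitk_to_grid(img))


def write_field(field: DisplacementField, path: Union[str, Path]) -> None:
    path = Path(path)
    _check_volume_path(path)
    arr = np.ascontiguousarray(field.data.transpose(2, 1, 0, 3).astype(np.float32))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(field.grid.spacing)
    img.SetOrigin(field.grid.origin)
    img.SetDirection(field.grid.direction)
    sitk.WriteImage(img, str(path))


def read_mesh(path: Union[str, Path]) -> SurfaceMesh:
    """Read a PLY/STL triangle mesh; PLY scalar vertex properties become attrs."""
    path = Path(path)
    tm = trimesh.load(str(path), process=False, force="mesh")
    if tm.faces.shape[1] != 3:
        raise ValueError("only triangle meshes are supported")
    mesh = SurfaceMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))
    # recover per-vertex scalar fields stored as extra PLY properties
    md = getattr(tm, "metadata", {}) or {}
    ply_raw = md.get("_ply_raw", {})
    vert_block = ply_raw.get("vertex", {}) if isinstance(ply_raw, dict) else {}
    vert_data = vert_block.get("data") if isinstance(vert_block, dict) else None
    if vert_data is not None and getattr(vert_data, "dtype", None) is not None:
        for name in vert_data.dtype.names or ():
            if name not in ("x", "y", "z", "nx", "ny", "nz",
                            "red", "green", "blue", "alpha"):
                mesh.attrs[name] = np.asarray(vert_data[name], dtype=float)
    return mesh


def write_mesh(
    mesh: SurfaceMesh,
    path: Union[str, Path],
    fields: Optional[dict] = None,
) -> None:
    """Write PLY (vertex order preserved, optional per-vertex scalar fields)
    or STL (correspondence lost on re-read; a warning says so)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        if fields:
            raise ValueError("STL cannot carry per-vertex fields; use PLY")
        warnings.warn(
            "STL stores independent facets; vertex order (and with it mesh "
            "correspondence) will not survive a read back", stacklevel=2
        )
        mesh.to_trimesh().export(str(path))
        return
    if suffix != ".ply":
        raise ValueError(f"unsupported mesh format {suffix}; use .ply or .stl")
    _write_ply(mesh, path, fields or {})


def _write_ply(mesh: SurfaceMesh, path: Path, fields: dict) -> None:
    """Binary little-endian PLY with float64 vertices and extra properties."""
    n_v, n_f = mesh.n_vertices, mesh.n_faces
    names = list(fields)
    for name in names:
        if len(fields[name]) != n_v:
            raise ValueError(f"field {name!r} length != vertex count")
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {n_v}",
              "property double x", "property double y", "property double z"]
    header += [f"property double {n}" for n in names]
    header += [f"element face {n_f}", "property list uchar int vertex_indices",
               "end_header"]
    vert_dtype = np.dtype([(c, "<f8") for c in ("x", "y", "z")]
                          + [(n, "<f8") for n in names])
    verts = np.empty(n_v, dtype=vert_dtype)
    verts["x"], verts["y"], verts["z"] = mesh.vertices.T
    for n in names:
        verts[n] = np.asarray(fields[n], dtype=float)
    face_dtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
    faces = np.empty(n_f, dtype=face_dtype)
    faces["n"] = 3
    faces["idx"] = mesh.faces.astype("<i4")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(verts.tobytes())
        fh.write(faces.tobytes())


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
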