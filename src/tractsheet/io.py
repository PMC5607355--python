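"""Readers and writers for every on-disk format the toolkit touches.

Volumes are NIfTI-1 (.nii/.nii.gz): tensor volumes as 4D files with 6
components in the canonical lower-triangle order (Dxx, Dxy, Dxz, Dyy, Dyz,
Dzz), or the 5D (X, Y, Z, 1, 6) symmetric-matrix dialect.  Streamlines are
TCK or TRK (auto-detected; points always surfaced in world mm).  Medial
surfaces are legacy-VTK ASCII polydata with "radius" and "normal" point-data
arrays.  Cohort tables are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .skeleton import MedialSurface
from .types import (
    BinaryMask,
    CohortTable,
    FormatError,
    ScalarVolume,
    TensorVolume,
    ValidationError,
)


# ---------------------------------------------------------------- volumes

def read_tensor_volume(path) -> TensorVolume:
    """Read a 6-component tensor NIfTI (4D, or the 5D symmetric-matrix dialect)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 5:
        if data.shape[3] == 1 and data.shape[4] == 6:
            data = data[:, :, :, 0, :]
        else:
            raise FormatError(
                f"5D tensor file must be (X, Y, Z, 1, 6), got {data.shape}")
    if data.ndim != 4 or data.shape[-1] != 6:
        raise FormatError(
            f"tensor file must have 6 components in the 4th dimension, got {data.shape}")
    return TensorVolume(tensors=data, affine=np.asarray(img.affine))


def write_tensor_volume(tv: TensorVolume, path) -> None:
    nib.save(nib.Nifti1Image(tv.tensors.astype(np.float64), tv.affine), str(path))


def read_scalar_volume(path) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D scalar volume, got shape {data.shape}")
    return ScalarVolume(values=data, affine=np.asarray(img.affine))


def write_scalar_volume(sv: ScalarVolume, path) -> None:
    nib.save(nib.Nifti1Image(sv.values.astype(np.float64), sv.affine), str(path))


def read_mask(path) -> BinaryMask:
    sv = read_scalar_volume(path)
    return BinaryMask(values=sv.values, affine=sv.affine)  # binarized at > 0.5


def write_mask(mask: BinaryMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine), str(path))


# ------------------------------------------------------------ tractograms

def read_tractogram(path):
    """Read TCK or TRK streamlines into world mm (RAS+)."""
    from .types import Tractogram

    path = str(path)
    try:
        tf = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises assorted header errors
        raise FormatError(f"cannot read tractogram {path!r}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    return Tractogram(streamlines=streamlines,
                      provenance={"source": path, "format": type(tf).__name__})


def write_tractogram(tg, path, affine: np.ndarray | None = None,
                     dims=None) -> None:
    """Write TCK or TRK by extension; TRK needs a reference grid (affine+dims)."""
    path = str(path)
    t = nib.streamlines.Tractogram(list(tg.streamlines), affine_to_rasmm=np.eye(4))
    if path.endswith(".tck"):
        nib.streamlines.save(t, path)
    elif path.endswith(".trk"):
        if affine is None:
            affine = np.asarray(tg.provenance.get("grid_affine", np.eye(4)))
        if dims is None:
            dims = tuple(tg.provenance.get("grid_dims", (1, 1, 1)))
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: np.asarray(affine),
            nib.streamlines.trk.Field.VOXEL_SIZES:
                np.linalg.norm(np.asarray(affine)[:3, :3], axis=0),
            nib.streamlines.trk.Field.DIMENSIONS: np.asarray(dims),
        }
        nib.streamlines.save(t, path, header=header)
    else:
        raise FormatError(f"unsupported tractogram extension: {path!r}")


# ------------------------------------------------------------ VTK meshes

def write_mesh(surface: MedialSurface, path) -> None:
    """Write legacy-VTK ASCII polydata with radius and normal point data."""
    v = surface.vertices
    t = surface.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1)
    bad = np.flatnonzero(areas < 1e-12)
    if bad.size:
        raise ValidationError(f"degenerate (zero-area) triangles at indices {bad.tolist()}")
    lines = [
        "# vtk DataFile Version 3.0",
        "tractsheet medial surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in v]
    lines.append(f"POLYGONS {len(t)} {4 * len(t)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in t]
    lines += [
        f"POINT_DATA {len(v)}",
        "SCALARS radius double 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{r:.9g}" for r in surface.radius]
    lines.append("NORMALS normal double")
    lines += [" ".join(f"{x:.9g}" for x in n) for n in surface.normals]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh(path) -> MedialSurface:
    """Read a legacy-VTK ASCII polydata written by :func:`write_mesh`."""
    tokens = Path(path).read_text().split("\n")
    tokens = [ln for ln in tokens if ln.strip()]

    def find(prefix: str) -> int:
        for i, ln in enumerate(tokens):
            if ln.startswith(prefix):
                return i
        raise FormatError(f"missing {prefix!r} section in {path}")

    try:
        ip = find("POINTS")
        npts = int(tokens[ip].split()[1])
        verts = np.array([[float(x) for x in tokens[ip + 1 + i].split()]
                          for i in range(npts)])
        ig = find("POLYGONS")
        ntri = int(tokens[ig].split()[1])
        tris = np.array([[int(x) for x in tokens[ig + 1 + i].split()[1:]]
                         for i in range(ntri)])
        ir = find("SCALARS radius")
        radius = np.array([float(tokens[ir + 2 + i]) for i in range(npts)])
        inn = find("NORMALS")
        normals = np.array([[float(x) for x in tokens[inn + 1 + i].split()]
                            for i in range(npts)])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed VTK polydata {path!r}: {exc}") from exc
    return MedialSurface(vertices=verts, triangles=tris, normals=normals, radius=radius)


# -------------------------------------------------------------- cohort CSV

def read_cohort(path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.table.to_csv(path, index=False)


# ------------------------------------------------------------- provenance

def write_provenance(out_path, params: dict, seed: int | None = None) -> None:
    """Write a <output>.provenance.json next to an output file."""
    rec = {"output": str(out_path), "parameters": params}
    if seed is not None:
        rec["seed"] = seed
    p = Path(str(out_path) + ".provenance.json")
    p.write_text(json.dumps(rec, indent=2, default=str) + "\n")


__all__ = [
    "read_tensor_volume", "write_tensor_volume",
    "read_scalar_volume", "write_scalar_volume",
    "read_mask", "write_mask",
    "read_tractogram", "write_tractogram",
    "write_mesh", "read_mesh",
    "read_cohort", "write_cohort",
    "write_provenance",
]
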