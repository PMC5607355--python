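"""Core domain types shared by every pipeline stage.

Conventions
-----------
* Voxel indexing is 0-based; voxel centers sit at integer indices and the
  4x4 affine maps voxel indices to world coordinates in mm (NIfTI convention).
* Diffusion tensors are stored as the 6 unique components in lower-triangle
  row order ``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)``, units mm^2/s.
* Streamline points are always world mm, whatever the on-disk convention was.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TractsheetError(Exception):
    """Base class for all package errors."""


class FormatError(TractsheetError):
    """A file's header or payload contradicts the declared format."""


class ValidationError(TractsheetError):
    """An in-memory object violates a type invariant or precondition."""


class GeometryError(TractsheetError):
    """Input geometry is unsuited to the medial-surface model (e.g. tubular)."""


class MisalignmentError(TractsheetError):
    """A volume and a skeleton do not occupy a common space."""


# lower-triangle row order; index pairs into the full 3x3 matrix
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_TRI_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine is non-invertible (singular 3x3 block)")
    return affine


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to world mm through the affine."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world-mm points (..., 3) to (fractional) voxel indices."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def sym6_to_mat(six: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique components to full symmetric (..., 3, 3)."""
    six = np.asarray(six, dtype=float)
    out = np.empty(six.shape[:-1] + (3, 3), dtype=float)
    for c, (i, j) in enumerate(_TRI_IDX):
        out[..., i, j] = six[..., c]
        out[..., j, i] = six[..., c]
    return out


def mat_to_sym6(mat: np.ndarray) -> np.ndarray:
    """Collapse full symmetric (..., 3, 3) to (..., 6) unique components."""
    mat = np.asarray(mat, dtype=float)
    out = np.empty(mat.shape[:-2] + (6,), dtype=float)
    for c, (i, j) in enumerate(_TRI_IDX):
        out[..., c] = mat[..., i, j]
    return out


@dataclass
class TensorVolume:
    """A 3D grid of symmetric diffusion tensors with a voxel-to-world affine.

    ``tensors`` has shape ``dims + (6,)`` in the canonical component order.
    All-zero tensors mark background voxels.
    """

    tensors: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[-1] != 6:
            raise ValidationError(
                f"tensor array must be (X, Y, Z, 6), got {self.tensors.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def matrices(self) -> np.ndarray:
        """Per-voxel full symmetric 3x3 tensors, shape dims + (3, 3)."""
        return sym6_to_mat(self.tensors)

    def background(self) -> np.ndarray:
        """Boolean mask of all-zero (background) voxels."""
        return ~np.any(self.tensors != 0.0, axis=-1)


@dataclass
class ScalarVolume:
    """One real value per voxel on the same kind of grid as TensorVolume."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError(f"scalar volume must be 3D, got {self.values.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class BinaryMask:
    """Boolean voxel mask; binarized as value > 0.5 on load."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0.5
        if self.values.ndim != 3:
            raise ValidationError(f"mask must be 3D, got {self.values.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def count(self) -> int:
        return int(self.values.sum())

    def same_grid(self, other) -> bool:
        return self.dims == tuple(other.dims) and np.allclose(self.affine, other.affine)


@dataclass
class Tractogram:
    """Streamline polylines in world mm plus a provenance record."""

    streamlines: list[np.ndarray] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = []
        for s in self.streamlines:
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValidationError(f"streamline must be (N, 3), got {s.shape}")
            if s.shape[0] < 2:
                raise ValidationError("streamline must have >= 2 points")
            if np.any(np.all(np.diff(s, axis=0) == 0.0, axis=1)):
                raise ValidationError("consecutive streamline points must be distinct")
            cleaned.append(s)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class CohortTable:
    """Subject covariates: id, gestational age at birth and post-menstrual
    age at scan (weeks), and the path to each subject's tensor volume."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "GA_birth", "PMA_scan")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        ga = df["GA_birth"].to_numpy(float)
        pma = df["PMA_scan"].to_numpy(float)
        if np.any(ga <= 0) or np.any(pma <= 0):
            raise ValidationError("GA and PMA must be positive")
        if np.any(ga >= pma):
            bad = df.loc[ga >= pma, "subject_id"].tolist()
            raise ValidationError(f"GA at birth must precede PMA at scan: {bad}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].astype(str).tolist()


@dataclass
class Histogram:
    """A normalized histogram: increasing bin edges and per-bin probabilities."""

    bin_edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.bin_edges) - 1:
            raise ValidationError("need len(probs) == len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.probs < 0):
            raise ValidationError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"probabilities must sum to 1, got {self.probs.sum()}")
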