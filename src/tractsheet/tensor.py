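"""Eigen-analysis of diffusion tensors and the scalar DTI metrics.

FA, MD, AD and RD are the standard rotational invariants of the diffusion
tensor: with eigenvalues l1 >= l2 >= l3 (mm^2/s),

    MD = (l1 + l2 + l3) / 3
    AD = l1
    RD = (l2 + l3) / 2
    FA = sqrt(3/2) * ||l - MD|| / ||l||

Tensor averaging for the mean-value projection strategy is provided in both
Euclidean and log-Euclidean space; log-Euclidean is the default because it
avoids the eigenvalue-swelling artifact and keeps the mean positive-definite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ScalarVolume, TensorVolume, ValidationError, mat_to_sym6, sym6_to_mat

METRICS = ("FA", "MD", "AD", "RD")


@dataclass
class EigenSystem:
    """Eigenvalues (descending) and matching unit eigenvectors of a tensor."""

    eigenvalues: np.ndarray  # (3,), l1 >= l2 >= l3
    eigenvectors: np.ndarray  # (3, 3), rows are e1, e2, e3

    def reconstruct(self) -> np.ndarray:
        """Sum of li * ei ei^T — recovers the original tensor."""
        return (self.eigenvectors.T * self.eigenvalues) @ self.eigenvectors


def eigensystem(tensor: np.ndarray) -> EigenSystem:
    """Eigen-decompose a symmetric 3x3 tensor, eigenvalues descending.

    Eigenvector signs are canonicalized (largest-magnitude component made
    positive) so repeated runs produce identical output.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise ValidationError(f"tensor must be 3x3, got {tensor.shape}")
    if not np.allclose(tensor, tensor.T, atol=1e-9):
        raise ValidationError("tensor is not symmetric")
    w, v = np.linalg.eigh(tensor)
    order = np.argsort(w)[::-1]
    w = w[order]
    vecs = v[:, order].T  # rows
    for i in range(3):
        k = np.argmax(np.abs(vecs[i]))
        if vecs[i, k] < 0:
            vecs[i] = -vecs[i]
    return EigenSystem(eigenvalues=w, eigenvectors=vecs)


def _fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """FA from eigenvalues along the last axis; 0 where all eigenvalues are 0."""
    lam = np.asarray(lam, dtype=float)
    norm2 = np.sum(lam * lam, axis=-1)
    m = np.mean(lam, axis=-1, keepdims=True)
    dev2 = np.sum((lam - m) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(1.5 * dev2 / norm2)
    return np.where(norm2 > 0, out, 0.0)


def fa(es: EigenSystem) -> float:
    """Fractional anisotropy in [0, 1]; 0 for a zero tensor by convention."""
    lam = es.eigenvalues
    if lam[0] < 0:
        warnings.warn("negative leading eigenvalue; FA computed on values as-is",
                      stacklevel=2)
    return float(_fa_from_eigenvalues(lam))


def md(es: EigenSystem) -> float:
    """Mean diffusivity (l1 + l2 + l3)/3, mm^2/s."""
    return float(np.mean(es.eigenvalues))


def ad(es: EigenSystem) -> float:
    """Axial diffusivity l1, mm^2/s."""
    return float(es.eigenvalues[0])


def rd(es: EigenSystem) -> float:
    """Radial diffusivity (l2 + l3)/2, mm^2/s."""
    return float(np.mean(es.eigenvalues[1:]))


def _metric_from_eigenvalues(lam: np.ndarray, metric: str) -> np.ndarray:
    # lam sorted ascending along last axis (np.linalg.eigvalsh order)
    if metric == "FA":
        return _fa_from_eigenvalues(lam)
    if metric == "MD":
        return np.mean(lam, axis=-1)
    if metric == "AD":
        return lam[..., -1]
    if metric == "RD":
        return np.mean(lam[..., :2], axis=-1)
    raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")


def metric_volume(tv: TensorVolume, metric: str) -> ScalarVolume:
    """Voxelwise DTI metric map; background (zero-tensor) voxels map to 0."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    mats = tv.matrices()
    lam = np.linalg.eigvalsh(mats)  # ascending
    vals = _metric_from_eigenvalues(lam, metric)
    vals = np.where(tv.background(), 0.0, vals)
    return ScalarVolume(values=vals, affine=tv.affine)


def principal_directions(tv: TensorVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel principal eigenvector field and FA map.

    Returns ``(e1, fa)`` with e1 of shape dims + (3,).  Sign is canonicalized
    per voxel; deterministic trackers re-orient per step anyway.
    """
    mats = tv.matrices()
    w, v = np.linalg.eigh(mats)
    e1 = v[..., :, -1]
    # canonical sign: largest-|component| positive
    k = np.argmax(np.abs(e1), axis=-1, keepdims=True)
    sign = np.sign(np.take_along_axis(e1, k, axis=-1))
    sign[sign == 0] = 1.0
    e1 = e1 * sign
    fa_map = np.where(tv.background(), 0.0, _fa_from_eigenvalues(w))
    return e1, fa_map


def mean_tensor(tensors, space: str = "log_euclidean") -> np.ndarray:
    """Average a list of symmetric 3x3 tensors.

    ``space="euclidean"`` is the arithmetic mean of components;
    ``space="log_euclidean"`` averages matrix logarithms, clamping eigenvalues
    below 1e-12 before the log so near-singular inputs stay finite.
    """
    ts = [np.asarray(t, dtype=float) for t in tensors]
    if len(ts) == 0:
        raise ValidationError("cannot average an empty tensor list")
    for t in ts:
        if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-9):
            raise ValidationError("all inputs must be symmetric 3x3 tensors")
    stack = np.stack(ts)
    if space == "euclidean":
        out = stack.mean(axis=0)
    elif space == "log_euclidean":
        w, v = np.linalg.eigh(stack)
        w = np.maximum(w, 1e-12)
        logs = np.einsum("nij,nj,nkj->nik", v, np.log(w), v)
        mean_log = logs.mean(axis=0)
        w2, v2 = np.linalg.eigh(mean_log)
        out = (v2 * np.exp(w2)) @ v2.T
    else:
        raise ValidationError(f"unknown averaging space {space!r}")
    return 0.5 * (out + out.T)


def tensor_from_metric(fa_value: float, md_value: float, direction: np.ndarray) -> np.ndarray:
    """Build an axially symmetric tensor with the given FA, MD and axis.

    With eigenvalues (l1, l2, l2), FA = (1 - r)/sqrt(1 + 2 r^2) for r = l2/l1;
    the quadratic is solved for r and the eigenvalues scaled to the target MD.
    Used by phantom generators and handy for tests.
    """
    f = float(fa_value)
    if not 0.0 <= f < 1.0:
        raise ValidationError(f"FA must be in [0, 1), got {f}")
    a = 1.0 - 2.0 * f * f
    if abs(a) < 1e-12:
        r = (1.0 - f * f) / 2.0
    else:
        disc = 1.0 - a * (1.0 - f * f)
        r = (1.0 - np.sqrt(max(disc, 0.0))) / a
    l1 = 3.0 * md_value / (1.0 + 2.0 * r)
    l2 = r * l1
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return l2 * np.eye(3) + (l1 - l2) * np.outer(d, d)


__all__ = [
    "EigenSystem", "eigensystem", "fa", "md", "ad", "rd",
    "metric_volume", "mean_tensor", "principal_directions",
    "tensor_from_metric", "METRICS",
]
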