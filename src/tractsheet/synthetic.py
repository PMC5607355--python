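"""Synthetic tensor phantoms and cohorts.

``make_sheet_phantom`` builds a 3D diffusion-tensor volume containing a
sheet-like tract: a curved mid-surface z = z0 + a sin(k x) of half-thickness
t, with the principal diffusion direction tangent to the sheet and an FA
profile that peaks at the mid-surface and falls off across the thickness.
The returned truth object answers analytic queries (signed distance to the
mid-surface, inside/outside, expected FA) so every geometric stage can be
validated against a known ground truth.  An optional high-FA distractor can
be planted just beyond the sheet boundary to probe projection stopping rules.

``make_cohort`` simulates a study cohort on a fitted skeleton: gestational
age at birth and post-menstrual age at scan drawn uniformly over
preterm-at-term-equivalent-age ranges (GA 24-32.86 weeks, PMA 38.57-47.14
weeks), with an optional linear PMA effect planted on a contiguous vertex
patch plus between-subject and per-vertex noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeleton import MedialSurface
from .types import BinaryMask, CohortTable, TensorVolume, ValidationError, mat_to_sym6, voxel_to_world


@dataclass
class SheetPhantomSpec:
    # odd z so the default mid-plane sits on a voxel-centre layer
    dims: tuple[int, int, int] = (36, 36, 25)
    voxel_size_mm: float = 1.0
    z0_mm: float | None = None        # default: grid mid-plane
    amplitude_mm: float = 0.0         # a in z = z0 + a sin(k x)
    wavenumber: float = 0.25          # k, rad/mm
    half_thickness_mm: float = 3.0    # t
    rotation_deg_x: float = 0.0       # rigid rotation of the sheet about x
    peak_fa: float = 0.7
    falloff: float = 0.5              # FA(d) = peak * (1 - falloff * (d/t)^2)
    outside_fa: float = 0.05
    md: float = 1.2e-3                # mm^2/s, neonatal-plausible
    distractor_offset_mm: float | None = None  # distance beyond the boundary
    distractor_fa: float = 0.9
    noise_sd: float = 0.0             # SD of additive tensor-component noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_thickness_mm < 2 * self.voxel_size_mm:
            raise ValidationError("half thickness must be at least 2 voxels")
        if not self.peak_fa > self.outside_fa:
            raise ValidationError("peak FA must exceed outside FA")
        if self.distractor_offset_mm is not None and self.distractor_offset_mm <= 0:
            raise ValidationError("distractor offset must be positive")
        if self.z0_mm is None:
            self.z0_mm = 0.5 * (self.dims[2] - 1) * self.voxel_size_mm


@dataclass
class SheetTruth:
    """Analytic ground truth for a sheet phantom."""

    spec: SheetPhantomSpec
    affine: np.ndarray
    mask: BinaryMask = field(repr=False, default=None)

    def _rotated(self, points: np.ndarray) -> np.ndarray:
        """World points expressed in the sheet's (unrotated) frame."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        th = np.deg2rad(self.spec.rotation_deg_x)
        if th == 0.0:
            return p
        c = np.array([(d - 1) * self.spec.voxel_size_mm / 2 for d in self.spec.dims])
        rot = np.array([[1, 0, 0],
                        [0, np.cos(th), -np.sin(th)],
                        [0, np.sin(th), np.cos(th)]])
        return (p - c) @ rot + c  # inverse rotation: p' = R^T (p - c) + c

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Approximate perpendicular signed distance to the mid-surface (mm)."""
        s = self.spec
        q = self._rotated(points)
        mid = s.z0_mm + s.amplitude_mm * np.sin(s.wavenumber * q[:, 0])
        slope = s.amplitude_mm * s.wavenumber * np.cos(s.wavenumber * q[:, 0])
        return (q[:, 2] - mid) * np.cos(np.arctan(slope))

    def inside(self, points: np.ndarray) -> np.ndarray:
        # strict inequality: voxel centres exactly t from the mid-surface are
        # background, so the digitized boundary coincides with the analytic one
        return np.abs(self.signed_distance(points)) < self.spec.half_thickness_mm

    def tangent(self, points: np.ndarray) -> np.ndarray:
        """Unit principal-direction field (tangent to the sheet, in world frame)."""
        s = self.spec
        q = self._rotated(points)
        slope = s.amplitude_mm * s.wavenumber * np.cos(s.wavenumber * q[:, 0])
        t = np.stack([np.ones_like(slope), np.zeros_like(slope), slope], axis=1)
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        th = np.deg2rad(s.rotation_deg_x)
        if th != 0.0:
            rot = np.array([[1, 0, 0],
                            [0, np.cos(th), -np.sin(th)],
                            [0, np.sin(th), np.cos(th)]])
            t = t @ rot.T
        return t

    def normal(self, points: np.ndarray) -> np.ndarray:
        """Unit sheet-normal field in the world frame."""
        t = self.tangent(points)
        y = np.tile(np.array([0.0, 1.0, 0.0]), (len(t), 1))
        th = np.deg2rad(self.spec.rotation_deg_x)
        if th != 0.0:
            rot = np.array([[1, 0, 0],
                            [0, np.cos(th), -np.sin(th)],
                            [0, np.sin(th), np.cos(th)]])
            y = y @ rot.T
        n = np.cross(t, y)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def expected_fa(self, points: np.ndarray) -> np.ndarray:
        """Noise-free FA at world points (distractor included)."""
        s = self.spec
        d = self.signed_distance(points)
        prof = s.peak_fa * (1.0 - s.falloff * (np.abs(d) / s.half_thickness_mm) ** 2)
        out = np.where(np.abs(d) < s.half_thickness_mm, prof, s.outside_fa)
        if s.distractor_offset_mm is not None:
            lo = s.half_thickness_mm + s.distractor_offset_mm
            hi = lo + 1.5 * s.voxel_size_mm
            out = np.where((d >= lo) & (d <= hi), s.distractor_fa, out)
        return out

    def distractor_band(self, points: np.ndarray) -> np.ndarray:
        s = self.spec
        if s.distractor_offset_mm is None:
            return np.zeros(len(np.atleast_2d(points)), dtype=bool)
        d = self.signed_distance(points)
        lo = s.half_thickness_mm + s.distractor_offset_mm
        return (d >= lo) & (d <= lo + 1.5 * s.voxel_size_mm)


def make_sheet_phantom(spec: SheetPhantomSpec) -> tuple[TensorVolume, SheetTruth]:
    """Generate the tensor volume and its analytic truth (with tract mask)."""
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    truth = SheetTruth(spec=spec, affine=affine)
    ijk = np.indices(spec.dims).reshape(3, -1).T
    pts = voxel_to_world(affine, ijk)

    fa_vals = truth.expected_fa(pts)
    dirs = truth.tangent(pts)
    inside = truth.inside(pts)
    fa_vals = np.clip(fa_vals, 0.0, 0.95)  # distractor FA arrives via expected_fa

    # vectorized axially symmetric tensor construction (see tensor_from_metric)
    f = fa_vals
    a = 1.0 - 2.0 * f * f
    disc = np.maximum(1.0 - a * (1.0 - f * f), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(np.abs(a) < 1e-12, (1.0 - f * f) / 2.0,
                     (1.0 - np.sqrt(disc)) / np.where(np.abs(a) < 1e-12, 1.0, a))
    l1 = 3.0 * spec.md / (1.0 + 2.0 * r)
    l2 = r * l1
    eye = np.eye(3)
    mats = l2[:, None, None] * eye + (l1 - l2)[:, None, None] * np.einsum(
        "ni,nj->nij", dirs, dirs)
    six = mat_to_sym6(mats)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        six = six + rng.normal(0.0, spec.noise_sd, six.shape)
    tensors = six.reshape(spec.dims + (6,))
    tv = TensorVolume(tensors=tensors, affine=affine)
    # the tract mask is the sheet interior only — the distractor is outside it
    truth.mask = BinaryMask(values=inside.reshape(spec.dims), affine=affine)
    return tv, truth


@dataclass
class CohortSpec:
    n_subjects: int = 20
    ga_range: tuple[float, float] = (24.0, 32.86)     # weeks at birth
    pma_range: tuple[float, float] = (38.57, 47.14)   # weeks at scan
    baseline_fa: float = 0.4
    beta: float = 0.0            # FA change per week of PMA, on the patch
    patch_size: int = 50         # contiguous vertices carrying the effect
    between_sd: float = 0.02     # subject-level FA offset SD
    within_sd: float = 0.02      # per-vertex noise SD
    ga_slope: float = 0.0        # optional nuisance effect of GA on all vertices
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 6:
            raise ValidationError("need at least 6 subjects")
        for lo, hi in (self.ga_range, self.pma_range):
            if not 0 < lo < hi:
                raise ValidationError("age ranges must be positive and increasing")
        if self.ga_range[1] >= self.pma_range[0]:
            raise ValidationError("GA range must lie below the PMA range")


def _contiguous_patch(surface: MedialSurface, size: int, start: int) -> np.ndarray:
    """Breadth-first vertex patch of the requested size on the mesh graph."""
    edges = surface.edges()
    nbrs: dict[int, list[int]] = {}
    for a, b in edges:
        nbrs.setdefault(int(a), []).append(int(b))
        nbrs.setdefault(int(b), []).append(int(a))
    seen = [start]
    in_patch = {start}
    i = 0
    while len(seen) < size and i < len(seen):
        for nb in sorted(nbrs.get(seen[i], [])):
            if nb not in in_patch:
                in_patch.add(nb)
                seen.append(nb)
                if len(seen) >= size:
                    break
        i += 1
    return np.array(sorted(seen[:size]))


def make_cohort(spec: CohortSpec, surface: MedialSurface):
    """Simulate a cohort of skeleton FA maps with a planted PMA effect.

    Per-vertex FA for subject i:

        FA_iv = baseline + beta * (PMA_i - mean PMA) * 1[v in patch]
                + ga_slope * (GA_i - mean GA) + u_i + e_iv

    with u_i ~ N(0, between_sd^2), e_iv ~ N(0, within_sd^2).

    Returns ``(cohort, maps, truth)`` where maps is (n_subjects, n_vertices)
    and truth records the patch vertex indices and the planted beta.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ga = rng.uniform(*spec.ga_range, size=n)
    pma = rng.uniform(*spec.pma_range, size=n)
    cohort = CohortTable(pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "GA_birth": ga,
        "PMA_scan": pma,
    }))
    nv = surface.n_vertices
    centroid = surface.vertices.mean(axis=0)
    start = int(np.argmin(np.linalg.norm(surface.vertices - centroid, axis=1)))
    patch = _contiguous_patch(surface, min(spec.patch_size, nv), start)
    effect = np.zeros(nv)
    effect[patch] = 1.0
    maps = (
        spec.baseline_fa
        + spec.beta * (pma - pma.mean())[:, None] * effect[None, :]
        + spec.ga_slope * (ga - ga.mean())[:, None]
        + rng.normal(0.0, spec.between_sd, size=(n, 1))
        + (rng.normal(0.0, spec.within_sd, size=(n, nv)) if spec.within_sd > 0 else 0.0)
    )
    truth = {"patch": patch, "beta": spec.beta}
    return cohort, maps, truth


__all__ = ["SheetPhantomSpec", "SheetTruth", "CohortSpec",
           "make_sheet_phantom", "make_cohort"]
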