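"""FACT deterministic tractography and ROI-based tract selection.

FACT (fiber assignment by continuous tracking) follows each voxel's principal
eigenvector from face to face with no interpolation: within a voxel the path
is a straight segment along that voxel's e1, entered and left through exact
ray-box intersections.  Seeding is one bidirectional streamline per voxel
above the FA threshold; propagation stops on low FA, a sharp turn, leaving
the grid, or a step cap.  Defaults follow common deterministic-tracking
practice for neonatal data: minimum FA 0.1, maximum turning angle 45 degrees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tensor import principal_directions
from .types import (
    BinaryMask,
    ScalarVolume,
    TensorVolume,
    Tractogram,
    ValidationError,
    world_to_voxel,
    voxel_to_world,
)

log = logging.getLogger(__name__)

_NUDGE = 1e-6  # fraction of a voxel pushed past a face to avoid re-entry


@dataclass
class TrackingParams:
    fa_threshold: float = 0.1
    angle_threshold_deg: float = 45.0
    max_steps: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 < self.fa_threshold < 1.0:
            raise ValidationError("fa_threshold must be in (0, 1)")
        if not 0.0 < self.angle_threshold_deg < 180.0:
            raise ValidationError("angle_threshold_deg must be in (0, 180)")
        if self.max_steps < 1:
            raise ValidationError("max_steps must be >= 1")


@dataclass
class SelectionRule:
    """Waypoint ROIs are ANDed; exclusion ROIs veto any streamline touching them."""

    waypoint_rois: list[BinaryMask]
    exclusion_rois: list[BinaryMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.waypoint_rois) < 1:
            raise ValidationError("at least one waypoint ROI is required")


def _track_half(vox0, dir_world, e1, fa_map, params, ainv3):
    """One unidirectional half-track in voxel coordinates; returns point list."""
    dims = fa_map.shape
    p = np.asarray(vox0, dtype=float)
    vox = tuple(vox0)
    prev_dir = np.asarray(dir_world, dtype=float)
    cos_thresh = np.cos(np.deg2rad(params.angle_threshold_deg))
    points = [p.copy()]
    for _ in range(params.max_steps):
        d_world = e1[vox]
        if np.dot(d_world, prev_dir) < 0:
            d_world = -d_world
        # turning angle between successive propagation directions
        if np.dot(d_world, prev_dir) < cos_thresh - 1e-12:
            break
        d_vox = ainv3 @ d_world
        nd = np.linalg.norm(d_vox)
        if nd < 1e-12:
            break
        d_vox = d_vox / nd
        # exact parametric exit through the current voxel's faces
        t_exit = np.inf
        for a in range(3):
            if abs(d_vox[a]) > 1e-12:
                b = vox[a] + (0.5 if d_vox[a] > 0 else -0.5)
                t = (b - p[a]) / d_vox[a]
                if t < t_exit:
                    t_exit = t
        if not np.isfinite(t_exit) or t_exit < 0:
            break
        exit_pt = p + t_exit * d_vox
        points.append(exit_pt.copy())
        p = p + (t_exit + _NUDGE) * d_vox
        nxt = tuple(int(np.rint(c)) for c in p)
        if any(c < 0 or c >= n for c, n in zip(nxt, dims)):
            break  # left the grid; terminal point stays clipped to the face
        if fa_map[nxt] < params.fa_threshold:
            break
        prev_dir = d_world
        vox = nxt
    return points


def fact_track(tv: TensorVolume, params: TrackingParams | None = None) -> Tractogram:
    """Whole-volume FACT tracking seeded once per voxel with FA >= threshold.

    Each seed launches along +e1 and -e1 from the voxel center; the two halves
    are concatenated into one bidirectional streamline.  Output is fully
    deterministic.
    """
    params = params or TrackingParams()
    e1, fa_map = principal_directions(tv)
    ainv3 = np.linalg.inv(tv.affine[:3, :3])
    seeds = np.argwhere(fa_map >= params.fa_threshold)
    if seeds.size == 0:
        log.warning("no voxels above FA threshold %.3f; empty tractogram",
                    params.fa_threshold)
        return Tractogram(streamlines=[], provenance=_provenance(tv, params))
    streamlines = []
    for vox in seeds:
        vox = tuple(int(v) for v in vox)
        d0 = e1[vox]
        fwd = _track_half(vox, d0, e1, fa_map, params, ainv3)
        bwd = _track_half(vox, -d0, e1, fa_map, params, ainv3)
        pts = bwd[::-1] + fwd[1:]  # seed center appears once
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        keep = np.r_[True, np.any(np.diff(arr, axis=0) != 0.0, axis=1)]
        arr = arr[keep]
        if arr.shape[0] < 2:
            continue
        streamlines.append(voxel_to_world(tv.affine, arr))
    return Tractogram(streamlines=streamlines, provenance=_provenance(tv, params))


def _provenance(tv: TensorVolume, params: TrackingParams) -> dict:
    return {
        "algorithm": "FACT",
        "fa_threshold": params.fa_threshold,
        "angle_threshold_deg": params.angle_threshold_deg,
        "max_steps": params.max_steps,
        "grid_dims": tuple(tv.dims),
        "grid_affine": np.asarray(tv.affine).tolist(),
    }


def _nearest_voxel(frac: np.ndarray) -> np.ndarray:
    # half-up rounding: a face point at i + 0.5 belongs to voxel i + 1,
    # so every voxel a streamline traverses is hit by its entry face
    return np.floor(frac + 0.5).astype(int)


def _points_in_mask(points: np.ndarray, mask: BinaryMask) -> bool:
    ijk = _nearest_voxel(world_to_voxel(mask.affine, points))
    dims = mask.dims
    ok = np.all((ijk >= 0) & (ijk < np.asarray(dims)), axis=1)
    if not np.any(ok):
        return False
    ijk = ijk[ok]
    return bool(mask.values[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any())


def _check_common_grid(tg: Tractogram, masks: list[BinaryMask]) -> None:
    dims = tg.provenance.get("grid_dims")
    aff = tg.provenance.get("grid_affine")
    for m in masks:
        if dims is not None and tuple(m.dims) != tuple(dims):
            raise ValidationError(
                f"ROI grid {m.dims} does not match tractogram grid {tuple(dims)}")
        if aff is not None and not np.allclose(m.affine, np.asarray(aff)):
            raise ValidationError("ROI affine does not match tractogram grid affine")


def select_streamlines(tg: Tractogram, rule: SelectionRule) -> Tractogram:
    """Keep streamlines that hit every waypoint ROI and no exclusion ROI."""
    _check_common_grid(tg, rule.waypoint_rois + rule.exclusion_rois)
    kept = []
    for s in tg.streamlines:
        if not all(_points_in_mask(s, roi) for roi in rule.waypoint_rois):
            continue
        if any(_points_in_mask(s, roi) for roi in rule.exclusion_rois):
            continue
        kept.append(s)
    prov = dict(tg.provenance)
    prov["selection"] = {
        "n_waypoints": len(rule.waypoint_rois),
        "n_exclusions": len(rule.exclusion_rois),
        "n_in": len(tg),
        "n_kept": len(kept),
    }
    return Tractogram(streamlines=kept, provenance=prov)


def densify(streamline: np.ndarray, max_spacing: float) -> np.ndarray:
    """Insert points so consecutive spacing never exceeds ``max_spacing`` mm."""
    out = [streamline[0]]
    for a, b in zip(streamline[:-1], streamline[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / max_spacing)), 1)
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def tract_mask(tg: Tractogram, dims, affine) -> BinaryMask:
    """Rasterize a tractogram: a voxel is set iff a (densified) point lies in it."""
    vals = np.zeros(dims, dtype=bool)
    mask = BinaryMask(values=vals, affine=affine)
    if len(tg) == 0:
        warnings.warn("empty tractogram; returning all-zero mask", stacklevel=2)
        return mask
    half_vox = 0.5 * float(np.min(mask.voxel_size))
    for s in tg.streamlines:
        pts = densify(s, half_vox)
        ijk = _nearest_voxel(world_to_voxel(affine, pts))
        ok = np.all((ijk >= 0) & (ijk < np.asarray(dims)), axis=1)
        ijk = ijk[ok]
        vals[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    return BinaryMask(values=vals, affine=affine)


def snr_estimate(b0: ScalarVolume, roi: BinaryMask) -> float:
    """Signal-to-noise ratio over an ROI: mean signal / sample SD."""
    if not roi.same_grid(b0):
        raise ValidationError("ROI grid does not match the b0 volume")
    vals = b0.values[roi.values]
    if vals.size < 2:
        raise ValidationError("ROI must contain at least 2 voxels")
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        warnings.warn("zero standard deviation in ROI; SNR is infinite", stacklevel=2)
        return float("inf")
    return float(np.mean(vals)) / sd


__all__ = [
    "TrackingParams", "SelectionRule", "fact_track", "select_streamlines",
    "tract_mask", "snr_estimate", "densify",
]
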