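"""FACT tracking geometry, ROI selection and rasterization oracles."""

import numpy as np
import pytest

from tractsheet.tensor import tensor_from_metric
from tractsheet.tracking import (
    SelectionRule, TrackingParams, densify, fact_track, select_streamlines,
    snr_estimate, tract_mask,
)
from tractsheet.types import (
    BinaryMask, ScalarVolume, TensorVolume, Tractogram, ValidationError,
    mat_to_sym6, world_to_voxel,
)


def _uniform_volume(direction, dims=(10, 10, 10), fa=0.8, affine=None):
    t = tensor_from_metric(fa, 1.2e-3, direction)
    tens = np.tile(mat_to_sym6(t), dims + (1,))
    return TensorVolume(tensors=tens, affine=affine if affine is not None else np.eye(4))


def _interface_volume():
    """x-fibers for x<10, y-fibers for x>=10: a 90-degree planar interface."""
    tens = np.empty((20, 20, 5, 6))
    tens[:10] = mat_to_sym6(tensor_from_metric(0.8, 1.2e-3, [1, 0, 0]))
    tens[10:] = mat_to_sym6(tensor_from_metric(0.8, 1.2e-3, [0, 1, 0]))
    return TensorVolume(tensors=tens, affine=np.eye(4))


class TestFactTrack:
    def test_uniform_field_straight_spanning(self):
        tv = _uniform_volume([1, 0, 0])
        tg = fact_track(tv)
        assert len(tg) == 1000  # one per voxel
        for s in tg:
            assert np.ptp(s[:, 1]) < 1e-9 and np.ptp(s[:, 2]) < 1e-9
            assert s[:, 0].min() == pytest.approx(-0.5)  # spans to the faces
            assert s[:, 0].max() == pytest.approx(9.5)

    def test_below_fa_threshold_no_streamlines(self):
        tv = _uniform_volume([1, 0, 0], fa=0.05)
        assert len(fact_track(tv)) == 0

    def test_interface_termination_and_crossing(self):
        tv = _interface_volume()
        tg45 = fact_track(tv, TrackingParams(angle_threshold_deg=45.0))
        crossed = [s for s in tg45 if np.ptp(s[:, 0]) > 1e-9 and np.ptp(s[:, 1]) > 1e-9]
        assert len(crossed) == 0
        x_block = [s for s in tg45 if np.ptp(s[:, 1]) < 1e-12]
        assert len(x_block) == 1000
        assert all(abs(s[:, 0].max() - 9.5) < 1e-9 for s in x_block)  # clipped at interface
        tg95 = fact_track(tv, TrackingParams(angle_threshold_deg=95.0))
        crossed = [s for s in tg95 if np.ptp(s[:, 0]) > 1e-9 and np.ptp(s[:, 1]) > 1e-9]
        assert len(crossed) == 1000  # every x-block seed turns through the interface

    def test_analytic_stepping_oracle_oblique(self):
        """Face-to-face stepping along an oblique uniform field matches the
        analytic ray through the grid."""
        d = np.array([2.0, 1.0, 0.0]) / np.sqrt(5)
        tv = _uniform_volume(d, dims=(12, 12, 3))
        tg = fact_track(tv)
        for s in tg:
            rel = s - s[0]
            proj = np.outer(rel @ d, d)
            assert np.max(np.abs(rel - proj)) < 1e-6  # collinear with d

    def test_deterministic(self):
        tv = _interface_volume()
        a = fact_track(tv)
        b = fact_track(tv)
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1, s2)

    def test_no_point_in_subthreshold_voxel(self):
        tens = np.tile(mat_to_sym6(tensor_from_metric(0.8, 1.2e-3, [1, 0, 0])),
                       (10, 5, 5, 1))
        tens[6:] = mat_to_sym6(tensor_from_metric(0.05, 1.2e-3, [1, 0, 0]))
        tv = TensorVolume(tensors=tens, affine=np.eye(4))
        tg = fact_track(tv)
        for s in tg:
            interior = s[(s[:, 0] % 1.0) != 0.5]  # exclude face points
            assert np.all(interior[:, 0] < 5.5)


def _mask_from_voxels(vox_list, dims=(20, 20, 5)):
    vals = np.zeros(dims, bool)
    for v in vox_list:
        vals[v] = True
    return BinaryMask(values=vals, affine=np.eye(4))


class TestSelectStreamlines:
    def _tg(self):
        tv = _uniform_volume([1, 0, 0], dims=(20, 20, 5))
        tg = fact_track(tv)
        return tg

    def test_waypoint_and_exclusion_semantics(self):
        tg = self._tg()
        w1 = _mask_from_voxels([(2, 5, 2)])
        w2 = _mask_from_voxels([(15, 5, 2)])
        excl = _mask_from_voxels([(10, 7, 2)])
        out = select_streamlines(tg, SelectionRule([w1, w2]))
        # x-parallel lines through (y=5, z=2) pass both waypoints
        assert len(out) == 20
        out2 = select_streamlines(tg, SelectionRule([w1, w2], [excl]))
        assert len(out2) == 20  # exclusion is on another row
        out3 = select_streamlines(tg, SelectionRule([w1], [_mask_from_voxels([(9, 5, 2)])]))
        assert len(out3) == 0  # exclusion on the same row removes all

    def test_single_waypoint_miss(self):
        tg = self._tg()
        out = select_streamlines(tg, SelectionRule([_mask_from_voxels([(5, 3, 1)]),
                                                    _mask_from_voxels([(5, 4, 1)])]))
        assert len(out) == 0  # no streamline crosses both rows

    def test_brute_force_membership_oracle(self, rng):
        sls = [np.cumsum(rng.uniform(-1, 1, size=(rng.integers(3, 12), 3)), axis=0) + 8
               for _ in range(100)]
        tg = Tractogram(streamlines=sls)
        w = _mask_from_voxels([(i, j, k) for i in range(6, 11) for j in range(6, 11)
                               for k in range(0, 5)])
        e = _mask_from_voxels([(12, 12, 2)])
        out = select_streamlines(tg, SelectionRule([w], [e]))

        def hit(s, m):
            for p in s:
                ijk = np.rint(world_to_voxel(m.affine, p)).astype(int)
                if np.all(ijk >= 0) and np.all(ijk < np.array(m.dims)) and m.values[tuple(ijk)]:
                    return True
            return False

        expected = [s for s in sls if hit(s, w) and not hit(s, e)]
        assert len(out) == len(expected)
        for a, b in zip(out, expected):
            assert np.array_equal(a, b)

    def test_idempotence(self):
        tg = self._tg()
        rule = SelectionRule([_mask_from_voxels([(2, 5, 2)])])
        once = select_streamlines(tg, rule)
        twice = select_streamlines(once, rule)
        assert len(once) == len(twice)

    def test_grid_mismatch_rejected(self):
        tg = self._tg()
        bad = BinaryMask(values=np.ones((3, 3, 3), bool), affine=np.eye(4))
        with pytest.raises(ValidationError):
            select_streamlines(tg, SelectionRule([bad]))


class TestTractMask:
    def test_single_row_rasterization(self):
        pts = np.column_stack([np.linspace(0, 9, 10), np.full(10, 3.0), np.full(10, 2.0)])
        tg = Tractogram(streamlines=[pts])
        m = tract_mask(tg, (10, 10, 5), np.eye(4))
        expected = np.zeros((10, 10, 5), bool)
        expected[:, 3, 2] = True
        assert np.array_equal(m.values, expected)

    def test_empty_tractogram_warns(self):
        with pytest.warns(UserWarning):
            m = tract_mask(Tractogram(streamlines=[]), (5, 5, 5), np.eye(4))
        assert m.count() == 0

    def test_densified_rasterization_oracle(self, rng):
        sls = [np.cumsum(rng.uniform(-1.5, 1.5, size=(6, 3)), axis=0) + 8
               for _ in range(20)]
        tg = Tractogram(streamlines=sls)
        m = tract_mask(tg, (20, 20, 20), np.eye(4))
        expected = np.zeros((20, 20, 20), bool)
        for s in sls:
            for p in densify(s, 0.5):
                ijk = np.rint(p).astype(int)
                if np.all(ijk >= 0) and np.all(ijk < 20):
                    expected[tuple(ijk)] = True
        assert np.array_equal(m.values, expected)


class TestSnr:
    def test_hand_computed(self):
        vals = np.zeros((2, 2, 1))
        vals[:, :, 0] = [[10, 10], [12, 12]]
        b0 = ScalarVolume(values=vals, affine=np.eye(4))
        roi = BinaryMask(values=np.ones((2, 2, 1), bool), affine=np.eye(4))
        assert snr_estimate(b0, roi) == pytest.approx(11 / np.std([10, 10, 12, 12], ddof=1))
        assert snr_estimate(b0, roi) == pytest.approx(9.5263, abs=1e-4)

    def test_constant_roi_infinite(self):
        b0 = ScalarVolume(values=np.full((3, 3, 1), 5.0), affine=np.eye(4))
        roi = BinaryMask(values=np.ones((3, 3, 1), bool), affine=np.eye(4))
        with pytest.warns(UserWarning):
            assert snr_estimate(b0, roi) == np.inf

    def test_gaussian_sampling_oracle(self, rng):
        vals = rng.normal(100, 5, size=(22, 22, 22))
        b0 = ScalarVolume(values=vals, affine=np.eye(4))
        roi = BinaryMask(values=np.ones((22, 22, 22), bool), affine=np.eye(4))
        assert snr_estimate(b0, roi) == pytest.approx(20.0, rel=0.05)
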