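"""Distance-transform diameters and morphometric summaries."""

import numpy as np
import pytest

from conftest import nearest_background_sq_distance
from pamvasc import morphometry as mm
from pamvasc import network_topology as nt
from pamvasc import vessel_segmentation as vseg
from pamvasc.rf_preprocessing import ValidationError
from pamvasc.vessel_segmentation import SkeletonMask, VesselMask

PX = 3.0


def _mask(arr):
    return VesselMask(mask=arr.astype(bool), pixel_size_um=PX)


def _skel(arr):
    return SkeletonMask(mask=arr.astype(bool), pixel_size_um=PX)


class TestDiameterMap:
    def test_horizontal_bar_strip_width(self):
        """11-px-tall bar at 3 um pixels: interior centerline diameter is
        within one pixel of the 33 um strip width."""
        mask = np.zeros((31, 80), dtype=bool)
        mask[10:21, 5:75] = True
        skel = np.zeros_like(mask)
        skel[15, 6:74] = True
        dmap = mm.diameter_map(_mask(mask), _skel(skel))
        interior = dmap.diameter_um[(dmap.cols > 20) & (dmap.cols < 60)]
        np.testing.assert_allclose(interior, 33.0, atol=PX)

    def test_one_pixel_line_matches_brute_force(self):
        mask = np.zeros((15, 40), dtype=bool)
        mask[7, 3:37] = True
        dmap = mm.diameter_map(_mask(mask), _skel(mask))
        for r, c, d in zip(dmap.rows, dmap.cols, dmap.diameter_um):
            sq = nearest_background_sq_distance(mask, r, c, window=5)
            assert d == pytest.approx(2.0 * np.sqrt(sq) * PX, rel=1e-12)

    def test_skeleton_off_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:6, 3:6] = True
        skel = np.zeros_like(mask)
        skel[1, 1] = True
        with pytest.raises(ValidationError, match="off the vessel mask"):
            mm.diameter_map(_mask(mask), _skel(skel))

    def test_phantom_diameters_match_windowed_exhaustive_oracle(self, segmented_phantom):
        mask, skel, _ = segmented_phantom
        dmap = mm.diameter_map(mask, skel)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(dmap), size=min(300, len(dmap)), replace=False)
        for i in idx:
            r, c = int(dmap.rows[i]), int(dmap.cols[i])
            dist_px = dmap.diameter_um[i] / (2 * PX)
            window = int(np.ceil(dist_px)) + 2
            sq = nearest_background_sq_distance(mask.mask, r, c, window)
            assert np.sqrt(sq) < window  # windowed search provably exhaustive
            assert dmap.diameter_um[i] == pytest.approx(2 * np.sqrt(sq) * PX, rel=1e-12)


class TestMorphometricFeatures:
    def _uniform_dmap(self, d_um, n=50):
        return mm.DiameterMap(
            rows=np.zeros(n, dtype=int),
            cols=np.arange(n),
            diameter_um=np.full(n, d_um),
            pixel_size_um=PX,
        )

    def _simple_geometry(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[8:13, 2:18] = True
        skel = np.zeros_like(mask)
        skel[10, 3:17] = True
        return _mask(mask), _skel(skel)

    def test_constant_diameters(self):
        mask, skel = self._simple_geometry()
        feats = mm.morphometric_features(self._uniform_dmap(15.0), mask, skel, 1e6)
        assert feats.mean_diameter_um == 15.0
        assert feats.sd_diameter_um == 0.0
        assert feats.min_diameter_um == feats.max_diameter_um == 15.0
        assert feats.median_diameter_um == 15.0

    def test_mean_sd_match_two_pass_reference(self, segmented_phantom):
        mask, skel, _ = segmented_phantom
        dmap = mm.diameter_map(mask, skel)
        area = nt.roi_area(mask.mask.shape, PX)
        feats = mm.morphometric_features(dmap, mask, skel, area)
        d = dmap.diameter_um
        mean_ref = d.sum() / len(d)
        sd_ref = np.sqrt(((d - mean_ref) ** 2).sum() / (len(d) - 1))
        assert feats.mean_diameter_um == pytest.approx(mean_ref, rel=1e-9)
        assert feats.sd_diameter_um == pytest.approx(sd_ref, rel=1e-9)

    def test_phantom_mean_recovery_within_ten_percent(self):
        from pamvasc import synthetic_data as sd

        spec = sd.calibration_spec(30.0, seed=1)
        mip, gt = sd.generate_vessel_phantom(spec)
        mask = vseg.binarize(mip)
        skel = vseg.skeletonize(mask)
        dmap = mm.diameter_map(mask, skel)
        area = nt.roi_area(mask.mask.shape, mask.pixel_size_um)
        feats = mm.morphometric_features(dmap, mask, skel, area)
        assert feats.mean_diameter_um == pytest.approx(gt.true_mean_diameter_um, rel=0.10)

    def test_unit_homogeneity_under_pixel_size_doubling(self):
        mask_arr = np.zeros((20, 20), dtype=bool)
        mask_arr[8:13, 2:18] = True
        skel_arr = np.zeros_like(mask_arr)
        skel_arr[10, 3:17] = True
        out = {}
        for px in (3.0, 6.0):
            mask = VesselMask(mask=mask_arr, pixel_size_um=px)
            skel = SkeletonMask(mask=skel_arr, pixel_size_um=px)
            area = nt.roi_area(mask_arr.shape, px)
            out[px] = mm.morphometric_features(mm.diameter_map(mask, skel), mask, skel, area)
        assert out[6.0].mean_diameter_um == pytest.approx(2 * out[3.0].mean_diameter_um)
        assert out[6.0].max_diameter_um == pytest.approx(2 * out[3.0].max_diameter_um)
        # length/area density halves; per-area intersection density quarters
        assert out[6.0].vessel_density_um_per_um2 == pytest.approx(
            out[3.0].vessel_density_um_per_um2 / 2
        )

    def test_invariance_under_rotation_and_translation(self, segmented_phantom):
        mask, skel, _ = segmented_phantom
        area = nt.roi_area(mask.mask.shape, PX)
        base = mm.morphometric_features(mm.diameter_map(mask, skel), mask, skel, area)
        rot_mask = VesselMask(mask=np.rot90(mask.mask).copy(), pixel_size_um=PX)
        rot_skel = SkeletonMask(mask=np.rot90(skel.mask).copy(), pixel_size_um=PX)
        rot = mm.morphometric_features(
            mm.diameter_map(rot_mask, rot_skel), rot_mask, rot_skel, area
        )
        assert rot.mean_diameter_um == pytest.approx(base.mean_diameter_um, rel=1e-12)
        assert rot.sd_diameter_um == pytest.approx(base.sd_diameter_um, rel=1e-12)
        assert rot.vessel_area_fraction == base.vessel_area_fraction

    def test_empty_map_rejected(self):
        mask, skel = self._simple_geometry()
        empty = mm.DiameterMap(
            rows=np.array([], dtype=int),
            cols=np.array([], dtype=int),
            diameter_um=np.array([]),
            pixel_size_um=PX,
        )
        with pytest.raises(ValidationError, match="empty diameter map"):
            mm.morphometric_features(empty, mask, skel, 1e6)
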