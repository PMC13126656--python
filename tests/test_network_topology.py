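"""Skeleton graph construction and topology features."""

import math

import numpy as np
import pytest

from conftest import topology_counts_oracle
from pamvasc import network_topology as nt
from pamvasc import vessel_segmentation as vseg
from pamvasc.rf_preprocessing import ValidationError
from pamvasc.vessel_segmentation import SkeletonMask

PX = 3.0


def _skel(arr):
    return SkeletonMask(mask=arr.astype(bool), pixel_size_um=PX)


def _y_skeleton():
    """Three 50-px arms meeting at one junction pixel."""
    arr = np.zeros((120, 120), dtype=bool)
    j = (60, 60)
    arr[j[0] - 50 : j[0] + 1, j[1]] = True  # arm up
    for i in range(1, 51):  # two diagonal arms down
        arr[j[0] + i, j[1] - i] = True
        arr[j[0] + i, j[1] + i] = True
    arr[j] = True
    return arr


def _h_skeleton(crossbar_steps=40):
    """Two vertical bars joined by a crossbar of the given step count."""
    arr = np.zeros((60, 80), dtype=bool)
    r = 30
    c1, c2 = 15, 15 + crossbar_steps
    arr[10:51, c1] = True
    arr[10:51, c2] = True
    arr[r, c1 : c2 + 1] = True
    return arr


class TestBuildSkeletonGraph:
    def test_straight_path(self):
        arr = np.zeros((5, 110), dtype=bool)
        arr[2, 5:105] = True  # 100 pixels
        g = nt.build_skeleton_graph(_skel(arr))
        assert g.n_endpoints == 2
        assert g.n_branch_nodes == 0
        assert len(g.segments) == 1
        assert g.segments[0].length_um == pytest.approx(99 * PX)

    def test_y_junction(self):
        g = nt.build_skeleton_graph(_skel(_y_skeleton()))
        assert g.n_endpoints == 3
        assert g.n_branch_nodes == 1
        assert len(g.segments) == 3

    def test_h_junctions_and_crossbar(self):
        g = nt.build_skeleton_graph(_skel(_h_skeleton()))
        assert g.n_endpoints == 4
        assert g.n_branch_nodes == 2
        assert len(g.segments) == 5

    def test_non_thin_skeleton_rejected(self):
        arr = np.zeros((6, 6), dtype=bool)
        arr[2:4, 2:4] = True
        with pytest.raises(ValidationError, match="not thin"):
            nt.build_skeleton_graph(_skel(arr))

    def test_counts_match_flood_fill_oracle_on_phantoms(self):
        from pamvasc import synthetic_data as sd

        for seed in range(8):
            mip, _ = sd.generate_vessel_phantom(sd.VesselNetworkSpec(seed=seed))
            skel = vseg.skeletonize(vseg.binarize(mip))
            g = nt.build_skeleton_graph(skel)
            n_end, n_branch, n_seg = topology_counts_oracle(skel.mask)
            assert g.n_endpoints == n_end
            assert g.n_branch_nodes == n_branch
            assert len(g.segments) == n_seg

    def test_invariant_under_rotation(self, segmented_phantom):
        _, skel, _ = segmented_phantom
        g1 = nt.build_skeleton_graph(skel)
        g2 = nt.build_skeleton_graph(
            SkeletonMask(mask=np.rot90(skel.mask).copy(), pixel_size_um=PX)
        )
        assert g1.n_endpoints == g2.n_endpoints
        assert g1.n_branch_nodes == g2.n_branch_nodes
        assert len(g1.segments) == len(g2.segments)
        assert g1.total_length_um == pytest.approx(g2.total_length_um, rel=1e-12)

    def test_isolated_component_flagging(self):
        arr = _y_skeleton()
        arr[5, 100:116] = True  # bare fragment far from the Y
        g = nt.build_skeleton_graph(_skel(arr))
        assert g.n_components == 2
        # exactly one component is isolated (the fragment: no branch node)
        assert g.is_isolated.sum() == 1
        frag_len = sum(
            s.length_um for s in g.segments if g.is_isolated[s.component]
        )
        assert frag_len == pytest.approx(15 * PX)
        assert g.isolated_length_um == pytest.approx(frag_len)

    def test_length_accounts_for_every_pixel(self, segmented_phantom):
        """Sum of segment lengths covers the skeleton pixel count to within
        one step-length per node (junction pixels are shared)."""
        _, skel, _ = segmented_phantom
        g = nt.build_skeleton_graph(skel)
        n_px = skel.mask.sum()
        total_steps = g.total_length_um / PX
        slack = math.sqrt(2) * (len(g.nodes) + 2 * len(g.segments))
        assert abs(total_steps - n_px) <= slack


class TestTopologyFeatures:
    def test_h_branching_interval(self):
        g = nt.build_skeleton_graph(_skel(_h_skeleton(crossbar_steps=40)))
        feats = nt.topology_features(g, roi_area_um2=1e6)
        assert feats.branching_interval_um == pytest.approx(40 * PX)

    def test_single_fragment_normalized_isolated_length(self):
        arr = np.zeros((400, 400), dtype=bool)
        arr[200, 100:131] = True  # 31 px line = 30 steps
        g = nt.build_skeleton_graph(_skel(arr))
        feats = nt.topology_features(g, roi_area_um2=1e6)  # 1 mm^2
        assert feats.normalized_isolated_branch_length == pytest.approx(30 * PX / 1e6)

    def test_missing_branching_interval_warns(self):
        arr = np.zeros((10, 40), dtype=bool)
        arr[5, 5:35] = True
        g = nt.build_skeleton_graph(_skel(arr))
        with pytest.warns(UserWarning, match="branching_interval"):
            feats = nt.topology_features(g, roi_area_um2=1e6)
        assert math.isnan(feats.branching_interval_um)

    def test_phantom_isolated_fraction_recovered(self):
        from pamvasc import synthetic_data as sd

        ratios = []
        for seed in range(4):
            spec = sd.VesselNetworkSpec(seed=seed, isolated_fragment_fraction=0.2)
            mip, _ = sd.generate_vessel_phantom(spec)
            skel = vseg.skeletonize(vseg.binarize(mip))
            g = nt.build_skeleton_graph(skel)
            ratios.append(g.isolated_length_um / g.total_length_um)
        assert np.mean(ratios) == pytest.approx(0.2, rel=0.15)

    def test_area_scaling(self):
        arr = _h_skeleton()
        g = nt.build_skeleton_graph(_skel(arr))
        f1 = nt.topology_features(g, roi_area_um2=1e6)
        f2 = nt.topology_features(g, roi_area_um2=2e6)
        assert f2.n_branches_per_mm2 == pytest.approx(f1.n_branches_per_mm2 / 2, rel=1e-12)
        assert f2.normalized_isolated_branch_length == pytest.approx(
            f1.normalized_isolated_branch_length / 2, rel=1e-12
        )
        assert f2.branching_interval_um == f1.branching_interval_um  # not per-area


class TestRoiArea:
    def test_standard_field(self):
        assert nt.roi_area((1000, 1000), 3.0) == pytest.approx(9e6)  # 9 mm^2

    def test_single_pixel(self):
        assert nt.roi_area((1, 1), 3.0) == pytest.approx(9.0)

    def test_quadratic_in_pixel_size(self):
        assert nt.roi_area((10, 10), 6.0) == 4 * nt.roi_area((10, 10), 3.0)
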