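import numpy as np
import pytest
from scipy import ndimage

import pats
from pats import StructuringElement
from pats.core_ops import (
    bitwise_combine,
    despeckle,
    morphological_operation,
    shrinkwrap_roi,
    threshold_global,
)
from pats.errors import PatsError, SegmentationError

from conftest import make_mask
from oracles import bfs_keep_largest, truth_table_bitwise


class TestThreshold:
    def test_printed_ranges_inclusive(self):
        """The two published ranges share intensity 55: both must keep it."""
        vals = np.array([0, 54, 55, 120, 255], dtype=np.uint8)
        vol = pats.VolumeImage(np.resize(vals, (2, 8, 8)), 35.0)
        body = threshold_global(vol, 55, 255)
        air = threshold_global(vol, 0, 55)
        expect_body = (vol.data >= 55)
        expect_air = (vol.data <= 55)
        np.testing.assert_array_equal(body.data, expect_body)
        np.testing.assert_array_equal(air.data, expect_air)
        # the single overlap value
        assert (body.data & air.data).sum() == (vol.data == 55).sum()

    def test_full_range_all_true(self, small_volume):
        assert threshold_global(small_volume, 0, 255).data.all()

    def test_invalid_range(self, small_volume):
        with pytest.raises(PatsError, match="invalid range"):
            threshold_global(small_volume, 100, 50)

    @pytest.mark.parametrize("cut", [0, 1, 55, 128, 255])
    def test_partition_property(self, small_volume, cut):
        """Masks for [0, t-1] and [t, max] partition the ROI exactly."""
        roi = make_mask(small_volume.data > 30)
        hi = threshold_global(small_volume, cut, 255, roi=roi)
        if cut == 0:
            assert hi.data[roi.data].all()
            return
        lo = threshold_global(small_volume, 0, cut - 1, roi=roi)
        assert not (lo.data & hi.data).any()
        np.testing.assert_array_equal(lo.data | hi.data, roi.data)

    def test_roi_restriction(self, small_volume):
        roi = make_mask(np.zeros(small_volume.shape))
        assert not threshold_global(small_volume, 0, 255, roi=roi).data.any()


class TestBitwise:
    @pytest.mark.parametrize("op", ["AND", "OR", "SUB", "XOR", "NOT_A"])
    def test_truth_table(self, op):
        """Each op matches the exhaustive 4-case truth table."""
        a = make_mask([[[False, False, True, True]]])
        b = make_mask([[[False, True, False, True]]])
        got = bitwise_combine(a, b, op).data[0, 0]
        want = [truth_table_bitwise(x, y, op)
                for x, y in zip([False, False, True, True],
                                [False, True, False, True])]
        assert list(got) == want

    def test_algebra(self, rng):
        a = make_mask(rng.random((4, 8, 8)) > 0.5)
        assert (bitwise_combine(a, a, "AND").data == a.data).all()
        comp = bitwise_combine(a, a, "NOT_A")
        assert not bitwise_combine(a, comp, "AND").data.any()

    def test_shape_mismatch(self):
        with pytest.raises(PatsError, match="shape mismatch"):
            bitwise_combine(make_mask(np.zeros((2, 4, 4))),
                            make_mask(np.zeros((2, 4, 5))), "AND")


class TestDespeckle:
    def test_sweep_matches_bfs_oracle(self, rng):
        """3D sweep equals brute-force BFS labelling on random masks."""
        for _ in range(20):
            data = rng.random((8, 10, 10)) > 0.72
            if not data.any():
                continue
            got = despeckle(make_mask(data), "sweep_keep_largest", "3D").data
            np.testing.assert_array_equal(got, bfs_keep_largest(data, True))

    def test_sweep_two_components(self):
        data = np.zeros((6, 10, 10), dtype=bool)
        data[1, 1:6, 1:3] = True   # 10 voxels
        data[4, 7:10, 7] = True    # 3 voxels
        out = despeckle(make_mask(data), "sweep_keep_largest", "3D").data
        assert out.sum() == 10 and out[1].any() and not out[4].any()

    def test_sweep_single_component_identity(self):
        data = np.zeros((4, 8, 8), dtype=bool)
        data[1:3, 2:5, 2:5] = True
        out = despeckle(make_mask(data), "sweep_keep_largest", "3D").data
        np.testing.assert_array_equal(out, data)

    def test_tie_break_lexicographic(self):
        """Equal sizes: the component with smallest first (z,y,x) voxel wins."""
        data = np.zeros((4, 8, 8), dtype=bool)
        data[2, 4, 4:6] = True   # later in z
        data[1, 1, 1:3] = True   # earlier
        out = despeckle(make_mask(data), "sweep_keep_largest", "3D").data
        assert out[1, 1, 1] and not out[2, 4, 4]
        np.testing.assert_array_equal(out, bfs_keep_largest(data, True))

    def test_empty_raises(self):
        with pytest.raises(SegmentationError, match="no objects"):
            despeckle(make_mask(np.zeros((3, 8, 8))), "sweep_keep_largest")

    def test_remove_white_and_black(self):
        data = np.zeros((3, 12, 12), dtype=bool)
        data[:, 2:8, 2:8] = True          # 3-slice slab object
        data[1, 4:6, 4:6] = False         # 4-voxel enclosed pore
        data[1, 10, 10] = True            # 1-voxel speck
        m = make_mask(data)
        white = despeckle(m, "remove_white_smaller_than", "3D", size_threshold=5)
        assert not white.data[1, 10, 10] and white.data[1, 2, 2]
        black = despeckle(m, "remove_black_smaller_than", "3D", size_threshold=5)
        assert black.data[1, 4:6, 4:6].all()

    def test_sweep_output_connected_subset(self, rng):
        data = rng.random((10, 12, 12)) > 0.7
        out = despeckle(make_mask(data), "sweep_keep_largest", "3D").data
        assert (out & ~data).sum() == 0
        _, n = ndimage.label(out, structure=np.ones((3, 3, 3)))
        assert n == 1


class TestMorphology:
    def test_erosion_square_shrinks(self):
        data = np.zeros((2, 9, 9), dtype=bool)
        data[:, 2:7, 2:7] = True  # 5x5 square per slice
        out = morphological_operation(
            make_mask(data), "erosion", StructuringElement("square", 1, "2D")
        ).data
        assert out.sum() == 2 * 9  # 3x3 per slice
        assert out[:, 3:6, 3:6].all()

    def test_round_erosion_radius1(self):
        data = np.zeros((2, 9, 9), dtype=bool)
        data[:, 2:7, 2:7] = True
        out = morphological_operation(
            make_mask(data), "erosion", StructuringElement("round", 1, "2D")
        ).data
        assert out[:, 3:6, 3:6].all() and out.sum() == 2 * 9

    def test_closing_fills_hole(self):
        """A radius-5 hole inside a radius-20 disc disappears under the
        published radius-40 closing."""
        yy, xx = np.mgrid[0:176, 0:176]
        disc = (yy - 88) ** 2 + (xx - 88) ** 2 <= 20**2
        hole = (yy - 88) ** 2 + (xx - 88) ** 2 <= 5**2
        data = (disc & ~hole)[None].repeat(2, axis=0)
        out = morphological_operation(
            make_mask(data), "closing", StructuringElement("round", 40, "2D")
        ).data
        assert out[0][hole].all()
        assert (out[0] & ~disc).sum() == 0  # no outward growth for a disc

    def test_closing_equals_dilation_then_erosion(self, rng):
        elem = StructuringElement("round", 3, "2D")
        for _ in range(100):
            data = (rng.random((1, 32, 32)) > 0.6)
            m = make_mask(data)
            closed = morphological_operation(m, "closing", elem)
            composed = morphological_operation(
                morphological_operation(m, "dilation", elem), "erosion", elem
            )
            np.testing.assert_array_equal(closed.data, composed.data)

    def test_ordering_and_idempotence(self, rng):
        elem = StructuringElement("round", 2, "2D")
        data = rng.random((3, 24, 24)) > 0.55
        m = make_mask(data)
        ero = morphological_operation(m, "erosion", elem).data
        dil = morphological_operation(m, "dilation", elem).data
        opn = morphological_operation(m, "opening", elem).data
        clo = morphological_operation(m, "closing", elem).data
        assert (ero & ~data).sum() == 0 and (data & ~dil).sum() == 0
        assert (opn & ~data).sum() == 0 and (data & ~clo).sum() == 0
        clo2 = morphological_operation(make_mask(clo), "closing", elem).data
        opn2 = morphological_operation(make_mask(opn), "opening", elem).data
        np.testing.assert_array_equal(clo, clo2)
        np.testing.assert_array_equal(opn, opn2)

    def test_3d_round_element(self):
        data = np.zeros((9, 9, 9), dtype=bool)
        data[4, 4, 4] = True
        out = morphological_operation(
            make_mask(data), "dilation", StructuringElement("round", 2, "3D")
        ).data
        zz, yy, xx = np.mgrid[0:9, 0:9, 0:9]
        ball = (zz - 4) ** 2 + (yy - 4) ** 2 + (xx - 4) ** 2 <= 4
        np.testing.assert_array_equal(out, ball)

    def test_translation_commutation(self, rng):
        """Operators commute with translation away from borders."""
        elem = StructuringElement("round", 2, "2D")
        data = np.zeros((2, 32, 32), dtype=bool)
        data[:, 8:18, 8:18] = rng.random((2, 10, 10)) > 0.4
        shifted = np.roll(data, (3, 4), axis=(1, 2))
        for op in ("erosion", "dilation", "opening", "closing"):
            a = morphological_operation(make_mask(shifted), op, elem).data
            b = np.roll(
                morphological_operation(make_mask(data), op, elem).data,
                (3, 4), axis=(1, 2),
            )
            np.testing.assert_array_equal(a, b)


class TestShrinkwrap:
    def test_convex_identity(self):
        data = np.zeros((2, 20, 20), dtype=bool)
        data[:, 5:15, 5:15] = True
        out = shrinkwrap_roi(make_mask(data), True, 4).data
        np.testing.assert_array_equal(out, data)

    @staticmethod
    def _c_shape(gap):
        """An annulus with a gap of the given width in its top wall."""
        yy, xx = np.mgrid[0:40, 0:40]
        r2 = (yy - 20) ** 2 + (xx - 20) ** 2
        ring = (r2 <= 15**2) & (r2 >= 9**2)
        ring[:20, 20 - gap // 2: 20 - gap // 2 + gap] = False
        return ring[None]

    def test_small_gap_bridged(self):
        """A 3-px opening is bridged at diameter 4: cavity joins the ROI."""
        ring = self._c_shape(3)
        out = shrinkwrap_roi(make_mask(ring), True, 4).data
        assert out[0, 20, 20]

    def test_large_gap_not_bridged(self):
        """An 8-px opening exceeds the bridging diameter: cavity excluded."""
        ring = self._c_shape(8)
        out = shrinkwrap_roi(make_mask(ring), True, 4).data
        assert not out[0, 20, 20]
        assert (ring[0] & ~out[0]).sum() == 0  # still a superset of the ring

    def test_superset_property(self, rng):
        data = rng.random((3, 24, 24)) > 0.8
        if not data.any():
            data[1, 5, 5] = True
        out = shrinkwrap_roi(make_mask(data), True, 4).data
        assert (data & ~out).sum() == 0

    def test_empty_body(self):
        with pytest.raises(SegmentationError, match="nothing to wrap"):
            shrinkwrap_roi(make_mask(np.zeros((2, 8, 8))), True, 4)
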