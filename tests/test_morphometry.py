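import numpy as np
import pytest

import pats
from pats.errors import PatsError, SegmentationError
from pats.morphometry import (
    cohort_correlation,
    compare_rois,
    compute_morphometry,
    marching_cubes_mesh,
    mesh_component_count,
    mesh_is_watertight,
    mesh_volume,
    object_volume,
    structure_linear_density,
    structure_thickness,
)

from conftest import make_mask
from oracles import brute_local_thickness


class TestVolumes:
    def test_closed_form(self):
        data = np.zeros((10, 16, 16), dtype=bool)
        data.ravel()[:1000] = True
        assert object_volume(make_mask(data, 35.0)) == pytest.approx(
            1000 * 0.035**3
        )

    def test_empty(self):
        assert object_volume(make_mask(np.zeros((2, 8, 8)))) == 0.0

    def test_digitized_sphere_within_2pct(self):
        truth = pats.generate_calibration_phantom("sphere", radius=25)
        n = truth.masks["object"].count()
        analytic = 4.0 / 3.0 * np.pi * 25**3
        assert abs(n - analytic) / analytic < 0.02

    def test_bvtv_translation_invariant(self, rng):
        data = np.zeros((8, 16, 16), dtype=bool)
        data[2:5, 3:9, 3:9] = rng.random((3, 6, 6)) > 0.4
        res = compute_morphometry(make_mask(data), additional=False)
        rolled = compute_morphometry(
            make_mask(np.roll(data, (2, 3), axis=(1, 2))), additional=False
        )
        assert res.volume_fraction == pytest.approx(rolled.volume_fraction)
        assert res.volume_fraction == pytest.approx(
            res.object_volume_mm3 / res.total_volume_mm3
        )


class TestStructureThickness:
    def test_slab_recovered_within_one_voxel(self):
        data = np.zeros((30, 16, 16), dtype=bool)
        data[10:20] = True  # 10-voxel slab spanning the volume
        mean_mm, _ = structure_thickness(make_mask(data, 1000.0))
        assert mean_mm == pytest.approx(10.0, abs=1.0)

    def test_single_voxel(self):
        data = np.zeros((3, 8, 8), dtype=bool)
        data[1, 4, 4] = True
        mean_mm, tmap = structure_thickness(make_mask(data, 1000.0))
        assert mean_mm == pytest.approx(1.0)
        assert tmap[1, 4, 4] == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [4, 6, 8])
    def test_sphere_matches_brute_force(self, r):
        """Optimised EDT sphere-painting equals the naive O(n^2) oracle."""
        n = 2 * r + 5
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        c = (n - 1) / 2
        data = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r * r
        mean_mm, tmap = structure_thickness(make_mask(data, 1000.0))
        oracle = brute_local_thickness(data)
        np.testing.assert_allclose(tmap[data], oracle[data], atol=1e-6)
        assert r <= mean_mm <= 2 * r

    def test_slab_thickness_scales_linearly(self):
        means = []
        for t in (6, 12):
            data = np.zeros((40, 12, 12), dtype=bool)
            data[10:10 + t] = True
            mean_mm, _ = structure_thickness(make_mask(data, 1000.0))
            means.append(mean_mm)
        assert means[1] == pytest.approx(2 * means[0], rel=0.15)

    def test_empty_mask(self):
        with pytest.raises(SegmentationError):
            structure_thickness(make_mask(np.zeros((2, 8, 8))))


class TestLinearDensity:
    def test_slab_stack_closed_form(self):
        """5-on/15-off plates at 1 mm voxels: 0.05 per mm along the axis,
        1/L along the in-plane axes."""
        truth = pats.generate_calibration_phantom(
            "slab_stack", thickness=5, gap=15, axis=0
        )
        mask = truth.masks["object"]
        mean, per_axis = structure_linear_density(mask)
        assert per_axis["z"] == pytest.approx(0.05)
        # in-plane test lines inside a slab carry one full-length run, lines
        # in a gap carry none, so the in-plane value is (t/period)/L
        assert per_axis["y"] == pytest.approx((5 / 20) / mask.shape[1])
        assert per_axis["x"] == pytest.approx((5 / 20) / mask.shape[2])
        assert mean == pytest.approx(np.mean(list(per_axis.values())))

    def test_solid_cube_density(self):
        data = np.ones((20, 20, 20), dtype=bool)
        mean, per_axis = structure_linear_density(make_mask(data, 1000.0))
        for v in per_axis.values():
            assert v == pytest.approx(1.0 / 20.0)

    def test_empty_foreground_zero(self):
        mean, per_axis = structure_linear_density(
            make_mask(np.zeros((4, 8, 8)), 1000.0)
        )
        assert mean == 0.0

    def test_empty_voi_raises(self):
        m = make_mask(np.ones((4, 8, 8)))
        with pytest.raises(SegmentationError, match="empty VOI"):
            structure_linear_density(m, voi=make_mask(np.zeros((4, 8, 8))))

    def test_merging_structures_lowers_density(self):
        """Merging two plate stacks into one solid halves-or-lower the run
        count: consolidation reads as lower linear density."""
        data = np.zeros((40, 10, 10), dtype=bool)
        data[np.arange(40) % 10 < 5] = True  # plates
        merged = np.ones((40, 10, 10), dtype=bool)
        _, plates_axes = structure_linear_density(make_mask(data, 1000.0))
        _, solid_axes = structure_linear_density(make_mask(merged, 1000.0))
        assert solid_axes["z"] <= plates_axes["z"] / 2 + 1e-12

    def test_stride_approximates_full(self, rng):
        data = rng.random((16, 24, 24)) > 0.6
        full, _ = structure_linear_density(make_mask(data, 1000.0))
        sub, _ = structure_linear_density(make_mask(data, 1000.0), stride=2)
        assert sub == pytest.approx(full, rel=0.2)


class TestMesh:
    def test_sphere_watertight_and_volume(self):
        truth = pats.generate_calibration_phantom("sphere", radius=20)
        mask = truth.masks["object"]
        mesh = marching_cubes_mesh(mask)
        assert mesh_is_watertight(mesh)
        assert mesh_volume(mesh) == pytest.approx(mask.volume_mm3(), rel=0.05)

    def test_single_voxel(self):
        data = np.zeros((3, 8, 8), dtype=bool)
        data[1, 4, 4] = True
        mesh = marching_cubes_mesh(make_mask(data, 1000.0))
        assert mesh_is_watertight(mesh)
        assert 0.1 < mesh_volume(mesh) <= 1.5  # ~1 voxel at 1 mm

    def test_two_cubes_two_components(self):
        data = np.zeros((10, 16, 16), dtype=bool)
        data[1:4, 1:4, 1:4] = True
        data[6:9, 10:13, 10:13] = True
        mesh = marching_cubes_mesh(make_mask(data))
        assert mesh_component_count(mesh) == 2

    def test_volume_error_shrinks_with_radius(self):
        errs = []
        for r in (10, 20, 40):
            truth = pats.generate_calibration_phantom("sphere", radius=r)
            mask = truth.masks["object"]
            mesh = marching_cubes_mesh(mask)
            errs.append(abs(mesh_volume(mesh) - mask.volume_mm3())
                        / mask.volume_mm3())
        assert errs[0] > errs[1] > errs[2]

    @pytest.mark.parametrize("bad", ["empty", "full"])
    def test_no_surface(self, bad):
        data = np.zeros((3, 8, 8), dtype=bool) if bad == "empty" else \
            np.ones((3, 8, 8), dtype=bool)
        with pytest.raises(SegmentationError, match="no surface"):
            marching_cubes_mesh(make_mask(data))


class TestComparisons:
    def test_identity_and_disjoint(self, rng):
        a = make_mask(rng.random((4, 8, 8)) > 0.5)
        same = compare_rois(a, a)
        assert same.dice == 1.0 and same.jaccard == 1.0
        b = make_mask(~a.data)
        disj = compare_rois(a, b)
        assert disj.dice == 0.0 and disj.jaccard == 0.0

    def test_dice_jaccard_relation(self, rng):
        a = make_mask(rng.random((4, 10, 10)) > 0.4)
        b = make_mask(rng.random((4, 10, 10)) > 0.4)
        c = compare_rois(a, b)
        assert c.dice == pytest.approx(2 * c.jaccard / (1 + c.jaccard))

    def test_both_empty_logged_as_one(self):
        z = make_mask(np.zeros((2, 8, 8)))
        assert compare_rois(z, z).dice == 1.0

    def test_perfect_linearity(self):
        r, r2 = cohort_correlation([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_r_squared_is_r_squared(self, rng):
        x = rng.random(10)
        y = 2 * x + rng.random(10)
        r, r2 = cohort_correlation(x, y)
        assert r2 == pytest.approx(r * r)

    def test_too_short(self):
        with pytest.raises(PatsError):
            cohort_correlation([1, 2], [3, 4])
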