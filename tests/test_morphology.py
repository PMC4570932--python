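"""Object extraction, shape descriptors, fragmentation index, population stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoloc.geometry import coords_to_mask, digital_box, digital_sphere, digital_tube
from mitoloc.morphology import (
    CellMorphology,
    MitoObject,
    centroid,
    compactness,
    distribution_isotropy,
    filter_small,
    fragmentation_index,
    isoperimetric_quotient,
    label_objects,
    population_summary,
    radius_variance,
    relative_volumes,
    sphericity,
    weighted_cell_features,
    voxel_volume,
)
from mitoloc.stacks import BinaryVolume

NEIGHBOURS_6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
NEIGHBOURS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def flood_fill_components(mask, neighbours):
    """Independent connected-components oracle by explicit flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            c = stack.pop()
            comp.append(c)
            for d in neighbours:
                n = tuple(a + b for a, b in zip(c, d))
                if all(0 <= v < s for v, s in zip(n, mask.shape)) and mask[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
        comps.append(frozenset(comp))
    return set(comps)


def _bv(mask):
    return BinaryVolume(mask, (1.0, 1.0, 1.0))


class TestLabeling:
    def test_two_disjoint_cubes(self):
        m = np.zeros((6, 6, 6), bool)
        m[0:2, 0:2, 0:2] = True
        m[4:6, 4:6, 4:6] = True
        comps = label_objects(_bv(m))
        assert sorted(len(c) for c in comps) == [8, 8]

    def test_corner_touching_cubes_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[0:2, 0:2, 0:2] = True
        m[2:4, 2:4, 2:4] = True
        assert len(label_objects(_bv(m), connectivity=26)) == 1
        assert len(label_objects(_bv(m), connectivity=6)) == 2

    def test_full_grid_single_component(self):
        assert len(label_objects(_bv(np.ones((3, 4, 5), bool)))) == 1

    def test_empty_mask_yields_empty_list(self):
        assert label_objects(_bv(np.zeros((3, 3, 3), bool))) == []

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_objects(_bv(np.ones((2, 2, 2), bool)), connectivity=4)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_matches_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        m = r.random((7, 7, 7)) < 0.35
        for conn, nb in ((6, NEIGHBOURS_6), (26, NEIGHBOURS_26)):
            got = {frozenset(map(tuple, c)) for c in label_objects(_bv(m), connectivity=conn)}
            assert got == flood_fill_components(m, nb)

    def test_volume_conservation(self, rng):
        m = rng.random((10, 10, 10)) < 0.3
        spacing = (0.2, 0.1, 0.1)
        comps = label_objects(BinaryVolume(m, spacing))
        total = sum(len(c) for c in comps) * voxel_volume(spacing)
        assert total == pytest.approx(m.sum() * 0.2 * 0.1 * 0.1, abs=0)


class TestVolumeFilter:
    spacing = (0.2, 0.1, 0.1)  # voxel = 0.002 um^3

    def test_threshold_is_strictly_smaller_than(self):
        # exactly 50 voxels = 0.1 um^3 is retained, 49 voxels is not
        objs = [np.zeros((49, 3), int), np.zeros((50, 3), int), np.zeros((100, 3), int)]
        kept = filter_small(objs, self.spacing, min_volume=0.1)
        assert [len(o) for o in kept] == [50, 100]

    def test_zero_threshold_is_identity(self):
        objs = [np.zeros((1, 3), int), np.zeros((7, 3), int)]
        assert filter_small(objs, self.spacing, min_volume=0.0) == objs


class TestCentroidAndCompactness:
    def test_single_voxel_centre_convention(self):
        c = centroid(np.array([[1, 2, 3]]), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(c, [1.5, 2.5, 3.5])

    def test_rod_midpoint(self):
        c = centroid(np.array([[0, 0, 0], [0, 0, 1]]), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(c, [0.5, 0.5, 1.0])

    def test_symmetric_object_centroid_at_centre(self):
        coords = digital_box((3, 3, 3))
        np.testing.assert_allclose(centroid(coords, (2.0, 1.0, 1.0)), [3.0, 1.5, 1.5])

    def test_single_voxel_compactness_zero(self):
        assert compactness(np.array([[0, 0, 0]]), (1, 1, 1)) == 0.0

    def test_ball_more_compact_than_rod_of_equal_volume(self):
        ball = digital_sphere(6.0, (1, 1, 1))
        n = len(ball)
        rod = digital_tube((1.5, 1.5, 2.0), (1.5, 1.5, 2.0 + n / (np.pi * 4)), 2.0, (4, 4, 80))
        assert abs(len(rod) - n) / n < 0.25  # volumes comparable
        assert compactness(ball, (1, 1, 1)) < compactness(rod, (1, 1, 1))

    def test_spacing_scaling_inverse_linear(self):
        coords = digital_sphere(5.0, (1, 1, 1))
        c1 = compactness(coords, (1.0, 1.0, 1.0))
        c2 = compactness(coords, (2.0, 2.0, 2.0))
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)


class TestIsotropy:
    def test_ball_close_to_minimum(self):
        val = distribution_isotropy(digital_sphere(10.0, (1, 1, 1)), (1, 1, 1))
        assert val == pytest.approx(3.0, rel=0.02)

    def test_rod_grows_with_aspect_ratio(self):
        vals = []
        for length in (10, 20, 40):
            rod = digital_tube((4.0, 4.0, 2.0), (4.0, 4.0, 2.0 + length), 2.5, (8, 8, 64))
            vals.append(distribution_isotropy(rod, (1, 1, 1)))
        assert vals[0] > 3.0
        assert vals[0] < vals[1] < vals[2]

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_at_least_three_for_any_object(self, seed):
        r = np.random.default_rng(seed)
        m = r.random((5, 5, 5)) < 0.4
        if m.sum() < 2:
            return
        assert distribution_isotropy(np.argwhere(m), (1, 1, 1)) >= 3.0

    def test_perfect_line_reports_infinity(self):
        coords = np.array([[0, 0, i] for i in range(5)])
        assert math.isinf(distribution_isotropy(coords, (1, 1, 1)))


class TestSphericityAndIPQ:
    def test_analytic_sphere_identities(self):
        v, a = 4 * math.pi / 3, 4 * math.pi
        assert isoperimetric_quotient(v, a) == pytest.approx(1.0, rel=1e-12)
        assert sphericity(v, a) == pytest.approx(1.0, rel=1e-12)

    def test_unit_cube_values(self):
        # independent plug-in evaluation of both formulas for V=1, A=6
        ipq_expected = 1.0 / ((4.0 / 3.0) * math.pi * (6.0 / (4 * math.pi)) ** 1.5)
        sph_expected = math.pi ** (1 / 3) * 6 ** (2 / 3) / 6
        assert isoperimetric_quotient(1.0, 6.0) == pytest.approx(ipq_expected, rel=1e-12)
        assert sphericity(1.0, 6.0) == pytest.approx(sph_expected, rel=1e-12)
        assert sph_expected == pytest.approx(0.80599, abs=1e-5)

    def test_doubling_area_power_law(self):
        assert isoperimetric_quotient(2.0, 8.0) == pytest.approx(
            isoperimetric_quotient(2.0, 4.0) / 2**1.5, rel=1e-12
        )

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(v=st.floats(1e-3, 1e3), a=st.floats(1e-3, 1e3))
    def test_sphericity_cubed_equals_ipq_squared(self, v, a):
        assert sphericity(v, a) ** 3 == pytest.approx(
            isoperimetric_quotient(v, a) ** 2, rel=1e-9
        )

    def test_nonpositive_inputs_rejected(self):
        for f in (isoperimetric_quotient, sphericity):
            with pytest.raises(ValueError):
                f(0.0, 1.0)
            with pytest.raises(ValueError):
                f(1.0, -2.0)


class TestRadiusVariance:
    def test_digital_spheres_converge_to_zero(self):
        normed = []
        for r in (5.0, 10.0, 20.0, 40.0):
            coords = digital_sphere(r, (1, 1, 1))
            normed.append(radius_variance(coords, (1, 1, 1)) / r**2)
        assert all(a > b for a, b in zip(normed, normed[1:]))
        assert normed[-1] < 1e-2

    def test_rod_has_large_variance(self):
        rod = digital_tube((2.0, 2.0, 2.0), (2.0, 2.0, 40.0), 1.5, (4, 4, 44))
        ball = digital_sphere(5.0, (1, 1, 1))
        assert radius_variance(rod, (1, 1, 1)) > radius_variance(ball, (1, 1, 1))


class TestFragmentation:
    def test_relative_volumes(self):
        np.testing.assert_allclose(relative_volumes([3.0, 1.0]), [75.0, 25.0])
        np.testing.assert_allclose(relative_volumes([5.0]), [100.0])
        np.testing.assert_allclose(relative_volumes([1.0] * 10), [10.0] * 10)
        assert relative_volumes(np.arange(1, 8)).sum() == pytest.approx(100.0, rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_volumes([0.0, 0.0])

    @pytest.mark.parametrize(
        "vs, expected",
        [([60, 25, 15, 5], 20.0), ([100], 0.0), ([10] * 10, 100.0), ([80, 20], 20.0)],
    )
    def test_index_from_vs_lists(self, vs, expected):
        assert fragmentation_index(np.array(vs, float)) == expected

    def test_threshold_is_inclusive(self):
        # an object holding exactly the threshold share counts as fragmented
        assert fragmentation_index(np.array([80.0, 20.0]), threshold=20.0) == 20.0


def _obj(area, features, vs=10.0, volume=1.0):
    return MitoObject(0, np.zeros((1, 3), int), (1, 1, 1), volume, area,
                      np.zeros(3), dict(features), vs)


FEATS = {"compactness": 1.0, "isotropy": 3.0, "ipq": 0.5, "sphericity": 0.7,
         "radius_variance": 0.1}


class TestWeightedFeatures:
    def test_constant_feature_preserved(self):
        objs = [_obj(a, FEATS) for a in (1.0, 2.0, 5.0)]
        assert weighted_cell_features(objs)["ipq"] == pytest.approx(0.5)

    def test_two_object_weighting(self):
        objs = [
            _obj(1.0, {**FEATS, "compactness": 0.0}),
            _obj(3.0, {**FEATS, "compactness": 4.0}),
        ]
        assert weighted_cell_features(objs)["compactness"] == pytest.approx(3.0)

    def test_equal_areas_reduce_to_plain_mean(self):
        objs = [_obj(2.0, {**FEATS, "sphericity": v}) for v in (0.2, 0.4, 0.9)]
        assert weighted_cell_features(objs)["sphericity"] == pytest.approx(np.mean([0.2, 0.4, 0.9]))


def _cell(f, vs_list=None):
    vs_list = vs_list if vs_list is not None else [100.0]
    objs = [_obj(1.0, FEATS, vs=v) for v in vs_list]
    return CellMorphology("c", objs, 1.0, f, dict(FEATS))


class TestPopulationSummary:
    def test_mean_and_sem(self):
        s = population_summary([_cell(10.0), _cell(30.0)])
        assert s.mean_f == 20.0
        assert s.sem_f == pytest.approx(10.0)

    def test_identical_cells_zero_sem(self):
        s = population_summary([_cell(5.0)] * 4)
        assert s.sem_f == 0.0

    def test_single_cell_sem_missing(self):
        assert population_summary([_cell(1.0)]).sem_f is None

    def test_histogram_matches_hand_binning(self):
        cells = [_cell(0.0, [55.0, 25.0, 12.0, 8.0]), _cell(0.0, [95.0, 5.0])]
        s = population_summary(cells, bin_width=10.0)
        hand = np.zeros(10)
        for vs in ([55.0, 25.0, 12.0, 8.0], [95.0, 5.0]):
            for v in vs:
                hand[min(int(v // 10), 9)] += v
        np.testing.assert_allclose(s.vs_histogram, hand)
        assert s.vs_histogram.sum() == pytest.approx(200.0)
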