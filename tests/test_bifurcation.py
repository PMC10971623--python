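import math

import numpy as np
import pytest

from aortoiliac import bifurcation as bif
from aortoiliac.errors import (
    GeometryError,
    MissingDataError,
    ParameterError,
    StructureError,
    UndefinedMetricError,
)
from aortoiliac.model import Centerline, CenterlineTree
from aortoiliac.synthetic import make_aortoiliac_tree
from conftest import random_rotation, rigid_transform_tree


def _frame(tree):
    return bif.build_frame(tree)


class TestBranchVector:
    def test_straight_daughter_exact(self):
        d = np.array([0.0, 0.5, -0.8660254037844386])
        pts = np.outer(np.arange(0, 30, 2.0), d)
        v = bif.branch_vector(Centerline(pts), np.zeros(3), 15.0, "away")
        assert np.abs(v - d).max() < 1e-9

    def test_aorta_orientation_toward_origin(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(40, 0, 20)])
        f = bif.branch_vector(Centerline(pts), np.zeros(3), 15.0, "toward")
        assert np.allclose(f, [0, 0, -1], atol=1e-12)

    def test_curved_daughter_near_chord(self):
        # R = 200 arc leaving the origin: fit within 2 degrees of the chord
        R, window = 200.0, 15.0
        theta = np.linspace(0, 0.25, 100)
        pts = np.column_stack([R * np.sin(theta), 0 * theta, -R * (1 - np.cos(theta))])
        v = bif.branch_vector(Centerline(pts), np.zeros(3), window, "away")
        half = window / (2 * R)
        chord = np.array([math.sin(half), 0.0, -(1 - math.cos(half))])
        chord /= np.linalg.norm(chord)
        ang = math.degrees(math.acos(np.clip(np.dot(v, chord), -1, 1)))
        assert ang < 2.0

    def test_too_few_points_in_window(self):
        pts = np.array([[0, 0, 0], [40, 0, 0], [80, 0, 0]])
        with pytest.raises(GeometryError):
            bif.branch_vector(Centerline(pts), np.zeros(3), 15.0, "away")


class TestBuildFrame:
    def test_planar_symmetric_normal(self, symmetric_tree):
        tree, _ = symmetric_tree
        frame = _frame(tree)
        # construction plane is x-z, so n must align with +/- y
        assert abs(abs(frame.n[1]) - 1.0) < 1e-9
        assert abs(np.dot(frame.n, frame.f)) < 1e-9

    def test_parallel_daughters_degenerate(self):
        aorta = Centerline(np.column_stack([np.zeros(20), np.zeros(20), np.linspace(40, 0, 20)]), np.full(20, 8.0))
        d = np.array([0.5, 0.0, -math.sqrt(0.75)])
        pts = np.outer(np.arange(0, 40, 2.0), d)
        left = Centerline(pts, np.full(len(pts), 6.0))
        right = Centerline(pts + [0, 1e-9, 0], np.full(len(pts), 6.0))
        tree = CenterlineTree(
            {"a": aorta, "l": left, "r": right},
            {"a": None, "l": "a", "r": "a"},
            {"a": "aorta", "l": "cia_left", "r": "cia_right"},
        )
        with pytest.raises(GeometryError, match="degenerate"):
            bif.build_frame(tree)

    def test_equivariant_under_rotation(self, symmetric_tree):
        tree, _ = symmetric_tree
        rot = random_rotation(np.random.default_rng(7))
        shift = np.array([12.0, -4.0, 9.0])
        f0 = _frame(tree)
        f1 = _frame(rigid_transform_tree(tree, rot, shift))
        assert np.abs(f1.f - rot @ f0.f).max() < 1e-9
        assert np.abs(f1.v_left - rot @ f0.v_left).max() < 1e-9
        assert np.abs(np.abs(np.dot(f1.n, rot @ f0.n)) - 1.0) < 1e-9

    def test_unlabeled_tree_rejected(self, unlabeled):
        with pytest.raises(StructureError):
            bif.build_frame(unlabeled)


class TestAngles:
    def test_takeoff_recovers_generator(self):
        tree, _ = make_aortoiliac_tree(takeoff_left_deg=30.0, takeoff_right_deg=30.0)
        frame = _frame(tree)
        assert bif.take_off_angle(frame, "left") == pytest.approx(30.0, abs=0.5)

    def test_takeoff_collinear_zero_and_perpendicular_90(self):
        f = np.array([0.0, 0.0, -1.0])
        n = np.array([0.0, 1.0, 0.0])
        v_r = np.array([-math.sin(0.3), 0.0, -math.cos(0.3)])
        frame = bif.BifurcationFrame(np.zeros(3), f, f, v_r, n)
        assert bif.take_off_angle(frame, "left") == pytest.approx(0.0, abs=1e-9)
        frame90 = bif.BifurcationFrame(
            np.zeros(3), f, np.array([1.0, 0.0, 0.0]), v_r, n
        )
        assert bif.take_off_angle(frame90, "left") == pytest.approx(90.0, abs=1e-9)

    def test_bifurcation_angle_sums_takeoffs(self):
        tree, _ = make_aortoiliac_tree(takeoff_left_deg=25.0, takeoff_right_deg=27.0)
        frame = _frame(tree)
        assert bif.bifurcation_angle(frame) == pytest.approx(52.0, abs=0.5)

    def test_mirror_symmetric_doubles_takeoff(self, symmetric_tree):
        tree, _ = symmetric_tree
        frame = _frame(tree)
        assert bif.bifurcation_angle(frame) == pytest.approx(
            2 * bif.take_off_angle(frame, "left"), abs=1e-9
        )

    def test_planar_tree_zero_planarity(self, symmetric_tree):
        tree, _ = symmetric_tree
        frame = _frame(tree)
        assert bif.planarity_angle(frame, "left") == pytest.approx(0.0, abs=1e-6)
        assert bif.planarity_angle(frame, "right") == pytest.approx(0.0, abs=1e-6)

    def test_tilt_recovered(self):
        tree, truth = make_aortoiliac_tree(tilt_left_deg=10.0, tilt_right_deg=10.0)
        frame = _frame(tree)
        assert bif.planarity_angle(frame, "left") == pytest.approx(10.0, abs=0.5)

    def test_planarity_monotone_in_tilt(self):
        vals = []
        for tilt in (10.0, 20.0):
            tree, _ = make_aortoiliac_tree(tilt_left_deg=tilt, tilt_right_deg=tilt)
            vals.append(bif.planarity_angle(_frame(tree), "left"))
        assert vals[1] > vals[0]


class TestAsymmetry:
    def test_symmetric_zero(self):
        assert bif.bifurcation_asymmetry(26.0, 26.0) == 0.0

    def test_formula_and_antisymmetry(self):
        assert bif.bifurcation_asymmetry(30.0, 20.0) == pytest.approx(0.2, abs=1e-12)
        assert bif.bifurcation_asymmetry(20.0, 30.0) == pytest.approx(-0.2, abs=1e-12)

    def test_zero_sum_undefined(self):
        with pytest.raises(UndefinedMetricError):
            bif.bifurcation_asymmetry(0.0, 0.0)


class TestCrossSectionalArea:
    def _branch(self, radii, spacing=5.0):
        n = len(radii)
        pts = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
        return Centerline(pts, np.asarray(radii, dtype=float))

    def test_constant_radius(self):
        cl = self._branch([8.0] * 10)
        a = bif.mean_cross_sectional_area(cl, np.zeros(3), 15.0)
        assert a == pytest.approx(math.pi * 64.0, rel=1e-12)

    def test_three_sample_average(self):
        # radii 4, 5, 6 at the 5/10/15 mm sample distances
        cl = self._branch([3.0, 4.0, 5.0, 6.0, 7.0])
        a = bif.mean_cross_sectional_area(cl, np.zeros(3), 15.0)
        assert a == pytest.approx(math.pi * (16 + 25 + 36) / 3, rel=1e-12)
        assert a == pytest.approx(80.6342, abs=1e-3)

    def test_parent_side_sampling(self):
        # origin at the far end: samples walk backwards along the branch
        cl = self._branch([6.0, 5.0, 4.0, 3.0])
        a = bif.mean_cross_sectional_area(cl, cl.points[-1], 10.0)
        assert a == pytest.approx(math.pi * (16 + 25) / 2, rel=1e-12)

    def test_window_below_spacing_is_geometry_error(self):
        cl = self._branch([8.0] * 10)
        with pytest.raises(GeometryError):
            bif.mean_cross_sectional_area(cl, np.zeros(3), 4.0)

    def test_missing_radii(self):
        cl = Centerline([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        with pytest.raises(MissingDataError):
            bif.mean_cross_sectional_area(cl, np.zeros(3), 15.0)


class TestMurray:
    def test_reference_value(self):
        assert bif.murray_ideal_radius(10.0) == pytest.approx(7.9370052598, abs=1e-9)

    def test_exact_cube(self):
        assert bif.murray_ideal_radius(2.0 ** (1.0 / 3.0)) == pytest.approx(1.0, rel=1e-14)

    def test_defining_identity_random_radii(self):
        rng = np.random.default_rng(42)
        for r in rng.uniform(0.5, 20.0, size=200):
            ri = bif.murray_ideal_radius(r)
            assert 2.0 * ri**3 == pytest.approx(r**3, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            bif.murray_ideal_radius(0.0)


class TestRadiusDiscrepancy:
    def test_zero_iff_ideal(self):
        assert bif.radius_discrepancy(5.5, 5.5, 5.5) == 0.0

    def test_formula(self):
        assert bif.radius_discrepancy(5.0, 6.0, 5.5) == pytest.approx(0.5, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            bif.radius_discrepancy(5.0, -1.0, 5.5)


class TestComputeBifurcationMetrics:
    def test_murray_symmetric_52deg(self):
        tree, truth = make_aortoiliac_tree(takeoff_left_deg=26.0, takeoff_right_deg=26.0)
        m = bif.compute_bifurcation_metrics(tree)
        assert m.bifurcation_angle_deg == pytest.approx(52.0, abs=0.5)
        assert m.asymmetry == pytest.approx(0.0, abs=0.01)
        assert m.r_discrepancy_mm <= 0.01
        assert m.r_aorta_mm == pytest.approx(8.0, abs=1e-9)
        assert m.r_cia_left_mm == pytest.approx(8.0 * 2 ** (-1 / 3), abs=1e-9)

    def test_unlabeled_tree_rejected(self, unlabeled):
        with pytest.raises(StructureError):
            bif.compute_bifurcation_metrics(unlabeled)

    def test_rigid_invariance(self, symmetric_tree):
        tree, _ = symmetric_tree
        m0 = bif.compute_bifurcation_metrics(tree)
        rot = random_rotation(np.random.default_rng(12))
        m1 = bif.compute_bifurcation_metrics(
            rigid_transform_tree(tree, rot, np.array([-30.0, 14.0, 2.0]))
        )
        for f in (
            "takeoff_left_deg",
            "takeoff_right_deg",
            "bifurcation_angle_deg",
            "planarity_left_deg",
            "planarity_right_deg",
            "asymmetry",
            "r_discrepancy_mm",
            "area_aorta_mm2",
        ):
            assert getattr(m1, f) == pytest.approx(getattr(m0, f), abs=1e-6)

    def test_end_to_end_murray_identity(self):
        tree, _ = make_aortoiliac_tree(
            takeoff_left_deg=33.0, takeoff_right_deg=21.0, murray_conforming=True
        )
        m = bif.compute_bifurcation_metrics(tree)
        assert m.r_discrepancy_mm < 1e-6
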