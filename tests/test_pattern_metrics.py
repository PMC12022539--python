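"""Pattern statistics: brute-force oracle agreement, invariances, the
zigzag-vs-parallel contrast, and degenerate-input handling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pavotrain as pt
from pavotrain.errors import (
    EmptyInputError,
    InsufficientPointsError,
    InvalidParameterError,
)
from pavotrain.pattern_metrics import _jitter

from oracles import brute_hexagonality, brute_nn_cv, brute_symmetry_error


def triangular_lattice(n: int = 10) -> np.ndarray:
    """Parallelogram patch of the triangular (densest-packing) lattice."""
    return np.array(
        [[c + 0.5 * r, r * np.sqrt(3) / 2] for r in range(n) for c in range(n)]
    )


def square_grid(n: int = 5) -> np.ndarray:
    g = np.arange(float(n))
    return np.array([[x, y] for y in g for x in g])


class TestHexagonality:
    def test_triangular_lattice_is_perfectly_hexagonal(self):
        assert pt.hexagonality(triangular_lattice(10)) == 1.0

    def test_square_grid_frozen_value(self):
        """5x5 grid under the documented tie-break jitter: 7 of the 9
        interior points end up with degree 6 (frozen brute-force value)."""
        assert pt.hexagonality(square_grid(5)) == pytest.approx(7.0 / 9.0)

    def test_square_grid_matches_oracle_on_jittered_points(self):
        pts = square_grid(5)
        assert pt.hexagonality(pts) == pytest.approx(
            brute_hexagonality(pts, _jitter(pts))
        )

    def test_zigzag_beats_parallel(self, zigzag_pattern, parallel_pattern):
        hz = pt.hexagonality(zigzag_pattern.select("eyespot").xy())
        hp = pt.hexagonality(parallel_pattern.select("eyespot").xy())
        assert hz > hp

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            pt.hexagonality(np.zeros((6, 2)))

    def test_collinear_points_rejected(self):
        pts = np.c_[np.arange(10.0), np.zeros(10)]
        with pytest.raises(InsufficientPointsError):
            pt.hexagonality(pts)

    def test_all_on_hull_rejected(self):
        t = np.linspace(0, 2 * np.pi, 9, endpoint=False)
        with pytest.raises(InsufficientPointsError):
            pt.hexagonality(np.c_[np.cos(t), np.sin(t)])


class TestNnDistanceCv:
    def test_triangular_lattice_uniform(self):
        assert pt.nn_distance_cv(triangular_lattice(10)) <= 1e-9

    def test_two_points(self):
        assert pt.nn_distance_cv(np.array([[0.0, 0.0], [3.0, 4.0]])) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientPointsError):
            pt.nn_distance_cv(np.array([[1.0, 1.0]]))

    def test_zigzag_more_uniform_than_parallel(self, zigzag_pattern, parallel_pattern):
        cz = pt.nn_distance_cv(zigzag_pattern.select("eyespot").xy())
        cp = pt.nn_distance_cv(parallel_pattern.select("eyespot").xy())
        assert cz < cp


class TestSymmetryError:
    def test_constructed_patterns_are_symmetric(self, zigzag_pattern):
        assert pt.symmetry_error(zigzag_pattern.xy(), 90.0) <= 1e-9

    def test_single_point_on_axis(self):
        assert pt.symmetry_error(np.array([[0.0, 2.0]]), 90.0) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(EmptyInputError):
            pt.symmetry_error(np.empty((0, 2)), 90.0)

    def test_displaced_point_matches_direct_computation(self):
        """One point nudged off-mirror: score equals the brute-force
        recomputation of the definition and scales with the nudge."""
        base = np.array(
            [[-2.0, 1.0], [2.0, 1.0], [-1.0, 3.0], [1.0, 3.0], [0.0, 5.0]]
        )
        for delta in (0.05, 0.1):
            pts = base.copy()
            pts[0, 0] -= delta
            got = pt.symmetry_error(pts, 90.0)
            assert got == pytest.approx(brute_symmetry_error(pts, 90.0), rel=1e-12)
            assert got > 0
        assert pt.symmetry_error(base, 90.0) <= 1e-12

    @given(delta=st.floats(min_value=0.01, max_value=0.2))
    def test_oracle_agreement_for_perturbations(self, delta):
        pts = np.array(
            [[-2.0, 1.0], [2.0, 1.0], [-1.0, 3.0], [1.0 + delta, 3.0], [0.0, 5.0]]
        )
        assert pt.symmetry_error(pts, 90.0) == pytest.approx(
            brute_symmetry_error(pts, 90.0), rel=1e-12
        )

    def test_zero_iff_mirror_image(self, rng):
        pts = rng.uniform(-5, 5, (20, 2))
        sym = np.vstack([pts, pts * [-1.0, 1.0]])
        assert pt.symmetry_error(sym, 90.0) <= 1e-12
        assert pt.symmetry_error(pts, 90.0) > 1e-3


class TestRadialLineCount:
    def test_parallel_const_10_has_10_lines(self):
        pattern = pt.expand(pt.build_lattice("parallel_10_10", 18))
        assert pt.radial_line_count(pattern) == 10

    def test_zigzag_alt_has_21_lines(self, zigzag_pattern):
        assert pt.radial_line_count(zigzag_pattern) == 21

    def test_single_row_n_lines(self):
        pattern = pt.expand(pt.build_lattice("zigzag_10_11", 1))
        assert pt.radial_line_count(pattern) == 10

    def test_raw_angles_need_tolerance(self):
        with pytest.raises(InvalidParameterError):
            pt.radial_line_count([0.0, 1.0, 2.0])
        assert pt.radial_line_count([0.0, 1.0, 2.0], angular_tolerance=0.5) == 3
        assert pt.radial_line_count([0.0, 1.0, 2.0], angular_tolerance=10.0) == 1

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(InvalidParameterError):
            pt.radial_line_count([0.0, 1.0], angular_tolerance=0.0)

    def test_full_circle_wraparound_merges(self):
        angles = [0.5, 90.0, 180.0, 270.0, 359.5]
        assert pt.radial_line_count(angles, angular_tolerance=5.0) == 5
        assert (
            pt.radial_line_count(angles, angular_tolerance=5.0, full_circle=True) == 4
        )


class TestInvariances:
    @pytest.mark.parametrize("angle", [17.0, 90.0, 213.0])
    def test_rigid_rotation_and_scaling(self, rng, angle):
        pts = rng.uniform(0, 10, (40, 2))
        t = np.deg2rad(angle)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        moved = 3.7 * pts @ rot.T
        assert pt.hexagonality(moved) == pytest.approx(pt.hexagonality(pts))
        assert pt.nn_distance_cv(moved) == pytest.approx(pt.nn_distance_cv(pts))

    def test_symmetry_error_rotates_with_axis(self, rng):
        pts = rng.uniform(-5, 5, (15, 2))
        sym = np.vstack([pts, pts * [-1.0, 1.0]])
        for angle in (30.0, 120.0):
            t = np.deg2rad(angle - 90.0)
            rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            assert pt.symmetry_error(sym @ rot.T, angle) <= 1e-9


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 51))
            pts = rng.uniform(0, 10, (n, 2))
            assert pt.hexagonality(pts) == pytest.approx(
                brute_hexagonality(pts, _jitter(pts)), abs=1e-12
            )
            assert pt.nn_distance_cv(pts) == pytest.approx(
                brute_nn_cv(pts), rel=1e-12
            )


class TestZigzagParallelSweep:
    @pytest.mark.parametrize("span", [150.0, 180.0, 210.0])
    @pytest.mark.parametrize("radial_pitch", [0.5, 0.75, 1.0])
    def test_ordering_holds_near_display_geometry(self, span, radial_pitch):
        """The zigzag's hexagonality and spacing-uniformity advantages hold
        across fan spans and radial pitches around the natural display fan
        (radial pitch up to about the inner-arc point spacing)."""
        geo = pt.ExpansionGeometry(fan_span=span, radial_pitch=radial_pitch)
        metrics = {}
        for scheme in ("zigzag_10_11", "parallel_10_11"):
            lattice = pt.build_lattice(scheme, 18)
            pattern = pt.classify_feathers(pt.expand(lattice, geo), 4, 2)
            metrics[scheme] = pt.compute_metrics(pattern)
        assert metrics["zigzag_10_11"].hexagonality > metrics["parallel_10_11"].hexagonality
        assert (
            metrics["zigzag_10_11"].nn_distance_cv
            < metrics["parallel_10_11"].nn_distance_cv
        )


class TestComputeMetrics:
    def test_bundle_and_json(self, zigzag_pattern):
        m = pt.compute_metrics(zigzag_pattern)
        d = m.to_dict()
        assert set(d) == {
            "hexagonality", "nn_distance_cv", "symmetry_error",
            "n_radial_lines", "density",
        }
        assert 0.0 <= d["hexagonality"] <= 1.0
        assert d["n_radial_lines"] == 21
        assert all(np.isfinite(v) for v in d.values())

    def test_class_selection_default_excludes_fringe(self, zigzag_pattern):
        m_eye = pt.compute_metrics(zigzag_pattern)
        m_all = pt.compute_metrics(zigzag_pattern, classes=None)
        assert m_eye.density != m_all.density

    def test_compare_schemes_table(self):
        df = pt.compare_schemes(n_rows=18)
        assert len(df) == 4
        assert df.loc[df["scheme"] == "zigzag_10_11", "hexagonality"].iloc[0] == df[
            "hexagonality"
        ].max()
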