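import numpy as np
import pytest

from _oracles import loop_axis_field, loop_centre_field
from vpsolenoid import (
    ConductorPath,
    NearSingularityError,
    SolenoidSpec,
    analytic_loop_axis,
    axial_profile,
    biot_savart_field,
    build_circular_loop,
    build_regular_solenoid,
    build_variable_pitch_solenoid,
)

MM = 1e-3


class TestLoopOracle:
    """Polyline solver against the closed-form circular-loop field."""

    def test_centre_field(self):
        loop = build_circular_loop(17.0, 0.0, 3600)
        fm = biot_savart_field(loop, [[0.0, 0.0, 0.0]])
        assert fm.b1[0] == pytest.approx(loop_centre_field(17.0 * MM), rel=1e-4)
        # 3.696e-5 T for R = 17 mm, I = 1 A
        assert fm.b1[0] == pytest.approx(3.696e-5, rel=1e-3)

    def test_on_axis_field(self):
        loop = build_circular_loop(17.0, 0.0, 3600)
        fm = biot_savart_field(loop, [[0.0, 0.0, 17.0 * MM]])
        # frozen value of mu0 I R^2 / (2 (R^2+z^2)^(3/2)) at R = z = 17 mm
        assert fm.b_vectors[0, 2] == pytest.approx(1.30673e-5, rel=1e-4)
        assert fm.b_vectors[0, 2] == pytest.approx(
            loop_axis_field(17.0 * MM, 17.0 * MM), rel=1e-4
        )

    def test_two_loop_superposition_on_axis(self):
        # field of a coaxial loop pair equals the analytic sum
        d = 10.0 * MM
        up = build_circular_loop(17.0, +10.0, 1800)
        dn = build_circular_loop(17.0, -10.0, 1800)
        z = 4.0 * MM
        total = (
            biot_savart_field(up, [[0, 0, z]]).b_vectors
            + biot_savart_field(dn, [[0, 0, z]]).b_vectors
        )
        expected = loop_axis_field(17.0 * MM, z - d) + loop_axis_field(17.0 * MM, z + d)
        assert total[0, 2] == pytest.approx(expected, rel=1e-4)

    def test_convergence_is_second_order(self):
        # halving the segment length cuts the on-axis error ~4x
        errs = []
        for n in (100, 200, 400, 800):
            loop = build_circular_loop(17.0, 0.0, n)
            got = biot_savart_field(loop, [[0.0, 0.0, 17.0 * MM]]).b_vectors[0, 2]
            errs.append(abs(got - loop_axis_field(17.0 * MM, 17.0 * MM)))
        errs = np.array(errs)
        assert np.all(np.diff(errs) < 0)
        ratios = errs[:-1] / errs[1:]
        assert np.all((ratios > 3.0) & (ratios < 5.0))


class TestAnalyticLoopAxis:
    def test_centre_limit(self):
        r = 0.017
        assert analytic_loop_axis(r, 0.0) == pytest.approx(loop_centre_field(r), rel=1e-15)

    def test_dipole_falloff(self):
        # far field decays as z^-3: B(10R)/B(20R) -> 8; at finite z the
        # exact ratio is ((1+400)/(1+100))^(3/2) = 7.9111
        r = 0.017
        ratio = analytic_loop_axis(r, 10 * r) / analytic_loop_axis(r, 20 * r)
        assert ratio == pytest.approx((401.0 / 101.0) ** 1.5, rel=1e-12)
        assert ratio == pytest.approx(8.0, rel=0.02)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            analytic_loop_axis(-1.0, 0.0)


class TestFieldProperties:
    def test_current_linearity(self, coarse_spec):
        path = build_variable_pitch_solenoid(coarse_spec.with_angles(80.0, 80.0))
        pts = [[2 * MM, 1 * MM, 3 * MM], [0.0, 0.0, 20 * MM]]
        b1 = biot_savart_field(path, pts).b_vectors
        b2 = biot_savart_field(path.with_current(2.0), pts).b_vectors
        assert np.array_equal(b2, 2.0 * b1)

    def test_scale_invariance(self, coarse_spec):
        # scaling geometry by s scales the field at scaled points by 1/s
        s = 2.5
        path = build_variable_pitch_solenoid(coarse_spec.with_angles(40.0, 60.0))
        scaled = ConductorPath(path.vertices * s, current_a=path.current_a)
        pts = np.array([[3 * MM, -2 * MM, 5 * MM], [0.0, 4 * MM, -11 * MM]])
        b = biot_savart_field(path, pts).b_vectors
        bs = biot_savart_field(scaled, pts * s).b_vectors
        assert np.allclose(bs, b / s, rtol=1e-12, atol=0)

    def test_long_solenoid_limit(self):
        # 50 turns, length = 10 diameters: central field ~ mu0 n I
        spec = SolenoidSpec(
            winding_diameter_mm=20.0,
            n_turns=50.0,
            winding_length_mm=200.0,
            segments_per_turn=72,
        )
        path = build_regular_solenoid(spec)
        got = biot_savart_field(path, [[0.0, 0.0, 0.0]]).b1[0]
        mu0 = 4e-7 * np.pi
        expected = mu0 * (50 / 0.2) * 1.0
        assert got == pytest.approx(expected, rel=0.05)

    def test_rotational_symmetry_on_axis(self, paper_spec):
        # rotating the whole helix about its axis leaves |B| on the axis
        # essentially unchanged
        path = build_variable_pitch_solenoid(paper_spec.with_angles(80.0, 80.0))
        ang = np.deg2rad(37.0)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rotated = ConductorPath(path.vertices @ rot.T, current_a=path.current_a)
        pts = np.column_stack(
            (np.zeros(5), np.zeros(5), np.linspace(-20 * MM, 20 * MM, 5))
        )
        b1 = biot_savart_field(path, pts).b1
        b2 = biot_savart_field(rotated, pts).b1
        assert np.allclose(b2, b1, rtol=5e-3)

    def test_engines_agree(self, coarse_spec):
        path = build_variable_pitch_solenoid(coarse_spec.with_angles(80.0, 80.0))
        rng = np.random.default_rng(7)
        pts = rng.uniform(-10 * MM, 10 * MM, size=(50, 3))
        a = biot_savart_field(path, pts, engine="numba").b_vectors
        b = biot_savart_field(path, pts, engine="numpy").b_vectors
        assert np.allclose(a, b, rtol=1e-13, atol=0)

    def test_b1_proxies(self, coarse_spec):
        path = build_variable_pitch_solenoid(coarse_spec)
        pts = [[5 * MM, 3 * MM, -7 * MM]]
        mag = biot_savart_field(path, pts, b1_proxy="magnitude")
        axial = biot_savart_field(path, pts, b1_proxy="axial")
        trans = biot_savart_field(path, pts, b1_proxy="transverse")
        b = mag.b_vectors[0]
        assert mag.b1[0] == pytest.approx(np.linalg.norm(b), rel=1e-15)
        assert axial.b1[0] == pytest.approx(abs(b[2]), rel=1e-15)
        assert trans.b1[0] == pytest.approx(0.5 * np.hypot(b[1], b[2]), rel=1e-15)
        assert axial.b1[0] <= mag.b1[0]

    def test_all_fields_finite(self, coarse_spec):
        path = build_variable_pitch_solenoid(coarse_spec)
        pts = np.column_stack(
            (np.zeros(9), np.zeros(9), np.linspace(-28 * MM, 28 * MM, 9))
        )
        fm = biot_savart_field(path, pts)
        assert np.all(np.isfinite(fm.b_vectors))
        assert np.all(fm.b1 >= 0)


class TestErrorHandling:
    @pytest.mark.parametrize("engine", ["numba", "numpy"])
    def test_near_singular_point_rejected(self, engine):
        loop = build_circular_loop(17.0, 0.0, 360)
        # a point a hundredth of a segment length away from a midpoint
        mid, dl = loop.segments()
        bad = [mid[0] + 0.01 * dl[0]]
        with pytest.raises(NearSingularityError, match="exclusion"):
            biot_savart_field(loop, bad, engine=engine)

    def test_bad_points_shape(self):
        loop = build_circular_loop(17.0, 0.0, 64)
        with pytest.raises(ValueError):
            biot_savart_field(loop, np.zeros((3, 2)))

    def test_unknown_proxy_and_engine(self):
        loop = build_circular_loop(17.0, 0.0, 64)
        with pytest.raises(ValueError, match="b1_proxy"):
            biot_savart_field(loop, [[0, 0, 0]], b1_proxy="nope")
        with pytest.raises(ValueError, match="engine"):
            biot_savart_field(loop, [[0, 0, 0]], engine="gpu")


class TestAxialProfile:
    def test_symmetric_for_regular_solenoid(self, paper_spec):
        prof = axial_profile(build_regular_solenoid(paper_spec), 41, -0.02, 0.02)
        asym = np.abs(prof.b1 - prof.b1[::-1]) / prof.b1.max()
        assert asym.max() < 1e-10

    @pytest.mark.parametrize("angles", [(0.0, 0.0), (80.0, 80.0)])
    def test_peak_at_centre(self, paper_spec, angles):
        path = build_variable_pitch_solenoid(paper_spec.with_angles(*angles))
        prof = axial_profile(path, 57, -0.028, 0.028)
        assert np.argmax(prof.b1) == 28  # middle sample, z = 0

    def test_optimized_profile_flatter_at_edges(self, paper_spec):
        # relative edge amplitude of the optimized coil exceeds the
        # regular solenoid's at every |z| near the edge
        prof0 = axial_profile(build_regular_solenoid(paper_spec), 57, -0.028, 0.028)
        prof8 = axial_profile(
            build_variable_pitch_solenoid(paper_spec.with_angles(80.0, 80.0)),
            57,
            -0.028,
            0.028,
        )
        rel0 = prof0.b1 / prof0.b1[28]
        rel8 = prof8.b1 / prof8.b1[28]
        assert rel8[0] > rel0[0] and rel8[-1] > rel0[-1]

    def test_requires_three_samples(self, coarse_spec):
        path = build_regular_solenoid(coarse_spec)
        with pytest.raises(ValueError):
            axial_profile(path, 2, -0.01, 0.01)
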