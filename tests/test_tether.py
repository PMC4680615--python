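"""Tethered-cell equations of motion, stability and phase portrait."""

import numpy as np
import pytest

from veilflow import tether as te
from veilflow.spheroid import CellGeometry, drag_tensor
from veilflow.wallflow import AmbientFlow

MU = 1e-3


def quiescent():
    return AmbientFlow(np.zeros(3), np.zeros(3), np.zeros((3, 3)))


def make_state(theta, phi, ell):
    return te.TetherState.from_angles(theta, phi, ell)


class TestStalkRate:
    def test_upright_fixed_point(self, uronemella_params):
        state = make_state(0.0, 0.0, 125.0)
        amb = te.cell_ambient(state, uronemella_params)
        np.testing.assert_allclose(
            te.stalk_rate(state, uronemella_params, amb), 0.0, atol=1e-14
        )

    def test_pure_swing_magnitude(self, uronemella_params):
        """With no ambient flow and d perpendicular to r the cell swings
        along its own axis: |dr/dt| = f0 / (6 pi mu a alpha_par l)."""
        p = uronemella_params
        ell = 125.0
        state = te.TetherState(
            stalk_direction=np.array([0.0, 0.0, 1.0]),
            cell_orientation=np.array([1.0, 0.0, 0.0]),
            stalk_length_um=ell,
        )
        rate = te.stalk_rate(state, p, quiescent())
        expected = p.force_pn / (
            6 * np.pi * MU * p.semi_major_um * p.drag.alpha_par * ell
        )
        np.testing.assert_allclose(rate, [expected, 0.0, 0.0], atol=1e-14)

    def test_matches_generic_linear_solve(self, uronemella_params):
        """Independent oracle: solve the anchor force balance + tension
        as a plain 4x4 linear system in (dr/dt, T)."""
        p = uronemella_params
        rng = np.random.default_rng(2)
        for _ in range(5):
            r = rng.normal(size=3)
            r[2] = abs(r[2]) + 0.5
            r /= np.linalg.norm(r)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ell = rng.uniform(50, 300)
            state = te.TetherState(r, d, ell)
            amb = te.cell_ambient(state, p)
            A = drag_tensor(d, p.drag.alpha_par, p.drag.alpha_perp)
            k = 6 * np.pi * MU * p.semi_major_um
            # unknowns x = (rdot, T): k*l*A rdot + T r = f0 d + k A u ; r.rdot = 0
            M = np.zeros((4, 4))
            M[:3, :3] = k * ell * A
            M[:3, 3] = r
            M[3, :3] = r
            b = np.concatenate([p.force_pn * d + k * (A @ amb.velocity), [0.0]])
            x = np.linalg.solve(M, b)
            np.testing.assert_allclose(
                te.stalk_rate(state, p, amb), x[:3], rtol=1e-10, atol=1e-12
            )

    def test_linear_in_force(self, uronemella_params):
        p1 = uronemella_params
        p2 = te.DynamicsParams(
            geometry=p1.geometry, force_pn=2 * p1.force_pn, image_mode=p1.image_mode
        )
        state = te.TetherState(
            np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), 125.0
        )
        r1 = te.stalk_rate(state, p1, quiescent())
        r2 = te.stalk_rate(state, p2, quiescent())
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-12)


class TestOrientationRate:
    def test_quiescent_flow_gives_no_rotation(self, uronemella_params):
        state = make_state(0.7, 0.2, 125.0)
        np.testing.assert_allclose(
            te.orientation_rate(state, uronemella_params, quiescent()), 0.0
        )

    def test_sphere_uniform_flow(self):
        """Sphere in a uniform flow perpendicular to d: |dd/dt| = 3u/(7a)."""
        a = 10.0
        params = te.DynamicsParams(geometry=CellGeometry(a, a), force_pn=40.0)
        state = te.TetherState(
            np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 1.0]), 100.0
        )
        u = np.array([5.0, 0.0, 0.0])
        amb = AmbientFlow(u, np.zeros(3), np.zeros((3, 3)))
        rate = te.orientation_rate(state, params, amb)
        np.testing.assert_allclose(rate, [3 * 5.0 / (7 * a), 0.0, 0.0], rtol=1e-12)

    def test_upright_axisymmetric_fixed_point(self, uronemella_params):
        state = make_state(0.0, 0.0, 125.0)
        amb = te.cell_ambient(state, uronemella_params)
        np.testing.assert_allclose(
            te.orientation_rate(state, uronemella_params, amb), 0.0, atol=1e-14
        )

    def test_rate_tangent_to_orientation(self, uronemella_params):
        rng = np.random.default_rng(8)
        for _ in range(5):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            r = np.array([0.3, -0.1, 1.0])
            r /= np.linalg.norm(r)
            state = te.TetherState(r, d, 125.0)
            amb = te.cell_ambient(state, uronemella_params)
            rate = te.orientation_rate(state, uronemella_params, amb)
            assert abs(rate @ d) < 1e-14 * max(np.linalg.norm(rate), 1.0)


class TestTorqueBalance:
    def test_three_torques_sum_to_zero(self, uronemella_params):
        rng = np.random.default_rng(4)
        for _ in range(5):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            r = np.r_[rng.normal(size=2) * 0.3, 1.0]
            r /= np.linalg.norm(r)
            state = te.TetherState(r, d, rng.uniform(40, 200))
            dec = te.torque_decomposition(state, uronemella_params)
            scale = max(
                np.linalg.norm(dec.translation_drag),
                np.linalg.norm(dec.rotation_drag),
                np.linalg.norm(dec.strain_torque),
            )
            assert np.linalg.norm(dec.residual) < 1e-9 * scale


class TestPolarRate:
    def test_zero_at_upright(self, uronemella_params):
        assert te.polar_rate(0.0, 0.0, uronemella_params, 125.0) == 0.0

    def test_zero_when_stalk_flat(self, uronemella_params):
        assert te.polar_rate(0.4, np.pi / 2, uronemella_params, 125.0) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_sign_flips_with_stalk_length(self, uronemella_params):
        a = uronemella_params.semi_major_um
        assert te.polar_rate(0.01, 0.0, uronemella_params, 0.01 * a) > 0
        assert te.polar_rate(0.01, 0.0, uronemella_params, 100 * a) < 0

    def test_sign_agrees_with_full_reduction_for_long_stalks(self, uronemella_params):
        """The single-angle closed form and the full coplanar reduction
        are both restoring (negative) above the critical length; their
        magnitudes differ by the closed form's timescale convention."""
        ell = 10 * uronemella_params.semi_major_um
        for theta in (0.2, 0.6, 1.0):
            closed = te.polar_rate(theta, 0.0, uronemella_params, ell)
            full = te.reduced_rates(theta, 0.0, uronemella_params, ell)[0]
            assert closed < 0 and full < 0


class TestIntegration:
    def test_stationary_at_fixed_point(self, uronemella_params):
        ell = 125.0
        traj = te.integrate(
            make_state(0.0, 0.0, ell), uronemella_params, duration_s=5.0
        )
        assert np.max(traj.theta) < 1e-6
        assert np.max(traj.phi) < 1e-6

    def test_righting_from_tilt(self, uronemella_params):
        """A cell tilted to theta = phi = 0.3 with l = 10 a rights itself."""
        ell = 10 * uronemella_params.semi_major_um
        _, tau_s = te.timescales(uronemella_params, ell)
        traj = te.integrate(
            make_state(0.3, 0.3, ell), uronemella_params, duration_s=15 * tau_s
        )
        assert traj.theta[-1] < 1e-3
        assert traj.phi[-1] < 1e-3

    def test_norm_conservation(self, uronemella_params):
        ell = 10 * uronemella_params.semi_major_um
        _, tau_s = te.timescales(uronemella_params, ell)
        traj = te.integrate(
            make_state(1.0, 0.2, ell),
            uronemella_params,
            duration_s=20 * tau_s,
            n_out=500,
        )
        for vecs in (traj.stalk_direction, traj.cell_orientation):
            norms = np.linalg.norm(vecs, axis=1)
            assert np.max(np.abs(norms - 1.0)) < 1e-8
        # the renormalization only polishes: raw drift stays near rtol
        assert traj.max_norm_drift < 1e-6

    def test_rotational_symmetry_about_wall_normal(self, uronemella_params):
        """Rotating the initial condition about e3 rotates the whole
        trajectory by the same angle."""
        ell = 10 * uronemella_params.semi_major_um
        _, tau_s = te.timescales(uronemella_params, ell)
        base = te.integrate(
            make_state(0.5, 0.3, ell), uronemella_params, duration_s=2 * tau_s, n_out=50
        )
        for az in (0.9, 2.2, -1.3):
            c, s = np.cos(az), np.sin(az)
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            rot = te.integrate(
                te.TetherState(
                    R @ base.stalk_direction[0], R @ base.cell_orientation[0], ell
                ),
                uronemella_params,
                duration_s=2 * tau_s,
                n_out=50,
            )
            np.testing.assert_allclose(
                rot.stalk_direction, base.stalk_direction @ R.T, atol=1e-6
            )
            np.testing.assert_allclose(
                rot.cell_orientation, base.cell_orientation @ R.T, atol=1e-6
            )


class TestCriticalLength:
    @pytest.mark.parametrize(
        "aspect, expected", [(1.3, 0.26), (2.0, 0.44), (1.0, 0.0)]
    )
    def test_closed_form_ratio(self, aspect, expected):
        geom = CellGeometry.from_aspect_ratio(aspect, 10.0)
        params = te.DynamicsParams(geometry=geom)
        ratio = te.critical_length(params.drag, geom) / geom.semi_major_um
        assert round(ratio, 2) == expected

    def test_stability_flips_across_a_crossing_length(self, uronemella_params):
        a = uronemella_params.semi_major_um
        rep_long = te.linear_stability(uronemella_params, 10 * a)
        origin_long = rep_long.fixed_points[0]
        assert origin_long.classification == "stable"
        rep_short = te.linear_stability(uronemella_params, 0.01 * a)
        origin_short = rep_short.fixed_points[0]
        assert np.max(origin_short.eigenvalues.real) > 0
        ell_star = te.eigenvalue_crossing_length(uronemella_params, 0.01 * a, 10 * a)
        assert 0.01 * a < ell_star < 10 * a
        # the numerical crossing is the same order as the closed form;
        # the two linearizations differ by the swing/orientation coupling
        lc = te.critical_length(uronemella_params.drag, uronemella_params.geometry)
        assert 0.2 < ell_star / lc < 2.0

    def test_inverted_cell_is_unstable(self, uronemella_params):
        rep = te.linear_stability(uronemella_params, 10 * uronemella_params.semi_major_um)
        inverted = rep.fixed_points[1]
        assert inverted.classification in ("unstable", "saddle")


class TestTimescales:
    def test_printed_estimates(self):
        params = te.DynamicsParams(
            geometry=CellGeometry.from_aspect_ratio(1.3, 10.0), force_pn=40.0
        )
        tau_f, tau_s = te.timescales(params, 100.0)
        assert tau_f == pytest.approx(0.47, abs=0.01)
        assert tau_s == pytest.approx(6.28, abs=0.01)
        assert tau_f / tau_s == pytest.approx(0.075, rel=1e-12)

    def test_ratio_scaling(self, uronemella_params):
        a = uronemella_params.semi_major_um
        for lov in (5.0, 20.0):
            tau_f, tau_s = te.timescales(uronemella_params, lov * a)
            assert tau_f / tau_s == pytest.approx(0.75 / lov, rel=1e-12)


class TestPhasePortrait:
    def test_field_mirror_symmetry(self, uronemella_params):
        ell = 10 * uronemella_params.semi_major_um
        pp = te.phase_portrait(
            uronemella_params, ell, n_theta=11, n_phi=7, compute_basin=False
        )
        # (theta, phi) -> (-theta, -phi) flips both rates
        np.testing.assert_allclose(pp.dtheta, -pp.dtheta[::-1, ::-1], atol=1e-10)
        np.testing.assert_allclose(pp.dphi, -pp.dphi[::-1, ::-1], atol=1e-10)

    def test_fixed_point_census(self, uronemella_params):
        """One stable point at the origin, two unstable spirals near the
        basin corners (stalk nearly flat), and the inverted-cell saddle."""
        ell = 10 * uronemella_params.semi_major_um
        pp = te.phase_portrait(
            uronemella_params, ell, n_theta=15, n_phi=7, compute_basin=False
        )
        by_kind = {}
        for f in pp.fixed_points:
            by_kind.setdefault(f.classification, []).append(f)
        assert len(by_kind["stable"]) == 1
        stable = by_kind["stable"][0]
        assert abs(stable.theta) < 1e-6 and abs(stable.phi) < 1e-6
        unstable = by_kind["unstable"]
        assert len(unstable) == 2
        for f in unstable:
            assert abs(f.theta) > np.pi / 2  # outside the basin strip
            assert np.sign(f.theta) == -np.sign(f.phi)
        saddles = by_kind["saddle"]
        assert len(saddles) == 1
        assert abs(abs(saddles[0].theta) - np.pi) < 1e-6

    def test_integration_matches_portrait_fixed_point(self, uronemella_params):
        """The stationary state of the 3-D integrator coincides with the
        portrait's stable fixed point at the origin."""
        ell = 10 * uronemella_params.semi_major_um
        _, tau_s = te.timescales(uronemella_params, ell)
        traj = te.integrate(
            make_state(0.2, 0.1, ell), uronemella_params, duration_s=20 * tau_s
        )
        pp = te.phase_portrait(
            uronemella_params, ell, n_theta=9, n_phi=5, compute_basin=False
        )
        stable = next(f for f in pp.fixed_points if f.classification == "stable")
        assert np.hypot(traj.theta[-1] - stable.theta, traj.phi[-1] - stable.phi) < 1e-3
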