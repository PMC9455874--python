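import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.optimize import fsolve

from phagospread import constitutive as law
from phagospread.constitutive import PhysicalParams
from phagospread.exceptions import InvalidArgumentError
from phagospread.geometry import init_spherical_cap, measure_contour


class TestCorticalTension:
    def test_printed_branch_values(self, params):
        A0 = params.area0
        assert law.cortical_tension(A0, A0, params, smoothed=False) == pytest.approx(0.01)
        assert law.cortical_tension(1.26 * A0, A0, params, smoothed=False) == \
            pytest.approx(0.0516)
        assert law.cortical_tension(1.5 * A0, A0, params, smoothed=False) == \
            pytest.approx(0.0516 + 0.545 * 0.24)

    def test_knee_continuity(self, params):
        A0 = params.area0
        below = law.cortical_tension((1.26 - 1e-12) * A0, A0, params, smoothed=False)
        above = law.cortical_tension((1.26 + 1e-12) * A0, A0, params, smoothed=False)
        assert below == pytest.approx(above, abs=1e-9)

    def test_below_rest_clamps(self, params):
        A0 = params.area0
        assert law.cortical_tension(0.9 * A0, A0, params) == pytest.approx(0.01)

    def test_nonpositive_area_raises(self, params):
        with pytest.raises(InvalidArgumentError):
            law.cortical_tension(-1.0, params.area0, params)

    def test_smoothed_close_and_c1(self, params):
        A0 = params.area0
        x = np.linspace(1.0, 1.6, 20001)
        sm = law.cortical_tension(x * A0, A0, params)
        pw = law.cortical_tension(x * A0, A0, params, smoothed=False)
        # within k2 * smoothing_width of the piecewise law everywhere
        assert np.max(np.abs(sm - pw)) <= params.k2 * params.smoothing_width + 1e-12
        # C1: numerical slope has no jumps beyond the grid scale
        slope = np.diff(sm) / np.diff(x)
        assert np.max(np.abs(np.diff(slope))) < 1e-2

    def test_constructor_rejects_discontinuous_knee(self):
        with pytest.raises(InvalidArgumentError):
            PhysicalParams(tau_b=0.06)


class TestCorticalStress:
    def test_sphere_laplace(self, sphere_contour):
        stress = law.cortical_stress(sphere_contour, tau=0.01)
        mag = np.hypot(stress[:, 0], stress[:, 1])
        expected = 0.01 * 1000.0 * 2.0 / 4.25  # τ·2/R in Pa
        assert np.allclose(mag, expected, rtol=0.02)
        # inward: at the apex the stress points in −z
        assert stress[0, 1] < 0

    def test_linearity_in_tau(self, sphere_contour):
        s1 = law.cortical_stress(sphere_contour, tau=0.01)
        s2 = law.cortical_stress(sphere_contour, tau=0.02)
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)

    def test_flat_region_zero(self):
        # contour with a long flat (z = const) free segment: curvature → 0
        from phagospread.geometry import CellContour
        n = 30
        r_flat = np.linspace(1.0, 3.0, n)
        r = np.concatenate([[0.0], [0.5], r_flat, [3.3, 3.4], [2.0, 0.0]])
        z = np.concatenate([[2.2], [2.0], np.full(n, 2.0), [1.0, 0.0], [0.0, 0.0]])
        c = CellContour(r, z, contact_index=len(r) - 2)
        stress = law.cortical_stress(c, tau=0.01)
        mid = slice(8, n - 6)
        mag = np.hypot(stress[mid, 0], stress[mid, 1])
        assert np.all(mag < 1e-6)


class TestAdhesionStress:
    def test_kernel_zero_at_D0(self, params):
        # pair kernel vanishes at D = D0 → stress at the well crossing ≈ 0
        z_star = 0.5 ** (1.0 / 3.0) * params.D0
        s = law.bare_plane_adhesion_stress(z_star, 1.0, params)
        peak = abs(law.bare_plane_adhesion_stress(1.0772 * params.D0, 1.0, params))
        assert abs(s) < 1e-6 * peak + 1e-12

    def test_far_node_negligible(self, params):
        # the attractive tail decays as z⁻²: far separations are negligible
        near = abs(law.bare_plane_adhesion_stress(params.D0, 1.0, params))
        assert abs(law.bare_plane_adhesion_stress(50 * params.D0, 1.0, params)) < 1e-2 * near
        assert abs(law.bare_plane_adhesion_stress(200 * params.D0, 1.0, params)) < 1e-4 * near

    def test_bare_plane_attractive_and_matches_bruteforce(self, params):
        """Node at 2 D0 above an uncontacted plane: net downward stress,
        cross-checked against a brute-force 2-D quadrature oracle."""
        D0 = params.D0
        z_p = 2.0 * D0
        scale = 1.0

        def integrand_z(psi, rho):
            D = np.sqrt(rho**2 + z_p**2)
            k = (D0 / D) ** 7 - (D0 / D) ** 4
            return (z_p / D) * k * rho

        # axisymmetric: azimuth integrates to 2π
        val, err = dblquad(integrand_z, 0.0, 60.0 * D0,
                           lambda _: 0.0, lambda _: 2.0 * np.pi, epsabs=1e-12)
        oracle = scale * val
        package = law.bare_plane_adhesion_stress(z_p, scale, params)
        assert package < 0  # attraction pulls toward the substrate
        assert package == pytest.approx(oracle, rel=0.01)

    def test_contour_stress_linear_in_scale(self, cap_contour, params):
        s1 = law.adhesion_stress(cap_contour, params, scale=100.0)
        s2 = law.adhesion_stress(cap_contour, params, scale=200.0)
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)

    def test_contour_stress_vanishes_far_from_contact(self, cap_contour, params):
        s = law.adhesion_stress(cap_contour, params, scale=1e5)
        # apex is ~8 μm above the substrate: no appreciable stress there
        assert np.hypot(*s[0]) < 1e-8 * np.max(np.hypot(s[:, 0], s[:, 1]))

    def test_disc_subtraction_against_bruteforce(self, params):
        """Exterior-plane integral for a point near the contact line against
        a direct 2-D quadrature over the uncontacted substrate."""
        D0 = params.D0
        r_c = 1.0
        r_p, z_p = 1.02, 0.5 * D0

        def kern(psi, rho):
            D2 = r_p**2 + rho**2 - 2 * r_p * rho * np.cos(psi) + z_p**2
            D = np.sqrt(D2)
            return ((D0 / D) ** 7 - (D0 / D) ** 4) * (z_p / D) * rho

        val, _ = dblquad(kern, r_c, r_c + 80 * D0, 0.0, np.pi,
                         epsabs=1e-11, epsrel=1e-9)
        oracle_z = 2.0 * val
        plane = law._plane_stress_z(z_p, D0)
        disc_r, disc_z = law._disc_integral(r_p, z_p, r_c, D0)
        assert plane - disc_z == pytest.approx(oracle_z, rel=0.02)


class TestProtrusionMagnitude:
    def test_printed_branch_values(self, params):
        A_trans = 100.0
        assert law.protrusion_magnitude(0.0, A_trans, 1.0, params, smoothed=False) == \
            pytest.approx(0.05 * 3500.0)
        assert law.protrusion_magnitude(A_trans, A_trans, 1.3, params, smoothed=False) == \
            pytest.approx(0.35 * 3500.0)
        assert law.protrusion_magnitude(A_trans + 130.0, A_trans, 1.5, params,
                                        smoothed=False) == pytest.approx(3500.0)

    def test_saturation_from_printed_formula(self, params):
        A_trans = 100.0
        val = law.protrusion_magnitude(A_trans + 120.0, A_trans, 1.5, params,
                                       smoothed=False)
        assert val == pytest.approx((0.35 + 0.65) * 3500.0)

    def test_monotone_and_bounded(self, params):
        A_trans = 104.0
        A = np.linspace(0.0, 300.0, 400)
        # area ratio grows with contact area in a real run
        ratio = 1.0 + 0.6 * A / 300.0
        vals = law.protrusion_magnitude(A, A_trans, ratio, params)
        assert np.all(np.diff(vals) > -1e-9)
        assert np.all(vals >= 0.05 * 3500.0 - 1e-9)
        assert np.all(vals <= 3500.0 + 1e-9)

    def test_negative_area_raises(self, params):
        with pytest.raises(InvalidArgumentError):
            law.protrusion_magnitude(-1.0, 100.0, 1.0, params)


class TestProtrusionProfile:
    def test_decay_values(self, cap_contour, params):
        sigma = 1000.0
        prof = law.protrusion_profile(cap_contour, sigma, params)
        mag = np.hypot(prof[:, 0], prof[:, 1])
        s = cap_contour.s[: cap_contour.n_free]
        sc = cap_contour.s_contact
        np.testing.assert_allclose(mag, sigma * np.exp(-(sc - s) / params.s0),
                                   rtol=1e-9)
        # full magnitude at the contact line
        assert mag[-1] == pytest.approx(sigma, rel=1e-9)

    def test_one_decay_length(self, cap_contour, params):
        sigma = 1000.0
        prof = law.protrusion_profile(cap_contour, sigma, params)
        s = cap_contour.s[: cap_contour.n_free]
        i = np.argmin(np.abs((cap_contour.s_contact - s) - params.s0))
        mag = np.hypot(prof[i, 0], prof[i, 1])
        expected = sigma * np.exp(-(cap_contour.s_contact - s[i]) / params.s0)
        assert mag == pytest.approx(expected, rel=1e-9)
        assert mag == pytest.approx(sigma / np.e, rel=0.05)

    def test_outward_normal_direction(self, cap_contour, params):
        prof = law.protrusion_profile(cap_contour, 1000.0, params)
        # near the contact line the outward normal has positive r component
        assert prof[-2, 0] > 0


class TestProtrusionDecay:
    def test_identity_at_bind_time(self, params):
        assert law.protrusion_decay(500.0, 10.0, 10.0, params) == pytest.approx(500.0)

    def test_one_time_constant(self, params):
        assert law.protrusion_decay(500.0, 10.0 + params.t0, 10.0, params) == \
            pytest.approx(500.0 / np.e)

    def test_reference_t0_is_66s(self, params):
        assert params.t0 == 66.0
        assert law.protrusion_decay(1.0, 66.0, 0.0, params) == pytest.approx(1 / np.e)

    def test_preceding_time_raises(self, params):
        with pytest.raises(InvalidArgumentError):
            law.protrusion_decay(500.0, 5.0, 10.0, params)


class TestFluctuationThreshold:
    def test_resting_tension_about_18nm(self, params):
        tau_rest = law.cortical_tension(params.area0, params.area0, params)
        d = law.fluctuation_threshold(tau_rest, params.area0, params)
        assert d == pytest.approx(18.0, rel=0.15)

    def test_high_tension_about_2nm(self, params):
        d = law.fluctuation_threshold(1.0, params.area0, params)
        assert 1.0 < d < 3.0

    def test_sqrt_kBT_scaling(self, params):
        hot = PhysicalParams(T=2.0 * params.T)
        ratio = law.fluctuation_threshold(0.01, params.area0, hot) / \
            law.fluctuation_threshold(0.01, params.area0, params)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_decreasing_in_tension(self, params):
        taus = np.logspace(-2, 1, 50)
        vals = [law.fluctuation_threshold(t, params.area0, params) for t in taus]
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_tension_raises(self, params):
        with pytest.raises(InvalidArgumentError):
            law.fluctuation_threshold(0.0, params.area0, params)


class TestAdhesionEnergyDensity:
    def test_binding_energy_about_14_kBT(self, params):
        assert params.E_bind == pytest.approx(-np.log(1e-6))
        assert round(params.E_bind) == 14

    def test_high_density(self, params):
        assert law.adhesion_energy_density(25000.0, params) == \
            pytest.approx(1500.0, rel=0.05)

    def test_low_density(self, params):
        assert law.adhesion_energy_density(44.0, params) == pytest.approx(2.6, rel=0.05)

    def test_zero(self, params):
        assert law.adhesion_energy_density(0.0, params) == 0.0

    def test_negative_raises(self, params):
        with pytest.raises(InvalidArgumentError):
            law.adhesion_energy_density(-1.0, params)


class TestYoungDupre:
    def test_right_angle_gives_gamma_equals_tau(self, params):
        """θ_c = 90° (hemisphere): γ = τ·(1 − cos 90°) = τ."""
        # hemisphere of the cell volume: a = (2V/ (2π/3))^(1/3)
        R = (3.0 * params.volume0 / (2.0 * np.pi)) ** (1.0 / 3.0)
        A_c = np.pi * R**2
        theta, A_cell, tau, gamma = law.young_dupre_equilibrium(A_c, params.volume0, params)
        assert theta == pytest.approx(np.pi / 2.0, rel=1e-9)
        assert gamma == pytest.approx(tau * 1000.0, rel=1e-9)  # mN/m → μJ/m²

    def test_vanishing_contact(self, params):
        _, _, _, gamma = law.young_dupre_equilibrium(1e-6, params.volume0, params)
        assert gamma < 1e-3

    def test_against_independent_cap_solver(self, params):
        """Cap geometry for (A_c, V) = (100 μm², cell volume) against an
        independent nonlinear solve of the cap equations."""
        V = params.volume0
        A_c = 100.0
        a = np.sqrt(A_c / np.pi)

        def equations(x):
            R, h = x
            return [np.pi * h**2 * (R - h / 3.0) - V,
                    a**2 - h * (2.0 * R - h)]

        R0 = params.cell_diameter / 2.0
        (R_or, h_or), info, ier, _ = fsolve(equations, [R0, 1.5 * R0],
                                            full_output=True)
        assert ier == 1
        theta_or = np.arccos(h_or / R_or - 1.0)
        A_cell_or = 2.0 * np.pi * R_or * h_or + A_c
        theta, A_cell, tau, gamma = law.young_dupre_equilibrium(A_c, V, params)
        assert theta == pytest.approx(theta_or, rel=1e-6)
        assert A_cell == pytest.approx(A_cell_or, rel=1e-6)
        tau_or = law.cortical_tension(A_cell_or, params.area0, params, smoothed=False)
        assert gamma == pytest.approx(tau_or * (1 - np.cos(theta_or)) * 1000.0, rel=1e-6)

    def test_forward_inverse_roundtrip(self, params):
        for A_c in (20.0, 60.0, 120.0, 200.0):
            gamma = law.young_dupre_equilibrium(A_c, params.volume0, params)[3]
            back = law.young_dupre_contact_area(gamma, params.volume0, params)
            assert back == pytest.approx(A_c, rel=1e-8)

    def test_inverse_monotone(self, params):
        gammas = np.linspace(10.0, 400.0, 12)
        areas = [law.young_dupre_contact_area(g, params.volume0, params) for g in gammas]
        assert np.all(np.diff(areas) > 0)

    def test_invalid_contact_area_raises(self, params):
        with pytest.raises(InvalidArgumentError):
            law.young_dupre_equilibrium(-5.0, params.volume0, params)


class TestAdhesionCalibration:
    def test_energy_roundtrip(self, params):
        gamma = 150.0
        scale = law.adhesion_scale_from_energy(gamma, params.D0)
        assert law.adhesion_well_energy(scale, params.D0) == pytest.approx(gamma)

    def test_well_energy_matches_integrated_attraction(self, params):
        """γ equals the work of the plane attraction from the well minimum
        (z where the net stress crosses zero) out to infinity."""
        from scipy.integrate import quad
        scale = 1.0
        z_min = 0.5 ** (1 / 3) * params.D0
        work, _ = quad(lambda z: -law.bare_plane_adhesion_stress(z, scale, params),
                       z_min, np.inf, limit=400)
        assert work == pytest.approx(law.adhesion_well_energy(scale, params.D0),
                                     rel=1e-3)
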