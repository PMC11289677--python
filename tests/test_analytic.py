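"""Closed-form theory: boundary conditions, flux law, run statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

from greedychemo import DivergentStatisticsError, ModelParams, analytic


def random_unit_vectors(rng, n):
    x = rng.normal(size=(n, 3))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


class TestCueDensity:
    def test_vanishes_on_cell_surface(self, rng, params_eps5):
        """Perfect absorption: the density is zero everywhere on |x| = a."""
        rs_vec = np.array([3.0, 0.0, 0.0])
        pts = params_eps5.a * random_unit_vectors(rng, 20)
        rho = analytic.cue_density(pts, rs_vec, params_eps5)
        scale = params_eps5.alpha / (4 * np.pi * params_eps5.D)
        assert np.all(np.abs(rho) < 1e-12 * scale)

    def test_decays_to_zero_far_away(self, params_eps5):
        rs_vec = np.array([3.0, 0.0, 0.0])
        radii = np.array([1e2, 1e4, 1e6])
        pts = np.outer(radii, [0.0, 1.0, 0.0])
        rho = analytic.cue_density(pts, rs_vec, params_eps5)
        assert np.all(np.diff(rho) < 0)
        assert rho[-1] < 1e-7

    def test_harmonic_away_from_sources(self, params_eps5):
        """The steady-state density solves Laplace's equation off-source."""
        rs_vec = np.array([3.0, 0.0, 0.0])
        x0 = np.array([1.7, 1.1, -0.6])
        h = 1e-3
        lap = 0.0
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = h
            lap += (
                analytic.cue_density(x0 + e, rs_vec, params_eps5)
                + analytic.cue_density(x0 - e, rs_vec, params_eps5)
                - 2 * analytic.cue_density(x0, rs_vec, params_eps5)
            ) / h**2
        scale = analytic.cue_density(x0, rs_vec, params_eps5)
        assert abs(lap) < 1e-6 * scale / h  # O(h^2) stencil error allowance

    def test_rejects_interior_and_source_points(self, params_eps5):
        rs_vec = np.array([3.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            analytic.cue_density([0.5, 0.0, 0.0], rs_vec, params_eps5)
        with pytest.raises(ValueError):
            analytic.cue_density(rs_vec, rs_vec, params_eps5)


class TestImageCharge:
    def test_strength_and_position(self):
        p = ModelParams(a=1.0, v=1.0, alpha=1.0, D=1.0)
        img = analytic.image_charge(2.0, p)
        assert img.strength == pytest.approx(-0.5)
        assert img.position == pytest.approx(0.5)

    def test_vanishes_in_far_source_limit(self):
        p = ModelParams(a=1.0, v=1.0, alpha=1.0, D=1.0)
        img = analytic.image_charge(1e12, p)
        assert abs(img.strength) < 1e-11
        assert img.position < 1e-11

    def test_source_inside_cell_rejected(self, params_eps5):
        with pytest.raises(ValueError):
            analytic.image_charge(0.5, params_eps5)


class TestSurfaceFlux:
    def test_independent_of_diffusivity(self):
        kw = dict(a=1.0, v=0.1, alpha=0.5)
        j1 = analytic.surface_flux(1.0, 3.0, ModelParams(D=1.0, **kw))
        j2 = analytic.surface_flux(1.0, 3.0, ModelParams(D=100.0, **kw))
        assert j1 == j2

    def test_integrates_to_total_rate(self, params_eps5):
        for rs in (1.5, 3.0, 20.0, 500.0):
            total, _ = quad(
                lambda ph: float(analytic.surface_flux(ph, rs, params_eps5))
                * 2 * np.pi * params_eps5.a**2 * np.sin(ph),
                0.0, np.pi,
            )
            assert total == pytest.approx(
                analytic.total_arrival_rate(rs, params_eps5), rel=1e-9
            )

    def test_pole_ratio(self, params_eps5):
        a = params_eps5.a
        for rs in (1.2, 2.0, 7.0):
            ratio = float(analytic.surface_flux(0.0, rs, params_eps5)
                          / analytic.surface_flux(np.pi, rs, params_eps5))
            assert ratio == pytest.approx(((rs + a) / (rs - a)) ** 3, rel=1e-12)

    def test_total_rate_examples(self):
        p = ModelParams(a=1.0, v=1.0, alpha=10.0, D=1.0)
        assert analytic.total_arrival_rate(1.0, p) == pytest.approx(10.0)
        assert analytic.total_arrival_rate(20.0, p) == pytest.approx(0.5)


class TestArrivalAngleLaw:
    @pytest.mark.parametrize("rs", [1.011, 2.0, 100.0, 9000.0])
    def test_normalised(self, rs):
        total, _ = quad(lambda ph: float(analytic.arrival_angle_pdf(ph, rs, 1.0)),
                        0.0, np.pi)
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("rs", [1.5, 4.0, 50.0])
    def test_mean_cosine_is_a_over_rs(self, rs):
        mean_cos, _ = quad(
            lambda ph: np.cos(ph) * float(analytic.arrival_angle_pdf(ph, rs, 1.0)),
            0.0, np.pi,
        )
        assert mean_cos == pytest.approx(1.0 / rs, abs=1e-10)

    def test_solid_angle_density_peaks_at_source_pole(self):
        phi = np.linspace(1e-3, np.pi - 1e-3, 500)
        per_solid = analytic.arrival_angle_pdf(phi, 3.0, 1.0) / np.sin(phi)
        assert np.all(np.diff(per_solid) < 0)  # monotone from phi=0 max to phi=pi min

    def test_cdf_endpoints_and_roundtrip(self):
        assert float(analytic.arrival_angle_cdf(0.0, 2.0, 1.0)) == pytest.approx(0.0, abs=1e-14)
        assert float(analytic.arrival_angle_cdf(np.pi, 2.0, 1.0)) == pytest.approx(1.0)
        phi = np.linspace(1e-6, np.pi - 1e-6, 100)
        back = analytic.arrival_angle_ppf(analytic.arrival_angle_cdf(phi, 2.0, 1.0), 2.0, 1.0)
        assert np.allclose(back, phi, atol=1e-8)

    def test_ppf_samples_match_cdf(self, rng):
        u = rng.random(100_000)
        samples = analytic.arrival_angle_ppf(u, 5.0, 1.0)
        res = stats.kstest(samples, lambda x: analytic.arrival_angle_cdf(x, 5.0, 1.0))
        assert res.pvalue > 0.01

    def test_u_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            analytic.arrival_angle_ppf(1.5, 2.0, 1.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(rs=st.floats(1.05, 1e3), u=st.floats(0.0, 1.0))
def test_ppf_cdf_inverse_property(rs, u):
    phi = float(analytic.arrival_angle_ppf(u, rs, 1.0))
    assert 0.0 <= phi <= np.pi
    assert float(analytic.arrival_angle_cdf(phi, rs, 1.0)) == pytest.approx(u, abs=1e-7)


class TestInfiniteRateLimit:
    def test_veff_values(self):
        p = ModelParams(a=1.0, v=0.1, alpha=1.0, D=1.0)
        assert float(analytic.veff_infinite(1.0, p)) == pytest.approx(0.1)
        assert float(analytic.veff_infinite(20.0, p)) == pytest.approx(0.005)

    def test_veff_equals_v_mean_cosine(self, params_eps5):
        for rs in (1.3, 6.0):
            mean_cos, _ = quad(
                lambda ph: np.cos(ph) * float(analytic.arrival_angle_pdf(ph, rs, 1.0)),
                0.0, np.pi,
            )
            assert params_eps5.v * mean_cos == pytest.approx(
                float(analytic.veff_infinite(rs, params_eps5)), abs=1e-10
            )

    def test_trajectory_endpoints_and_slope(self, params_eps10):
        p = params_eps10
        r0 = 15.0
        t_star = (r0**2 - p.a**2) / (2 * p.a * p.v)
        assert float(analytic.trajectory_infinite(0.0, r0, p)) == pytest.approx(r0)
        assert float(analytic.trajectory_infinite(t_star, r0, p)) == pytest.approx(p.a)
        h = 1e-6
        slope = (float(analytic.trajectory_infinite(h, r0, p)) - r0) / h
        assert slope == pytest.approx(-float(analytic.veff_infinite(r0, p)), rel=1e-4)
        with pytest.raises(ValueError):
            analytic.trajectory_infinite(t_star * 1.01, r0, p)


class TestRunGeometry:
    def test_radial_displacement_special_angles(self, params_eps5):
        p = params_eps5
        rs, dt = 3.0, 7.0
        assert float(analytic.radial_displacement(rs, np.pi, dt, p)) == pytest.approx(p.v * dt)
        dt_hit = rs / p.v
        assert float(analytic.radial_displacement(rs, 0.0, dt_hit, p)) == pytest.approx(-rs)
        expected = np.hypot(rs, p.v * dt) - rs
        assert float(analytic.radial_displacement(rs, np.pi / 2, dt, p)) == pytest.approx(expected)

    def test_collision_rate_along_run(self, params_eps5):
        p = params_eps5
        rs = 4.0
        assert float(analytic.run_collision_rate(0.0, rs, 1.1, p)) == pytest.approx(
            p.alpha * p.a / rs
        )
        # away-run: rate decreases monotonically and approaches alpha*a/(v t)
        t = np.linspace(0.0, 5e4, 200)
        lam = analytic.run_collision_rate(t, rs, np.pi, p)
        assert np.all(np.diff(lam) < 0)
        t_far = 1e8
        assert float(analytic.run_collision_rate(t_far, rs, np.pi, p)) == pytest.approx(
            p.alpha * p.a / (p.v * t_far), rel=1e-3
        )


class TestRunDurationLaw:
    def test_hazard_zero_at_zero(self, params_eps5):
        for phi in (0.0, 0.4, np.pi / 2, np.pi):
            assert analytic.cumulative_hazard(0.0, 3.0, phi, params_eps5) == 0.0

    def test_away_run_hazard_is_logarithmic(self, params_eps5):
        p = params_eps5
        rs, dt = 2.5, 40.0
        expected = p.epsilon * np.log1p(p.v * dt / rs)
        assert analytic.cumulative_hazard(dt, rs, np.pi, p) == pytest.approx(expected, rel=1e-12)

    def test_hazard_matches_quadrature(self, rng, params_eps5):
        p = params_eps5
        for _ in range(50):
            rs = float(rng.uniform(1.2, 30.0))
            phi = float(rng.uniform(0.0, np.pi))
            dt = float(rng.uniform(0.01, 200.0))
            num, _ = quad(lambda t: float(analytic.run_collision_rate(t, rs, phi, p)),
                          0.0, dt, limit=200)
            closed = analytic.cumulative_hazard(dt, rs, phi, p)
            assert closed == pytest.approx(num, rel=1e-8)

    def test_ppf_inverts_hazard(self, rng, params_eps5):
        p = params_eps5
        u = rng.random(1000)
        phi = float(rng.uniform(0.1, np.pi - 0.1))
        dt = analytic.run_duration_ppf(u, 3.0, phi, p)
        haz = analytic.cumulative_hazard(dt, 3.0, phi, p)
        assert np.allclose(haz, -np.log1p(-u), rtol=1e-10, atol=1e-12)

    def test_sampled_durations_match_density(self, rng, params_eps5):
        """Inverse-transform samples follow the inhomogeneous-Poisson law."""
        p = params_eps5
        rs, phi = 3.0, 2.0
        samples = analytic.run_duration_ppf(rng.random(100_000), rs, phi, p)
        cdf = lambda t: 1.0 - np.exp(-analytic.cumulative_hazard(np.asarray(t), rs, phi, p))
        res = stats.kstest(samples, cdf)
        assert res.pvalue > 0.01

    def test_u_one_rejected(self, params_eps5):
        with pytest.raises(ValueError):
            analytic.run_duration_ppf(1.0, 3.0, 1.0, params_eps5)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    rs=st.floats(1.1, 100.0),
    phi=st.floats(0.0, np.pi),
    dt1=st.floats(0.0, 1e3),
    dt2=st.floats(0.0, 1e3),
)
def test_cumulative_hazard_monotone_property(rs, phi, dt1, dt2):
    p = ModelParams(a=1.0, v=0.1, alpha=0.5, D=1.0)
    lo, hi = sorted((dt1, dt2))
    h_lo = analytic.cumulative_hazard(lo, rs, phi, p)
    h_hi = analytic.cumulative_hazard(hi, rs, phi, p)
    assert h_lo >= 0.0
    assert h_hi >= h_lo * (1.0 - 1e-12)


class TestMeanRunStatistics:
    def test_displacement_vanishes_at_homing_radius(self, params_eps5):
        assert analytic.mean_run_displacement(params_eps5.rh, params_eps5) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_mean_run_length_at_rh_is_cell_radius(self, params_eps5):
        p = params_eps5
        assert p.v * analytic.mean_run_duration(p.rh, p) == pytest.approx(p.a, abs=1e-10)

    def test_match_monte_carlo(self, rng, params_eps5):
        from greedychemo import run_sim

        p, rs = params_eps5, 3.0
        n = 300_000
        _, dt, drs = run_sim.sample_first_runs(rng, rs, p, n)
        se_r = drs.std() / np.sqrt(n)
        se_t = dt.std() / np.sqrt(n)
        assert abs(drs.mean() - analytic.mean_run_displacement(rs, p)) < 3 * se_r
        assert abs(dt.mean() - analytic.mean_run_duration(rs, p)) < 3 * se_t

    def test_divergent_regime_raises(self):
        p = ModelParams(a=1.0, v=1.0, alpha=0.5, D=1.0)  # epsilon = 0.5
        with pytest.raises(DivergentStatisticsError):
            analytic.mean_run_duration(3.0, p)
        with pytest.raises(DivergentStatisticsError):
            analytic.chemotactic_index(3.0, p)


class TestChemotacticIndex:
    def test_boundary_values(self, params_eps5):
        p = params_eps5
        assert float(analytic.chemotactic_index(p.rh, p)) == pytest.approx(0.0, abs=1e-14)
        assert float(analytic.chemotactic_index(p.a * (1 + 1e-12), p)) == pytest.approx(1.0, rel=1e-6)

    def test_identity_with_mean_runs(self, params_eps5):
        p = params_eps5
        for rs in (1.5, 3.0, 5.0, 8.0, 40.0):
            expected = -analytic.mean_run_displacement(rs, p) / analytic.mean_run_duration(rs, p)
            assert float(analytic.veff_finite(rs, p)) == expected  # same formula path
            assert float(analytic.chemotactic_index(rs, p)) == pytest.approx(
                (p.a * p.epsilon - rs) / (rs * p.epsilon - p.a), rel=1e-12
            )

    def test_sign_structure(self, params_eps5):
        p = params_eps5
        assert float(analytic.chemotactic_index(0.5 * p.rh, p)) > 0
        assert float(analytic.chemotactic_index(2.0 * p.rh, p)) < 0

    def test_infinite_rate_limit(self):
        p = ModelParams(a=1.0, v=0.1, alpha=1e5, D=1.0)  # epsilon = 1e6
        assert float(analytic.veff_finite(20.0, p)) / p.v == pytest.approx(0.05, abs=1e-4)

    def test_gap_to_infinite_rate_halves_when_eps_doubles(self):
        rs = 20.0
        gaps = []
        for alpha in (10.0, 20.0, 40.0):
            p = ModelParams(a=1.0, v=0.1, alpha=alpha, D=1.0)
            gaps.append(abs(float(analytic.veff_finite(rs, p))
                            - float(analytic.veff_infinite(rs, p))))
        assert gaps[0] / gaps[1] == pytest.approx(2.0, rel=0.05)
        assert gaps[1] / gaps[2] == pytest.approx(2.0, rel=0.05)


class TestHomingRadius:
    def test_printed_configurations(self):
        assert analytic.homing_radius(ModelParams(a=1.0, v=0.1, alpha=1.0, D=1.0)) == 10.0
        assert analytic.homing_radius(ModelParams(a=1.0, v=0.1, alpha=0.5, D=1.0)) == 5.0

    def test_is_root_of_mean_displacement(self, params_eps10):
        p = params_eps10
        root = brentq(lambda rs: analytic.mean_run_displacement(rs, p),
                      1.001 * p.a, 100.0, xtol=1e-12)
        assert root == pytest.approx(p.rh, abs=1e-9)

    def test_warns_outside_validity(self):
        p = ModelParams(a=1.0, v=1.0, alpha=0.5, D=1.0)
        with pytest.warns(UserWarning):
            rh = analytic.homing_radius(p)
        assert rh == pytest.approx(0.5)


class TestDivergenceThreshold:
    def test_truncated_expectation_converges_above_one(self):
        p = ModelParams(a=1.0, v=1.0, alpha=2.0, D=1.0)  # epsilon = 2
        i1 = analytic.truncated_mean_run_duration(1e3, 2.0, p)
        i2 = analytic.truncated_mean_run_duration(1e5, 2.0, p)
        assert i2 - i1 < 0.05 * i2
        assert i2 == pytest.approx(analytic.mean_run_duration(2.0, p), rel=0.01)
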