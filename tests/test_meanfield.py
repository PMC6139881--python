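import numpy as np
import pytest
from scipy.optimize import brentq

from kintraffic import meanfield as mf
from kintraffic.params import ModelParams


def params(nu=1.0, omega_A=0.0, omega_D=0.0, theta=0.0, **kw):
    """Convenience constructor setting omega_A through a unit concentration."""
    return ModelParams(nu=nu, omega_a=omega_A, c=1.0 if omega_A else 0.0,
                       omega_D=omega_D, theta=theta, **kw)


class TestStationaryDensity:
    def test_dimer_lk_value(self):
        # omega_A = 0.01 nu, omega_D = omega_A/10, no facilitated detachment
        rho = mf.stationary_density(params(omega_A=0.01, omega_D=0.001))
        assert rho == pytest.approx(0.4219, abs=5e-5)

    def test_no_attachment(self):
        assert mf.stationary_density(params(omega_D=0.3)) == 0.0

    def test_with_facilitated_detachment(self):
        rho = mf.stationary_density(
            params(omega_A=0.01, omega_D=0.001, theta=0.1))
        assert rho == pytest.approx(0.1913, abs=5e-5)

    def test_closed_form_is_root_of_balance(self, rng):
        # plug-back: the closed form zeroes the net attachment flux
        for _ in range(1000):
            p = params(omega_A=10**rng.uniform(-4, 1),
                       omega_D=10**rng.uniform(-4, 1),
                       theta=10**rng.uniform(-4, 1.5))
            rho = mf.stationary_density(p)
            assert 0 < rho <= 0.5
            assert abs(mf.stationarity_residual(rho, p)) < 1e-10

    def test_attachment_detachment_balance(self, rng):
        # gain omega_A (1-2rho)^2/(1-rho) equals loss omega_D rho + theta rho^2/(1-rho)
        for _ in range(50):
            p = params(omega_A=10**rng.uniform(-3, 0.5),
                       omega_D=10**rng.uniform(-3, 0.5),
                       theta=10**rng.uniform(-3, 1))
            rho = mf.stationary_density(p)
            gain = p.omega_A * (1 - 2 * rho) ** 2 / (1 - rho)
            loss = p.omega_D * rho + p.theta * rho**2 / (1 - rho)
            assert gain == pytest.approx(loss, rel=1e-9)

    def test_theta_zero_reduction(self):
        # recovers the dimer TASEP/LK discriminant sqrt(4 wA wD + wD^2)
        wA, wD = 0.037, 0.0051
        expected = 2 * wA / (4 * wA + wD + np.sqrt(4 * wA * wD + wD**2))
        assert mf.stationary_density(params(omega_A=wA, omega_D=wD)) == \
            pytest.approx(expected, rel=1e-12)

    def test_monotonicity(self):
        rhos_theta = [mf.stationary_density(
            params(omega_A=0.01, omega_D=0.001, theta=th))
            for th in np.linspace(0, 1, 20)]
        assert np.all(np.diff(rhos_theta) < 0)
        rhos_wa = [mf.stationary_density(
            params(omega_A=wa, omega_D=0.001, theta=0.05))
            for wa in np.linspace(0.001, 0.1, 20)]
        assert np.all(np.diff(rhos_wa) > 0)

    def test_one_site_variant_root(self):
        p = params(omega_A=0.05, omega_D=0.01, theta=0.05,
                   landing_variant="one_site")
        rho = mf.stationary_density(p)
        assert 0 < rho < 0.5
        # closed-form-free check: residual of the one-site balance vanishes
        assert abs(p.omega_A * (1 - rho) - p.omega_D * rho
                   - p.theta * rho**2 / (1 - rho)) < 1e-10
        # agreement with an independent numeric root
        f = lambda r: p.omega_A * (1 - r) - p.omega_D * r \
            - p.theta * r**2 / (1 - r)
        assert rho == pytest.approx(brentq(f, 0, 0.499999), abs=1e-9)

    def test_one_site_no_root(self):
        # attachment overwhelms detachment: no stationary density below 1/2
        with pytest.raises(ValueError):
            mf.stationary_density(params(omega_A=5.0, omega_D=0.1,
                                         theta=0.1,
                                         landing_variant="one_site"))


class TestCurrent:
    def test_boundary_values(self):
        assert mf.current(0.0, 79.0) == 0.0
        assert mf.current(0.5, 79.0) == 0.0

    def test_maximum_value(self):
        rho_star = (2 - np.sqrt(2)) / 2
        assert mf.current(rho_star, 1.0) == pytest.approx(3 - 2 * np.sqrt(2),
                                                          rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            mf.current(0.6)


class TestOptimalDensity:
    def test_value_and_grid_search(self):
        rho = mf.optimal_density(verify=True)  # verify runs the grid oracle
        assert rho == pytest.approx((2 - np.sqrt(2)) / 2, rel=1e-12)
        assert round(rho, 2) == 0.29

    def test_monomer_reference(self):
        # the monomer fundamental diagram rho(1-rho) peaks at 1/2
        grid = np.linspace(0, 1, 100001)
        assert grid[np.argmax(grid * (1 - grid))] == pytest.approx(0.5,
                                                                   abs=1e-4)


class TestPredictObservables:
    def test_low_concentration_anchors(self, kinesin_params):
        r = mf.predict_observables(kinesin_params.at_concentration(1e-9))
        assert round(r.tau, 1) == 1.9
        assert r.V == pytest.approx(79 * 0.0084, rel=1e-9)
        assert r.lam == pytest.approx(1.8e-2, rel=1e-6)
        assert r.l == pytest.approx(79 * 0.0084 / 0.53, rel=1e-6)

    def test_run_length_is_dwell_times_velocity(self, kinesin_params, rng):
        for c in rng.uniform(0.1, 150, 30):
            r = mf.predict_observables(kinesin_params.at_concentration(c))
            assert r.l == pytest.approx(r.tau * r.V, rel=1e-12)
            assert 0 <= r.rho <= 0.5
            assert r.j >= 0

    def test_jammed_limit_formulas(self, kinesin_params):
        p = kinesin_params
        assert mf.velocity(0.5, p) == 0.0
        assert mf.landing_rate(0.5, p) == 0.0
        assert mf.dwell_time(0.5, p) == pytest.approx(
            1 / (p.omega_D + p.theta))

    def test_one_site_landing_rate(self):
        p = params(omega_A=0.05, omega_D=0.01, theta=0.05, lambda0=0.018,
                   landing_variant="one_site")
        r = mf.predict_observables(p)
        assert r.lam == pytest.approx(0.018 * (1 - r.rho), rel=1e-9)


class TestCrossoverConcentration:
    def test_fitted_parameters(self, kinesin_params):
        c = mf.crossover_concentration(kinesin_params)
        assert c == pytest.approx(7.14, abs=0.01)
        assert round(c) == 7

    def test_bisection_cross_check(self, kinesin_params):
        p = kinesin_params
        rho_star = p.omega_D / (p.omega_D + p.theta)
        c_bisect = brentq(
            lambda c: mf.stationary_density(p.at_concentration(c)) - rho_star,
            1e-6, 1e4, xtol=1e-10)
        assert mf.crossover_concentration(p) == pytest.approx(c_bisect,
                                                              abs=1e-8)

    def test_large_theta_limit(self):
        c = mf.crossover_concentration(
            ModelParams(omega_a=0.054, omega_D=0.53, theta=1e6))
        assert c < 1e-4

    def test_theta_below_omega_d_unreachable(self):
        with pytest.raises(ValueError):
            mf.crossover_concentration(ModelParams(omega_D=1.0, theta=0.5))


class TestNonmonotoneCurrent:
    def test_interior_maximum_in_theta(self):
        # crowded regime: facilitated detachment first helps, then starves
        thetas = np.linspace(0.0, 0.5, 200)
        js = [mf.current(mf.stationary_density(
            params(omega_A=0.01, omega_D=0.001, theta=th)), 1.0)
            for th in thetas]
        k = int(np.argmax(js))
        assert 0 < k < len(js) - 1
        assert js[k] > js[0]
        assert js[k] > js[-1]


class TestDensityProfile:
    def test_ring_uniform(self, kinesin_params):
        p = kinesin_params.at_concentration(5.0)
        prof = mf.density_profile(p, L=50, boundary_mode="ring")
        rho = mf.stationary_density(p)
        assert np.max(np.abs(prof.rho_i - rho)) < 1e-8
        assert prof.residual < 1e-10

    def test_open_boundary_layers(self, kinesin_params):
        p = kinesin_params.at_concentration(5.0)
        prof = mf.density_profile(p, L=400, boundary_mode="open")
        rho_bulk = mf.stationary_density(p)
        # boundary layers confined to roughly 100 sites at each end
        assert abs(prof.rho_i[100] - rho_bulk) < 0.05 * rho_bulk
        interior = prof.rho_i[150:-150]
        assert np.max(np.abs(interior - rho_bulk)) < 0.01 * rho_bulk
        # antenna gradient: density grows from the minus end
        assert prof.rho_i[0] < 0.5 * rho_bulk
        assert prof.residual < 1e-10

    def test_validation(self, kinesin_params):
        with pytest.raises(ValueError):
            mf.density_profile(kinesin_params, L=5)
        with pytest.raises(ValueError):
            mf.density_profile(kinesin_params, L=50, boundary_mode="torus")
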