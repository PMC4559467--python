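"""Mean-field theory: closed forms, quadrature oracles, distributions."""

import math

import numpy as np
import pytest
from scipy import integrate

import drivernet as dn


@pytest.fixture(scope="module")
def inh():
    return dn.TheoryParams.inhibitory()


@pytest.fixture(scope="module")
def exc():
    return dn.TheoryParams.excitatory()


class TestInhibitoryStrand:
    def test_delay_plug_in(self, inh):
        # 1 mV at 5 Hz over a 10 mV gap: 20 ms
        assert dn.inhibitory_delay(1.0, inh) == pytest.approx(0.02)

    def test_delay_zero_weight_and_homogeneity(self, inh):
        assert dn.inhibitory_delay(0.0, inh) == 0.0
        d1 = dn.inhibitory_delay(1.0, inh)
        d2 = dn.inhibitory_delay(
            1.0, dn.TheoryParams.inhibitory(nu_0=10.0))
        assert d2 == pytest.approx(d1 / 2)

    def test_stationary_weight_plug_in(self, inh):
        # 5 Hz * 20 ms * 10 mV * ln 4 = 1.386 mV
        assert dn.stationary_inhibitory_weight(5.0, inh) == pytest.approx(
            5 * 0.02 * 10 * math.log(4.0), rel=1e-12)

    def test_stationary_weight_trivial_cases(self):
        assert dn.stationary_inhibitory_weight(
            0.0, dn.TheoryParams.inhibitory()) == 0.0
        equal = dn.TheoryParams.inhibitory(A_plus=0.005, A_minus=0.005)
        assert dn.stationary_inhibitory_weight(5.0, equal) == 0.0

    @pytest.mark.parametrize("nu0", [0.5, 2.0, 5.0, 11.0, 40.0])
    def test_stationary_weight_is_root_of_averaged_update(self, inh, nu0):
        w = dn.stationary_inhibitory_weight(nu0, inh)
        assert abs(dn.mean_inhibitory_update(w, nu0, inh)) < 1e-12

    def test_rate_with_inhibition_plug_in(self, inh):
        assert dn.rate_with_inhibition(5.0, inh) == pytest.approx(
            5.0 / (1.0 + 0.02 * 5.0 * math.log(4.0)))  # 4.391 Hz

    def test_rate_without_inhibition_unchanged(self):
        p = dn.TheoryParams.inhibitory(nu_inh=0.0)
        assert dn.rate_with_inhibition(7.0, p) == 7.0

    def test_partial_compensation_contraction(self, inh):
        # 0 < nu(nu0 + d) - nu(nu0) < d for every d > 0
        for d in [0.1, 1.0, 5.0, 20.0]:
            diff = (dn.rate_with_inhibition(5.0 + d, inh)
                    - dn.rate_with_inhibition(5.0, inh))
            assert 0.0 < diff < d


class TestPairContribution:
    def test_limits(self, exc):
        tau_s = exc.tau / 1000.0
        assert dn.pair_contribution(0.0, exc) == 0.0
        assert dn.pair_contribution(100.0, exc) == pytest.approx(
            exc.A_plus * tau_s - exc.A_minus * tau_s, rel=1e-6)

    def test_quadrature_oracle(self, exc):
        # numerical integral of the kernel vs the closed form at T = 50 ms
        T = 0.050
        tau_s = exc.tau / 1000.0

        def integrand(t):
            return (exc.A_plus * math.exp(-(T - t) / tau_s)
                    - exc.A_minus * math.exp(-t / tau_s))

        want, _ = integrate.quad(integrand, 0.0, T, epsabs=1e-14)
        assert dn.pair_contribution(T, exc) == pytest.approx(want, abs=1e-9)

    def test_negative_when_depression_dominates(self, exc):
        for T in [0.001, 0.01, 0.1, 1.0]:
            assert dn.pair_contribution(T, exc) < 0


class TestShiftAndTrigger:
    def test_shift_plug_in(self):
        p = dn.TheoryParams.excitatory(nu=5.0, delta_r_slope=0.5)
        # dr = 0.5 Hz at w=1: 0.5/(5*5.5) s
        assert dn.postsynaptic_shift(1.0, p) == pytest.approx(
            0.5 / (5.0 * 5.5))

    def test_shift_zero_without_rate_change(self):
        p = dn.TheoryParams.excitatory(nu=5.0, delta_r_slope=0.0)
        assert dn.postsynaptic_shift(3.0, p) == 0.0

    def test_fire_probability_uniform_density(self, exc):
        grid = np.linspace(-60.0, -50.0, 501)
        dist = dn.MembraneDistribution(grid, np.ones_like(grid))
        assert dn.fire_probability(0.0, dist, exc) == 0.0
        assert dn.fire_probability(5.0, dist, exc) == pytest.approx(0.5,
                                                                    abs=1e-6)
        assert dn.fire_probability(50.0, dist, exc) == pytest.approx(1.0)

    def test_fire_probability_monotone(self, exc):
        grid = np.linspace(-66.0, -50.0, 300)
        dens = np.exp(-0.5 * ((grid + 57.0) / 2.0) ** 2)
        dist = dn.MembraneDistribution(grid, dens)
        ws = np.linspace(0, 12, 40)
        ps = [dn.fire_probability(w, dist, exc) for w in ws]
        assert np.all(np.diff(ps) >= -1e-12)
        assert all(0.0 <= p <= 1.0 + 1e-12 for p in ps)


class TestMembraneDistribution:
    def test_empirical_normalization(self, rng):
        v = rng.normal(-55.0, 1.5, 20_000)
        dist = dn.membrane_distribution("empirical", trace=v)
        assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0)

    def test_empirical_excludes_refractory_samples(self, rng):
        v = np.concatenate([rng.normal(-55, 1, 1000), np.full(1000, -60.0)])
        refr = np.concatenate([np.zeros(1000, bool), np.ones(1000, bool)])
        dist = dn.membrane_distribution("empirical", trace=v, refractory=refr)
        assert dist.cdf_above(-58.0) > 0.95

    def test_empirical_empty_rejected(self):
        with pytest.raises(ValueError):
            dn.membrane_distribution("empirical", trace=np.empty(0))

    def test_degenerate_trace_collapses_to_point(self):
        dist = dn.membrane_distribution("empirical", trace=np.full(10, -60.0))
        assert dist.cdf_above(-60.0 - 1e-3) == pytest.approx(1.0)

    def test_diffusion_density_normalized(self):
        dist = dn.diffusion_membrane_density(mu_in=16.5, sigma_in=2.87)
        assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0)
        assert dist.grid[-1] == -50.0

    def test_diffusion_matches_empirical_two_neuron_drive(self):
        """Cross-validation: the diffusion form against the subthreshold
        voltage histogram of the Poisson-bombarded cell (1650 synapses,
        1 Hz, 0.5 mV)."""
        res = dn.run_two_neuron_excitatory_dw(
            [0.0], duration=80.0, n_repeats=2, seed=12)
        v = res["v_samples"]
        assert v.size > 10_000
        emp = dn.membrane_distribution("empirical", trace=v, n_grid=60)
        # mu = J R tau_m, sigma^2 = J^2 R tau_m (R in per-ms, tau_m in ms)
        mu = 0.5 * 1.65 * 20.0
        sigma = math.sqrt(0.25 * 1.65 * 20.0)
        diff = dn.diffusion_membrane_density(mu_in=mu, sigma_in=sigma)
        # compare CDFs on a common grid (KS style)
        grid = np.linspace(-60, -50.001, 200)
        c_emp = np.array([1.0 - emp.cdf_above(v0) for v0 in grid])
        c_dif = np.array([1.0 - diff.cdf_above(v0) for v0 in grid])
        assert np.max(np.abs(c_emp - c_dif)) < 0.05


class TestExpectedWeightChange:
    def test_negative_at_zero_weight(self):
        p = dn.TheoryParams.excitatory(nu=40.0, delta_r_slope=0.3)
        grid = np.linspace(-60, -50.0, 200)
        dist = dn.MembraneDistribution(grid, np.ones_like(grid))
        assert dn.expected_weight_change(0.0, p, dist) < 0

    def test_lambda_insensitivity(self):
        """The ISI-dispersion parameter barely moves the estimate within
        the stated interval lambda in [0.5/nu, 1/nu]."""
        nu = 40.0
        grid = np.linspace(-60, -50.0, 200)
        dist = dn.MembraneDistribution(
            grid, np.exp(-0.5 * ((grid + 54) / 2.0) ** 2))
        vals = []
        for lam in [0.5 / nu, 0.75 / nu, 1.0 / nu]:
            p = dn.TheoryParams.excitatory(nu=nu, delta_r_slope=0.3, lam=lam)
            vals.append(dn.expected_weight_change(1.5, p, dist))
        spread = (max(vals) - min(vals)) / abs(np.mean(vals))
        assert spread < 0.05

    def test_continuous_and_single_sign_change_shape(self):
        p = dn.TheoryParams.excitatory(nu=40.0, delta_r_slope=0.5)
        grid = np.linspace(-60, -50.0, 300)
        dist = dn.MembraneDistribution(
            grid, np.exp(-0.5 * ((grid + 53.5) / 1.8) ** 2))
        ws = np.linspace(0.0, 3.0, 13)
        vals = np.array([dn.expected_weight_change(w, p, dist) for w in ws])
        signs = np.sign(vals)
        changes = np.sum(np.abs(np.diff(signs)) > 0)
        assert vals[0] < 0
        assert changes == 1
        # continuity: no jumps an order of magnitude above neighbours
        steps = np.abs(np.diff(vals))
        assert steps.max() < 10 * np.median(steps) + 1e-9


class TestRateSlopeFit:
    def test_recovers_linear_relation(self):
        w = np.linspace(0, 3, 7)
        rates = 40.0 + 2.5 * w
        slope, intercept, resid = dn.fit_rate_slope(w, rates)
        assert slope == pytest.approx(2.5)
        assert intercept == pytest.approx(40.0)
        assert resid < 1e-9
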