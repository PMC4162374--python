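import numpy as np
import pytest
from scipy import integrate
from scipy.special import erfcx

from hetnet.core import NeuronConstants, SynapticWeights, default_spec
from hetnet.meanfield import (
    averaged_transfer,
    fI_curve,
    recurrent_moments,
    siegert_rate,
    solve_fixed_point,
    _hermite_thresholds,
    _siegert_vec,
)


def siegert_quad(mu, sigma, theta, nc):
    """Independent oracle: adaptive quadrature of the first-passage integral."""
    a = (nc.V_r - mu) / sigma
    b = (theta - mu) / sigma
    val, err = integrate.quad(lambda u: erfcx(-u), a, b, limit=500, epsabs=0, epsrel=1e-12)
    return 1000.0 / (nc.tau_ref + nc.tau_m * np.sqrt(np.pi) * val)


class TestSiegertRate:
    def test_far_subthreshold_is_negligible(self, constants):
        assert siegert_rate(0.0, 0.5, 20.0, constants) < 1e-10

    def test_refractory_saturation(self, constants):
        """Rate approaches 1/tau_ref = 200 Hz from below as the drive grows."""
        r1 = siegert_rate(1e4, 3.0, 20.0, constants)
        r2 = siegert_rate(1e6, 3.0, 20.0, constants)
        assert r1 < r2 < 200.0
        assert r2 == pytest.approx(200.0, rel=1e-4)

    def test_noiseless_suprathreshold_limit(self, constants):
        """sigma -> 0 recovers the deterministic LIF rate 1000/(tau_ref + tau_m ln 3)."""
        expected = 1000.0 / (5.0 + 20.0 * np.log(3.0))
        assert siegert_rate(25.0, 1e-7, 20.0, constants) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize(
        "mu,sigma", [(15.0, 3.0), (10.0, 1.0), (19.0, 0.5), (22.0, 3.0), (5.0, 4.0)]
    )
    def test_against_adaptive_quadrature(self, mu, sigma, constants):
        ours = siegert_rate(mu, sigma, 20.0, constants)
        oracle = siegert_quad(mu, sigma, 20.0, constants)
        assert ours == pytest.approx(oracle, rel=1e-8)

    def test_rejects_zero_noise(self, constants):
        with pytest.raises(ValueError):
            siegert_rate(15.0, 0.0, 20.0, constants)


class TestRecurrentMoments:
    def test_silent_network_passes_external_drive(self, spec):
        m = recurrent_moments(0.0, 0.0, spec, mu_ext=15.0, sigma=3.0, population="E")
        assert (m.mu_tot, m.sigma_tot) == (15.0, 3.0)

    def test_hand_computed_recurrent_mean(self, spec):
        """tau_m K (gamma J_EE + (1-gamma) J_EI) nu = 0.96 mV at 10 Hz."""
        m = recurrent_moments(10.0, 10.0, spec, mu_ext=0.0, sigma=3.0, population="E")
        assert m.mu_tot == pytest.approx(0.96, abs=1e-12)

    def test_fluctuations_increase_with_rates(self, spec):
        lo = recurrent_moments(5.0, 5.0, spec, 15.0, 3.0, "I").sigma_tot
        hi = recurrent_moments(10.0, 10.0, spec, 15.0, 3.0, "I").sigma_tot
        assert hi > lo > 3.0


class TestAveragedTransfer:
    def test_zero_width_equals_pointwise_siegert(self, spec, constants):
        s0 = spec.with_heterogeneity(0.0, 0.0)
        phi = averaged_transfer(5.0, 5.0, s0, 15.0, 3.0, "E")
        m = recurrent_moments(5.0, 5.0, s0, 15.0, 3.0, "E")
        assert phi == pytest.approx(siegert_rate(m.mu_tot, m.sigma_tot, 20.0, constants), rel=1e-12)

    def test_continuity_at_zero_width(self, spec):
        lo = averaged_transfer(5.0, 5.0, spec.with_heterogeneity(0.0, 0.0), 15.0, 3.0, "E")
        eps = averaged_transfer(5.0, 5.0, spec.with_heterogeneity(1e-4, 0.0), 15.0, 3.0, "E")
        assert abs(eps - lo) < 1e-6 * lo

    def test_matches_monte_carlo_threshold_average(self, spec, constants, rng):
        s = spec.with_heterogeneity(2.0, 0.1)
        phi = averaged_transfer(5.0, 5.0, s, 15.0, 3.0, "E")
        m = recurrent_moments(5.0, 5.0, s, 15.0, 3.0, "E")
        draws = rng.normal(20.0, 2.0, 1_000_000)
        draws = draws[draws > constants.V_r]
        mc = _siegert_vec(m.mu_tot, m.sigma_tot, draws, constants)
        sem = mc.std(ddof=1) / np.sqrt(mc.size)
        assert abs(phi - mc.mean()) < 3 * sem

    def test_quadrature_order_converged(self, spec):
        for w in (0.5, 1.5, 2.5):
            s = spec.with_heterogeneity(w, 0.1)
            a = averaged_transfer(5.0, 5.0, s, 15.0, 3.0, "E", n_nodes=41)
            b = averaged_transfer(5.0, 5.0, s, 15.0, 3.0, "E", n_nodes=81)
            assert a == pytest.approx(b, rel=1e-8)

    def test_sub_reset_nodes_are_excluded(self):
        nodes, wts = _hermite_thresholds(12.0, 3.0, 10.0, 41)
        assert np.all(nodes > 10.0)
        assert wts.sum() == pytest.approx(1.0)


class TestFixedPoint:
    def test_decoupled_limit_equals_external_transfer(self, constants):
        from dataclasses import replace

        spec = replace(
            default_spec(), weights=SynapticWeights(0.0, 0.0, 0.0, 0.0)
        ).with_heterogeneity(0.0, 0.0)
        fp = solve_fixed_point(spec, 15.0, 15.0, 3.0)
        assert fp.converged
        expected = siegert_rate(15.0, 3.0, 20.0, constants)
        assert fp.nu_E == pytest.approx(expected, abs=1e-5)
        assert fp.nu_I == pytest.approx(expected, abs=1e-5)

    def test_damped_iteration_agrees_with_root_finder(self, spec):
        """Dual-solver cross-check over a (w_E, w_I) grid."""
        from scipy import optimize

        from hetnet.meanfield import _transfer_pair

        for we in np.linspace(0.0, 2.5, 3):
            for wi in np.linspace(0.0, 2.5, 3):
                s = spec.with_heterogeneity(we, wi)
                fp = solve_fixed_point(s, 15.0, 15.0, 3.0)
                sol = optimize.root(
                    lambda x: _transfer_pair(x, s, 15.0, 15.0, 3.0, 41) - x,
                    [1.0, 1.0],
                    method="hybr",
                )
                assert fp.converged and sol.success
                assert fp.nu_E == pytest.approx(sol.x[0], abs=1e-4)
                assert fp.nu_I == pytest.approx(sol.x[1], abs=1e-4)

    def test_rates_respect_refractory_bound(self, spec):
        for mu in (15.0, 25.0, 60.0):
            fp = solve_fixed_point(spec, mu, mu, 3.0)
            assert 0.0 <= fp.nu_E <= 200.0
            assert 0.0 <= fp.nu_I <= 200.0


class TestFICurve:
    def test_monotone_in_drive_at_zero_width(self, spec):
        grid = np.linspace(10.0, 20.0, 11)
        c = fI_curve(spec.with_heterogeneity(0.0, 0.0), grid, mu0=17.0, sigma=3.0)
        assert np.all(np.diff(c.nu_E) >= 0)
        assert c.converged.all()

    def test_excitatory_heterogeneity_raises_both_rates(self, spec):
        fp_lo = solve_fixed_point(spec.with_heterogeneity(0.1, 0.1), 15.0, 15.0, 3.0)
        fp_hi = solve_fixed_point(spec.with_heterogeneity(2.0, 0.1), 15.0, 15.0, 3.0)
        assert fp_hi.nu_E > fp_lo.nu_E
        assert fp_hi.nu_I > fp_lo.nu_I

    def test_inhibitory_heterogeneity_divides_excitation(self, spec):
        fp_lo = solve_fixed_point(spec.with_heterogeneity(0.1, 0.1), 15.0, 15.0, 3.0)
        fp_hi = solve_fixed_point(spec.with_heterogeneity(0.1, 2.0), 15.0, 15.0, 3.0)
        assert fp_hi.nu_E < fp_lo.nu_E
        assert fp_hi.nu_I > fp_lo.nu_I

    def test_rejects_unsorted_grid(self, spec):
        with pytest.raises(ValueError):
            fI_curve(spec, np.array([1.0, 0.5, 2.0]), 15.0, 3.0)
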