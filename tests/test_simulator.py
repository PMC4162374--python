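import numpy as np
import pytest

from hetnet.core import default_spec, build_realization
from hetnet.meanfield import siegert_rate
from hetnet.presets import make_fixture
from hetnet.simulator import (
    DriveSpec,
    RateSeries,
    mean_rates,
    population_rate,
    rate_distribution,
    simulate,
    synchrony_index,
)


def lif_deterministic_period(mu, nc):
    return nc.tau_ref + nc.tau_m * np.log((mu - nc.V_r) / (mu - nc.theta_mean))


class TestSingleNeuron:
    def test_noiseless_period_matches_closed_form(self, single_neuron):
        """Suprathreshold noiseless LIF fires with period tau_ref + tau_m ln 3."""
        nc = single_neuron.spec.constants
        drive = DriveSpec(mu=25.0, mu0=25.0, sigma=0.0)
        spikes = simulate(single_neuron, drive, duration=2000.0, dt=0.01, seed=0)
        isis = np.diff(spikes.times)
        assert np.allclose(isis, isis[0])
        assert isis.mean() == pytest.approx(lif_deterministic_period(25.0, nc), rel=0.01)

    def test_subthreshold_noiseless_is_silent(self, single_neuron):
        spikes = simulate(single_neuron, DriveSpec(mu=18.0, mu0=18.0, sigma=0.0), 1000.0, 0.05, 3)
        assert len(spikes) == 0

    def test_unconnected_rate_matches_diffusion_theory(self):
        """Empirical rate of an uncoupled noisy population converges to the
        first-passage (Siegert) prediction within statistical error."""
        real, _ = make_fixture("unconnected-population")
        nc = real.spec.constants
        spikes = simulate(real, DriveSpec(mu=15.0, mu0=15.0, sigma=3.0), 6000.0, 0.01, 5)
        rates = mean_rates(spikes, 500.0)
        predicted = siegert_rate(15.0, 3.0, 20.0, nc)
        sem = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - predicted) < 3 * max(sem, 1e-9)

    def test_timestep_error_decreases_monotonically(self):
        """The ~sqrt(dt) threshold-crossing bias shrinks as the step refines.

        Uses a 400-neuron uncoupled ensemble over 8 s so the statistical
        error (~1%) stays below the bias separation between step sizes."""
        from dataclasses import replace

        from hetnet.core import PopulationStructure, build_realization, default_spec

        spec = replace(
            default_spec(), structure=PopulationStructure(N=400, gamma=0.8, eps=0.0)
        ).with_heterogeneity(0.0, 0.0)
        real = build_realization(spec, 1)
        predicted = siegert_rate(15.0, 3.0, 20.0, spec.constants)
        errs = []
        for dt in (0.1, 0.05, 0.01):
            spikes = simulate(
                real, DriveSpec(mu=15.0, mu0=15.0, sigma=3.0), 8000.0, dt, 5, allow_coarse_dt=True
            )
            errs.append(abs(mean_rates(spikes, 500.0).mean() - predicted))
        assert errs[0] > errs[2]
        assert errs[1] > errs[2]


class TestNetworkSimulation:
    def test_refractory_invariant(self, tiny_ei):
        spikes = simulate(tiny_ei, DriveSpec(mu=25.0, mu0=25.0, sigma=3.0), 2000.0, 0.05, 9)
        tau_ref = tiny_ei.spec.constants.tau_ref
        for i in np.unique(spikes.indices):
            t = spikes.times[spikes.indices == i]
            if t.size > 1:
                assert np.diff(t).min() >= tau_ref

    def test_rates_below_refractory_bound(self, tiny_ei):
        spikes = simulate(tiny_ei, DriveSpec(mu=40.0, mu0=40.0, sigma=3.0), 2000.0, 0.05, 9)
        assert mean_rates(spikes).max() <= 200.0

    def test_seed_determinism(self, tiny_ei):
        d = DriveSpec(mu=16.0, mu0=16.0, sigma=3.0)
        a = simulate(tiny_ei, d, 1000.0, 0.05, 77)
        b = simulate(tiny_ei, d, 1000.0, 0.05, 77)
        c = simulate(tiny_ei, d, 1000.0, 0.05, 78)
        assert np.array_equal(a.times, b.times) and np.array_equal(a.indices, b.indices)
        assert not (len(a) == len(c) and np.array_equal(a.times, c.times))

    def test_rejects_coarse_dt(self, tiny_ei):
        with pytest.raises(ValueError):
            simulate(tiny_ei, DriveSpec(), 100.0, dt=3.0, seed=0)
        with pytest.raises(ValueError):
            simulate(tiny_ei, DriveSpec(), 100.0, dt=6.0, seed=0)


class TestRateSummaries:
    def test_mean_rates_arithmetic(self):
        from hetnet.simulator import SpikeData

        sd = SpikeData(
            times=np.linspace(600.0, 9500.0, 95),
            indices=np.zeros(95, dtype=np.int64),
            n_neurons=2,
            is_exc=np.array([True, False]),
            duration=10_000.0,
        )
        r = mean_rates(sd, transient=500.0)
        assert r[0] == pytest.approx(10.0)
        assert r[1] == 0.0

    def test_population_rate_conserves_spike_count(self, tiny_ei):
        spikes = simulate(tiny_ei, DriveSpec(mu=25.0, mu0=25.0, sigma=3.0), 2000.0, 0.05, 1)
        series = population_rate(spikes, 5.0, "E")
        n_exc = int(tiny_ei.is_exc.sum())
        total = series.rate.sum() * series.bin_width / 1000.0 * n_exc
        assert total == pytest.approx(int(spikes.is_exc[spikes.indices].sum()), abs=0.5)

    def test_empty_population_rate_is_zero(self):
        from hetnet.simulator import SpikeData

        sd = SpikeData(
            times=np.array([]),
            indices=np.array([], dtype=np.int64),
            n_neurons=4,
            is_exc=np.array([True, True, False, False]),
            duration=500.0,
        )
        series = population_rate(sd, 10.0, "I")
        assert np.all(series.rate == 0)


class TestRateDistribution:
    def test_normalized_density(self, rng):
        rates = rng.gamma(2.0, 3.0, 500)
        x, pdf = rate_distribution(rates, bandwidth=1.0)
        assert np.trapezoid(pdf, x) == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_rates_concentrate(self):
        x, pdf = rate_distribution(np.full(50, 7.0), bandwidth=0.5)
        assert x[np.argmax(pdf)] == pytest.approx(7.0, abs=0.1)

    def test_heterogeneity_broadens_and_skews_rates(self):
        """Threshold heterogeneity turns the narrow rate distribution long-tailed."""
        from scipy import stats

        drive = DriveSpec(mu=15.0, mu0=15.0, sigma=3.0)
        skews = {}
        for w in (0.1, 2.0):
            spec = default_spec().with_heterogeneity(w, 0.1)
            real = build_realization(spec, 4)
            spikes = simulate(real, drive, 3000.0, 0.05, 6)
            r = mean_rates(spikes, 500.0)[real.is_exc]
            skews[w] = stats.skew(r)
        assert skews[2.0] > skews[0.1]


class TestSynchronyIndex:
    def test_white_noise_surrogate_is_flat(self, rng):
        """Index on white-noise surrogates stays in the range the surrogate
        distribution itself spans (no spurious peaks)."""
        idx = []
        for _ in range(20):
            series = RateSeries(
                t=np.arange(2000) * 1.0 + 0.5,
                rate=rng.normal(10.0, 2.0, 2000),
                population="E",
                bin_width=1.0,
            )
            idx.append(synchrony_index(series))
        idx = np.asarray(idx)
        assert np.median(idx) < 3.0
        assert idx.max() < 6.0

    def test_sinusoid_dominates_spectrum(self, rng):
        t = np.arange(2000) * 1.0 + 0.5
        rate = 10.0 + 5.0 * np.sin(2 * np.pi * 0.05 * t) + rng.normal(0, 0.3, t.size)
        series = RateSeries(t=t, rate=rate, population="E", bin_width=1.0)
        assert synchrony_index(series) > 10.0

    def test_requires_enough_bins(self):
        series = RateSeries(
            t=np.arange(40) * 1.0, rate=np.zeros(40), population="E", bin_width=1.0
        )
        with pytest.raises(ValueError):
            synchrony_index(series)
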