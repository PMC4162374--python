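"""Stochastic simulation of the heterogeneous LIF network.

Integrates the membrane equation

    tau_m dV_i/dt = -V_i + mu_i(t) + sigma sqrt(tau_m) xi_i(t) + tau_m sum_jk J_ij delta(t - t_j^k)

with fixed-step Euler-Maruyama. The external drive is mu (optionally with a
sinusoidal modulation S0 sin(2 pi f_s t)) for excitatory neurons and a
constant bias mu_0 for inhibitory neurons; xi_i are independent unit-
spectral-density Gaussian white noises, so sigma is the stationary
membrane-potential standard deviation of a free membrane. Spikes reset the
membrane to V_r and clamp it there for the refractory period tau_ref.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hetnet._kernel import run_lif
from hetnet.core import NetworkRealization

__all__ = [
    "DriveSpec",
    "SimConfig",
    "SpikeData",
    "RateSeries",
    "simulate",
    "mean_rates",
    "population_rate",
    "rate_distribution",
    "synchrony_index",
]


@dataclass(frozen=True)
class DriveSpec:
    """External input protocol.

    Parameters
    ----------
    mu : float
        Constant drive to every excitatory neuron (mV).
    mu0 : float
        Constant bias to every inhibitory neuron (mV).
    sigma : float
        White-noise intensity (mV), shared by all neurons.
    S0 : float
        Amplitude of a sinusoidal modulation added to the excitatory drive
        (mV); 0 disables the signal.
    f_s : float
        Signal frequency (Hz); required positive when S0 > 0.
    """

    mu: float = 15.0
    mu0: float = 15.0
    sigma: float = 3.0
    S0: float = 0.0
    f_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.S0 < 0:
            raise ValueError("S0 must be >= 0")
        if self.S0 > 0 and self.f_s <= 0:
            raise ValueError("f_s must be > 0 when a signal is present")


@dataclass(frozen=True)
class SimConfig:
    """Integration and statistics protocol."""

    duration: float = 10_000.0  # ms
    dt: float = 0.05  # ms
    transient: float = 500.0  # ms discarded before statistics
    n_trials: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.transient < self.duration:
            raise ValueError("transient must lie in [0, duration)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class SpikeData:
    """Spike times (ms) with neuron indices, time-sorted.

    ``is_exc`` carries the population label of every neuron so rate
    summaries can be computed without the full realization at hand.
    """

    times: np.ndarray
    indices: np.ndarray
    n_neurons: int
    is_exc: np.ndarray
    duration: float

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RateSeries:
    """Binned population firing rate nu(t) in Hz per neuron."""

    t: np.ndarray  # bin centers, ms
    rate: np.ndarray  # Hz
    population: str
    bin_width: float  # ms


def simulate(
    realization: NetworkRealization,
    drive: DriveSpec,
    duration: float,
    dt: float = 0.05,
    seed: int = 0,
    allow_coarse_dt: bool = False,
) -> SpikeData:
    """Integrate the network for ``duration`` ms and return its spikes.

    Synaptic jumps produced by spikes in one step are applied at the start
    of the next (effective delay <= dt); threshold crossings are detected at
    step ends without interpolation. Initial potentials are drawn uniformly
    in [V_r, theta_i) from the simulation RNG stream, so start-up artifacts
    are confined to the transient.

    Parameters
    ----------
    realization : NetworkRealization
        Quenched network (thresholds + connectivity).
    drive : DriveSpec
        External input protocol.
    duration : float
        Simulated time (ms).
    dt : float
        Integration step (ms). Rejected when larger than tau_ref (refractory
        bookkeeping would alias) or tau_m/10 (accuracy guard, overridable
        with ``allow_coarse_dt``).
    seed : int
        Seed of the dynamical-noise stream; independent from the quenched
        disorder recorded in the realization.
    """
    nc = realization.spec.constants
    if dt > nc.tau_ref and nc.tau_ref > 0:
        raise ValueError(f"dt={dt} exceeds the refractory period {nc.tau_ref} ms")
    if dt > nc.tau_m / 10 and not allow_coarse_dt:
        raise ValueError(
            f"dt={dt} exceeds tau_m/10 = {nc.tau_m / 10}; pass allow_coarse_dt=True to override"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")

    n_steps = int(round(duration / dt))
    ref_steps = int(round(nc.tau_ref / dt))
    N = realization.N

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    V0 = nc.V_r + rng.random(N) * (realization.thresholds - nc.V_r)
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    # hard upper bound on spike count from the refractory period
    max_spikes = N * (n_steps // max(ref_steps, 1) + 2)
    spike_t = np.empty(max_spikes)
    spike_i = np.empty(max_spikes, dtype=np.int64)

    conn = realization.connectivity
    count = run_lif(
        V0,
        realization.thresholds,
        realization.is_exc,
        conn.indptr,
        conn.indices,
        conn.data,
        float(drive.mu),
        float(drive.mu0),
        float(drive.sigma),
        float(drive.S0),
        float(drive.f_s),
        float(nc.tau_m),
        float(nc.V_r),
        float(dt),
        n_steps,
        ref_steps,
        kernel_seed,
        spike_t,
        spike_i,
    )
    return SpikeData(
        times=spike_t[:count].copy(),
        indices=spike_i[:count].copy(),
        n_neurons=N,
        is_exc=realization.is_exc.copy(),
        duration=float(duration),
    )


def mean_rates(spikes: SpikeData, transient: float = 0.0) -> np.ndarray:
    """Per-neuron mean firing rate (Hz) after discarding the transient."""
    if transient >= spikes.duration:
        raise ValueError("transient must be smaller than the duration")
    window_s = (spikes.duration - transient) / 1000.0
    counts = np.bincount(
        spikes.indices[spikes.times > transient], minlength=spikes.n_neurons
    )
    return counts / window_s


def population_rate(
    spikes: SpikeData, bin_width: float, population: str = "E"
) -> RateSeries:
    """Population firing rate nu(t) (Hz per neuron) in fixed time bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if population not in ("E", "I"):
        raise ValueError("population must be 'E' or 'I'")
    sel = spikes.is_exc if population == "E" else ~spikes.is_exc
    n_pop = int(sel.sum())
    n_bins = int(np.ceil(spikes.duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    mask = sel[spikes.indices]
    counts, _ = np.histogram(spikes.times[mask], bins=edges)
    rate = counts * 1000.0 / (bin_width * max(n_pop, 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RateSeries(t=centers, rate=rate, population=population, bin_width=bin_width)


def rate_distribution(
    rates: np.ndarray, bandwidth: float, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of per-neuron rates, reflected at zero.

    Rates are nonnegative, so the kernel mass that would leak below zero is
    reflected back, keeping the estimate normalized on [0, inf).

    Returns
    -------
    (grid, density) : tuple of ndarray
        Evaluation points (Hz) and density values (1/Hz) integrating to ~1.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("rates must be nonempty")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        hi = max(rates.max() + 5 * bandwidth, 10 * bandwidth)
        grid = np.linspace(0.0, hi, 512)
    z = (grid[:, None] - rates[None, :]) / bandwidth
    z_ref = (grid[:, None] + rates[None, :]) / bandwidth
    norm = 1.0 / (np.sqrt(2 * np.pi) * bandwidth * rates.size)
    density = norm * (np.exp(-0.5 * z**2) + np.exp(-0.5 * z_ref**2)).sum(axis=1)
    return grid, density


def synchrony_index(
    series: RateSeries,
    transient: float = 0.0,
    band: tuple[float, float] = (20.0, 500.0),
) -> float:
    """Normalized spectral peak prominence of the population rate.

    Welch power spectrum of the mean-subtracted rate series; the index is
    the maximum power in the 20-500 Hz band divided by the median power in
    that band. An asynchronous network has a flat spectrum (index near 1,
    up to sampling fluctuations of the Welch estimate); a synchronously
    oscillating one shows a dominant peak (index >> 10).
    """
    from scipy.signal import welch

    x = series.rate[series.t > transient]
    if x.size <= 50:
        raise ValueError("need more than 50 bins after the transient")
    fs = 1000.0 / series.bin_width  # Hz
    nperseg = min(x.size, max(64, x.size // 8))
    f, p = welch(x - x.mean(), fs=fs, nperseg=nperseg)
    lo, hi = band
    hi = min(hi, fs / 2)
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        raise ValueError("frequency band is empty at this bin width")
    pband = p[sel]
    med = np.median(pband)
    if med == 0:
        return 1.0 if pband.max() == 0 else np.inf
    return float(pband.max() / med)
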