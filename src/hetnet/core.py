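"""Network specification and quenched realizations.

A network is described in two layers: a :class:`NetworkSpec` holds the
statistical parameters of the circuit (sizes, sparseness, synaptic weights,
heterogeneity widths, single-neuron constants), and a
:class:`NetworkRealization` is one concrete sample from that ensemble —
per-neuron firing thresholds plus a sparse directed weighted connectivity
matrix. Both thresholds and connectivity are *quenched* disorder: frozen at
construction time, independent of the dynamical noise used later by the
simulator.

All inputs and synaptic weights are expressed as voltages (mV); the membrane
resistance is absorbed into them. Rates are in Hz, times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NeuronConstants",
    "PopulationStructure",
    "SynapticWeights",
    "HeterogeneityLevels",
    "NetworkSpec",
    "NetworkRealization",
    "sample_thresholds",
    "build_realization",
    "default_spec",
]


@dataclass(frozen=True)
class NeuronConstants:
    """Leaky integrate-and-fire single-neuron constants.

    Parameters
    ----------
    tau_m : float
        Membrane time constant (ms).
    V_r : float
        Reset potential (mV); the membrane is clamped here for ``tau_ref``
        after each spike.
    theta_mean : float
        Population-mean firing threshold (mV).
    tau_ref : float
        Absolute refractory period (ms). Caps attainable rates at
        ``1000 / tau_ref`` Hz.
    """

    tau_m: float = 20.0
    V_r: float = 10.0
    theta_mean: float = 20.0
    tau_ref: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.tau_ref < 0:
            raise ValueError(f"tau_ref must be nonnegative, got {self.tau_ref}")
        if self.theta_mean <= self.V_r:
            raise ValueError(
                f"mean threshold ({self.theta_mean}) must exceed reset ({self.V_r})"
            )

    @property
    def rate_ceiling(self) -> float:
        """Maximum attainable firing rate 1/tau_ref, in Hz."""
        return np.inf if self.tau_ref == 0 else 1000.0 / self.tau_ref


@dataclass(frozen=True)
class PopulationStructure:
    """Circuit size and sparse random-connectivity statistics.

    Any ordered pair of distinct neurons is connected independently with
    probability ``eps``, so the mean in-degree is ``K = eps * N``. A fraction
    ``gamma`` of the neurons is excitatory.
    """

    N: int = 1000
    gamma: float = 0.8
    eps: float = 0.2

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("eps must be in [0, 1]")

    @property
    def K(self) -> float:
        """Mean number of synapses onto a given neuron."""
        return self.eps * self.N

    @property
    def n_exc(self) -> int:
        return int(round(self.gamma * self.N))

    @property
    def n_inh(self) -> int:
        return self.N - self.n_exc


@dataclass(frozen=True)
class SynapticWeights:
    """Voltage jump (mV) per presynaptic spike, indexed post-pre.

    ``J_EI`` is the weight of an inhibitory synapse onto an excitatory
    neuron (first label postsynaptic). Excitatory weights are nonnegative,
    inhibitory weights nonpositive.
    """

    J_EE: float = 0.05
    J_IE: float = 0.05
    J_EI: float = -0.08
    J_II: float = -0.08

    def __post_init__(self) -> None:
        if self.J_EE < 0 or self.J_IE < 0:
            raise ValueError("excitatory weights J_EE, J_IE must be >= 0")
        if self.J_EI > 0 or self.J_II > 0:
            raise ValueError("inhibitory weights J_EI, J_II must be <= 0")

    def weight(self, post_exc: bool, pre_exc: bool) -> float:
        if pre_exc:
            return self.J_EE if post_exc else self.J_IE
        return self.J_EI if post_exc else self.J_II


@dataclass(frozen=True)
class HeterogeneityLevels:
    """Standard deviations (mV) of the Gaussian threshold distributions."""

    w_E: float = 0.1
    w_I: float = 0.1

    def __post_init__(self) -> None:
        if self.w_E < 0 or self.w_I < 0:
            raise ValueError("heterogeneity widths must be >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Complete static description of the circuit ensemble."""

    constants: NeuronConstants = field(default_factory=NeuronConstants)
    structure: PopulationStructure = field(default_factory=PopulationStructure)
    weights: SynapticWeights = field(default_factory=SynapticWeights)
    heterogeneity: HeterogeneityLevels = field(default_factory=HeterogeneityLevels)

    def with_heterogeneity(self, w_E: float | None = None, w_I: float | None = None) -> "NetworkSpec":
        """Return a copy with modified heterogeneity widths."""
        het = HeterogeneityLevels(
            w_E=self.heterogeneity.w_E if w_E is None else w_E,
            w_I=self.heterogeneity.w_I if w_I is None else w_I,
        )
        return replace(self, heterogeneity=het)


def default_spec() -> NetworkSpec:
    """The reference parameter set for a cortical-like sparse E-I circuit.

    N = 1000 neurons, 80% excitatory, connection probability 0.2 (mean
    in-degree K = 200), tau_m = 20 ms, V_r = 10 mV, theta = 20 mV,
    tau_ref = 5 ms, J_EE = J_IE = 0.05 mV, J_EI = J_II = -0.08 mV.
    """
    return NetworkSpec()


def sample_thresholds(
    count: int,
    mean: float,
    width: float,
    rng: np.random.Generator,
    v_reset: float = 10.0,
) -> np.ndarray:
    """Draw per-neuron firing thresholds from Normal(mean, width).

    Values at or below the reset potential are rejection-resampled: a
    threshold below reset would make the neuron fire continuously and
    invalidate the diffusion treatment. At the widths of interest
    (width <= 2.5 mV with mean - v_reset = 10 mV) the rejected mass is
    below 3e-7, so the sampled law is indistinguishable from the stated
    Gaussian.

    Parameters
    ----------
    count : int
        Number of thresholds, >= 1.
    mean, width : float
        Gaussian mean and standard deviation (mV); ``width = 0`` yields a
        homogeneous population.
    rng : numpy.random.Generator
        Source of randomness.
    v_reset : float
        Reset potential (mV); every returned threshold is strictly above it.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if width < 0:
        raise ValueError("width must be >= 0")
    if mean <= v_reset:
        raise ValueError(
            f"threshold mean ({mean}) must exceed the reset potential ({v_reset})"
        )
    if width == 0.0:
        return np.full(count, float(mean))
    theta = rng.normal(mean, width, size=count)
    bad = theta <= v_reset
    while np.any(bad):
        theta[bad] = rng.normal(mean, width, size=int(bad.sum()))
        bad = theta <= v_reset
    return theta


@dataclass
class NetworkRealization:
    """One quenched sample of a :class:`NetworkSpec`.

    Attributes
    ----------
    spec : NetworkSpec
        The generating specification.
    thresholds : ndarray, shape (N,)
        Per-neuron firing thresholds (mV), all strictly above ``V_r``.
    is_exc : ndarray of bool, shape (N,)
        Population label; the first ``round(gamma*N)`` neurons are excitatory.
    connectivity : scipy.sparse.csc_matrix, shape (N, N)
        Directed weighted adjacency, entry (i, j) is the voltage jump (mV)
        neuron i receives when presynaptic neuron j spikes. CSC layout so
        that a presynaptic neuron's outgoing column is contiguous, which is
        what the integrator walks on every spike.
    seed_record : int
        Master seed the realization was built from.
    """

    spec: NetworkSpec
    thresholds: np.ndarray
    is_exc: np.ndarray
    connectivity: sp.csc_matrix
    seed_record: int

    @property
    def N(self) -> int:
        return self.thresholds.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkRealization):
            return NotImplemented
        return (
            self.spec == other.spec
            and self.seed_record == other.seed_record
            and np.array_equal(self.thresholds, other.thresholds)
            and np.array_equal(self.is_exc, other.is_exc)
            and (self.connectivity != other.connectivity).nnz == 0
        )


def build_realization(spec: NetworkSpec, seed: int) -> NetworkRealization:
    """Sample thresholds and connectivity for one concrete network.

    Each ordered pair (i, j), i != j, carries a synapse independently with
    probability ``eps``; its weight is fixed by the postsynaptic/presynaptic
    population labels. Self-connections are excluded. Thresholds are drawn
    per population via :func:`sample_thresholds`.

    Two independent RNG streams (thresholds, connectivity) are spawned from
    the master seed so the same quenched network can later be re-simulated
    with fresh dynamical noise.
    """
    ss = np.random.SeedSequence(int(seed))
    rng_theta, rng_conn = (np.random.default_rng(s) for s in ss.spawn(2))

    st = spec.structure
    nc = spec.constants
    n_e, n_i = st.n_exc, st.n_inh
    N = st.N

    is_exc = np.zeros(N, dtype=bool)
    is_exc[:n_e] = True

    theta = np.empty(N)
    theta[:n_e] = sample_thresholds(
        n_e, nc.theta_mean, spec.heterogeneity.w_E, rng_theta, nc.V_r
    )
    if n_i > 0:
        theta[n_e:] = sample_thresholds(
            n_i, nc.theta_mean, spec.heterogeneity.w_I, rng_theta, nc.V_r
        )

    if st.eps == 0.0:
        conn = sp.csc_matrix((N, N))
    else:
        mask = rng_conn.random((N, N)) < st.eps
        np.fill_diagonal(mask, False)
        post, pre = np.nonzero(mask)
        w = spec.weights
        row_w = np.where(is_exc, w.J_EE, w.J_IE)  # weight by post label, pre = E
        row_w_i = np.where(is_exc, w.J_EI, w.J_II)  # pre = I
        data = np.where(is_exc[pre], row_w[post], row_w_i[post])
        conn = sp.csc_matrix((data, (post, pre)), shape=(N, N))

    return NetworkRealization(
        spec=spec,
        thresholds=theta,
        is_exc=is_exc,
        connectivity=conn,
        seed_record=int(seed),
    )
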