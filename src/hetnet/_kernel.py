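"""Compiled Euler-Maruyama integration kernel for the LIF network.

Kept free of any package imports so numba can compile it in isolation. The
membrane update per step dt is

    V += (dt/tau_m) * (mu_i(t) - V) + sigma * sqrt(dt/tau_m) * N(0, 1) + rec,

where ``rec`` collects the delta-synapse jumps J_ij from presynaptic spikes
of the *previous* step (effective one-step transmission delay <= dt). A
neuron whose potential reaches its threshold at the end of a step emits a
spike, is reset to V_r and clamped there for tau_ref, discarding all input
while refractory.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_lif(
    V0,
    thetas,
    is_exc,
    indptr,
    indices,
    data,
    mu_e,
    mu_i,
    sigma,
    s0,
    f_s,
    tau_m,
    V_r,
    dt,
    n_steps,
    ref_steps,
    seed,
    spike_t,
    spike_i,
):
    np.random.seed(seed)
    N = V0.shape[0]
    V = V0.copy()
    ref = np.zeros(N, dtype=np.int64)
    rec = np.zeros(N)
    noise_scale = sigma * np.sqrt(dt / tau_m)
    leak = dt / tau_m
    omega = 2.0 * np.pi * f_s / 1000.0  # rad per ms
    count = 0
    for k in range(n_steps):
        t = k * dt
        sig = s0 * np.sin(omega * t) if s0 > 0.0 else 0.0
        noise = np.random.standard_normal(N)
        for i in range(N):
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = V_r
            else:
                mu = mu_e + sig if is_exc[i] else mu_i
                V[i] += leak * (mu - V[i]) + noise_scale * noise[i] + rec[i]
            rec[i] = 0.0
        t_spk = t + dt
        for i in range(N):
            if ref[i] == 0 and V[i] >= thetas[i]:
                spike_t[count] = t_spk
                spike_i[count] = i
                count += 1
                V[i] = V_r
                ref[i] = ref_steps
                for p in range(indptr[i], indptr[i + 1]):
                    rec[indices[p]] += data[p]
    return count
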