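# hetnet

Simulation and mean-field analysis of **heterogeneous sparse
excitatory–inhibitory spiking networks**.

Cortical circuits are not made of identical neurons: even within one cell
class, excitability varies from cell to cell. `hetnet` implements a
sparse random network of leaky integrate-and-fire neurons in which every
neuron carries its own firing threshold, drawn from population-specific
Gaussian distributions — width `w_E` for the excitatory population, `w_I`
for the inhibitory one — together with the diffusion-approximation
mean-field theory of the same circuit. It is written for computational
neuroscientists who want to study, analytically and numerically, how
population-specific *quenched* heterogeneity reshapes network activity:
firing-rate distributions, f-I curves and divisive gain control,
synchronization onset, and rate-coded transmission of slow signals.

## Model

Each of N neurons (fraction γ excitatory; directed connection probability
ε, mean in-degree K = εN) obeys

    τ_m dV_i/dt = −V_i + μ_i(t) + σ √τ_m ξ_i(t) + τ_m Σ_{j,k} J_ij δ(t − t_j^k),

spiking and resetting to V_r (clamped for τ_ref) whenever V_i reaches its
own threshold θ_i ~ Normal(θ, w_α). Stationary population rates solve the
self-consistent pair

    ν_E = Φ_E(ν_E, ν_I; w_E, w_I),    ν_I = Φ_I(ν_E, ν_I; w_E, w_I),

where Φ_α is the first-passage (Siegert) rate of a single neuron under the
diffusion approximation, averaged over the population's threshold
distribution (Gauss–Hermite / truncated-Gauss–Legendre quadrature) with
recurrent input moments closed through the mean in-degrees. See
`docs/methods.md` for the full account.

## Worked example

Divisive gain control by inhibitory heterogeneity: compare mean-field
excitatory f-I curves at `w_I = 0` and `w_I = 2 mV` in the strong-inhibition
configuration, and fit a single multiplicative factor between them.

```python
import numpy as np
from dataclasses import replace
from hetnet import default_spec, fI_curve, optimal_rescaling
from hetnet.core import SynapticWeights

spec = replace(default_spec(),
               weights=SynapticWeights(J_EE=0.05, J_IE=0.05, J_EI=-0.4, J_II=-0.08))
grid = np.linspace(10.0, 15.5, 25)            # mV, sub-saturation regime
c0 = fI_curve(spec.with_heterogeneity(0.1, 0.0), grid, mu0=12.0, sigma=3.0)
c2 = fI_curve(spec.with_heterogeneity(0.1, 2.0), grid, mu0=12.0, sigma=3.0)
fit = optimal_rescaling(c0, c2)
print(f"zeta = {fit.zeta:.4f}, Delta = {fit.delta:.2e}")
```

Output:

    zeta = 0.7799, Delta = 8.55e-04

Meaning: multiplying the homogeneous-inhibition f-I curve by the single
constant 0.78 reproduces the `w_I = 2 mV` curve with a mean squared
distance of under 10⁻³ Hz² across all 25 input levels — inhibitory
heterogeneity scales the excitatory transfer function down without shifting
it, i.e. it acts as a divisive gain control knob.

A simulation to compare against the theory:

```python
from hetnet import build_realization, simulate, mean_rates, solve_fixed_point, DriveSpec

spec = default_spec().with_heterogeneity(2.0, 0.1)
real = build_realization(spec, seed=42)
spikes = simulate(real, DriveSpec(mu=15, mu0=15, sigma=3), duration=3000, dt=0.01, seed=7)
rates = mean_rates(spikes, transient=500)
fp = solve_fixed_point(spec, 15.0, 15.0, 3.0)
print(f"sim nu_E = {rates[real.is_exc].mean():.2f} Hz, mean-field nu_E = {fp.nu_E:.2f} Hz")
```

Output:

    sim nu_E = 5.88 Hz, mean-field nu_E = 6.03 Hz

## Command line

    hetnet simulate  --config net.cfg --seed 1 --out runs/
    hetnet meanfield --config net.cfg --sweep wE=0:2.5:0.1 --out rates.csv
    hetnet stability --config net.cfg --out onset.csv
    hetnet gainfit   --curve0 c0.csv --curvew cw.csv --out fit.json
    hetnet signal    --config net.cfg --sweep wE=0.1:2.5:0.5 --out cov.csv
    hetnet run-preset fig3e --out results/   # named experiment presets

Configs are flat INI files (`[neuron]`, `[structure]`, `[weights]`,
`[heterogeneity]`, `[drive]`, `[sim]`); spike data and sweep results are
plain-text columnar files with commented headers.

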