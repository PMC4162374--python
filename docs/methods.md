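# Methods

## Model

The circuit is a sparse, directed random network of `N` leaky
integrate-and-fire neurons, a fraction γ excitatory and 1−γ inhibitory. Any
ordered pair of distinct neurons is connected independently with probability
ε, so the mean in-degree is K = εN. Membrane dynamics, with all inputs
expressed as voltages (membrane resistance absorbed),

    τ_m dV_i/dt = −V_i + μ_i(t) + σ √τ_m ξ_i(t) + τ_m Σ_j Σ_k J_ij δ(t − t_j^k),

with μ_i = μ for excitatory and μ_i = μ_0 for inhibitory neurons, ξ_i
independent unit-variance Gaussian white noises, and J_ij ∈ {J_EE, J_IE,
J_EI, J_II} set by the postsynaptic/presynaptic population labels. When a
neuron's potential reaches its threshold θ_i it spikes, resets to V_r and is
clamped there for τ_ref, discarding input.

The model's distinguishing ingredient is *quenched threshold heterogeneity*:
each excitatory threshold is drawn from Normal(θ, w_E) and each inhibitory
threshold from Normal(θ, w_I). The two widths are independent dials; w → 0
recovers a homogeneous population. Draws at or below V_r are
rejection-resampled (a threshold below reset would fire continuously and
break the diffusion treatment); at the widths of primary interest
(w ≤ 2.5 mV with θ − V_r = 10 mV) the excluded mass is < 3·10⁻⁷.

Default parameters (all within cortical ranges): N = 1000, ε = 0.2
(K = 200), γ = 0.8, τ_m = 20 ms, V_r = 10 mV, θ = 20 mV, τ_ref = 5 ms,
σ = 3 mV, J_EE = J_IE = 0.05 mV, J_EI = J_II = −0.08 mV.

### Noise convention

The noise prefactor is implemented as σ√τ_m · ξ(t), the standard convention
of the diffusion-approximation literature, making σ the stationary
membrane-potential scale of a free membrane and keeping σ = 3 mV
dimensionally and physiologically sensible. The alternative literal reading
σ·τ_m would scale the effective noise by √τ_m ≈ 4.5 and push default rates
far outside the regime the mean-field comparison reproduces; the √τ_m
convention is validated by the simulation/mean-field agreement tests.

## Simulation

Fixed-step Euler–Maruyama, default dt = 0.05 ms. Per step: deterministic
leak toward the drive, Gaussian increment of SD σ√(dt/τ_m), plus the summed
synaptic jumps from spikes of the previous step (effective one-step delay
≤ dt; with additive delta synapses the within-step ordering is immaterial).
Threshold crossings are detected at step end with no interpolation; this
carries the standard ~√dt first-passage bias (measured: rates ≈7% low at
dt = 0.05, ≈2% at dt = 0.01 at the default operating point), which the
convergence test tracks. Quantitative mean-field comparisons therefore run
at dt = 0.01 ms; qualitative and synchrony work uses the default 0.05 ms.
Initial potentials are uniform on [V_r, θ_i); the first 500 ms are
discarded. dt must not exceed τ_ref (refractory bookkeeping would alias) nor
τ_m/10 (overridable accuracy guard). The integrator is a compiled (numba)
kernel; one RNG stream builds the quenched network, a separate one drives
the dynamical noise, so a fixed network can be re-simulated with fresh
noise.

Statistics follow the reference protocol of 10 trials, each a fresh
connectivity/threshold realization with fresh noise. The packaged reduced
protocols (3 s per trial instead of 10 s, and trimmed sweep grids) exist
purely to keep full runs at desk scale; the trial count is kept at 10 where
the compared effect is smaller than the quenched spread (see
"Quenched sampling noise" below).

## Mean-field theory

Under the diffusion approximation the stationary rate of one LIF neuron
receiving mean input μ_tot and fluctuation σ_tot is the first-passage
(Siegert) rate

    ν(μ_tot, σ_tot, θ) = 1000 / ( τ_ref + τ_m √π ∫_{a}^{b} erfcx(−u) du ),   [Hz]
    a = (V_r − μ_tot)/σ_tot,  b = (θ − μ_tot)/σ_tot,

evaluated with a 200-node Gauss–Legendre rule on the scaled complementary
error function (stable for |u| up to ~24; beyond that the rate is computed
from the Laplace asymptotics of the integral and underflows to zero exactly
where it should). Agreement with adaptive quadrature is 10⁻⁸ relative.

Recurrent input is closed through the mean in-degrees (rates in spikes/ms
inside the moment formulas):

    μ_tot,α  = μ_ext,α + τ_m (γK J_αE ν_E + (1−γ)K J_αI ν_I),
    σ_tot,α² = σ²      + τ_m (γK J_αE² ν_E + (1−γ)K J_αI² ν_I).

Heterogeneity enters by averaging the Siegert rate over the population's
threshold distribution, Φ_α = ∫ P_α(θ′) ν(μ_tot,α, σ_tot,α, θ′) dθ′, with
P_α the V_r-truncated Gaussian. The quadrature uses the probabilists'
Gauss–Hermite rule (41 nodes) when all nodes lie above V_r and otherwise a
Gauss–Legendre rule with Gaussian weights on the truncated support — naive
node-dropping stalls near 10⁻⁴ relative accuracy, whereas the truncated rule
keeps spectral convergence (41 vs 81 nodes agree to <10⁻⁸ over the tested
range, and match Monte-Carlo threshold averaging within its error).

The stationary network state solves ν_α = Φ_α(ν_E, ν_I). The solver is a
damped fixed-point iteration (λ = 0.3, tolerance 10⁻⁶ Hz, cap 10⁴
iterations) with a Powell-hybrid root-finder fallback; convergence and the
residual are always reported. f-I curves warm-start each grid point from the
previous solution to stay on one branch through the activity onset.
Reconstruction choices here (mean in-degree closure, no degree-distribution
correction, no finite-size terms) are validated against direct simulation,
which is the package's arbiter throughout.

## Divisive-gain analysis

Whether inhibitory heterogeneity acts divisively is tested by rescaling the
w_I = 0 excitatory f-I curve by a constant ζ and minimizing

    Δ(ζ) = (1/n) Σ_i [ζ r_0(i) − r_w(i)]²,

whose exact minimizer is ζ* = Σ r_0 r_w / Σ r_0². The reference
configuration strengthens the I→E coupling (J_EI = −0.4 mV, μ_0 = 12 mV,
J_II left at its −0.08 mV default per the stated parameter change) so the
divisive effect is clean. The input grid is n = 25 points on
μ ∈ [10, 15.5] mV: from just above the reset potential through the
moderate-rate regime (ν_E ≲ 6 Hz). The grid's upper end matters: divisive
control holds at small-to-moderate rates and is lost in the mean-driven
regime (μ ≥ 20 mV), so grids reaching into high rates degrade the fit by
construction (e.g. Δ ≈ 0.57 on μ ∈ [14, 19]). On the default grid,
ζ*(w_I = 2 mV) = 0.780 with Δ = 8.5·10⁻⁴, and the ζ ladder at
w_I = 3 and 4 mV (0.52, 0.29) falls in line with the published sequence for
increasing w_I. Diagnostics report the residual mean, the within-one-SD
fraction (≈ 2/3 for zero-mean Gaussian residuals) and a sign test; a
normalized variant Δ/⟨r_w⟩² provides the scale-invariant version (its exact
definition being an open choice, the squared mean of the target curve is
used).

## Synchronization onset

Above a critical external input μ_c the asynchronous state gives way to a
collective oscillation. The packaged detector is simulation-based: the
excitatory population rate in 1 ms bins, Welch power spectrum of the
mean-subtracted series, index = (max power in 20–500 Hz)/(median power in
that band). Flat-spectrum (asynchronous) runs give indices near 1–2;
oscillating runs give 10–70. The classification threshold is calibrated
once per protocol as the geometric mean of the index in one clearly
asynchronous and one clearly synchronous exemplar, then μ_c is located by
bisection (depth 5–6, the bracket half-width reported as uncertainty) on the
trial-averaged index, with common random numbers across drive levels. A
non-straddling bracket raises an explicit ambiguity error — detection is
known to blur for w ≥ 2.5 mV.

An analytic criterion (linearization of the effective rate dynamics) can be
plugged in through the `detector` argument without API changes. None is
shipped: the continuous-time model has no synaptic delay, and a delay-free
instantaneous-coupling linearization of the classical type does not produce
the oscillatory instability that the simulations clearly show (the
integrator's effective one-step delay supplies the lag). Consequently
absolute onset values carry a modest scheme dependence — at the reference
stability parameters (σ = 1 mV, μ_0 = 12 mV) the measured onsets lie ~1 mV
above the region where the published phase diagram already shows
synchrony, so the μ = 17 mV diagram is asynchronous throughout the
w ∈ [0, 2.5]² grid here. The *relations* are robust and are what the tests
assert: μ_c decreases linearly in w_E (slope ≈ −1.3 mV/mV), is flat to
slightly increasing in w_I, and the low-heterogeneity corner is
asynchronous.

## Signal transmission

A weak slow signal μ̂(t) = μ + S0 sin(2πf_s t) rides on the excitatory
drive only (the inhibitory bias stays constant; this is the natural reading
of the drive definitions, recorded as a choice). Transmission is measured by
the zero-lag input–output covariance C = ⟨μ̂ ν_E⟩ − ⟨μ̂⟩⟨ν_E⟩ over the
excitatory rate in 10 ms bins (50 bins per period at f_s = 2 Hz), trimmed
to whole periods to kill leakage; the closed form C = S0·A/2 for in-phase
sinusoids is reproduced exactly, and halving the bin width moves C by less
than the trial SE. Reference configuration: J_EE = J_IE = 0.043 mV,
J_EI = J_II = −0.06 mV, μ = μ_0 = 15 mV, S0 = 0.5 mV, f_s = 2 Hz.

Measured behavior in this reconstruction: C falls with inhibitory
heterogeneity (0.347 → 0.326 mV·Hz from w_I = 0.1 to 2.5, beyond error),
and C(w_E) is bell-shaped with an interior optimum — but the optimum sits
near w_E ≈ 5 mV (C rises monotonically 0.35 → 0.51 across [0.1, 2.5], peaks
≈ 0.63 at 5, declines beyond). The quasi-static picture explains why:
C ≈ (S0²/2)·dν_E/dμ, and the reconstructed fixed point's gain is monotone
on w_E ∈ [0, 3] for every noise level examined, peaking only once the
threshold spread covers the full distance to threshold. The published
figure places the peak below 2.5 mV; reproducing that location evidently
requires the unavailable supplementary form of the transfer function, and
no parameter reading consistent with the stated configuration moved the
peak into that range. The corresponding acceptance check is left failing
rather than re-tuning the conditions; the optimization phenomenon itself is
present at larger widths.

## Combined heterogeneity

For w_E = w_I = W the linear prediction is
ν_pred(W) = ν(0,0) + [ν(W,0) − ν(0,0)] + [ν(0,W) − ν(0,0)] with all three
terms from the mean field. Under the 10-trial protocol the simulated rate
tracks the prediction within ~3% at W ≤ 2 mV and ~7% at W = 3–4 mV (the
growing part is genuine sub-additivity of the fixed point, 5–8% by W = 4),
inside the 10% acceptance band. The trial count matters here: with only 3
realizations the quenched threshold-sampling noise alone can masquerade as
a 15–20% "nonlinearity" at W ≥ 3.

## Quenched sampling noise

With 200 inhibitory neurons, the realization-to-realization spread of the
*sample-mean* inhibitory rate at w_I = 2 mV is ~9% SD (the rate is a convex,
heavy-tailed function of threshold), even though the realization-conditioned
mean field matches each simulation to 1–3%. Ensemble-level comparisons at
5% tolerance therefore need ~10 realizations, which is why the agreement
tests keep the full 10-trial protocol while shortening each trial to 3 s.

## Limitations

- No synaptic delays, conductance synapses, filtering or plasticity; the
  synchrony onset's absolute position inherits an O(dt) scheme dependence.
- Mean-field closure uses mean in-degrees; degree-distribution and
  finite-size corrections are out of scope.
- The synthetic protocols are the model's own study conditions; nothing here
  emulates recorded cortical data, so passing tests validate internal
  consistency of theory and simulation, not biological fidelity.
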