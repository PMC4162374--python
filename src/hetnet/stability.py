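"""Synchronization onset and the heterogeneity phase diagram.

The asynchronous stationary state loses stability when the external drive
exceeds a critical value mu_c that depends on the heterogeneity widths
(w_E, w_I). The onset is located empirically: the trial-averaged synchrony
index of the excitatory population rate (spectral peak prominence, see
:func:`hetnet.simulator.synchrony_index`) is compared against a calibrated
threshold, and mu_c is bracketed by bisection. The detector is pluggable so
an analytic criterion (e.g. linearization of the effective rate dynamics)
can replace the simulation-based one without API changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from hetnet.core import NetworkSpec, build_realization
from hetnet.simulator import DriveSpec, SimConfig, population_rate, simulate, synchrony_index

__all__ = [
    "StabilityResult",
    "PhaseDiagram",
    "AmbiguousOnsetError",
    "mean_synchrony",
    "calibrate_threshold",
    "critical_input_sim",
    "linear_onset_fit",
    "phase_diagram",
]


class AmbiguousOnsetError(RuntimeError):
    """Raised when the synchrony index does not straddle the threshold.

    Quenched disorder plus dynamical noise can blur the onset at large
    heterogeneity (w >= 2.5 mV), where detection is known to be unreliable.
    """


@dataclass
class StabilityResult:
    """Critical external input locating the asynchronous-synchronous onset."""

    mu_critical: float  # mV
    method: str  # 'simulation' or 'analytic'
    threshold: float  # synchrony-index threshold used
    uncertainty: float  # half-width of the final bisection bracket, mV
    w_E: float = np.nan
    w_I: float = np.nan


@dataclass
class PhaseDiagram:
    """Regime classification over a (w_E, w_I) grid at fixed drive."""

    w_E: np.ndarray
    w_I: np.ndarray
    synchronous: np.ndarray  # bool matrix, shape (len(w_E), len(w_I))
    index: np.ndarray  # trial-averaged synchrony index per cell
    mu: float
    mu0: float
    threshold: float

    @property
    def synchronous_count(self) -> int:
        return int(self.synchronous.sum())


def mean_synchrony(
    spec: NetworkSpec,
    drive: DriveSpec,
    config: SimConfig,
    rate_bin: float = 1.0,
) -> float:
    """Trial-averaged synchrony index of the excitatory population rate.

    Each trial uses a fresh quenched realization and fresh dynamical noise,
    both derived deterministically from ``config.master_seed``.
    """
    ss = np.random.SeedSequence(config.master_seed)
    seeds = ss.generate_state(2 * config.n_trials).astype(np.int64) % (2**31 - 1)
    vals = []
    for k in range(config.n_trials):
        real = build_realization(spec, int(seeds[2 * k]))
        spikes = simulate(
            real, drive, config.duration, dt=config.dt, seed=int(seeds[2 * k + 1])
        )
        series = population_rate(spikes, rate_bin, "E")
        vals.append(synchrony_index(series, transient=config.transient))
    return float(np.mean(vals))


def calibrate_threshold(index_async: float, index_sync: float) -> float:
    """Synchrony threshold as the geometric mean of two exemplar indices.

    ``index_async`` and ``index_sync`` should come from clearly asynchronous
    and clearly synchronous reference runs of the same protocol.
    """
    if index_async <= 0 or index_sync <= index_async:
        raise ValueError("need 0 < index_async < index_sync")
    return float(np.sqrt(index_async * index_sync))


def critical_input_sim(
    spec: NetworkSpec,
    drive_template: DriveSpec,
    mu_bracket: tuple[float, float],
    threshold: float,
    config: SimConfig,
    depth: int = 6,
    detector: Callable[[NetworkSpec, DriveSpec, SimConfig], float] | None = None,
) -> StabilityResult:
    """Bisect the external input for the synchronization onset.

    The synchrony index must straddle ``threshold`` across ``mu_bracket``
    (asynchronous at the lower end, synchronous at the upper); otherwise
    :class:`AmbiguousOnsetError` is raised. Returns the bracket midpoint
    after ``depth`` bisection steps with the half-width as uncertainty.
    """
    from dataclasses import replace

    detect = detector or mean_synchrony
    lo, hi = float(mu_bracket[0]), float(mu_bracket[1])
    if not lo < hi:
        raise ValueError("mu_bracket must be increasing")

    def index_at(mu: float) -> float:
        return detect(spec, replace(drive_template, mu=mu), config)

    i_lo, i_hi = index_at(lo), index_at(hi)
    if not (i_lo < threshold <= i_hi):
        raise AmbiguousOnsetError(
            f"synchrony index does not straddle threshold {threshold:.3g} over "
            f"bracket ({lo}, {hi}): index({lo})={i_lo:.3g}, index({hi})={i_hi:.3g}"
        )
    for _ in range(depth):
        mid = 0.5 * (lo + hi)
        if index_at(mid) >= threshold:
            hi = mid
        else:
            lo = mid
    return StabilityResult(
        mu_critical=0.5 * (lo + hi),
        method="simulation" if detector is None else "analytic",
        threshold=threshold,
        uncertainty=0.5 * (hi - lo),
        w_E=spec.heterogeneity.w_E,
        w_I=spec.heterogeneity.w_I,
    )


def linear_onset_fit(
    w_values: np.ndarray, results: list[StabilityResult] | np.ndarray
) -> tuple[float, float, float]:
    """Least-squares line through the critical input as a function of w.

    Returns ``(slope, intercept, rms_residual)``. The onset is expected to
    move to lower inputs as excitatory heterogeneity grows, i.e. negative
    slope.
    """
    w = np.asarray(w_values, dtype=float)
    mu_c = np.asarray(
        [r.mu_critical if isinstance(r, StabilityResult) else r for r in results],
        dtype=float,
    )
    if w.size < 3 or w.size != mu_c.size:
        raise ValueError("need >= 3 matched (w, mu_c) points")
    slope, intercept = np.polyfit(w, mu_c, 1)
    resid = mu_c - (slope * w + intercept)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2)))


def phase_diagram(
    spec_template: NetworkSpec,
    w_E_grid: np.ndarray,
    w_I_grid: np.ndarray,
    mu: float,
    mu0: float,
    sigma: float,
    threshold: float,
    config: SimConfig,
    detector: Callable[[NetworkSpec, DriveSpec, SimConfig], float] | None = None,
) -> PhaseDiagram:
    """Classify every (w_E, w_I) cell as asynchronous or synchronous.

    Cells are synchronous where the trial-averaged synchrony index exceeds
    ``threshold`` at external input ``mu`` and inhibitory bias ``mu0``.
    """
    detect = detector or mean_synchrony
    w_E_grid = np.asarray(w_E_grid, dtype=float)
    w_I_grid = np.asarray(w_I_grid, dtype=float)
    drive = DriveSpec(mu=mu, mu0=mu0, sigma=sigma)
    index = np.empty((w_E_grid.size, w_I_grid.size))
    for i, we in enumerate(w_E_grid):
        for j, wi in enumerate(w_I_grid):
            cell_cfg = SimConfig(
                duration=config.duration,
                dt=config.dt,
                transient=config.transient,
                n_trials=config.n_trials,
                master_seed=config.master_seed + 1000 * i + j,
            )
            index[i, j] = detect(spec_template.with_heterogeneity(we, wi), drive, cell_cfg)
    return PhaseDiagram(
        w_E=w_E_grid,
        w_I=w_I_grid,
        synchronous=index >= threshold,
        index=index,
        mu=mu,
        mu0=mu0,
        threshold=threshold,
    )
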