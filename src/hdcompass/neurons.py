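"""Leaky integrate-and-fire dynamics and per-cell firing-rate statistics.

This module holds the lowest layer of the model: the spiking neuron
population, the synaptic current kinetics, and the three rate statistics
that every calibration rule upstream consumes:

* ``instantaneous_rate`` r_i -- an interspike-interval based estimate that
  equals 1/ISI at spike instants and decays exponentially (tau = 33 ms)
  while the cell is silent.  A cell that has never completed an ISI reads 0.
* ``short_term_average`` m_s -- an exponential moving average of r_i with a
  20 ms time constant.  The difference r_i - m_s ("delta rate") is positive
  on the leading edge of a moving activity bump and negative on its
  trailing edge.
* ``firing_trace`` -- a slowly decaying record of the highest recent firing
  rate (tau = 2000 ms), used to decide whether a landmark reset moved the
  bump forward into fresh territory or backward over recently visited cells.

Voltages are dimensionless: rest = 0, threshold = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFParams",
    "PopulationState",
    "SynapseKinetics",
    "step_lif",
    "estimate_rate",
    "delta_rate",
    "update_short_term_average",
    "update_trace",
]

#: time constant of the instantaneous-rate estimator (s)
RATE_TAU = 0.033
#: time constant of the short-term average (s)
SHORT_TERM_TAU = 0.020
#: time constant of the long firing trace (s)
TRACE_TAU = 2.0


@dataclass
class LIFParams:
    """Leaky integrate-and-fire cell parameters (free, fixed by calibration)."""

    tau_m: float = 0.010        # membrane time constant (s)
    v_thresh: float = 1.0       # spike threshold
    v_reset: float = 0.0        # post-spike reset potential
    v_rest: float = 0.0         # resting potential
    t_ref: float = 0.005        # absolute refractory period (s)


@dataclass
class PopulationState:
    """Dynamic state of one spiking population.

    ``last_spike_time``/``previous_spike_time`` start at -inf so that cells
    which have never spiked (or spiked only once) report a zero
    instantaneous rate.
    """

    n: int
    membrane_potential: np.ndarray = field(default=None)
    last_spike_time: np.ndarray = field(default=None)
    previous_spike_time: np.ndarray = field(default=None)
    inv_isi: np.ndarray = field(default=None)           # 1/most-recent ISI (Hz)
    instantaneous_rate: np.ndarray = field(default=None)
    short_term_average: np.ndarray = field(default=None)
    firing_trace: np.ndarray = field(default=None)
    refractory_remaining: np.ndarray = field(default=None)
    time: float = 0.0

    def __post_init__(self) -> None:
        z = lambda: np.zeros(self.n)
        if self.membrane_potential is None:
            self.membrane_potential = z()
        if self.last_spike_time is None:
            self.last_spike_time = np.full(self.n, -np.inf)
        if self.previous_spike_time is None:
            self.previous_spike_time = np.full(self.n, -np.inf)
        for name in ("inv_isi", "instantaneous_rate", "short_term_average",
                     "firing_trace", "refractory_remaining"):
            if getattr(self, name) is None:
                setattr(self, name, z())

    def copy(self) -> "PopulationState":
        return PopulationState(
            n=self.n,
            membrane_potential=self.membrane_potential.copy(),
            last_spike_time=self.last_spike_time.copy(),
            previous_spike_time=self.previous_spike_time.copy(),
            inv_isi=self.inv_isi.copy(),
            instantaneous_rate=self.instantaneous_rate.copy(),
            short_term_average=self.short_term_average.copy(),
            firing_trace=self.firing_trace.copy(),
            refractory_remaining=self.refractory_remaining.copy(),
            time=self.time,
        )


@dataclass
class SynapseKinetics:
    """Difference-of-exponentials synaptic filter (fast rise, slow decay).

    Each presynaptic spike contributes a kernel
    ``(exp(-t/tau_decay) - exp(-t/tau_rise)) / peak`` normalised to unit
    peak amplitude.  The filter is linear, so population output is held as
    two per-cell exponential accumulators.
    """

    n: int
    tau_rise: float = 0.001
    tau_decay: float = 0.008
    _acc_decay: np.ndarray = field(default=None)
    _acc_rise: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not self.tau_rise < self.tau_decay:
            raise ValueError("synapse rise time constant must be below decay")
        if self._acc_decay is None:
            self._acc_decay = np.zeros(self.n)
        if self._acc_rise is None:
            self._acc_rise = np.zeros(self.n)
        tr, td = self.tau_rise, self.tau_decay
        t_peak = np.log(td / tr) * tr * td / (td - tr)
        self._peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)

    def step(self, spikes: np.ndarray, dt: float) -> np.ndarray:
        """Advance the filter one step; returns per-cell synaptic output."""
        if dt != getattr(self, "_dt_cache", None):
            self._dt_cache = dt
            self._decay_f = float(np.exp(-dt / self.tau_decay))
            self._rise_f = float(np.exp(-dt / self.tau_rise))
        self._acc_decay *= self._decay_f
        self._acc_rise *= self._rise_f
        if spikes.any():
            self._acc_decay += spikes
            self._acc_rise += spikes
        return (self._acc_decay - self._acc_rise) / self._peak

    @property
    def output(self) -> np.ndarray:
        return (self._acc_decay - self._acc_rise) / self._peak

    def copy(self) -> "SynapseKinetics":
        return SynapseKinetics(self.n, self.tau_rise, self.tau_decay,
                               self._acc_decay.copy(), self._acc_rise.copy())


def step_lif(state: PopulationState, input_current: np.ndarray, dt: float,
             params: LIFParams | None = None) -> np.ndarray:
    """Advance the LIF population by one time step of length ``dt``.

    The membrane decays exponentially toward rest and integrates the input
    current; cells crossing threshold emit a spike, reset, and refresh
    their spike-time bookkeeping.  Refractory cells neither integrate nor
    spike.  Returns the boolean spike flags (and mutates ``state``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    input_current = np.asarray(input_current, dtype=float)
    if input_current.shape != (state.n,):
        raise ValueError(
            f"input current has shape {input_current.shape}, expected ({state.n},)")
    if not np.isfinite(input_current.sum()):
        bad = int(np.flatnonzero(~np.isfinite(input_current))[0])
        raise ValueError(f"non-finite input current for cell {bad}")
    p = params or LIFParams()

    t = state.time + dt
    leak = np.exp(-dt / p.tau_m)
    v = state.membrane_potential
    active = state.refractory_remaining <= 0
    # exact exponential relaxation toward v_rest + I (R = 1)
    target = p.v_rest + input_current
    v_new = target + (v - target) * leak
    np.copyto(v, v_new, where=active)
    state.refractory_remaining = np.maximum(state.refractory_remaining - dt, 0.0)

    spikes = active & (v >= p.v_thresh)
    if spikes.any():
        idx = np.flatnonzero(spikes)
        isi = t - state.last_spike_time[idx]
        finite = np.isfinite(isi)
        state.inv_isi[idx[finite]] = 1.0 / isi[finite]
        state.previous_spike_time[idx] = state.last_spike_time[idx]
        state.last_spike_time[idx] = t
        v[idx] = p.v_reset
        state.refractory_remaining[idx] = p.t_ref

    state.time = t
    state.instantaneous_rate = estimate_rate(state, t)
    update_short_term_average(state, dt)
    return spikes


def estimate_rate(state: PopulationState, t: float,
                  tau: float = RATE_TAU) -> np.ndarray:
    """Instantaneous firing rate: (1/ISI) * exp(-(t - t_s)/tau) per cell.

    Equals the reciprocal of the most recent interspike interval at spike
    instants and decays exponentially afterwards; exactly zero for cells
    that have not yet completed an ISI.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    dt_since = t - state.last_spike_time
    if dt_since.min() < -1e-12:
        raise ValueError("evaluation time precedes a recorded spike time")
    # never-spiked cells have inv_isi = 0 and dt_since = inf -> exactly 0
    return state.inv_isi * np.exp(np.maximum(-dt_since / tau, -745.0))


def delta_rate(state: PopulationState) -> np.ndarray:
    """Instantaneous rate minus its short-term (20 ms) average, per cell."""
    return state.instantaneous_rate - state.short_term_average


def update_short_term_average(state: PopulationState, dt: float,
                              tau: float = SHORT_TERM_TAU) -> PopulationState:
    k = 1.0 - np.exp(-dt / tau)
    state.short_term_average += k * (state.instantaneous_rate
                                     - state.short_term_average)
    return state


def update_trace(state: PopulationState, dt: float,
                 tau: float = TRACE_TAU) -> PopulationState:
    """Decaying record of the highest recent instantaneous rate.

    trace <- max(current rate, trace * exp(-dt/tau)) with tau = 2000 ms,
    giving cells a several-second memory of having been inside the bump.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    np.maximum(state.instantaneous_rate, state.firing_trace * np.exp(-dt / tau),
               out=state.firing_trace)
    return state
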