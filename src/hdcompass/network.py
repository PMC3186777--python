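"""Ring-attractor network: architecture, connectome, and one-step dynamics.

The network is the classic head-direction continuous attractor:

* ``n_hd`` spiking HD cells on a ring, with preferred direction
  ``k * 360/n_hd`` degrees for cell ``k`` (angles increase counter-clockwise).
  Recurrent excitation is Gaussian in circular distance with no autapses;
  this self-excitation sustains a single activity bump.
* Two asymmetric angular-head-velocity (AHV) rings whose inhibitory
  back-projections onto the HD ring are circularly offset, one ring per
  turn direction.  Their tonic, bump-shaped inhibition bounds the bump
  width; a velocity-dependent imbalance between the two rings moves the
  bump.  The rings are rate-coded: their spatial profile follows the HD
  synaptic output and their amplitude is modulated by ``g * |v|`` on the
  side matching the turn direction, where ``g`` is the global turn gain.
* A single symmetric AHV unit delivering an identical speed-proportional
  current to every HD cell (its main role is the teaching signal of the
  drift-removal rule, see :mod:`hdcompass.plasticity`).
* Landmark input: a Gaussian current template centred on the HD cell
  associated with the landmark, gated by a heading-attenuation window that
  is exactly zero once the head deviates more than ``epsilon`` (3 deg)
  from the landmark bearing.

A deliberately miscalibrated initial state is produced by
:func:`apply_circular_bias`, which shifts the postsynaptic targets of the
recurrent excitatory connections and makes the untrained bump drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circular import circ_dist_cells, circ_diff_deg
from .neurons import (LIFParams, PopulationState, SynapseKinetics,
                      delta_rate, step_lif, update_trace)

__all__ = [
    "NetworkParams",
    "Connectome",
    "LandmarkModel",
    "GainState",
    "build_connectome",
    "apply_circular_bias",
    "landmark_current",
    "RingAttractor",
    "step_network",
]


@dataclass
class NetworkParams:
    """All structural and intensity parameters of the ring attractor.

    Absolute current/weight magnitudes are free parameters of the model
    (they are fixed by :func:`hdcompass.metrics.calibrate_physiology`
    against the published physiology anchors: 150 Hz peak rate, 110 deg
    tuning width, 4 s drift period for the standard biased fixture).
    """

    n_hd: int = 200
    b_hh: float = 22.0              # width (cells) of recurrent excitation
    w_exc: float = 0.365            # recurrent excitatory weight scale
    inh_offset: int = 5             # circular offset (cells) of AHV inhibition
    inh_sigma: float = 31.0         # width (cells) of AHV inhibitory kernels
    w_inh: float = 0.1215           # offset inhibitory weight scale
    inh_baseline: float = 1.0       # tonic AHV ring activation
    w_uniform_inh: float = 0.01     # weak global inhibition (winner-take-all)
    velocity_drive: float = 0.0033  # AHV ring modulation per deg/s of g*|v|
    w_sym_current: float = 0.002    # symmetric AHV current per deg/s
    landmark_peak: float = 15.0     # peak landmark reset current
    landmark_epsilon: float = 3.0   # heading window half-width (deg)
    landmark_width_ratio: float = 1.5   # bump-to-connection width ratio
    landmark_sigma: float = 12.0    # template width (cells), bump-core scale
    gain_vote_scale: float = 80.0   # unit-matching factor for per-event votes
    noise_amp: float = 0.2          # per-step membrane noise current (sd)
    threshold_jitter: float = 0.05  # relative spread of per-cell thresholds
    syn_tau_rise: float = 0.001     # synaptic rise time constant (s)
    syn_tau_decay: float = 0.024    # synaptic decay time constant (s)
    lif: LIFParams = field(default_factory=LIFParams)

    @property
    def deg_per_cell(self) -> float:
        return 360.0 / self.n_hd


@dataclass
class Connectome:
    """All weight matrices of the architecture plus the bias fixture state.

    ``w_hh[j, i]`` is the excitatory weight from presynaptic HD cell ``i``
    to postsynaptic HD cell ``j``; its diagonal (autapses) is exactly zero.
    ``m_ccw``/``m_cw`` are the combined AHV-ring inhibitory projections,
    folded into circulant matrices: the ring recruited during counter-
    clockwise (positive) turns inhibits the trailing side of the bump,
    pushing it counter-clockwise, and symmetrically for ``m_cw``.
    """

    params: NetworkParams
    w_hh: np.ndarray
    m_ccw: np.ndarray
    m_cw: np.ndarray
    w_sym: float
    bias_shift: float = 0.0

    @property
    def n_hd(self) -> int:
        return self.params.n_hd

    def copy(self) -> "Connectome":
        return Connectome(self.params, self.w_hh.copy(), self.m_ccw,
                          self.m_cw, self.w_sym, self.bias_shift)


@dataclass
class LandmarkModel:
    """A single landmark: its world bearing and its associated HD cell."""

    bearing: float                  # degrees in [0, 360)
    associated_cell_index: int
    epsilon: float = 3.0            # heading tolerance half-width (deg)
    width_ratio: float = 1.5        # bump-to-connection width ratio
    peak_current: float = 15.0
    sigma_cells: float | None = None    # template width override (cells)


@dataclass
class GainState:
    """Global turn gain ``g`` and the two gain-calibration learning rates.

    The reduction rate is fixed at 1.5x the enhancement rate, compensating
    for the delayed fall of the instantaneous-rate estimator behind the
    bump (which shrinks the pool of reduction-signalling cells).
    """

    g: float = 1.0
    alpha_e: float = 1e-6

    @property
    def alpha_r(self) -> float:
        return 1.5 * self.alpha_e

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("turn gain must stay positive")


def _circulant(kernel: np.ndarray) -> np.ndarray:
    """Matrix C with C[i, j] = kernel[(i - j) mod n]."""
    n = len(kernel)
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    return kernel[idx]


def build_connectome(params: NetworkParams | None = None) -> Connectome:
    """Construct the full connectome from structural parameters.

    With ``bias_shift = 0`` the resulting network sustains a single
    stationary bump at any of the ring positions.
    """
    p = params or NetworkParams()
    if p.n_hd < 20:
        raise ValueError("need at least 20 HD cells for a meaningful ring")
    if p.inh_offset >= p.n_hd / 2:
        raise ValueError("inhibitory offset >= n_hd/2 gives a degenerate ring")
    for name in ("b_hh", "w_exc", "inh_sigma", "w_inh"):
        v = getattr(p, name)
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive")
    n = p.n_hd
    d = circ_dist_cells(np.arange(n), 0, n)

    k_exc = p.w_exc * np.exp(-d**2 / (2 * p.b_hh**2))
    w_hh = _circulant(k_exc)
    np.fill_diagonal(w_hh, 0.0)

    # AHV ring -> HD: offset Gaussian inhibition. The kernel centred at
    # -offset inhibits cells trailing the bump, so extra drive on that ring
    # pushes the bump counter-clockwise (positive direction).
    k_ccw = p.w_inh * np.exp(-(d + p.inh_offset) ** 2 / (2 * p.inh_sigma**2))
    k_cw = p.w_inh * np.exp(-(d - p.inh_offset) ** 2 / (2 * p.inh_sigma**2))
    m_ccw = _circulant(k_ccw)
    m_cw = _circulant(k_cw)
    return Connectome(params=p, w_hh=w_hh, m_ccw=m_ccw, m_cw=m_cw,
                      w_sym=p.w_sym_current)


def apply_circular_bias(conn: Connectome, shift: float) -> Connectome:
    """Shift the postsynaptic targets of the recurrent HD connections.

    ``shift`` may be fractional (linear interpolation between adjacent
    integer shifts); every row of ``w_hh`` is rotated identically, which
    makes the untrained bump drift at a speed that grows with the shift.
    The standard miscalibrated fixture uses the calibrated shift whose
    drift completes one revolution in about 4 s.
    """
    n = conn.n_hd
    if abs(shift) >= n / 4:
        raise ValueError("bias shift must be below a quarter ring")
    s0 = int(np.floor(shift))
    frac = shift - s0
    w = ((1.0 - frac) * np.roll(conn.w_hh, s0, axis=0)
         + frac * np.roll(conn.w_hh, s0 + 1, axis=0))
    np.fill_diagonal(w, 0.0)  # autapses stay omitted
    out = conn.copy()
    out.w_hh = w
    out.bias_shift = float(shift)
    return out


def landmark_template(model: LandmarkModel, n_hd: int, b_hh: float) -> np.ndarray:
    """Per-cell current template, maximal at the associated cell.

    Gaussian in cell distance, sized to the core of the activity bump
    (``sigma_cells`` when given, else the connection footprint ``b_hh``
    rescaled by the bump-to-connection width ratio).  A template much
    wider than the bump would reach the high-trace region trailing the
    bump and corrupt the gain votes, so the core scale is the default.
    """
    d = circ_dist_cells(np.arange(n_hd), model.associated_cell_index, n_hd)
    sigma = model.sigma_cells if model.sigma_cells else b_hh / model.width_ratio
    return model.peak_current * np.exp(-d**2 / (2 * sigma**2))


def heading_attenuation(model: LandmarkModel, a) -> np.ndarray | float:
    """Attenuation factor h(a): smooth, even, unit peak, zero for |a| > eps.

    Raised-cosine squared window: maximal current when the head faces the
    landmark exactly, falling to exactly zero at +-epsilon degrees.
    """
    a = np.abs(np.asarray(a, dtype=float))
    h = np.where(a < model.epsilon,
                 np.cos(np.pi * a / (2.0 * model.epsilon)) ** 2, 0.0)
    return h if h.ndim else float(h)


def landmark_current(model: LandmarkModel, n_hd: int, b_hh: float,
                     heading_diff: float) -> np.ndarray:
    """Injected current per HD cell for head-to-landmark offset ``heading_diff``.

    Separable: template(cell distance) x attenuation(|heading error|);
    identically zero everywhere once |heading_diff| exceeds epsilon.  While
    the head stays on the landmark the same current is injected every step.
    """
    h = heading_attenuation(model, heading_diff)
    if h == 0.0:
        return np.zeros(n_hd)
    return landmark_template(model, n_hd, b_hh) * h


class RingAttractor:
    """The stepping network: composes connectome, LIF population, synapses.

    Parameters
    ----------
    conn : Connectome
    gain : GainState, optional
        The global turn gain state (mutated by gain calibration upstream).
    seed : int or numpy Generator, optional
        Source of membrane noise and initial-condition randomness.
    """

    def __init__(self, conn: Connectome, gain: GainState | None = None,
                 seed=0):
        self.conn = conn
        self.params = conn.params
        self.gain = gain or GainState()
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        n = conn.n_hd
        self.state = PopulationState(n)
        base = self.params.lif
        self.state.membrane_potential = self.rng.uniform(
            0.0, 0.5 * base.v_thresh, n)
        # quenched heterogeneity: per-cell thresholds desynchronise the
        # population (a homogeneous ring locks into lock-step volleys)
        jitter = self.params.threshold_jitter
        thresh = base.v_thresh * (1.0 + jitter * self.rng.uniform(-1, 1, n))
        self.lif = LIFParams(tau_m=base.tau_m, v_thresh=thresh,
                             v_reset=base.v_reset, v_rest=base.v_rest,
                             t_ref=base.t_ref)
        self.syn = SynapseKinetics(n, tau_rise=self.params.syn_tau_rise,
                                   tau_decay=self.params.syn_tau_decay)
        theta = np.arange(n) * 2 * np.pi / n
        self._cos = np.cos(theta)
        self._sin = np.sin(theta)
        self._zero = np.zeros(n)

    # -- readouts ---------------------------------------------------------
    @property
    def rates(self) -> np.ndarray:
        return self.state.instantaneous_rate

    def decode(self) -> tuple[float, float]:
        """Population-vector decode: (angle deg in [0,360), resultant amplitude)."""
        r = self.state.instantaneous_rate
        x = float(r @ self._cos)
        y = float(r @ self._sin)
        amp = math.hypot(x, y) / max(len(r), 1)
        if amp <= 0:
            return float("nan"), 0.0
        return math.degrees(math.atan2(y, x)) % 360.0, amp

    # -- dynamics ---------------------------------------------------------
    def input_current(self, ahv_asym: float, ahv_sym_speed: float,
                      landmark_input: np.ndarray | None = None,
                      ext_current: np.ndarray | None = None) -> np.ndarray:
        """Total current per HD cell for one tick (before membrane noise)."""
        if not np.isfinite(ahv_asym) or not np.isfinite(ahv_sym_speed):
            raise ValueError("AHV input must be finite (got NaN/inf)")
        if ahv_sym_speed < 0:
            raise ValueError("symmetric AHV drive encodes |speed|, must be >= 0")
        p, c = self.params, self.conn
        s = self.syn.output
        # push-pull: the ring matching the turn direction is driven up,
        # the opposing ring down, keeping total inhibition roughly fixed
        m = 0.5 * self.gain.g * p.velocity_drive * ahv_asym
        d_ccw = max(p.inh_baseline + m, 0.0)
        d_cw = max(p.inh_baseline - m, 0.0)
        current = c.w_hh @ s
        current -= d_ccw * (c.m_ccw @ s)
        current -= d_cw * (c.m_cw @ s)
        current -= p.w_uniform_inh * float(s.sum())
        current += c.w_sym * ahv_sym_speed
        if landmark_input is not None:
            if len(landmark_input) != c.n_hd:
                raise ValueError("landmark input length must equal n_hd")
            current = current + landmark_input
        if ext_current is not None:
            current = current + ext_current
        return current

    def step(self, ahv_asym: float = 0.0, ahv_sym_speed: float = 0.0,
             landmark_input: np.ndarray | None = None, dt: float = 1e-3,
             ext_current: np.ndarray | None = None) -> np.ndarray:
        """One network tick; returns HD spike flags and advances all state."""
        current = self.input_current(ahv_asym, ahv_sym_speed,
                                     landmark_input, ext_current)
        if self.params.noise_amp > 0:
            current = current + self.params.noise_amp * self.rng.standard_normal(
                self.conn.n_hd)
        spikes = step_lif(self.state, current, dt, self.lif)
        update_trace(self.state, dt)
        self.syn.step(spikes.astype(float), dt)
        return spikes

    def delta_rates(self) -> np.ndarray:
        return delta_rate(self.state)

    def initialize_bump(self, angle_deg: float, dt: float = 1e-3,
                        pulse: float = 0.1, settle: float = 0.3,
                        amplitude: float = 3.0) -> None:
        """Ignite a bump at ``angle_deg`` with a brief Gaussian current pulse."""
        p = self.params
        centre = angle_deg / p.deg_per_cell
        d = circ_dist_cells(np.arange(p.n_hd), centre, p.n_hd)
        ext = amplitude * np.exp(-d**2 / (2 * p.b_hh**2))
        for _ in range(int(round(pulse / dt))):
            self.step(dt=dt, ext_current=ext)
        for _ in range(int(round(settle / dt))):
            self.step(dt=dt)


def step_network(net: RingAttractor, ahv_asym: float, ahv_sym_speed: float,
                 landmark_input: np.ndarray | None = None,
                 dt: float = 1e-3) -> tuple[PopulationState, np.ndarray]:
    """Functional wrapper over :meth:`RingAttractor.step`."""
    spikes = net.step(ahv_asym, ahv_sym_speed, landmark_input, dt)
    return net.state, spikes
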