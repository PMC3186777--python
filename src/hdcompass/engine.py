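"""Closed-loop simulation driver: network + behaviour + calibration rules.

:class:`Simulation` advances the ring attractor along a head trajectory,
feeding it the emulated vestibular stream, injecting landmark current when
the (possibly unreliable) detector reports an alignment, and applying the
two calibration mechanisms when enabled:

* condition 1 (drift removal / turn equalisation): the recurrent-weight
  update with presynaptic sharing, annealing, and post-reset suppression;
* condition 2 (turn-gain calibration): per-cell landmark-gated gain votes
  summed into one global gain update at the onset of each reset event.

Landmark association is handled the way the postsubiculum abstraction
demands: for a fixed landmark the caller supplies the associated HD cell;
for the warm-up schedule, each new bearing is associated with the decoded
bump position the first time the head faces it (the network's own current
belief), which is what allows calibration to start from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gain import gain_update_step
from .metrics import BumpTrace, CalibrationResult
from .network import (GainState, LandmarkModel, RingAttractor,
                      landmark_template, heading_attenuation)
from .plasticity import (PlasticityState, RESET_DISPLACEMENT_DEG,
                         anneal_learning_rate, row_consensus,
                         share_presynaptic_weights, stability_update,
                         suppression_gate)
from .protocols import HeadTrajectory, SensorStream

__all__ = ["Simulation", "SimResult"]


def _sdiff(a: float, b: float) -> float:
    """Scalar signed circular difference a - b in (-180, 180]."""
    d = (a - b) % 360.0
    return d - 360.0 if d > 180.0 else d


@dataclass
class SimResult:
    """Recorded time series of one simulation run."""

    times: np.ndarray
    decoded: np.ndarray
    amplitude: np.ndarray
    true_heading: np.ndarray
    gain: np.ndarray
    learning_rate: np.ndarray
    suppressed: np.ndarray
    landmark_on: np.ndarray
    reset_log: list = field(default_factory=list)   # (t, displacement deg)

    @property
    def bump_trace(self) -> BumpTrace:
        return BumpTrace(self.times, self.decoded, self.amplitude)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times, "decoded_deg": self.decoded,
            "amplitude": self.amplitude, "heading_deg": self.true_heading,
            "gain": self.gain, "learning_rate": self.learning_rate,
            "suppressed": self.suppressed.astype(int),
            "landmark_on": self.landmark_on.astype(int),
        })


class Simulation:
    """Run the ring attractor through a behavioural protocol."""

    def __init__(self, net: RingAttractor, calib: CalibrationResult,
                 plasticity: PlasticityState | None = None,
                 seed: int = 0):
        self.net = net
        self.calib = calib
        self.plast = plasticity
        self.rng = np.random.default_rng(seed)

    def run(self, traj: HeadTrajectory, sensors: SensorStream | None = None,
            *, learn_stability: bool = False, learn_gain: bool = False,
            landmark: LandmarkModel | None = None,
            miss_probability: float = 0.0,
            record_every: float = 0.02) -> SimResult:
        """Advance the network along ``traj`` and record the read-outs.

        ``landmark`` fixes a single pre-associated landmark (its events are
        taken from ``sensors.landmark_active`` if present, else detected on
        the fly).  If instead the trajectory carries a per-step bearing
        schedule (warm-up stage 2 and the ablations), landmarks are
        associated on first alignment with the decoded bump position and
        ``miss_probability`` controls detection reliability.
        """
        net, p = self.net, self.net.params
        dt = traj.dt
        n_steps = traj.n_steps
        heading = traj.heading
        omega = traj.omega
        sensed = sensors.sensed_omega if sensors is not None else omega
        darkness = sensors.darkness if sensors is not None else False
        precomputed_lm = (sensors.landmark_active
                          if sensors is not None and landmark is not None
                          and sensors.landmark_active.any() else None)
        bearing_schedule = traj.extras.get("landmark_bearing")

        rec_stride = max(1, int(round(record_every / dt)))
        n_rec = n_steps // rec_stride + 1
        rec = {k: np.zeros(n_rec) for k in
               ("t", "dec", "amp", "head", "g", "lr", "sup", "lm")}
        reset_log = []

        template = None
        if landmark is not None:
            template = landmark_template(landmark, p.n_hd, p.b_hh)
        assoc_bearing = np.nan       # bearing currently associated (schedule)
        assoc_template = None
        window_detected = False      # detection decision for current crossing
        in_window_prev = False
        event_dec0 = np.nan          # decoded position at reset-event onset
        prev_dec = net.decode()[0]
        c_teach = self.calib.c_teach
        teach_floor = self.calib.teach_floor
        # low-pass filtered delta-rate for the stability rule: the raw
        # per-step estimator is dominated by spike noise, the bump-motion
        # signal lives at >= 100 ms timescales
        dr_filt = np.zeros(p.n_hd)
        filt_k = 1.0 - np.exp(-dt / 0.05)
        second_edge = int(round(1.0 / dt))
        consensus_edge = (max(1, int(round(self.plast.consensus_interval / dt)))
                          if self.plast is not None else 0)
        i_rec = 0

        for k in range(n_steps):
            h = heading[k]
            v_sense = sensed[k]
            sym_speed = abs(v_sense)

            # -- landmark geometry -------------------------------------
            lm_vec = None
            lm_on = False
            if not darkness:
                if landmark is not None:
                    a = _sdiff(h, landmark.bearing)
                    in_win = abs(a) < landmark.epsilon
                    if in_win and not in_window_prev:
                        window_detected = (precomputed_lm[k] if precomputed_lm
                                           is not None else
                                           self.rng.random() >= miss_probability)
                        if window_detected and learn_gain:
                            # one lumped gain update per reset event, from
                            # the pre-reset state (the votes are about
                            # where the bump was when the landmark came
                            # into view, not about the reset transient)
                            gain_update_step(net.rates,
                                             net.state.firing_trace,
                                             template, net.gain,
                                             scale=p.gain_vote_scale)
                    if in_win and window_detected:
                        lm_vec = template * heading_attenuation(landmark, a)
                        lm_on = True
                    in_window_prev = in_win
                elif bearing_schedule is not None:
                    b = bearing_schedule[k]
                    if np.isfinite(b):
                        a = _sdiff(h, b)
                        in_win = abs(a) < p.landmark_epsilon
                        if in_win and not in_window_prev:
                            window_detected = self.rng.random() >= miss_probability
                            if (window_detected and learn_gain
                                    and b == assoc_bearing
                                    and assoc_template is not None):
                                gain_update_step(net.rates,
                                                 net.state.firing_trace,
                                                 assoc_template, net.gain,
                                                 scale=p.gain_vote_scale)
                            if b != assoc_bearing:
                                # associate new bearing with current belief
                                dec = net.decode()[0]
                                if np.isfinite(dec):
                                    assoc_bearing = b
                                    cell = int(round(dec / p.deg_per_cell)) % p.n_hd
                                    assoc_template = landmark_template(
                                        LandmarkModel(
                                            b, cell, p.landmark_epsilon,
                                            p.landmark_width_ratio,
                                            p.landmark_peak,
                                            p.landmark_sigma),
                                        p.n_hd, p.b_hh)
                        if (in_win and window_detected
                                and b == assoc_bearing
                                and assoc_template is not None):
                            att = float(np.cos(np.pi * abs(a)
                                               / (2 * p.landmark_epsilon)) ** 2) \
                                if abs(a) < p.landmark_epsilon else 0.0
                            lm_vec = assoc_template * att
                            lm_on = True
                        in_window_prev = in_win
                    else:
                        in_window_prev = False

            # -- network tick ------------------------------------------
            net.step(ahv_asym=v_sense, ahv_sym_speed=sym_speed,
                     landmark_input=lm_vec, dt=dt)
            dec, amp = net.decode()

            # -- reset bookkeeping and calibration ---------------------
            # displacement is tracked cumulatively over the whole landmark
            # event: resets may be slow drags (well under a degree per
            # step) and still move the bump far from where it was
            reset_disp = 0.0
            if lm_on:
                if not np.isfinite(event_dec0):
                    event_dec0 = prev_dec
                if np.isfinite(dec) and np.isfinite(event_dec0):
                    reset_disp = _sdiff(dec, event_dec0)
                    if (abs(reset_disp) > RESET_DISPLACEMENT_DEG
                            and (not reset_log
                                 or reset_log[-1][0] < (k - 1) * dt - dt / 2)):
                        reset_log.append((k * dt, float(reset_disp)))
                    elif (reset_log
                          and reset_log[-1][0] >= (k - 1) * dt - dt / 2):
                        reset_log[-1] = (k * dt, float(reset_disp))
            else:
                event_dec0 = np.nan
            prev_dec = dec

            if self.plast is not None:
                suppression_gate(self.plast, reset_disp, dt)
                if learn_stability and not self.plast.suppressed:
                    dr_filt += filt_k * (net.delta_rates() - dr_filt)
                    # the weight rule runs only while the head is (nearly)
                    # still: at rest the teaching comparison is clean, and
                    # a drifting bump sweeps the ring so coverage is
                    # global; during driven turns weight braking softens
                    # the attractor and fights the turn-gain loop
                    if sym_speed < self.plast.rest_gate_speed:
                        stability_update(net.conn, net.state,
                                         teach_floor + c_teach * sym_speed,
                                         self.plast, dt, dr=dr_filt)
                    if (k + 1) % 10 == 0:   # sharing batched 10 steps
                        share_presynaptic_weights(
                            net.conn, 10.0 * self.plast.share_rate)
                    if (k + 1) % consensus_edge == 0:
                        row_consensus(net.conn, self.plast.consensus_rate)
                if (k + 1) % second_edge == 0:
                    anneal_learning_rate(self.plast)

            # -- recording ---------------------------------------------
            if k % rec_stride == 0:
                rec["t"][i_rec] = k * dt
                rec["dec"][i_rec] = dec
                rec["amp"][i_rec] = amp
                rec["head"][i_rec] = h
                rec["g"][i_rec] = net.gain.g
                rec["lr"][i_rec] = (self.plast.current_lr
                                    if self.plast else 0.0)
                rec["sup"][i_rec] = (1.0 if self.plast
                                     and self.plast.suppressed else 0.0)
                rec["lm"][i_rec] = 1.0 if lm_on else 0.0
                i_rec += 1

        sl = slice(0, i_rec)
        return SimResult(times=rec["t"][sl], decoded=rec["dec"][sl],
                         amplitude=rec["amp"][sl], true_heading=rec["head"][sl],
                         gain=rec["g"][sl], learning_rate=rec["lr"][sl],
                         suppressed=rec["sup"][sl].astype(bool),
                         landmark_on=rec["lm"][sl].astype(bool),
                         reset_log=reset_log)
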