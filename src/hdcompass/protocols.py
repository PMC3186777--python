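"""Synthetic embodiment: movement protocols and noisy sensor emulation.

The model is trained and evaluated on simulated head trajectories that
emulate the behavioural calibration protocols:

* ``random_turn_protocol`` -- random turns in [-90, 90] deg/s held for
  random durations up to 15 s, perturbed on average once per second by a
  random increment in [-45, 45] deg/s, capped at +-135 deg/s, with a 10%
  chance that any new turn is replaced by rest.
* ``warmup_protocol`` -- the infant-mammal warm-up schedule: alternating
  60 s blocks of small lateral turns (amplitudes 40-80 deg, centred on a
  per-block random heading) and full revolutions (1-3 whole turns,
  alternating direction), command speeds uniform in [25, 100] deg/s.  In
  stage 2 the centre heading of each small-turn block becomes the landmark
  bearing for the blocks that follow.
* ``spot_turn_protocol`` -- the robot-style gain-only preset: 1-3 whole
  revolutions in alternating directions at 14-70 deg/s.
* ``ablation_protocol`` -- the movement-strategy controls: (a) small turns
  only, (b) revolutions only (the omitted block type is replaced by a
  stationary head), (c) vestibular input decoupled from true motion.

Sensors are deliberately imperfect: the vestibular channel systematically
under-reports turning by ~8% and carries Gaussian noise, and the landmark
detector drops ~30% of alignments at random.  Darkness disables landmark
events entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circ_diff_deg, wrap_deg
from .network import LandmarkModel

__all__ = [
    "HeadTrajectory",
    "SensorStream",
    "random_turn_protocol",
    "warmup_protocol",
    "spot_turn_protocol",
    "ablation_protocol",
    "vestibular_sensor",
    "landmark_detector",
]

SPEED_CAP = 135.0           # absolute turn-rate cap (deg/s)
REST_PROBABILITY = 0.10     # chance a new random turn is replaced by rest
BLOCK_S = 60.0              # warm-up block duration (s)
WARMUP_SPEEDS = (25.0, 100.0)       # small lateral turns
REVOLUTION_SPEEDS = (14.0, 70.0)    # whole revolutions (gain calibration)
SMALL_TURN_AMPLITUDE = (40.0, 80.0)
DEFAULT_VESTIBULAR_BIAS = 0.08
DEFAULT_VESTIBULAR_NOISE = 5.0   # deg/s, per-step Gaussian sd
DEFAULT_MISS_PROBABILITY = 0.30


@dataclass
class HeadTrajectory:
    """Ground-truth heading/angular-velocity time series on a fixed grid.

    ``heading[k+1] = wrap(heading[k] + omega[k] * dt)``; the unwrapped
    series is kept alongside so cumulative rotation is exact.
    """

    dt: float
    omega: np.ndarray                 # signed deg/s per step
    heading0: float = 0.0
    protocol_tag: str = "custom"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        steps = np.concatenate(([0.0], np.cumsum(self.omega[:-1]) * self.dt))
        self._unwrapped = self.heading0 + steps

    @property
    def n_steps(self) -> int:
        return len(self.omega)

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    @property
    def heading(self) -> np.ndarray:
        return wrap_deg(self._unwrapped)

    @property
    def heading_unwrapped(self) -> np.ndarray:
        return self._unwrapped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "heading_deg": self.heading,
                             "omega_deg_s": self.omega})


@dataclass
class SensorStream:
    """Emulated vestibular drive and landmark-alignment events.

    ``sensed_omega`` is the biased, noisy angular-velocity report;
    ``ahv_sym_drive`` its magnitude (the symmetric-AHV channel).
    ``landmark_active`` marks steps during which landmark current is being
    injected (empty in darkness); ``events`` lists the window crossings as
    (start_step, stop_step, detected).
    """

    dt: float
    sensed_omega: np.ndarray
    landmark_active: np.ndarray = None
    events: list = field(default_factory=list)
    bias_fraction: float = 0.0
    velocity_noise_sd: float = 0.0
    miss_probability: float = 0.0
    darkness: bool = False

    def __post_init__(self) -> None:
        self.sensed_omega = np.asarray(self.sensed_omega, dtype=float)
        if self.landmark_active is None:
            self.landmark_active = np.zeros(len(self.sensed_omega), dtype=bool)

    @property
    def ahv_sym_drive(self) -> np.ndarray:
        return np.abs(self.sensed_omega)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": np.arange(len(self.sensed_omega)) * self.dt,
            "sensed_omega": self.sensed_omega,
            "landmark_flag": self.landmark_active.astype(int),
        })


# ---------------------------------------------------------------------------
# movement protocols
# ---------------------------------------------------------------------------

def random_turn_protocol(duration: float, seed=0, dt: float = 1e-3,
                         heading0: float | None = None) -> HeadTrajectory:
    """Random-turn exploration used for gain-only calibration runs."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    total = int(round(duration / dt))
    omega = np.empty(total)
    i = 0
    n_turns = n_rests = 0
    while i < total:
        seg = max(1, int(round(rng.uniform(0.0, 15.0) / dt)))
        seg = min(seg, total - i)
        if rng.random() < REST_PROBABILITY:
            omega[i:i + seg] = 0.0
            n_rests += 1
        else:
            rate = rng.uniform(-90.0, 90.0)
            pert = np.flatnonzero(rng.random(seg) < dt)
            path = np.full(seg, rate)
            for k in pert:     # sequential so the cap applies after each change
                rate = float(np.clip(rate + rng.uniform(-45.0, 45.0),
                                     -SPEED_CAP, SPEED_CAP))
                path[k:] = rate
            omega[i:i + seg] = path
            n_turns += 1
        i += seg
    h0 = rng.uniform(0.0, 360.0) if heading0 is None else heading0
    return HeadTrajectory(dt, omega, h0, "random_turn",
                          {"n_turns": n_turns, "n_rests": n_rests})


def _revolution_segments(rng, n_blocks_steps: int, dt: float,
                         speeds=REVOLUTION_SPEEDS,
                         direction0: int | None = None):
    """Fill a block with whole-revolution turns; rest if none fits.

    Revolutions run at the 14-70 deg/s used for the 360-degree gain
    calibration: one lap then takes longer than the ~5.4 s firing-trace
    persistence, so the trace can distinguish "the bump just passed the
    landmark" (overshoot) from "its last pass was a lap ago" (lag).
    """
    omega = np.zeros(n_blocks_steps)
    segments = []
    direction = direction0 if direction0 is not None else int(rng.choice((-1, 1)))
    i = 0
    while i < n_blocks_steps:
        n_rev = int(rng.integers(1, 4))
        speed = rng.uniform(*speeds)
        steps = int(round(n_rev * 360.0 / (speed * dt)))
        if steps > n_blocks_steps - i or steps == 0:
            break   # head rests for the remainder of the block
        exact = direction * n_rev * 360.0 / (steps * dt)
        omega[i:i + steps] = exact
        segments.append((i, i + steps, direction * n_rev * 360.0))
        direction = -direction
        i += steps
    return omega, segments, direction


def _small_turn_block(rng, current_heading: float, n_steps: int, dt: float,
                      speeds=WARMUP_SPEEDS):
    """Travel to a random centre, then alternate small turns around it."""
    omega = np.zeros(n_steps)
    centre = rng.uniform(0.0, 360.0)
    h = current_heading
    i = 0
    # travel phase: shortest arc to the block centre
    gap = float(circ_diff_deg(centre, h))
    speed = rng.uniform(*speeds)
    steps = int(np.ceil(abs(gap) / (speed * dt)))   # ceil: never exceed speed
    steps = min(steps, n_steps)
    if steps > 0:
        omega[:steps] = gap / (steps * dt)
        h += gap
        i = steps
    settle = i
    side = int(rng.choice((-1, 1)))
    offset = float(circ_diff_deg(h, centre))   # ~0 after travel
    while i < n_steps:
        target = side * rng.uniform(*SMALL_TURN_AMPLITUDE) / 2.0
        move = target - offset
        speed = rng.uniform(*speeds)
        steps_full = max(1, int(np.ceil(abs(move) / (speed * dt))))
        steps = min(steps_full, n_steps - i)
        # unclipped denominator: a swing truncated by the block end keeps
        # its commanded speed and simply does not complete
        rate = move / (steps_full * dt)
        omega[i:i + steps] = rate
        offset += rate * steps * dt
        i += steps
        side = -side
    return omega, centre, settle


def warmup_protocol(total: float, stage: int = 1, seed=0,
                    dt: float = 1e-3, heading0: float = 0.0) -> HeadTrajectory:
    """Infant-mammal warm-up schedule: 60 s blocks, small turns <-> revolutions.

    ``stage=2`` additionally records the landmark-bearing schedule: the
    centre heading of each small-turn block becomes the landmark bearing
    from that block onward (until the next small-turn block replaces it).
    """
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    n_blocks = int(round(total / BLOCK_S))
    if n_blocks < 1 or abs(n_blocks * BLOCK_S - total) > 1e-9:
        raise ValueError("total duration must be a positive multiple of 60 s")
    rng = np.random.default_rng(seed)
    steps_per_block = int(round(BLOCK_S / dt))
    omega = np.zeros(n_blocks * steps_per_block)
    bearing = np.full(n_blocks * steps_per_block, np.nan)
    blocks = []
    h = heading0
    direction = int(rng.choice((-1, 1)))
    current_bearing = np.nan
    for b in range(n_blocks):
        lo = b * steps_per_block
        hi = lo + steps_per_block
        if b % 2 == 0:   # small lateral turns
            blk, centre, settle = _small_turn_block(rng, h, steps_per_block, dt)
            omega[lo:hi] = blk
            if stage == 2:
                # the centre learned during this block becomes the landmark
                # for the following revolution block (the landmark is not
                # active while it is still being learned)
                current_bearing = centre
            blocks.append({"kind": "small", "start": lo, "stop": hi,
                           "centre": centre, "settle": lo + settle})
        else:            # full revolutions
            blk, segs, direction = _revolution_segments(
                rng, steps_per_block, dt, direction0=direction)
            omega[lo:hi] = blk
            if stage == 2:
                bearing[lo:hi] = current_bearing
            blocks.append({"kind": "revolution", "start": lo, "stop": hi,
                           "segments": [(s + lo, e + lo, rot) for s, e, rot in segs]})
        h = wrap_deg(h + omega[lo:hi].sum() * dt)
    tag = f"warmup_stage{stage}"
    return HeadTrajectory(dt, omega, heading0, tag,
                          {"blocks": blocks, "landmark_bearing": bearing})


def spot_turn_protocol(duration: float, seed=0, dt: float = 1e-3,
                       speeds=(14.0, 70.0), heading0: float = 0.0) -> HeadTrajectory:
    """Robot-style preset: 1-3 whole revolutions, alternating directions."""
    rng = np.random.default_rng(seed)
    total = int(round(duration / dt))
    omega = np.zeros(total)
    segments = []
    direction = int(rng.choice((-1, 1)))
    i = 0
    while i < total:
        n_rev = int(rng.integers(1, 4))
        speed = rng.uniform(*speeds)
        steps = int(round(n_rev * 360.0 / (speed * dt)))
        steps = min(steps, total - i)
        omega[i:i + steps] = direction * n_rev * 360.0 / (max(steps, 1) * dt) \
            if steps else 0.0
        if steps:
            segments.append((i, i + steps, direction * n_rev * 360.0))
        direction = -direction
        i += max(steps, 1)
    return HeadTrajectory(dt, omega, heading0, "spot_turn",
                          {"segments": segments})


def ablation_protocol(variant: str, total: float, seed=0, dt: float = 1e-3,
                      bias_fraction: float = DEFAULT_VESTIBULAR_BIAS,
                      noise_sd: float = DEFAULT_VESTIBULAR_NOISE
                      ) -> tuple[HeadTrajectory, SensorStream]:
    """Movement-strategy controls; calibration is expected to fail on all.

    a -- small turns only (head held still during revolution blocks);
    b -- revolutions only (head held still during small-turn blocks);
    c -- vestibular input generated from an independent trajectory, so
         sensation is uncorrelated with true motion (landmark geometry
         stays tied to the true heading: the world is still physical).
    """
    if variant not in ("a", "b", "c"):
        raise ValueError(f"unknown ablation variant {variant!r}")
    traj = warmup_protocol(total, stage=2, seed=seed, dt=dt)
    omega = traj.omega.copy()
    if variant in ("a", "b"):
        drop = "revolution" if variant == "a" else "small"
        for blk in traj.extras["blocks"]:
            if blk["kind"] == drop:
                omega[blk["start"]:blk["stop"]] = 0.0
        out = HeadTrajectory(traj.dt, omega, traj.heading0,
                             f"ablation_{variant}", dict(traj.extras))
        sensors = vestibular_sensor(out, bias_fraction, noise_sd,
                                    seed=np.random.default_rng(seed).integers(2**31))
        return out, sensors
    # variant c: sensed velocities come from a different movement history
    decoy = warmup_protocol(total, stage=2, seed=(seed or 0) + 104729, dt=dt)
    sensors = vestibular_sensor(decoy, bias_fraction, noise_sd,
                                seed=np.random.default_rng(seed).integers(2**31))
    sensors = SensorStream(dt, sensors.sensed_omega,
                           bias_fraction=bias_fraction,
                           velocity_noise_sd=noise_sd)
    out = HeadTrajectory(traj.dt, traj.omega, traj.heading0,
                         "ablation_c", dict(traj.extras))
    return out, sensors


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

def vestibular_sensor(traj: HeadTrajectory,
                      bias_fraction: float = DEFAULT_VESTIBULAR_BIAS,
                      noise_sd: float = DEFAULT_VESTIBULAR_NOISE,
                      seed=0) -> SensorStream:
    """Biased, noisy angular-velocity report: sensed = true*(1-bias) + noise.

    With the default 8% bias the integrated sensed angle is 92% of the
    true total turn in expectation.
    """
    if not -0.5 < bias_fraction < 0.5:
        raise ValueError("bias fraction must lie in (-0.5, 0.5)")
    rng = np.random.default_rng(seed)
    sensed = traj.omega * (1.0 - bias_fraction)
    if noise_sd > 0:
        sensed = sensed + rng.normal(0.0, noise_sd, traj.n_steps)
    return SensorStream(traj.dt, sensed, bias_fraction=bias_fraction,
                        velocity_noise_sd=noise_sd)


def window_events(in_window: np.ndarray, miss_probability: float, rng):
    """Split a boolean in-window mask into crossings; drop some at random."""
    mask = np.asarray(in_window, bool)
    padded = np.concatenate(([False], mask, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    stops = np.flatnonzero(~padded[1:] & padded[:-1])
    active = np.zeros(len(mask), dtype=bool)
    events = []
    for s, e in zip(starts, stops):
        detected = rng.random() >= miss_probability
        if detected:
            active[s:e] = True
        events.append((int(s), int(e), bool(detected)))
    return active, events


def landmark_detector(traj: HeadTrajectory, landmark: LandmarkModel,
                      miss_probability: float = DEFAULT_MISS_PROBABILITY,
                      seed=0, darkness: bool = False,
                      base: SensorStream | None = None) -> SensorStream:
    """Emit landmark-alignment events for a fixed-bearing landmark.

    An event spans each contiguous interval during which the true heading
    sits within +-epsilon of the landmark bearing; each crossing is
    detected with probability 1 - miss_probability.  ``darkness`` disables
    all events.  If ``base`` is given, its vestibular channel is reused.
    """
    if not 0.0 <= miss_probability <= 1.0:
        raise ValueError("miss probability must lie in [0, 1]")
    sensed = base.sensed_omega if base is not None else traj.omega.copy()
    if darkness:
        return SensorStream(traj.dt, sensed, darkness=True,
                            miss_probability=miss_probability)
    rng = np.random.default_rng(seed)
    in_window = np.abs(circ_diff_deg(traj.heading, landmark.bearing)) \
        < landmark.epsilon
    active, events = window_events(in_window, miss_probability, rng)
    stream = SensorStream(traj.dt, sensed, landmark_active=active,
                          events=events, miss_probability=miss_probability)
    if base is not None:
        stream.bias_fraction = base.bias_fraction
        stream.velocity_noise_sd = base.velocity_noise_sd
    return stream
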