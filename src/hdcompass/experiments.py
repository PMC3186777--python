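"""Scripted end-to-end experiments: configuration, training, evaluation.

Each experiment is one of the model's canonical study designs:

* :func:`run_gain_only` -- turn-gain calibration in isolation on an
  unbiased network, with a fixed landmark at 180 deg and an initially
  wrong gain (Fig 5/6 style).
* :func:`run_full_training` -- the two-stage warm-up schedule on the
  deliberately miscalibrated (biased) network: stage 1 trains drift
  removal only on alternating small-turn/revolution blocks; stage 2 adds
  turn-gain calibration with per-block landmark association (Fig 7/8).
* :func:`run_darkness_eval` -- a trained network tracking in darkness (no
  landmark events) under continued alternating turns (Fig 9).
* :func:`run_ablations` -- the three movement-strategy controls
  (Fig 10/11): small turns only, revolutions only, uncorrelated sensors.

All randomness derives from a single seed per experiment; identical
config + seed reproduce identical logs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SimResult, Simulation
from .metrics import (BumpTrace, CalibrationResult, circular_tracking_error,
                      drift_rate)
from .network import (GainState, LandmarkModel, NetworkParams, RingAttractor,
                      apply_circular_bias, build_connectome)
from .plasticity import PlasticityState
from .protocols import (DEFAULT_MISS_PROBABILITY, DEFAULT_VESTIBULAR_BIAS,
                        DEFAULT_VESTIBULAR_NOISE, ablation_protocol,
                        landmark_detector, random_turn_protocol,
                        spot_turn_protocol, vestibular_sensor, warmup_protocol)
from ._defaults import default_calibration

__all__ = ["ExperimentConfig", "run_gain_only", "run_full_training",
           "run_darkness_eval", "run_ablations", "drift_audit"]


@dataclass
class ExperimentConfig:
    """Everything an experiment needs, fully serialisable.

    The default durations follow the full experimental schedule (10 min gain-only
    runs, 15+15 min two-stage training); :meth:`desk` returns a scaled-
    down preset for quick runs.
    """

    seed: int = 0
    n_hd: int = 200
    gain_only_duration: float = 600.0
    stage_duration: float = 900.0        # per training stage
    darkness_duration: float = 300.0
    gain_initial_low_factor: float = 0.6    # x true gain for the "low" run
    gain_initial_high_factor: float = 1.5   # x true gain for the "high" run
    train_initial_gain: float = 1.0         # gain at the start of training
    landmark_bearing: float = 180.0
    protocol: str = "random_turn"        # gain-only protocol preset
    vestibular_bias: float = 0.0
    vestibular_noise: float = 0.0
    miss_probability: float = 0.0
    alpha_stability: float = 2e-4
    audit_positions: int = 10
    record_every: float = 0.05
    out_dir: str | None = None

    @classmethod
    def desk(cls, seed: int = 0, **over) -> "ExperimentConfig":
        """Scaled-down preset (shorter stages, fewer audit positions)."""
        base = dict(seed=seed, gain_only_duration=300.0, stage_duration=300.0,
                    darkness_duration=200.0, audit_positions=5)
        base.update(over)
        return cls(**base)

    @classmethod
    def robot(cls, seed: int = 0, **over) -> "ExperimentConfig":
        """Robot-style preset: spot turns, biased/noisy/missy sensors."""
        base = dict(seed=seed, protocol="spot_turn",
                    vestibular_bias=DEFAULT_VESTIBULAR_BIAS,
                    vestibular_noise=DEFAULT_VESTIBULAR_NOISE,
                    miss_probability=DEFAULT_MISS_PROBABILITY)
        base.update(over)
        return cls(**base)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ResultsBundle:
    """Outputs of one experiment; optionally written to ``out_dir``."""

    config: ExperimentConfig
    logs: dict = field(default_factory=dict)       # name -> DataFrame
    scalars: dict = field(default_factory=dict)

    def save(self) -> None:
        if not self.config.out_dir:
            return
        out = Path(self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.logs.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        (out / "scalars.json").write_text(json.dumps(self.scalars, indent=2))
        self.config.to_yaml(out / "config.yaml")


def _sub_seed(seed: int, k: int) -> int:
    """Deterministic per-module sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _calibration(config: ExperimentConfig) -> CalibrationResult:
    calib = default_calibration()
    if config.n_hd != calib.params.n_hd:
        from .metrics import calibrate_physiology
        calib = calibrate_physiology(replace(calib.params, n_hd=config.n_hd),
                                     seed=_sub_seed(config.seed, 99))
    return calib


def drift_audit(conn, calib: CalibrationResult, positions: int = 10,
                seed: int = 0, sim_time: float = 2.5) -> pd.DataFrame:
    """Measure decoded drift from bumps started at several ring positions."""
    from .metrics import _measure_drift
    rows = []
    for i, start in enumerate(np.linspace(0.0, 360.0, positions,
                                          endpoint=False)):
        d = _measure_drift(conn, start=float(start), sim_time=sim_time,
                           seed=_sub_seed(seed, i))
        rows.append({"start_deg": float(start), "drift_deg_s": d})
    return pd.DataFrame(rows)


def run_gain_only(config: ExperimentConfig,
                  start_high: bool = False) -> ResultsBundle:
    """Turn-gain calibration alone on an unbiased, drift-free network.

    The gain starts wrong (low by default, high with ``start_high``); a
    single landmark at ``landmark_bearing`` is pre-associated with the
    matching HD cell and resets the bump whenever the head crosses the
    bearing and the detector does not miss.
    """
    calib = _calibration(config)
    p = calib.params
    conn = build_connectome(p)
    proto = {"random_turn": random_turn_protocol,
             "spot_turn": spot_turn_protocol}[config.protocol]
    traj = proto(config.gain_only_duration, seed=_sub_seed(config.seed, 1))
    lm = LandmarkModel(config.landmark_bearing,
                       int(round(config.landmark_bearing / p.deg_per_cell))
                       % p.n_hd,
                       epsilon=p.landmark_epsilon,
                       width_ratio=p.landmark_width_ratio,
                       peak_current=p.landmark_peak,
                       sigma_cells=p.landmark_sigma)
    sensors = vestibular_sensor(traj, config.vestibular_bias,
                                config.vestibular_noise,
                                seed=_sub_seed(config.seed, 2))
    sensors = landmark_detector(traj, lm, config.miss_probability,
                                seed=_sub_seed(config.seed, 3), base=sensors)
    g0 = calib.g_true * (config.gain_initial_high_factor if start_high
                         else config.gain_initial_low_factor)
    net = RingAttractor(conn, gain=GainState(g=g0),
                        seed=_sub_seed(config.seed, 4))
    net.initialize_bump(traj.heading[0])
    sim = Simulation(net, calib, seed=_sub_seed(config.seed, 5))
    res = sim.run(traj, sensors, learn_gain=True, landmark=lm,
                  record_every=config.record_every)
    err = circular_tracking_error(res.decoded, res.true_heading)
    final = res.times >= res.times[-1] - 60.0
    err_final = circular_tracking_error(res.decoded[final],
                                        res.true_heading[final])
    bundle = ResultsBundle(config, logs={"gain_only": res.to_frame()},
                           scalars={
                               "g_initial": g0, "g_final": float(res.gain[-1]),
                               "g_true": calib.g_true,
                               "mean_abs_error_deg": err["mean_abs"],
                               "final_min_mean_abs_error_deg":
                                   err_final["mean_abs"],
                               "n_resets": len(res.reset_log)})
    bundle.save()
    return bundle


def _train(config: ExperimentConfig, trajectories, sensors_list,
           learn_flags, calib: CalibrationResult,
           net: RingAttractor, plast: PlasticityState,
           miss: float) -> list[SimResult]:
    results = []
    for i, (traj, sensors, flags) in enumerate(
            zip(trajectories, sensors_list, learn_flags)):
        sim = Simulation(net, calib, plasticity=plast,
                         seed=_sub_seed(config.seed, 50 + i))
        results.append(sim.run(traj, sensors,
                               learn_stability=flags.get("stability", False),
                               learn_gain=flags.get("gain", False),
                               miss_probability=miss,
                               record_every=config.record_every))
    return results


def run_full_training(config: ExperimentConfig) -> ResultsBundle:
    """Two-stage warm-up training of the deliberately miscalibrated network.

    Stage 1 (drift removal only) runs on alternating small-turn and
    revolution blocks; stage 2 runs the same behaviour with all
    calibration mechanisms active and per-block landmark association.
    Pre/post drift audits cover ``audit_positions`` bump start positions.
    """
    calib = _calibration(config)
    p = calib.params
    conn = apply_circular_bias(build_connectome(p), calib.bias_shift)

    audit_pre = drift_audit(conn, calib, config.audit_positions,
                            seed=_sub_seed(config.seed, 10))

    plast = PlasticityState(alpha=config.alpha_stability)
    net = RingAttractor(conn, gain=GainState(g=config.train_initial_gain),
                        seed=_sub_seed(config.seed, 11))
    traj1 = warmup_protocol(config.stage_duration, stage=1,
                            seed=_sub_seed(config.seed, 12))
    traj2 = warmup_protocol(config.stage_duration, stage=2,
                            seed=_sub_seed(config.seed, 13),
                            heading0=float(traj1.heading[-1]))
    s1 = vestibular_sensor(traj1, config.vestibular_bias,
                           config.vestibular_noise,
                           seed=_sub_seed(config.seed, 14))
    s2 = vestibular_sensor(traj2, config.vestibular_bias,
                           config.vestibular_noise,
                           seed=_sub_seed(config.seed, 15))
    net.initialize_bump(traj1.heading[0])
    # stage 1: the weight rule trains at all speeds (condition 1 alone).
    # stage 2: it retreats to rest moments -- during driven turns weight
    # braking softens the attractor and chases the now-active gain loop
    plast.rest_gate_speed = float("inf")
    res1 = _train(config, [traj1], [s1], [{"stability": True}],
                  calib, net, plast, config.miss_probability)[0]
    plast.rest_gate_speed = 15.0
    res2 = _train(config, [traj2], [s2],
                  [{"stability": True, "gain": True}],
                  calib, net, plast, config.miss_probability)[0]

    audit_post = drift_audit(net.conn, calib, config.audit_positions,
                             seed=_sub_seed(config.seed, 16))
    err2 = circular_tracking_error(res2.decoded, res2.true_heading)
    final = res2.times >= res2.times[-1] - 120.0
    err_final = circular_tracking_error(res2.decoded[final],
                                        res2.true_heading[final])
    bundle = ResultsBundle(
        config,
        logs={"stage1": res1.to_frame(), "stage2": res2.to_frame(),
              "audit_pre": audit_pre, "audit_post": audit_post},
        scalars={
            "g_final": float(res2.gain[-1]), "g_true": calib.g_true,
            "max_abs_drift_pre": float(audit_pre.drift_deg_s.abs().max()),
            "max_abs_drift_post": float(audit_post.drift_deg_s.abs().max()),
            "stage2_mean_abs_error_deg": err2["mean_abs"],
            "final_2min_mean_abs_error_deg": err_final["mean_abs"]})
    bundle.save()
    bundle.trained_net = net
    bundle.calibration = calib
    return bundle


def run_darkness_eval(config: ExperimentConfig,
                      trained_net: RingAttractor | None = None,
                      calib: CalibrationResult | None = None) -> ResultsBundle:
    """Track head direction with no landmark events (darkness).

    A fully trained network is expected; passing an untrained one is
    permitted but flagged in the result scalars.  Tracking runs through
    continued alternating one-minute blocks; the angular disparity between
    decoded and true heading grows only slowly if calibration succeeded.
    """
    calib = calib or _calibration(config)
    trained = trained_net is not None
    if not trained:
        import warnings
        warnings.warn("darkness evaluation on an untrained network")
        conn = apply_circular_bias(build_connectome(calib.params),
                                   calib.bias_shift)
        trained_net = RingAttractor(conn, gain=GainState(
            g=config.train_initial_gain), seed=_sub_seed(config.seed, 20))
    dur = max(120.0, 60.0 * round(config.darkness_duration / 60.0))
    traj = warmup_protocol(dur, stage=1, seed=_sub_seed(config.seed, 21))
    sensors = vestibular_sensor(traj, config.vestibular_bias,
                                config.vestibular_noise,
                                seed=_sub_seed(config.seed, 22))
    sensors.darkness = True
    trained_net.initialize_bump(traj.heading[0])
    sim = Simulation(trained_net, calib, seed=_sub_seed(config.seed, 23))
    res = sim.run(traj, sensors, record_every=config.record_every)
    err = circular_tracking_error(res.decoded, res.true_heading)
    abs_err = np.abs(err["error"])
    below = res.times[abs_err < 45.0]
    held = 0.0
    if below.size:
        # longest initial stretch with error inside 45 deg
        breaks = np.flatnonzero(abs_err >= 45.0)
        held = res.times[breaks[0] - 1] if breaks.size else res.times[-1]
    bundle = ResultsBundle(config, logs={"darkness": res.to_frame()},
                           scalars={"trained": trained,
                                    "mean_abs_error_deg": err["mean_abs"],
                                    "max_abs_error_deg": err["max_abs"],
                                    "seconds_within_45deg": float(held)})
    bundle.save()
    return bundle


def run_ablations(config: ExperimentConfig) -> dict[str, ResultsBundle]:
    """Movement-strategy controls a/b/c over the stage-2 style schedule.

    Each variant trains a fresh biased network with all calibration
    mechanisms active for one stage duration and reports the post-training
    drift audit and the gain trajectory; the three failure signatures
    (stable-but-misgained, residual drift with wandering gain, unstable
    with erroneous gain growth) can be read off the bundles.
    """
    calib = _calibration(config)
    out = {}
    for variant in ("a", "b", "c"):
        conn = apply_circular_bias(build_connectome(calib.params),
                                   calib.bias_shift)
        traj, sensors = ablation_protocol(
            variant, config.stage_duration,
            seed=_sub_seed(config.seed, 30),
            bias_fraction=config.vestibular_bias,
            noise_sd=config.vestibular_noise)
        plast = PlasticityState(alpha=config.alpha_stability)
        # start the gain well below its true value: the ablations are about
        # whether the (crippled) movement schedule can still calibrate it
        g0 = calib.g_true * config.gain_initial_low_factor
        net = RingAttractor(conn, gain=GainState(g=g0),
                            seed=_sub_seed(config.seed, 31))
        net.initialize_bump(traj.heading[0])
        sim = Simulation(net, calib, plasticity=plast,
                         seed=_sub_seed(config.seed, 32))
        res = sim.run(traj, sensors, learn_stability=True, learn_gain=True,
                      miss_probability=config.miss_probability,
                      record_every=config.record_every)
        audit = drift_audit(net.conn, calib, config.audit_positions,
                            seed=_sub_seed(config.seed, 33))
        gain_sd = float(np.std(res.gain))
        bundle = ResultsBundle(
            replace(config, out_dir=(f"{config.out_dir}/ablation_{variant}"
                                     if config.out_dir else None)),
            logs={"run": res.to_frame(), "audit": audit},
            scalars={"variant": variant,
                     "g_final": float(res.gain[-1]), "g_true": calib.g_true,
                     "gain_sd": gain_sd,
                     "max_abs_drift_post":
                         float(audit.drift_deg_s.abs().max())})
        bundle.save()
        out[variant] = bundle
    return out
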