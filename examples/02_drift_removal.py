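"""Removing the built-in drift with warm-up movements (stability condition 1).

Starts from the standard miscalibrated network -- recurrent connections
circularly shifted so the bump sweeps a full revolution in about four
seconds with the head still -- and trains the drift-removal rule for five
simulated minutes of alternating small head turns and whole revolutions,
with a biased, noisy vestibular sense.  Prints the drift measured at four
bump start positions before and after training.
"""

from hdcompass import (GainState, PlasticityState, RingAttractor, Simulation,
                       apply_circular_bias, build_connectome,
                       default_calibration, vestibular_sensor, warmup_protocol)
from hdcompass.metrics import _measure_drift

calib = default_calibration()
conn = apply_circular_bias(build_connectome(calib.params), calib.bias_shift)

print("before training:")
for start in (0.0, 90.0, 180.0, 270.0):
    d = _measure_drift(conn, start=start, sim_time=2.0, seed=9)
    print(f"  bump at {start:5.1f} deg: drift {d:+7.1f} deg/s")

net = RingAttractor(conn, gain=GainState(g=1.0), seed=1)
traj = warmup_protocol(300.0, stage=1, seed=5)
sensors = vestibular_sensor(traj, bias_fraction=0.08, noise_sd=5.0, seed=6)
net.initialize_bump(traj.heading[0])
plast = PlasticityState(alpha=3e-5)
plast.rest_gate_speed = float("inf")   # weights-only stage: train at all speeds
sim = Simulation(net, calib, plasticity=plast, seed=7)
sim.run(traj, sensors, learn_stability=True)

print("after 5 min of warm-up training:")
for start in (0.0, 90.0, 180.0, 270.0):
    d = _measure_drift(net.conn, start=start, sim_time=2.0, seed=9)
    print(f"  bump at {start:5.1f} deg: drift {d:+7.1f} deg/s")
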