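# hdcompass

A spiking ring-attractor model of the mammalian head-direction (HD)
system that **calibrates itself** through stereotyped "warm-up"
movements, a noisy vestibular sense, and a single landmark — no
pre-wired, perfectly tuned synapses.

## The science

HD cells fire when the animal faces their preferred azimuth; collectively
they form an *activity bump* on a ring attractor whose peak encodes the
current heading.  For the bump to track the head, two conditions must
hold:

1. **Stability / equalisation** — the bump must not drift when the head
   is still, and equal turns in opposite directions must displace it
   equally.  A Hebbian-like rule on the recurrent HD weights achieves
   this using only the symmetric angular-head-velocity (AHV) signal
   `AHV_sym ∝ |ω|` as teacher:

       Δw_ij ∝ α(t) · Δr_i · (|Δr_j| − AHV_sym)

   where `Δr = r − m` is each cell's instantaneous rate minus its 20 ms
   average.  If the bump outruns the head, the update retards it; if it
   lags, the update speeds it up.  The learning rate α(t) starts at 20×
   base and anneals by 0.5 %/s; updates are suppressed for 1 s after any
   landmark reset that displaces the bump, and presynaptic weight
   *sharing* diffuses efficacy between adjacent synapses (conserving each
   cell's total input) to keep the profiles Gaussian.

2. **Turn gain** — a global gain `g` scales the vestibular drive
   (`g·AHV_asym`), setting bump speed per unit head speed.  The physical
   invariant that a 360° turn returns the head to its start lets a
   *single* landmark calibrate `g`: whenever the head faces the landmark
   and the bump is elsewhere, each silent HD cell receiving landmark
   current votes by its firing trace (τ = 2 s): trace > 10 Hz means the
   bump ran past (reduce g, rate `α_r = 1.5 α_e`), trace ≤ 10 Hz means it
   lagged (raise g, rate `α_e = 1e−6`); `Δg = Σg_e − Σg_r`.

The *movement strategy matters*: small lateral head turns train
condition 1, whole revolutions train condition 2, and the model
reproduces the systematic failure signatures when either movement class
is withheld or when sensation is decorrelated from motion.

## A worked example

```bash
python examples/01_stationary_bump.py
```

prints, with the shipped calibration:

```
peak rate   :  154.7 Hz   (anchor ~150 Hz)
bump width  :  109.8 deg  (anchor ~110 deg)
drift       :  -1.00 deg/s (unbiased network; ~0)
```

i.e. a settled bump whose peak rate and directional tuning width match
the published physiology of lateral-mammillary HD cells, and which is
stable with the head still.  `examples/02_drift_removal.py` starts from
the standard *miscalibrated* fixture (one full revolution of spontaneous
drift every ~4 s) and removes the drift with five minutes of warm-up
movements; `examples/03_gain_calibration.py` shows the turn gain
converging from 40 % low and 50 % high; `examples/04_full_training_and_
darkness.py` runs the complete two-stage schedule and then tracks in
darkness.

A thin CLI wraps the same experiments:

```bash
hdcompass simulate --seed 1 --desk        # gain-only calibration run
hdcompass train    --seed 1 --desk        # two-stage warm-up training
hdcompass ablate   --seed 1 --desk        # movement-strategy controls
hdcompass calibrate                       # re-fit physiology anchors
```

## Layout

```
src/hdcompass/
  neurons.py      LIF cells, synapse kinetics, rate statistics
  network.py      ring architecture, connectome, landmark input
  plasticity.py   condition-1 rule, sharing, annealing, suppression
  gain.py         condition-2 landmark-gated gain votes
  protocols.py    movement generators and noisy sensor emulation
  engine.py       closed-loop simulation driver
  metrics.py      decoding, drift/tracking metrics, physiology calibration
  experiments.py  scripted end-to-end studies
  cli.py          command-line wrapper
docs/methods.md   model description, assumptions, numerical choices
examples/         narrative walk-throughs, one per capability
```

See `docs/methods.md` for the full model description, the free-parameter
calibration procedure, and known limitations.
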