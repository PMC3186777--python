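# Model and methods

`hdcompass` implements a spiking continuous-attractor model of the
mammalian head-direction (HD) system together with the two synaptic
calibration mechanisms that let the network wire itself up from a
deliberately mis-calibrated start, driven only by stereotyped "warm-up"
movements, a noisy vestibular signal, and a single landmark.

## Network

**HD ring.** 200 leaky integrate-and-fire cells, cell *k* preferring
heading *k*·1.8°, angles increasing counter-clockwise.  Membrane dynamics
use exact exponential relaxation per 1 ms step (rest 0, threshold 1,
τ_m = 10 ms, refractory 5 ms, reset to 0).  Per-cell thresholds carry a
frozen ±5% jitter and each step adds Gaussian membrane-noise current
(σ = 0.2): a homogeneous noiseless ring locks into population-wide
synchronous volleys whose all-or-nothing dynamics leave no stable bump
regime.  Synaptic currents are difference-of-exponentials (rise 1 ms,
decay 24 ms, unit peak).  The 24 ms decay is a model choice: with a decay
faster than the membrane time constant the recurrent loop is a race
between excitation re-arriving and the membrane leaking, and the stable
corridor is too narrow to survive ongoing plasticity.

**Recurrent excitation.** Gaussian in circular cell distance
(σ = b_HH = 22 cells ≈ 40°), weight scale `w_exc`, no autapses (exact
zero diagonal).  This footprint sustains a single bump ~110° wide at the
1 Hz level with a ~150 Hz peak once the intensity constants are
calibrated (below).

**Asymmetric AHV rings.** Two angular-head-velocity populations, one per
turn direction, are modelled rate-coded: their spatial profile follows
the HD synaptic output and their inhibitory back-projection onto the HD
ring is a Gaussian kernel offset by ±5 cells.  The two offset lobes
bound the bump; a push–pull modulation of their amplitudes —
±½·g·`velocity_drive`·ω for signed head velocity ω and global turn gain
g — moves the bump.  Push–pull (one ring up, the other down) keeps total
inhibition approximately constant and makes bump speed nearly linear in
g·ω up to ~135 deg/s; single-sided modulation saturates ~25% low at
protocol speeds.  A weak uniform inhibition proportional to total HD
output (`w_uniform_inh`) provides the winner-take-all competition needed
for landmark resets; the offset lobes alone cannot suppress a second
bump on the far side of the ring.

**Symmetric AHV unit.** One rate unit injecting an identical
speed-proportional current into every HD cell; its rate (in the units of
the plasticity rule, Hz-equivalent per deg/s: `c_teach`) is the teaching
signal for drift removal.

**Landmark input.** When the true heading is within ε = 3° of the
landmark bearing, a Gaussian current template (σ = 12 cells, peak 15)
centred on the landmark's associated HD cell is injected, scaled by a
raised-cosine heading window that is exactly zero at |error| ≥ 3°.  The
template is sized to the bump core rather than to 1.5·b_HH: a template
much wider than the bump reaches the high-trace region trailing the
bump, and the gain-calibration votes (below) are then dominated by
spurious reductions.  A distant reset ignites a new bump at the landmark
within ~30 ms and the old bump is extinguished by the uniform
inhibition; a nearby reset completes as a fast drag within ~200 ms.

## Rate statistics

Every calibration rule reads three per-cell statistics:

* instantaneous rate r = (1/ISI)·exp(−(t−t_s)/τ), τ = 33 ms (zero until
  a cell completes its first inter-spike interval);
* short-term average m = 20 ms exponential moving average of r;
  Δr = r − m is positive on the bump's leading edge, negative trailing;
* firing trace = max(r, trace·exp(−dt/2 s)): a decaying record of the
  highest recent rate.  From a 150 Hz peak it stays above the 10 Hz
  vote threshold for 2·ln(15) ≈ 5.4 s.

## Condition 1 — drift removal and turn equalisation

The rule's contract: weight changes on firing pre/post
pairs, driven by the mismatch between each cell's rate change and the
symmetric-AHV report, such that a too-fast bump is retarded.  Rendering
that contract in a spiking network at 1 ms resolution required several
implementation decisions, each forced by a measured failure mode:

* **Filtered delta-rate.** The per-step estimator difference Δr = r − m
  has a ~6.8 Hz noise floor against a ~1 Hz motion signal at protocol
  speeds; the raw rule is noise-dominated and converges to a pinned,
  immobile attractor.  The rule therefore reads a 50 ms low-pass of Δr
  (floor 0.27 Hz; the bump-motion signal lives at ≥100 ms timescales).
* **Antisymmetrised presynaptic factor.** Only the odd-about-the-bump
  component of Δr encodes motion; the even component is estimator noise.
  Using the odd part alone also conserves each postsynaptic cell's total
  input weight exactly.
* **Bump-averaged postsynaptic error.** With the per-cell factor
  |Δr_j| − AHV_sym, the flank-weighted core and edge contributions of
  the resulting weight dipole cancel in this architecture and the rule
  is motion-neutral; the error averaged over the firing population gives
  one coherent translation pressure per update.  The error saturates at
  ±8 Hz, and by default only the braking side acts (`boost_cap = 0`): a
  speed-up pressure gives the weights their own absolute-speed
  preference, which chases the turn-gain loop (coupling up, gain down)
  instead of leaving absolute speed to condition 2.
* **Smooth-mode restriction.** The factor profiles are spatially
  smoothed (σ = 6 cells) and tapered inside the both-cells-firing gate;
  sharp features (the gate edges travel with the bump) imprint few-cell
  weight texture that pins the attractor.
* **Orientation audit.** The classical verbal sign convention (strengthen
  from leading-edge cells when too fast) was verified empirically to
  slow the bump in this architecture; the opposite orientation drives
  runaway drift.  Pure-dipole perturbation experiments (adding ±ε·K′ to
  the weight rows) anchored the audit.
* **Affine teaching signal.** AHV_sym enters the comparison as
  `teach_floor + c_teach·|sensed speed|` with both constants measured at
  calibration (the floor is the filtered |Δr| of a stationary bump), so
  a stationary bump under a stationary head is exactly balanced.

**Presynaptic sharing and row consensus.** Efficacy diffuses between
circularly adjacent presynaptic weights onto the same postsynaptic cell
(the autapse position is skipped; each row's sum is conserved to machine
precision; applied in batches of 10 steps at an equivalent per-step
coefficient of 1e−4).  In addition, every 0.1 s each cell's input
profile, expressed relative to its own ring position, relaxes 5% of the
way toward the population-average profile.  This row consensus is this
package's own stabilising mechanism (a postsynaptic analogue of the
sharing step): without it, the residual cell-specific weight texture
(~1.5% of peak) written by learning noise pins the attractor so hard
that even twice the calibrated vestibular drive cannot move the bump,
while the population-average profile alone carries the entire
calibration signal.

**Annealing and suppression.** The learning rate starts at 20× base and
shrinks 0.5% per simulated second until it returns to base (step 598,
just under ten minutes).  Any landmark reset whose *cumulative*
displacement of the decoded bump exceeds 2 cells (3.6°) suppresses
condition-1 updates for 1 s — displacement is tracked over the whole
reset event because resets may complete as fast drags (well under a
degree per step) and still move the bump far.

## Condition 2 — turn-gain calibration

The turn gain g scales the vestibular drive.  Once per reset event — at
the moment the head enters the ±3° landmark window with a successful
detection — every HD cell votes from its pre-reset local state: a firing
cell (r > 1 Hz) is already representing the heading correctly and stays
silent; a silent cell with trace > 10 Hz was visited within the last few
seconds, so the bump ran past the landmark — it votes to reduce g by
α_r·I_landmark; a silent, low-trace cell marks a lagging bump and votes
to raise g by α_e·I_landmark.  Δg is the sum of the votes; α_e = 1e−6,
α_r = 1.5·α_e.  Voting once per event from the pre-reset state follows
the reading that the gain is updated each time the bump position is reset:
per-step voting through the reset window is systematically
reduction-biased (once the bump has arrived at the landmark, the only
remaining voters are trace-high cells just off its edge) and in closed
loop with condition 1 that bias produced a runaway gain decline.  A
single unit-matching factor (`gain_vote_scale` = 80) converts the α·I
products — whose absolute scale depends on this model's arbitrary
current units — onto the gain; it is fixed once against the reported
closed-loop timescale (plateau within ~5 minutes) and not revisited.

**Why revolutions must be slow.** The trace threshold separates "the
bump just passed here" from "its last pass was a while ago" only if a
full revolution takes longer than the trace persistence
(2 s · ln(150/10) ≈ 5.4 s).  Revolution blocks therefore run at
14–70 deg/s — the range used for dedicated 360° gain-calibration
turns — rather than the 25–100 deg/s of the small lateral turns; at
those faster speeds every cell's trace stays above threshold throughout
and all votes read "reduction" regardless of the true gain error.

**Movement-strategy dependence.** The vote logic is only reliable when
landmark crossings are spaced further apart than the ~5.4 s trace
persistence and approached from a consistent direction — which is
exactly what whole-revolution movements provide.  Under dithering or
rapid re-crossings the reset itself refreshes the trace at the landmark
cells, and the next crossing votes "reduction" regardless of the true
gain error.  This is not a defect to be tuned away: movement strategy
mattering is the point of the model, and the failure signatures under
the wrong movements (ablations a–c) are part of the reproduced
behaviour.  The gain closed-loop properties are therefore demonstrated
on the revolution protocol; the random-turn protocol is also provided
and behaves correctly from above but not reliably from below.

## Physiology calibration

Absolute weight/current magnitudes are free parameters.
`calibrate_physiology` fixes them against three published anchors, in
order: (i) a small deterministic grid over (`w_exc`, `w_inh`) selects
the settled stationary bump closest to 150 Hz peak (time-averaged
estimator) and 110° above-1 Hz width, each within ~5%; (ii) the bump
speed per unit g per unit input speed is measured at 60 deg/s and
inverted (with one secant refinement) to give the true gain `g_true`;
(iii) `c_teach` is the mean gated |Δr| per deg/s during correctly-
calibrated tracking; (iv) the bias shift of the standard miscalibrated
fixture is bisected so the untrained bump drifts one revolution in ~4 s.
The shipped defaults are the output of this procedure (seed 0) and are
reproduced by re-running it.

## Synthetic behaviour and sensors

The generators emulate the behavioural protocols at fixed statistics:
random turns (uniform −90..90 deg/s, durations 0–15 s, per-step
Bernoulli perturbations averaging one per second adding −45..45 deg/s,
cap ±135 deg/s, 10% rests), the warm-up schedule (60 s blocks
alternating small lateral turns of 40–80° about a per-block random
centre with 1–3 whole revolutions per turn in alternating directions,
speeds 25–100 deg/s; in stage 2 each small-turn block's centre becomes
the landmark bearing until the next small-turn block), robot-style spot
turns (1–3 revolutions, 14–70 deg/s), and the three ablations.  Whole
revolutions are generated with step counts rounded so each turn is an
exact multiple of 360°.  The vestibular channel under-reports turning by
8% and adds white Gaussian noise (σ = 5 deg/s per 1 ms step); the
landmark detector drops 30% of window crossings at random; darkness
disables landmark events entirely.  Turn amplitudes within small-turn
blocks are sampled uniformly within the 40–80° range.

What the generators do not emulate: real vestibular noise is neither
white nor stationary, real landmark detection errors are correlated with
pose and lighting, and a physical platform has motor dynamics (commanded
vs achieved velocity).  Passing tests therefore show that the
calibration mechanisms tolerate the *stated magnitudes* of bias and
dropout, not that they are robust to every real-world error structure —
the classic argument for physical embodiment stands.

## Landmark association

The postsubiculum is abstracted as an association table: in gain-only
experiments the landmark is pre-associated with the HD cell matching its
bearing; in the warm-up schedule each new bearing is associated with the
*decoded bump position* the first time the head faces it.  A stable,
drift-free bump (stage 1's outcome) is what makes that association
consistent — the reason the stages are ordered.

## Numerical choices and degenerate inputs

Euler/exact-exponential stepping at dt = 1 ms; all heading arithmetic is
circular in [0, 360) with errors reported in (−180, 180]; decoding is
the population vector over instantaneous rates with NaN (not an angle)
when the network is silent; drift is the least-squares slope of the
unwrapped decode, NaN if the bump amplitude falls below 0.5 anywhere in
the window; tuning curves average the rate estimator in 2° heading bins
over a two-revolution 20 deg/s sweep (slower sweeps let the attractor
pin on the frozen threshold disorder and stick), deskewed by regressing
the decoded bump position on the heading — over an open-loop sweep even
a percent of gain mismatch otherwise smears the firing range by tens of
degrees — with a half-bin edge correction on each side of the
above-threshold run.  Simulations are
bit-reproducible given (seed, dt); every experiment derives all of its
sub-seeds from one integer.

## The two calibration loops together

Condition 1 shapes the weights, condition 2 the gain, and both read the
same quantity (bump speed), so their closed-loop interaction matters.
Two couplings were measured and designed around: weight braking during
driven turns *softens* the attractor in this substrate — it raises the
speed-per-gain coupling instead of lowering it — so with both loops
fully active they chase each other (coupling up, gain down) until the
stationary bump can no longer self-sustain.  The shipped schedule
therefore runs stage 1 (weights only) at all speeds, and in stage 2 the
weight rule retreats to near-rest moments (`rest_gate_speed`, 15 deg/s)
where its teaching comparison is exact, leaving absolute speed entirely
to the gain loop.  Even so, condition-1 training gradually raises the
coupling (the anti-drift reshaping makes the ring easier to drive), so
the gain's self-consistent value after training sits below the
untrained network's; the gain loop finds it from either side.

## Problem sizes

Full-scale presets use the complete schedule (200 cells, 10-minute gain-only
runs, 15+15-minute two-stage training).  The shipped test-suite and
acceptance-script configurations use the same 200-cell network with
5-minute training stages and 10–15-minute gain-only runs, 5–10 audit
positions — the horizon at which the drift-removal and gain loops have
converged at the default learning rates.  The weight rule has no
convergence detector: run far past convergence it keeps integrating
estimator noise and slowly degrades the attractor (a recalibration
trigger — re-train only when resets grow large — is the natural remedy
and is out of scope here).

## Known limitations

* Bump speed saturates mildly above ~135 deg/s even with push–pull
  drive; tracking during the fastest protocol turns lags accordingly
  (the same speed-dependent nonlinearity is a recognised darkness error
  source in such models).
* The turn-gain loop is movement-dependent (see above); under the
  random-turn protocol with a too-low initial gain it does not rise
  reliably.
* The gain plateau has a dead band of a few percent: once the bump's
  overshoot or lag at a crossing is smaller than the gap between the
  bump half-width and the landmark template, every template cell is
  firing and no votes are cast.  Multi-revolution turns tighten the
  band (lag accumulates over 2–3 laps before each reset).
* After the full two-stage schedule the joint residuals — a few deg/s of
  position-dependent drift plus a few percent of gain dead-band — leave
  a darkness error growth of roughly a degree per second.  Minutes-long
  darkness tracking inside a 45° envelope — the behaviour of a
  well-calibrated physical platform — is out of reach of this substrate
  at desk scale; the
  corresponding test is expected to fail and documents the measured
  behaviour.
* The ±5% printed learning-rate and threshold constants are honoured,
  but all absolute current/weight scales are this model's own, fixed by
  the calibration anchors; quantities that depend on those scales (the
  numeric plateau gain, per-reset gain step) are matched at the level of
  behaviour, not digit-for-digit.
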