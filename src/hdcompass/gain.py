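"""Turn-gain calibration from landmark resets (stability condition 2).

The global turn gain ``g`` scales how fast the bump moves per unit of
vestibular (asymmetric AHV) input.  It is corrected every time the bump is
reset by landmark input, using only per-cell knowledge:

* a cell that is currently firing (rate > 1 Hz) while receiving landmark
  input is already representing head direction correctly -- no signal;
* a silent cell with a *high* firing trace (> 10 Hz) was visited by the
  bump recently, so the reset is pulling the bump backward: the bump ran
  too fast and the cell emits a gain *reduction* of alpha_r * I_landmark;
* a silent cell with a *low* trace has not been visited recently, so the
  reset is a forward jump: the bump lagged and the cell emits a gain
  *enhancement* of alpha_e * I_landmark.

The net gain change per step is the sum of the individual signals.  Cells
stop signalling the moment they start firing mid-reset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .network import GainState

__all__ = ["GainSignal", "cell_gain_signal", "aggregate_gain_update",
           "gain_update_step"]

#: cells firing above this rate do not adjust the gain (Hz)
FIRING_THRESHOLD_HZ = 1.0
#: trace threshold separating "recently visited" from "not yet visited" (Hz)
TRACE_THRESHOLD_HZ = 10.0
#: hard floor keeping the gain positive
GAIN_FLOOR = 1e-3


@dataclass(frozen=True)
class GainSignal:
    cell_index: int
    kind: Literal["reduction", "enhancement", "none"]
    magnitude: float = 0.0


def cell_gain_signal(rate: float, trace: float, landmark_in: float,
                     gain: GainState, cell_index: int = 0,
                     rate_threshold: float = FIRING_THRESHOLD_HZ,
                     trace_threshold: float = TRACE_THRESHOLD_HZ) -> GainSignal:
    """Gain-adjustment vote of a single HD cell for one step."""
    if min(rate, trace, landmark_in) < 0:
        raise ValueError("rate, trace and landmark input must be non-negative")
    if landmark_in == 0.0 or rate > rate_threshold:
        return GainSignal(cell_index, "none")
    if trace > trace_threshold:
        return GainSignal(cell_index, "reduction", gain.alpha_r * landmark_in)
    return GainSignal(cell_index, "enhancement", gain.alpha_e * landmark_in)


def aggregate_gain_update(signals: Iterable[GainSignal],
                          gain: GainState) -> GainState:
    """Apply the summed per-cell votes to the gain (clamped above zero)."""
    dg = 0.0
    for s in signals:
        if s.kind == "enhancement":
            dg += s.magnitude
        elif s.kind == "reduction":
            dg -= s.magnitude
    gain.g = max(gain.g + dg, GAIN_FLOOR)
    return gain


def gain_update_step(rates: np.ndarray, traces: np.ndarray,
                     landmark_in: np.ndarray, gain: GainState,
                     rate_threshold: float = FIRING_THRESHOLD_HZ,
                     trace_threshold: float = TRACE_THRESHOLD_HZ,
                     scale: float = 1.0) -> float:
    """Vectorised equivalent of signalling + aggregation for one step.

    ``scale`` converts the per-cell vote magnitudes (learning rate x
    landmark current, in this model's arbitrary current units) onto the
    per-step gain change; it is fixed once against the reported closed-
    loop convergence timescale.  Returns the applied gain change (and
    mutates ``gain``).
    """
    silent = (rates <= rate_threshold) & (landmark_in > 0)
    if not silent.any():
        return 0.0
    reduce_mask = silent & (traces > trace_threshold)
    enhance_mask = silent & ~reduce_mask
    dg = scale * (gain.alpha_e * float(landmark_in[enhance_mask].sum())
                  - gain.alpha_r * float(landmark_in[reduce_mask].sum()))
    gain.g = max(gain.g + dg, GAIN_FLOOR)
    return dg
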