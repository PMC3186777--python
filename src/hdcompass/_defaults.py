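"""Frozen default calibration shipped with the package.

These numbers are the output of :func:`hdcompass.metrics.calibrate_physiology`
run with the default parameter ranges and seed 0; they anchor the model's
free intensity constants to the published physiology (150 Hz peak,
110 deg tuning width, 4 s biased-fixture drift period).  Re-running the
calibration reproduces them.
"""

from __future__ import annotations

from functools import lru_cache

from .metrics import CalibrationResult
from .network import NetworkParams

_DEFAULT = dict(
    bias_shift=0.4357,      # fixture shift -> 89.7 deg/s untrained drift
    speed_per_gain=0.985,   # bump deg/s per unit gain per deg/s input
    g_true=1.0015,          # gain at which bump speed matches head speed
    c_teach=0.0462,         # symmetric-AHV teaching slope, Hz per deg/s
    teach_floor=0.278,      # teaching baseline: stationary filtered |delta r| (Hz)
)


@lru_cache(maxsize=1)
def default_calibration() -> CalibrationResult:
    """The package's frozen physiology calibration (200-cell network)."""
    return CalibrationResult(params=NetworkParams(), **_DEFAULT)
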