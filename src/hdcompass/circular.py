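"""Small helpers for circular (heading) arithmetic in degrees."""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "circ_diff_deg", "circ_dist_cells", "unwrap_deg"]


def wrap_deg(a):
    """Wrap angle(s) into [0, 360)."""
    return np.mod(a, 360.0)


def circ_diff_deg(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - b, 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def circ_dist_cells(i, j, n):
    """Signed circular index distance i - j on a ring of n cells, in (-n/2, n/2]."""
    d = np.mod(np.asarray(i) - np.asarray(j), n)
    return np.where(d > n / 2, d - n, d)


def unwrap_deg(angles):
    """Unwrap a time series of headings in degrees into a continuous series."""
    return np.degrees(np.unwrap(np.radians(np.asarray(angles, dtype=float))))
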