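"""Drift-removal and turn-equalisation plasticity (stability condition 1).

The recurrent HD weights are updated from a purely local teaching signal:
the symmetric AHV input, a rate-coded copy of |head turning speed| that is
identical for every HD cell.  For connection i -> j (both cells firing):

    dw_ij = alpha_eff * delta_r_i * (|delta_r_j| - AHV_sym) * dt

If the bump moves faster than the head (|delta_r_j| > AHV_sym), weights
from trailing-edge presynaptic cells (delta_r_i < 0) are weakened and
weights from leading-edge cells are strengthened, which retards the bump;
when the bump is too slow the update reverses and speeds it up.  The fixed
point is a bump whose rate of change matches the symmetric AHV report --
i.e. no drift when the head is still, and equal-magnitude displacement for
equal-magnitude turns in either direction.

Two supporting mechanisms keep learning well behaved:

* presynaptic weight sharing -- efficacy diffuses between circularly
  adjacent presynaptic connections onto the same postsynaptic cell
  (conserving each cell's total input weight), smoothing noise so the
  weight profiles tend back toward clean Gaussians;
* suppression and annealing -- updates are silenced for 1 s after any
  landmark reset that actually displaces the bump (the reset transient
  would otherwise be read as a huge instability), and the learning rate
  starts at 20x base and shrinks by 0.5% per simulated second until it
  returns to base after just under ten minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .network import Connectome
from .neurons import PopulationState, delta_rate

__all__ = [
    "PlasticityState",
    "stability_update",
    "share_presynaptic_weights",
    "row_consensus",
    "suppression_gate",
    "anneal_learning_rate",
]

#: a cell counts as "firing" for the Hebbian gate above this rate (Hz)
FIRING_GATE_HZ = 1.0
#: a landmark reset displacing the bump by more than this suppresses learning
RESET_DISPLACEMENT_DEG = 3.6
#: suppression window after a displacing reset (s)
SUPPRESSION_S = 1.0


@dataclass
class PlasticityState:
    """Learning-rate bookkeeping for the condition-1 rule."""

    alpha: float = 1e-4                   # base learning rate
    current_lr: float | None = None       # annealed effective rate
    anneal_multiplier_initial: float = 20.0
    anneal_decay_per_second: float = 0.005
    suppression_remaining: float = 0.0    # seconds of suppression left
    share_rate: float = 1e-4              # per-step diffusion coefficient
    delta_cap: float = 8.0                # saturation of the rate factors (Hz)
    boost_cap: float = 0.0                # cap on the too-slow (speed-up) error
    smooth_sigma: float = 6.0             # spatial smoothing of factors (cells)
    consensus_rate: float = 0.05          # row-consensus relaxation per application
    consensus_interval: float = 0.1       # seconds between applications
    rest_gate_speed: float = 15.0         # apply updates only below this |speed|

    def __post_init__(self) -> None:
        if self.current_lr is None:
            self.current_lr = self.alpha * self.anneal_multiplier_initial

    @property
    def suppressed(self) -> bool:
        return self.suppression_remaining > 0.0


@lru_cache(maxsize=8)
def _unit_vectors(n: int) -> np.ndarray:
    """(n, 2) array of preferred-direction unit vectors for decoding."""
    theta = np.arange(n) * 2 * np.pi / n
    return np.column_stack((np.cos(theta), np.sin(theta)))


@lru_cache(maxsize=8)
def _smoothing_kernel_fft(n: int, sigma: float) -> np.ndarray:
    """rFFT of a unit-sum circular Gaussian smoothing kernel."""
    d = np.arange(n)
    d = np.minimum(d, n - d).astype(float)
    k = np.exp(-d**2 / (2 * sigma**2))
    k /= k.sum()
    return np.fft.rfft(k)


def _circular_smooth(x: np.ndarray, sigma: float) -> np.ndarray:
    return np.fft.irfft(np.fft.rfft(x) * _smoothing_kernel_fft(len(x), sigma),
                        len(x))


@lru_cache(maxsize=8)
def _skip_diagonal_ring(n: int) -> np.ndarray:
    """Index matrix G with G[j, k] = presynaptic cell k steps past j.

    Row j lists the n-1 presynaptic indices of postsynaptic cell j in ring
    order, skipping j itself (autapses do not exist); the first and last
    entries (j+1 and j-1) are circular neighbours of each other.
    """
    j = np.arange(n)[:, None]
    k = np.arange(n - 1)[None, :]
    return (j + 1 + k) % n


def stability_update(conn: Connectome, state: PopulationState,
                     ahv_sym: float, plast: PlasticityState,
                     dt: float, dr: np.ndarray | None = None) -> Connectome:
    """Apply one step of the condition-1 weight update (in place).

    No-op while suppression is active.  Updates are restricted to pairs of
    cells that are both firing (rate above 1 Hz), so silent connections --
    and everything far from the bump -- are untouched.  Weights are
    floored at zero; the (non-existent) diagonal is never written.
    """
    if ahv_sym < 0:
        raise ValueError("symmetric AHV input encodes |speed|, must be >= 0")
    if plast.suppressed:
        return conn
    r = state.instantaneous_rate
    gate = r > FIRING_GATE_HZ
    if gate.sum() < 2:
        return conn
    if dr is None:
        dr = delta_rate(state)
    pre = np.where(gate, dr, 0.0)
    # antisymmetrise the presynaptic factor about the bump centre: the
    # motion information in delta_r is its odd component (positive on the
    # leading edge, negative trailing); the even component is estimator
    # noise.  The antisymmetric update also conserves every postsynaptic
    # cell's total input weight.
    n = len(pre)
    rates_vec = r @ _unit_vectors(n)
    centre = int(round(np.arctan2(rates_vec[1], rates_vec[0])
                       / (2 * np.pi / n))) % n
    mirror = (2 * centre - np.arange(n)) % n
    pre = 0.5 * (pre - pre[mirror])
    # the postsynaptic factor is the speed-error term |delta_r_j| - AHV_sym
    # averaged over the firing population: per-cell flank weighting makes
    # the core and edge contributions of the resulting dipole cancel in
    # this architecture, whereas the bump-averaged error produces one
    # coherent translation pressure on every active row
    err = float(np.abs(dr[gate]).mean()) - ahv_sym
    # one-sided saturation: the rule brakes a too-fast bump but (by
    # default) never boosts a too-slow one.  Drift removal and turn
    # equalisation only need braking of whichever motion is too fast;
    # a speed-up pressure gives the weights their own absolute speed
    # preference, which fights the turn-gain loop (the two controllers
    # chase each other: coupling up, gain down) instead of leaving the
    # absolute speed to the gain
    err = float(np.clip(err, -plast.boost_cap, plast.delta_cap))
    cap = plast.delta_cap
    np.clip(pre, -cap, cap, out=pre)
    # restrict the update to smooth spatial modes: sharp (few-cell) weight
    # texture carries no calibration information but pins the attractor,
    # after which vestibular input can no longer move the bump.  The hard
    # both-cells-firing gate still masks the update, but the factor
    # profiles are tapered inside it so the gate edges (which travel with
    # the bump) do not imprint step-like texture.
    gf = gate.astype(float)
    if plast.smooth_sigma > 0:
        taper = np.clip(_circular_smooth(gf, plast.smooth_sigma), 0.0, 1.0) * gf
        pre = _circular_smooth(pre, plast.smooth_sigma) * taper
        post = err * taper
    else:
        taper = gf
        pre = pre * gf
        post = err * gf
    # the taper breaks the exact zero sum of the antisymmetrised factor;
    # re-centre within the taper so each postsynaptic row's total input
    # weight stays conserved (otherwise sustained braking bleeds row mass
    # and the attractor eventually cannot sustain a bump)
    tsum = float(taper.sum())
    if tsum > 0:
        pre -= taper * (float(pre.sum()) / tsum)
    # orientation: the classical sign convention (strengthen from
    # leading-edge cells when too fast); verified empirically to slow a
    # too-fast bump in this architecture -- the opposite orientation
    # drives runaway drift (see the methods note for the sign audit)
    w = conn.w_hh
    w += (plast.current_lr * dt) * np.outer(post, pre)
    np.fill_diagonal(w, 0.0)              # keep autapses absent
    np.maximum(w, 0.0, out=w)
    return conn


def share_presynaptic_weights(conn: Connectome, alpha: float,
                              rows: np.ndarray | int | None = None) -> Connectome:
    """Diffuse efficacy between circularly adjacent presynaptic weights.

    For each postsynaptic cell j, weight flows from stronger to weaker
    synapses among presynaptic triples (i-1, i, i+1) -- discrete diffusion
    on the ring of n-1 presynaptic cells (the autapse position is skipped,
    so cells j-1 and j+1 are treated as adjacent).  Each row's total
    incoming weight is conserved to machine precision.

    ``rows`` selects the postsynaptic cells to update (default: all);
    ``alpha`` is the per-call diffusion coefficient (must be < 0.5 for
    stability of the explicit scheme).
    """
    n = conn.n_hd
    if n < 3:
        raise ValueError("need at least 3 cells to share presynaptic weight")
    if not 0 <= alpha < 0.5:
        raise ValueError("sharing coefficient must lie in [0, 0.5)")
    g = _skip_diagonal_ring(n)
    if rows is None:
        gi = g
        aligned = np.take_along_axis(conn.w_hh, gi, axis=1)
        lap = np.roll(aligned, 1, axis=1) + np.roll(aligned, -1, axis=1) - 2 * aligned
        aligned += alpha * lap
        np.put_along_axis(conn.w_hh, gi, aligned, axis=1)
    else:
        rows = np.atleast_1d(np.asarray(rows, dtype=int))
        gi = g[rows]
        aligned = conn.w_hh[rows[:, None], gi]
        lap = np.roll(aligned, 1, axis=1) + np.roll(aligned, -1, axis=1) - 2 * aligned
        aligned += alpha * lap
        conn.w_hh[rows[:, None], gi] = aligned
    return conn


@lru_cache(maxsize=8)
def _align_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Column indices that rotate each row j of a matrix left by j (and back)."""
    j = np.arange(n)[:, None]
    i = np.arange(n)[None, :]
    return (i + j) % n, (i - j) % n


def row_consensus(conn: Connectome, rate: float) -> Connectome:
    """Relax every row's input profile toward the population consensus.

    Each HD cell's incoming weight profile, expressed relative to its own
    ring position, is pulled toward the average profile of all cells.
    The translation-invariant (circulant) structure of the ring is thereby
    continuously restored: the calibration signal all cells agree on (the
    drift/turn-rate correction) passes through untouched, while
    cell-specific residue -- which only roughens the attractor landscape
    until vestibular input can no longer move the bump -- decays with time
    constant ``1/rate`` applications.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("consensus rate must lie in [0, 1]")
    if rate == 0.0:
        return conn
    n = conn.n_hd
    fwd, back = _align_indices(n)
    aligned = np.take_along_axis(conn.w_hh, fwd, axis=1)
    mean_row = aligned.mean(axis=0)
    aligned += rate * (mean_row[None, :] - aligned)
    conn.w_hh = np.take_along_axis(aligned, back, axis=1)
    np.fill_diagonal(conn.w_hh, 0.0)
    return conn


def suppression_gate(plast: PlasticityState, reset_displacement: float,
                     dt: float,
                     threshold: float = RESET_DISPLACEMENT_DEG) -> PlasticityState:
    """Advance the suppression timer; refresh it if a reset moved the bump.

    ``reset_displacement`` is the decoded bump displacement (degrees)
    caused by a landmark reset this step (0 when no reset occurred).  A
    displacing reset restarts the full 1 s window, so overlapping resets
    extend suppression until 1 s after the last one.
    """
    plast.suppression_remaining = max(plast.suppression_remaining - dt, 0.0)
    if abs(reset_displacement) > threshold:
        plast.suppression_remaining = SUPPRESSION_S
    return plast


def anneal_learning_rate(plast: PlasticityState,
                         seconds_elapsed: float | None = None) -> PlasticityState:
    """One annealing step (call at the end of each simulated second).

    The effective rate shrinks by 0.5% per call, starting from 20x the
    base rate, and never falls below the base rate -- after which no
    further reduction occurs.
    """
    plast.current_lr = max(plast.alpha,
                           plast.current_lr * (1.0 - plast.anneal_decay_per_second))
    return plast
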