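"""Condition-1 rule semantics: annealing, suppression, sharing, gating."""

import numpy as np
import pytest

from hdcompass.network import NetworkParams, build_connectome
from hdcompass.neurons import PopulationState
from hdcompass.plasticity import (PlasticityState, anneal_learning_rate,
                                  share_presynaptic_weights,
                                  stability_update, suppression_gate)

DT = 1e-3


def small_connectome(n=40):
    return build_connectome(NetworkParams(n_hd=n, b_hh=4.0, inh_offset=3,
                                          inh_sigma=6.0))


def state_with(n, rates, short_term=None):
    st = PopulationState(n)
    st.instantaneous_rate = np.asarray(rates, dtype=float)
    st.short_term_average = (np.zeros(n) if short_term is None
                             else np.asarray(short_term, dtype=float))
    return st


class TestAnnealing:
    def test_starts_at_twenty_times_base(self):
        p = PlasticityState(alpha=1e-4)
        assert p.current_lr == pytest.approx(20e-4)

    def test_sixty_steps_cut_about_a_quarter(self):
        p = PlasticityState(alpha=1e-4)
        for _ in range(60):
            anneal_learning_rate(p)
        assert p.current_lr / 20e-4 == pytest.approx(0.995**60)
        assert 1 - 0.995**60 == pytest.approx(0.26, abs=0.005)

    def test_baseline_reached_at_step_598(self):
        p = PlasticityState(alpha=1e-4)
        step = 0
        while p.current_lr > p.alpha:
            anneal_learning_rate(p)
            step += 1
        assert step == 598

    def test_no_reduction_below_baseline(self):
        p = PlasticityState(alpha=1e-4, current_lr=1e-4)
        for _ in range(50):
            anneal_learning_rate(p)
        assert p.current_lr == 1e-4


class TestSuppression:
    def test_displacing_reset_suppresses_for_one_second(self):
        p = PlasticityState()
        suppression_gate(p, 40.0, DT)
        assert p.suppression_remaining == pytest.approx(1.0)
        assert p.suppressed

    def test_non_moving_reset_does_not_suppress(self):
        p = PlasticityState()
        suppression_gate(p, 1.0, DT)
        assert not p.suppressed

    def test_timer_counts_down_and_expires(self):
        p = PlasticityState()
        suppression_gate(p, 40.0, DT)
        for _ in range(1000):
            suppression_gate(p, 0.0, DT)
        assert not p.suppressed

    def test_second_reset_refreshes_window(self):
        # two resets 0.5 s apart: suppression lasts until 1 s after the
        # second, i.e. 1.5 s after the first
        p = PlasticityState()
        suppression_gate(p, 40.0, DT)
        for _ in range(500):
            suppression_gate(p, 0.0, DT)
        suppression_gate(p, 40.0, DT)
        assert p.suppression_remaining == pytest.approx(1.0)

    def test_stability_update_noop_while_suppressed(self):
        conn = small_connectome()
        before = conn.w_hh.copy()
        st = state_with(conn.n_hd, np.full(conn.n_hd, 50.0))
        p = PlasticityState(suppression_remaining=0.5)
        stability_update(conn, st, 0.0, p, DT)
        assert np.array_equal(conn.w_hh, before)


class TestStabilityUpdate:
    def test_silent_cells_leave_weights_unchanged(self):
        conn = small_connectome()
        before = conn.w_hh.copy()
        n = conn.n_hd
        rates = np.zeros(n)
        rates[:4] = 50.0            # a few firing cells, rest silent
        st = state_with(n, rates, short_term=rates * 0.9)
        stability_update(conn, st, 0.0, PlasticityState(), DT)
        silent = np.ones(n, dtype=bool)
        silent[:4] = False
        # any connection touching a silent cell is untouched
        assert np.array_equal(conn.w_hh[silent][:, silent],
                              before[silent][:, silent])
        assert np.array_equal(conn.w_hh[:, silent], before[:, silent])
        assert np.array_equal(conn.w_hh[silent, :], before[silent, :])

    def test_matched_bump_and_head_is_a_fixed_point(self):
        conn = small_connectome()
        before = conn.w_hh.copy()
        n = conn.n_hd
        rates = np.full(n, 50.0)
        st = state_with(n, rates, short_term=rates)  # delta r = 0
        stability_update(conn, st, 0.0, PlasticityState(), DT)
        assert np.allclose(conn.w_hh, before)

    def test_negative_symmetric_input_rejected(self):
        conn = small_connectome()
        st = state_with(conn.n_hd, np.zeros(conn.n_hd))
        with pytest.raises(ValueError):
            stability_update(conn, st, -1.0, PlasticityState(), DT)

    def test_diagonal_never_written(self):
        conn = small_connectome()
        n = conn.n_hd
        rates = np.full(n, 50.0)
        st = state_with(n, rates, short_term=rates * 0.5)
        stability_update(conn, st, 0.0, PlasticityState(), DT)
        assert np.all(np.diag(conn.w_hh) == 0.0)

    def test_weights_stay_nonnegative(self):
        conn = small_connectome()
        n = conn.n_hd
        st = state_with(n, np.full(n, 50.0), short_term=np.full(n, 80.0))
        p = PlasticityState(alpha=1.0)   # absurdly large to force clipping
        stability_update(conn, st, 0.0, p, DT)
        assert conn.w_hh.min() >= 0.0


class TestSharing:
    def test_equal_weights_unchanged(self):
        conn = small_connectome()
        conn.w_hh[:] = 0.3
        np.fill_diagonal(conn.w_hh, 0.0)
        before = conn.w_hh.copy()
        share_presynaptic_weights(conn, 0.1)
        assert np.allclose(conn.w_hh, before)

    def test_row_sums_conserved_to_machine_precision(self, rng):
        conn = small_connectome()
        conn.w_hh += rng.uniform(0, 0.2, conn.w_hh.shape)
        np.fill_diagonal(conn.w_hh, 0.0)
        before = conn.w_hh.sum(axis=1)
        for _ in range(200):
            share_presynaptic_weights(conn, 0.2)
        after = conn.w_hh.sum(axis=1)
        assert np.allclose(after, before, rtol=1e-12)

    def test_flow_from_stronger_to_weaker(self):
        conn = small_connectome(n=20)
        conn.w_hh[:] = 0.0
        conn.w_hh[0, 5] = 2.0    # isolated strong synapse
        share_presynaptic_weights(conn, 0.1, rows=0)
        assert conn.w_hh[0, 5] < 2.0
        assert conn.w_hh[0, 4] > 0.0 and conn.w_hh[0, 6] > 0.0

    def test_smoothing_reduces_roughness_monotonically(self, rng):
        # oracle: diffusion shrinks the high-frequency residual around the
        # best-fit smooth profile; track the second-difference energy
        conn = small_connectome()
        conn.w_hh += rng.normal(0.0, 0.02, conn.w_hh.shape).clip(min=0.0)
        np.fill_diagonal(conn.w_hh, 0.0)

        def roughness(row):
            return float(np.sum(np.diff(np.diff(row)) ** 2))

        vals = [roughness(conn.w_hh[7, np.r_[8:conn.n_hd, 0:7]])]
        for _ in range(100):
            share_presynaptic_weights(conn, 0.2)
            vals.append(roughness(conn.w_hh[7, np.r_[8:conn.n_hd, 0:7]]))
        diffs = np.diff(vals)
        assert vals[-1] < 0.1 * vals[0]
        assert np.all(diffs <= 1e-12)

    def test_coefficient_validated(self):
        conn = small_connectome()
        with pytest.raises(ValueError):
            share_presynaptic_weights(conn, 0.7)
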