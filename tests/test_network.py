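"""Connectome structure, landmark geometry, and bump dynamics."""

import numpy as np
import pytest

from hdcompass.circular import circ_diff_deg
from hdcompass.metrics import _bump_stats, _measure_drift, _measure_speed
from hdcompass.network import (GainState, LandmarkModel, NetworkParams,
                               RingAttractor, apply_circular_bias,
                               build_connectome, heading_attenuation,
                               landmark_current, landmark_template)


class TestBuildConnectome:
    def test_default_shape_and_zero_diagonal(self, connectome):
        assert connectome.w_hh.shape == (200, 200)
        assert np.all(np.diag(connectome.w_hh) == 0.0)
        assert connectome.w_hh.min() >= 0.0

    def test_rows_are_rotations_of_row_zero(self, connectome):
        w = connectome.w_hh
        for k in (1, 57, 121):
            assert np.allclose(np.roll(w[0], k), w[k])

    def test_row_sums_all_equal(self, connectome):
        sums = connectome.w_hh.sum(axis=1)
        assert np.allclose(sums, sums[0])

    def test_too_small_ring_rejected(self):
        with pytest.raises(ValueError):
            build_connectome(NetworkParams(n_hd=10))

    def test_degenerate_offset_rejected(self):
        with pytest.raises(ValueError):
            build_connectome(NetworkParams(n_hd=40, inh_offset=25))


class TestCircularBias:
    def test_zero_shift_is_identity(self, connectome):
        out = apply_circular_bias(connectome, 0.0)
        assert np.allclose(out.w_hh, connectome.w_hh)

    def test_quarter_ring_shift_rejected(self, connectome):
        with pytest.raises(ValueError):
            apply_circular_bias(connectome, 60.0)

    def test_fractional_shift_interpolates(self, connectome):
        lo = apply_circular_bias(connectome, 1.0).w_hh
        hi = apply_circular_bias(connectome, 2.0).w_hh
        mid = apply_circular_bias(connectome, 1.5).w_hh
        blend = 0.5 * (lo + hi)
        np.fill_diagonal(blend, 0.0)
        assert np.allclose(mid, blend)

    def test_autapses_stay_absent(self, connectome):
        out = apply_circular_bias(connectome, 0.7)
        assert np.all(np.diag(out.w_hh) == 0.0)

    def test_opposite_shifts_drift_symmetrically(self, connectome, calib):
        """+s and -s fixtures drift at equal magnitude, opposite sign."""
        s = calib.bias_shift
        d_pos = _measure_drift(apply_circular_bias(connectome, s),
                               sim_time=2.0, seed=0)
        d_neg = _measure_drift(apply_circular_bias(connectome, -s),
                               sim_time=2.0, seed=0)
        assert np.sign(d_pos) == -np.sign(d_neg)
        assert abs(d_pos) == pytest.approx(abs(d_neg), rel=0.15)


class TestLandmarkCurrent:
    def lm(self, params):
        return LandmarkModel(180.0, 100, epsilon=params.landmark_epsilon,
                             peak_current=params.landmark_peak,
                             sigma_cells=params.landmark_sigma)

    def test_peak_at_centre_facing_exactly(self, params):
        cur = landmark_current(self.lm(params), params.n_hd, params.b_hh, 0.0)
        assert cur.argmax() == 100
        assert cur.max() == pytest.approx(params.landmark_peak)

    def test_template_nonincreasing_with_distance(self, params):
        t = landmark_template(self.lm(params), params.n_hd, params.b_hh)
        left = t[100::-1]
        assert np.all(np.diff(left) <= 1e-12)

    def test_zero_everywhere_outside_window(self, params):
        for a in (3.0, 3.5, -4.0, 180.0):
            cur = landmark_current(self.lm(params), params.n_hd,
                                   params.b_hh, a)
            assert np.all(cur == 0.0)

    def test_window_boundary_is_exactly_epsilon(self, params):
        # finest relevant scan: nonzero strictly inside +-3 deg, zero outside
        offsets = np.arange(0.0, 10.0, 0.01)
        att = heading_attenuation(self.lm(params), offsets)
        nonzero = offsets[att > 0.0]
        assert nonzero.max() < 3.0
        assert att[offsets <= 2.99].min() > 0.0

    def test_attenuation_symmetric(self, params):
        lm = self.lm(params)
        a = np.linspace(0.0, 4.0, 100)
        assert np.allclose(heading_attenuation(lm, a),
                           heading_attenuation(lm, -a))


class TestBumpDynamics:
    def test_settled_bump_is_single_and_contiguous(self, settled_bump):
        r = settled_bump.rates
        above = r > 0.1 * r.max()
        transitions = np.diff(np.r_[0, above.astype(int), 0])
        assert (transitions == 1).sum() - int(above[0] and above[-1]) <= 1

    def test_stationary_bump_metrics_match_anchors(self, params):
        peak, width, _ = _bump_stats(params, sim_time=3.0, measure=2.0,
                                     seed=11)
        assert peak == pytest.approx(150.0, rel=0.08)
        assert width == pytest.approx(110.0, rel=0.12)

    def test_bump_position_invariance(self, connectome):
        """Peak rate and width vary little across starting positions."""
        stats = []
        for start in (0.0, 100.0, 217.0):
            net = RingAttractor(connectome, seed=5)
            net.initialize_bump(start)
            acc = np.zeros(connectome.n_hd)
            for k in range(1500):
                net.step()
                if k > 500:
                    acc += net.rates
            acc /= 1000
            stats.append((acc.max(),
                          (acc > 1.0).sum() * connectome.params.deg_per_cell))
        peaks, widths = zip(*stats)
        assert max(peaks) - min(peaks) < 0.15 * max(peaks)
        assert max(widths) - min(widths) < 0.15 * max(widths)

    def test_velocity_sign_symmetry(self, connectome):
        sp = _measure_speed(connectome, g=1.0, v=60.0, sim_time=2.0, seed=2)
        sn = _measure_speed(connectome, g=1.0, v=-60.0, sim_time=2.0, seed=2)
        assert sp > 10.0 and sn < -10.0

    def test_gain_speed_map_monotone_and_roughly_linear(self, connectome):
        speeds = [_measure_speed(connectome, g=g, v=30.0, sim_time=2.0,
                                 seed=3) for g in (0.5, 1.0, 2.0)]
        assert speeds[0] < speeds[1] < speeds[2]
        assert speeds[1] / speeds[0] == pytest.approx(2.0, rel=0.35)
        assert speeds[2] / speeds[1] == pytest.approx(2.0, rel=0.35)

    def test_nan_velocity_rejected(self, connectome):
        net = RingAttractor(connectome, seed=0)
        with pytest.raises(ValueError):
            net.step(ahv_asym=float("nan"))

    def test_landmark_reset_snaps_bump_within_200ms(self, connectome, params):
        net = RingAttractor(connectome, seed=4)
        net.initialize_bump(60.0)
        lm = LandmarkModel(180.0, 100, peak_current=params.landmark_peak,
                           sigma_cells=params.landmark_sigma)
        cur = landmark_current(lm, params.n_hd, params.b_hh, 0.0)
        for _ in range(200):
            net.step(landmark_input=cur)
        angle, amp = net.decode()
        assert abs(circ_diff_deg(angle, 180.0)) < 15.0
        assert amp > 10.0

    def test_fixed_seed_simulation_is_reproducible(self, connectome):
        def run():
            net = RingAttractor(connectome, seed=9)
            net.initialize_bump(45.0)
            for _ in range(1000):
                net.step(ahv_asym=20.0, ahv_sym_speed=20.0)
            return net.state.membrane_potential.copy(), net.rates.copy()
        v1, r1 = run()
        v2, r2 = run()
        assert np.array_equal(v1, v2) and np.array_equal(r1, r2)
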