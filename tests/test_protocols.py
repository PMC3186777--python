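"""Movement-protocol and sensor-emulation tests."""

import numpy as np
import pytest

from hdcompass.circular import circ_diff_deg, wrap_deg
from hdcompass.network import LandmarkModel
from hdcompass.protocols import (SPEED_CAP, HeadTrajectory, ablation_protocol,
                                 landmark_detector, random_turn_protocol,
                                 spot_turn_protocol, vestibular_sensor,
                                 warmup_protocol)

DT = 1e-3


def reintegrate(traj: HeadTrajectory) -> None:
    """The defining invariant: heading[k+1] = wrap(heading[k] + omega[k]*dt)."""
    h = traj.heading
    expected = wrap_deg(h[:-1] + traj.omega[:-1] * traj.dt)
    assert np.allclose(circ_diff_deg(h[1:], expected), 0.0, atol=1e-8)


class TestRandomTurnProtocol:
    def test_speed_cap_holds_for_any_seed(self):
        for seed in range(5):
            traj = random_turn_protocol(60.0, seed=seed)
            assert np.max(np.abs(traj.omega)) <= SPEED_CAP + 1e-9

    def test_rest_fraction_near_ten_percent(self):
        # aggregate many short runs for ~10^4 turn initiations
        turns = rests = 0
        for seed in range(40):
            traj = random_turn_protocol(2000.0, seed=seed, dt=0.01)
            turns += traj.extras["n_turns"]
            rests += traj.extras["n_rests"]
        frac = rests / (turns + rests)
        assert turns + rests > 10_000
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_same_seed_reproduces_trajectory(self):
        a = random_turn_protocol(30.0, seed=7)
        b = random_turn_protocol(30.0, seed=7)
        assert np.array_equal(a.omega, b.omega)
        assert np.array_equal(a.heading, b.heading)

    def test_integration_invariant(self):
        reintegrate(random_turn_protocol(20.0, seed=3))

    def test_turn_rates_cover_stated_range(self):
        traj = random_turn_protocol(600.0, seed=2)
        moving = traj.omega[traj.omega != 0.0]
        assert moving.min() < -60.0 and moving.max() > 60.0


class TestWarmupProtocol:
    def test_duration_must_be_multiple_of_block(self):
        with pytest.raises(ValueError):
            warmup_protocol(90.0, stage=1, seed=0)

    def test_block_boundaries_on_minute_grid(self):
        traj = warmup_protocol(240.0, stage=1, seed=1)
        for blk in traj.extras["blocks"]:
            assert blk["start"] % int(60.0 / DT) == 0
            assert (blk["stop"] - blk["start"]) == int(60.0 / DT)

    def test_revolution_segments_are_whole_turns(self):
        traj = warmup_protocol(360.0, stage=1, seed=4)
        unwrapped = traj.heading_unwrapped
        seen = 0
        for blk in traj.extras["blocks"]:
            if blk["kind"] != "revolution":
                continue
            for s, e, rot in blk["segments"]:
                seen += 1
                assert abs(rot) in (360.0, 720.0, 1080.0)
                actual = unwrapped[min(e, len(unwrapped) - 1)] - unwrapped[s]
                assert actual == pytest.approx(rot, abs=1.0)
        assert seen >= 2

    def test_small_turn_block_stays_near_centre(self):
        traj = warmup_protocol(240.0, stage=1, seed=5)
        h = traj.heading
        for blk in traj.extras["blocks"]:
            if blk["kind"] != "small":
                continue
            seg = h[blk["settle"]:blk["stop"]]
            off = np.abs(circ_diff_deg(seg, blk["centre"]))
            assert off.max() <= 80.0

    def test_speeds_within_commanded_ranges(self):
        # small lateral turns are commanded at 25-100 deg/s, whole
        # revolutions at the slower 14-70 deg/s gain-calibration range
        traj = warmup_protocol(240.0, stage=2, seed=6)
        for blk in traj.extras["blocks"]:
            seg = traj.omega[blk["start"]:blk["stop"]]
            moving = np.abs(seg[seg != 0.0])
            if not moving.size:
                continue
            if blk["kind"] == "small":
                assert moving.max() <= 100.0 + 1e-6
            else:
                assert moving.max() <= 70.0 + 1e-6
                assert moving.min() >= 14.0 - 1e-6

    def test_stage2_bearing_schedule_follows_small_blocks(self):
        traj = warmup_protocol(240.0, stage=2, seed=7)
        bearing = traj.extras["landmark_bearing"]
        blocks = traj.extras["blocks"]
        smalls = [b for b in blocks if b["kind"] == "small"]
        revs = [b for b in blocks if b["kind"] == "revolution"]
        # during each revolution block the active bearing is the centre of
        # the preceding small-turn block
        for small, rev in zip(smalls, revs):
            vals = bearing[rev["start"]:rev["stop"]]
            assert np.allclose(vals, small["centre"])

    def test_integration_invariant(self):
        reintegrate(warmup_protocol(120.0, stage=2, seed=8))


class TestAblationProtocol:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ablation_protocol("d", 120.0)

    def test_variant_a_rests_during_revolution_blocks(self):
        traj, _ = ablation_protocol("a", 240.0, seed=1)
        for blk in traj.extras["blocks"]:
            if blk["kind"] == "revolution":
                assert np.all(traj.omega[blk["start"]:blk["stop"]] == 0.0)

    def test_variant_b_rests_during_small_blocks(self):
        traj, _ = ablation_protocol("b", 240.0, seed=1)
        for blk in traj.extras["blocks"]:
            if blk["kind"] == "small":
                assert np.all(traj.omega[blk["start"]:blk["stop"]] == 0.0)

    def test_variant_c_decorrelates_sensation_from_motion(self):
        traj, sensors = ablation_protocol("c", 600.0, seed=2,
                                          bias_fraction=0.0, noise_sd=0.0)
        moving = (traj.omega != 0) | (sensors.sensed_omega != 0)
        r = np.corrcoef(traj.omega[moving], sensors.sensed_omega[moving])[0, 1]
        assert abs(r) < 0.1


class TestVestibularSensor:
    def test_identity_with_no_bias_no_noise(self):
        traj = spot_turn_protocol(30.0, seed=0)
        s = vestibular_sensor(traj, bias_fraction=0.0, noise_sd=0.0)
        assert np.array_equal(s.sensed_omega, traj.omega)

    def test_eight_percent_underreport_of_total_angle(self):
        traj = spot_turn_protocol(600.0, seed=1)
        s = vestibular_sensor(traj, bias_fraction=0.08, noise_sd=0.0)
        ratio = np.abs(s.sensed_omega).sum() / np.abs(traj.omega).sum()
        assert 0.915 <= ratio <= 0.925

    def test_noise_statistics(self):
        traj = HeadTrajectory(DT, np.zeros(200_000))
        s = vestibular_sensor(traj, bias_fraction=0.0, noise_sd=5.0, seed=3)
        assert abs(s.sensed_omega.mean()) < 0.1
        assert s.sensed_omega.std() == pytest.approx(5.0, rel=0.1)

    def test_bias_range_validated(self):
        traj = spot_turn_protocol(10.0, seed=0)
        with pytest.raises(ValueError):
            vestibular_sensor(traj, bias_fraction=0.6)


class TestLandmarkDetector:
    def lm(self):
        return LandmarkModel(bearing=180.0, associated_cell_index=100)

    def test_no_misses_catches_every_crossing(self):
        traj = spot_turn_protocol(300.0, seed=4)
        s = landmark_detector(traj, self.lm(), miss_probability=0.0)
        in_window = np.abs(circ_diff_deg(traj.heading, 180.0)) < 3.0
        assert np.array_equal(s.landmark_active, in_window)

    def test_thirty_percent_miss_rate(self):
        detected = total = 0
        for seed in range(12):
            traj = spot_turn_protocol(3000.0, seed=seed, dt=0.01)
            s = landmark_detector(traj, self.lm(), miss_probability=0.3,
                                  seed=seed)
            total += len(s.events)
            detected += sum(1 for *_, d in s.events if d)
        assert total > 900
        assert detected / total == pytest.approx(0.7, abs=0.03)

    def test_darkness_emits_nothing(self):
        traj = spot_turn_protocol(120.0, seed=5)
        s = landmark_detector(traj, self.lm(), miss_probability=0.0,
                              darkness=True)
        assert s.darkness and not s.landmark_active.any()
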