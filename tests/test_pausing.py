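import numpy as np
import pandas as pd
import pytest

from kintraffic.params import DetectionConfig, ModelParams, PausingParams
from kintraffic.pausing import (add_localization_noise, detect_periods,
                                exponential_tail_correct,
                                jam_membership_periods, jam_size,
                                jam_state_frequency, period_probability)
from kintraffic.simulate import SimulationConfig, run_gillespie


def make_traj(positions, motor_id=0, dt=0.1):
    return pd.DataFrame({
        "motor_id": motor_id,
        "time_s": np.arange(len(positions)) * dt,
        "position_sites": np.asarray(positions, dtype=float),
    })


class TestLocalizationNoise:
    def test_zero_sigma_identity(self):
        traj = make_traj(np.arange(50))
        out = add_localization_noise(traj, 0.0)
        pd.testing.assert_frame_equal(out, traj)

    def test_noise_scale(self):
        # sigma = 20 nm over a = 8.4 nm sites -> s.d. ~ 2.38 sites
        traj = make_traj(np.zeros(100_000))
        out = add_localization_noise(traj, 20.0, seed=5)
        sd = out["position_sites"].std()
        assert sd == pytest.approx(20.0 / 8.4, rel=0.02)

    def test_determinism(self):
        traj = make_traj(np.arange(100))
        a = add_localization_noise(traj, 20.0, seed=7)
        b = add_localization_noise(traj, 20.0, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sigma(self):
        with pytest.raises(ValueError):
            add_localization_noise(make_traj([0, 1]), -1.0)


class TestDetectPeriods:
    def test_hand_traced_protocol(self):
        # displacements 8,8,1,0,1,8,8 with d_c = 5: onset after the three
        # small displacements starting at frame 2, terminated by the pair
        # of large displacements starting at frame 5
        cfg = DetectionConfig(d_c=5.0)
        per = detect_periods(make_traj([0, 8, 16, 17, 17, 18, 26, 34]), cfg)
        assert len(per) == 1
        row = per.iloc[0]
        assert row["start_time"] == pytest.approx(0.2)
        assert row["end_time"] == pytest.approx(0.5)
        assert row["duration"] == pytest.approx(0.3)
        assert row["progression"] == pytest.approx(2.0)
        # between the detection boundaries the motor also covers the two
        # terminating displacements
        assert row["progression_inclusive"] == pytest.approx(18.0)
        assert not row["truncated"]

    def test_immobile_motor_truncated(self):
        cfg = DetectionConfig(d_c=2.0)
        per = detect_periods(make_traj(np.full(21, 7.0)), cfg)
        assert len(per) == 1
        row = per.iloc[0]
        assert row["truncated"]
        assert row["duration"] == pytest.approx(2.0)
        assert row["progression"] == 0.0

    def test_fast_walker_no_periods(self):
        cfg = DetectionConfig(d_c=2.0)
        per = detect_periods(make_traj(np.arange(40) * 7.9), cfg)
        assert len(per) == 0

    def test_equality_is_not_small(self):
        # advancing exactly d_c never starts a period
        cfg = DetectionConfig(d_c=2.0)
        per = detect_periods(make_traj(np.arange(40) * 2.0), cfg)
        assert len(per) == 0

    def test_single_large_tolerated(self):
        cfg = DetectionConfig(d_c=5.0)
        # 4 small, 1 large, 3 small, then the terminating pair
        x = np.cumsum([0, 1, 1, 1, 1, 9, 1, 1, 1, 9, 9, 9])
        per = detect_periods(make_traj(x), cfg)
        assert len(per) == 1
        # ends at the frame preceding the first of the terminating pair
        assert per.iloc[0]["end_time"] == pytest.approx(0.8)

    def test_short_trajectories_skipped(self):
        cfg = DetectionConfig(d_c=2.0)
        traj = pd.concat([make_traj([0, 0, 0], motor_id=1),
                          make_traj(np.zeros(10), motor_id=2)])
        per = detect_periods(traj, cfg)
        assert set(per["motor_id"]) == {2}

    def test_nonuniform_frames_rejected(self):
        cfg = DetectionConfig(d_c=2.0)
        traj = make_traj(np.zeros(10))
        traj.loc[5, "time_s"] += 0.03
        with pytest.raises(ValueError, match="uniform"):
            detect_periods(traj, cfg)


class TestExponentialTailCorrect:
    def test_closed_form_correction(self):
        # 50 detected periods, fitted mean 0.2 s, cutoff 0.3 s:
        # corrected count = 50 / exp(-1.5)
        cfg = DetectionConfig(d_c=2.0)
        # continuous (non-frame-quantized) excesses with mean exactly 0.2
        durations = 0.5 + np.linspace(0.05, 0.35, 50)
        stats = exponential_tail_correct(durations, cfg, total_steps=10_000)
        assert stats.tau_hat == pytest.approx(0.2, rel=1e-12)
        assert stats.corrected_count == pytest.approx(50 * np.exp(1.5),
                                                      rel=1e-9)
        assert stats.corrected_count == pytest.approx(224.1, abs=0.1)
        assert stats.per_step_probability == pytest.approx(
            stats.corrected_count / 10_000)

    def test_continuous_round_trip(self):
        # censored exponential: generator and estimator agree
        tau = 0.12
        d = np.random.default_rng(1).exponential(tau, 1_000_000)
        d = d[d >= 0.3]
        cfg = DetectionConfig(d_c=2.0)
        stats = exponential_tail_correct(d, cfg, total_steps=1)
        assert stats.tau_hat == pytest.approx(tau, rel=0.03)

    def test_frame_quantized_round_trip(self, rng):
        # durations snapped to 0.1 s frames: the geometric MLE undoes the
        # discretisation bias of the naive mean excess
        tau = 0.12
        d = np.ceil(rng.exponential(tau, 200_000) / 0.1) * 0.1
        d = d[d >= 0.3]
        cfg = DetectionConfig(d_c=2.0)
        stats = exponential_tail_correct(d, cfg, total_steps=1)
        assert stats.tau_hat == pytest.approx(tau, rel=0.05)

    def test_empty_tail_rejected(self):
        cfg = DetectionConfig(d_c=2.0)
        with pytest.raises(ValueError, match="tail"):
            exponential_tail_correct(np.full(100, 0.4), cfg, total_steps=1)


class TestJamMembership:
    @staticmethod
    def frame_table(site_active_pairs, frame=0, L=100):
        return pd.DataFrame({
            "motor_id": np.arange(len(site_active_pairs)),
            "frame": frame,
            "position_sites": [s for s, _ in site_active_pairs],
            "active": [a for _, a in site_active_pairs],
        })

    def test_no_inactive_motors_no_periods(self):
        frames = self.frame_table([(10, True), (20, True)])
        assert len(jam_membership_periods(frames, 100,
                                          DetectionConfig(d_c=2.0))) == 0

    def test_isolated_inactive_motor(self):
        frames = pd.concat([
            self.frame_table([(10, False), (40, True)], frame=k)
            for k in range(5)])
        per = jam_membership_periods(frames, 100, DetectionConfig(d_c=2.0))
        assert len(per) == 1
        assert per.iloc[0]["motor_id"] == 0
        assert per.iloc[0]["duration"] == pytest.approx(0.4)

    def test_adjacent_followers_join_the_jam(self):
        # inactive motor at front site 20 with followers at 18, 16, 14
        # (strict adjacency); the motor at 11 has a one-site gap and the
        # motor at 40 is far away - both stay out
        frames = self.frame_table([(20, False), (18, True), (16, True),
                                   (14, True), (11, True), (40, True)])
        per = jam_membership_periods(frames, 100, DetectionConfig(d_c=2.0))
        assert sorted(per["motor_id"]) == [0, 1, 2, 3]

    def test_chain_wraps_around_ring(self):
        frames = self.frame_table([(1, False), (99, True)], L=100)
        per = jam_membership_periods(frames, 100, DetectionConfig(d_c=2.0))
        assert sorted(per["motor_id"]) == [0, 1]

    def test_missing_activity_column(self):
        frames = self.frame_table([(10, True)]).drop(columns="active")
        with pytest.raises(ValueError, match="active"):
            jam_membership_periods(frames, 100, DetectionConfig(d_c=2.0))


class TestJamSize:
    def test_direct_evaluation(self):
        p = ModelParams()  # nu = 79/s
        # rho = 1/4: V = 52.67 sites/s, gap 2, N = 6.32 / 1.333
        assert jam_size(0.12, p, 0.25, "spaced") == pytest.approx(4.74,
                                                                  abs=0.01)
        assert jam_size(0.12, p, 0.25, "compact") == pytest.approx(2.71,
                                                                   abs=0.01)

    def test_compact_gap_is_larger_so_jam_is_smaller(self, rng):
        p = ModelParams()
        for rho in rng.uniform(0.05, 0.45, 20):
            spaced = jam_size(0.12, p, rho, "spaced")
            compact = jam_size(0.12, p, rho, "compact")
            assert compact < spaced

    def test_vanishing_density(self):
        assert jam_size(0.12, ModelParams(), 1e-6) == pytest.approx(
            0.0, abs=1e-4)

    def test_divergence_toward_full_decoration(self):
        # the gap 1/rho - 2 meets V/nu = (1-2 rho)/(1-rho) only at
        # rho -> 1/2, where N grows like 1/(1-2 rho)
        p = ModelParams()
        assert jam_size(10.0, p, 0.499999) > 1e6
        sizes = [jam_size(0.12, p, r) for r in [0.4, 0.45, 0.49, 0.499]]
        assert np.all(np.diff(sizes) > 0)

    def test_domain(self):
        with pytest.raises(ValueError):
            jam_size(0.12, ModelParams(), 0.6)
        with pytest.raises(ValueError):
            jam_size(0.12, ModelParams(), 0.25, "stacked")


class TestPeriodProbability:
    def test_values(self):
        assert period_probability(0.004, 0.0) == 0.004
        assert period_probability(0.004, 4.74) == pytest.approx(0.023,
                                                                abs=5e-4)
        assert period_probability(0.0, 10.0) == 0.0

    def test_domain(self):
        with pytest.raises(ValueError):
            period_probability(-0.1, 1.0)


class TestLowConcentrationRecovery:
    def test_protocol_recovers_pause_statistics(self):
        """At vanishing crowding the detector reads back the intrinsic
        switching statistics (up to frame-quantisation losses around the
        0.3 s cutoff)."""
        p = ModelParams().at_concentration(0.5)
        pp = PausingParams()  # p_in = 0.004 per step, T = 0.12 s
        out = run_gillespie(p, pp, SimulationConfig(
            L=2000, t_end=250.0, burn_in=5.0, seed=11))
        cfg = DetectionConfig(d_c=2.0)
        per = detect_periods(out.trajectories, cfg)
        ok = per.loc[~per["truncated"], "duration"]
        stats = exponential_tail_correct(
            ok, cfg, out.summary["total_steps_measured"])
        assert stats.tau_hat == pytest.approx(pp.T_pause, rel=0.4)
        p_in = pp.p_inactivation(p.nu)
        assert p_in / 2.5 < stats.per_step_probability < p_in * 2.5
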