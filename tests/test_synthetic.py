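"""The generator must reproduce the study design and its own generative model."""

import numpy as np
import pandas as pd
import pytest

import wearload as wl
from wearload.errors import UsageError
from wearload.synthetic import grf_waveform


class TestRoster:
    def test_full_factorial_counts(self):
        assert len(wl.make_roster(12)) == 216
        assert len(wl.make_roster(1)) == 18

    def test_override_restricts_one_participant(self):
        ov = {12: [c for c in wl.study_conditions() if c.speed_kmh in (5.0, 8.0)]}
        roster = wl.make_roster(12, overrides=ov)
        assert len(roster) == 210  # 11*18 + 12
        by_pid = pd.DataFrame(
            [(pid, c.speed_kmh) for pid, c in roster], columns=["pid", "speed"]
        )
        assert set(by_pid[by_pid.pid == 12].speed) == {5.0, 8.0}

    def test_deterministic_ordering(self):
        roster = wl.make_roster(3)
        keys = [(pid, c.bodyweight_pct, c.speed_kmh) for pid, c in roster]
        assert keys == sorted(keys)

    def test_unknown_override_participant_rejected(self):
        with pytest.raises(UsageError, match="unknown participant"):
            wl.make_roster(2, overrides={99: wl.study_conditions()})


class TestSummaryDataset:
    def test_degenerate_noise_gives_exact_line(self, noiseless_table):
        cfg = wl.SimulationConfig(sd_intercept=0.0, sd_slope=0.0, sd_residual=0.0, seed=5)
        resid = noiseless_table.y - (
            cfg.fixed_intercept_alpha + cfg.fixed_slope_beta * noiseless_table.x
        )
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_seed_determinism(self):
        cfg = wl.SimulationConfig(seed=42)
        a = wl.simulate_summary_dataset(cfg)
        b = wl.simulate_summary_dataset(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = wl.simulate_summary_dataset(wl.SimulationConfig(seed=1))
        b = wl.simulate_summary_dataset(wl.SimulationConfig(seed=2))
        assert not np.allclose(a.x, b.x)

    def test_random_intercept_variance_recovered(self):
        # with only intercept noise, per-participant mean residuals are the a_i
        cfg = wl.SimulationConfig(
            n_participants=200,
            fixed_intercept_alpha=5000.0,
            fixed_slope_beta=0.8,
            sd_intercept=500.0,
            sd_slope=0.0,
            sd_residual=0.0,
            seed=9,
        )
        tab = wl.simulate_summary_dataset(cfg)
        resid = tab.y - (5000.0 + 0.8 * tab.x)
        per_pid = resid.groupby(tab.participant_id).mean()
        assert np.var(per_pid) == pytest.approx(500.0**2, rel=0.15)

    def test_effects_shared_within_participant(self):
        cfg = wl.SimulationConfig(n_participants=5, sd_residual=0.0, sd_slope=0.0, seed=3)
        tab = wl.simulate_summary_dataset(cfg)
        # residual intercept is constant within a participant when only a_i varies
        resid = tab.y - (cfg.fixed_intercept_alpha + cfg.fixed_slope_beta * tab.x)
        spread = resid.groupby(tab.participant_id).apply(lambda s: s.max() - s.min())
        assert np.allclose(spread, 0.0, atol=1e-9)

    def test_x_location_monotone_in_design(self):
        # mean load rate must not decrease with speed or bodyweight (20 seeds)
        frames = [
            wl.simulate_summary_dataset(wl.SimulationConfig(seed=s)) for s in range(20)
        ]
        tab = pd.concat(frames)
        by_speed = tab.groupby("speed_kmh").x.mean()
        assert by_speed.is_monotonic_increasing
        by_pct = tab.groupby("bodyweight_pct").x.mean()
        assert by_pct.is_monotonic_increasing


class TestTrialSimulation:
    def test_force_conserves_supported_weight(self, small_config):
        # time-average over an integer number of step cycles ~ (pct/100)*m*g
        profile = wl.ParticipantProfile(1, mass=71.0)
        for pct in (30.0, 80.0, 110.0):
            for speed in wl.SPEEDS_KMH:
                cond = wl.TrialCondition(pct, speed)
                bundle = wl.simulate_trial(profile, cond, small_config)
                fs = bundle.forceplate_series
                f_step = profile.step_freq_base + 0.12 * speed
                n_cycles = int(np.floor(60.0 * f_step))
                mask = fs.timestamps < n_cycles / f_step
                mean_force = fs.values[mask].mean()
                assert mean_force == pytest.approx(pct / 100.0 * 71.0 * 9.81, rel=0.05)

    def test_zero_bodyweight_gives_zero_load(self, small_config):
        cfg = wl.SimulationConfig(n_participants=1, accel_noise_sd=0.0,
                                  attenuation_jitter=0.0, seed=2)
        profile = wl.ParticipantProfile(1, mass=70.0)
        bundle = wl.simulate_trial(profile, wl.TrialCondition(0.0, 8.0), cfg)
        assert np.allclose(bundle.forceplate_series.values, 0.0, atol=1e-9)
        lr = wl.mean_load_rate_from_accel(bundle.wearable_series["wearable"], 70.0)
        assert lr.value == pytest.approx(0.0, abs=1e-9)

    def test_walking_dual_peak_running_single_peak(self):
        profile = wl.ParticipantProfile(1, mass=70.0, step_freq_base=1.4)
        phase = np.linspace(0.0, 1.0, 2000, endpoint=False)

        def peaks_per_cycle(speed):
            f_step = 1.4 + 0.12 * speed
            f = grf_waveform(phase / f_step, wl.TrialCondition(100.0, speed), profile)
            # circular comparison: the cycle is periodic, peaks may sit at phase 0
            is_peak = (f > np.roll(f, 1)) & (f >= np.roll(f, -1)) & (f > 0)
            return int(is_peak.sum())

        assert peaks_per_cycle(5.0) == 2
        assert peaks_per_cycle(8.0) == 1
        assert peaks_per_cycle(12.0) == 1

    def test_load_rate_monotone_in_speed_and_weight(self):
        profile = wl.ParticipantProfile(1, mass=70.0)
        cfg = wl.SimulationConfig(accel_noise_sd=0.0, attenuation_jitter=0.0, seed=1)

        def force_lr(pct, speed):
            b = wl.simulate_trial(profile, wl.TrialCondition(pct, speed), cfg)
            return wl.mean_load_rate_from_force(b.forceplate_series).value

        speeds = [force_lr(100.0, s) for s in wl.SPEEDS_KMH]
        assert speeds == sorted(speeds)
        pcts = [force_lr(p, 8.0) for p in wl.BODYWEIGHT_PCTS]
        assert pcts == sorted(pcts)

    def test_trial_determinism_and_bundle_shape(self, small_config):
        profile = wl.ParticipantProfile(3, mass=65.0)
        cond = wl.TrialCondition(90.0, 8.0)
        devices = [wl.DeviceSpec("SP1"), wl.DeviceSpec("SW1", attenuation_scale=0.8)]
        a = wl.simulate_trial(profile, cond, small_config, devices=devices)
        b = wl.simulate_trial(profile, cond, small_config, devices=devices)
        assert set(a.wearable_series) == {"SP1", "SW1"}
        assert np.array_equal(a.wearable_series["SP1"].az, b.wearable_series["SP1"].az)
        assert np.array_equal(a.forceplate_series.values, b.forceplate_series.values)
        assert len(a.forceplate_series) == int(90 * 128)
        assert len(a.wearable_series["SP1"]) == int(90 * 50)

    def test_cohort_wearable_force_correlation(self):
        # end-to-end consistency: wearable and force-plate load rates correlate
        cfg = wl.SimulationConfig(seed=4)
        report = wl.run_pipeline(
            wl.RunConfig(sim=cfg, B=2, seed=4, replica_completion=False,
                         replica_exclusions=False),
            write=False,
        )
        for _, sub in report.observations.groupby("device"):
            assert np.corrcoef(sub.x, sub.y)[0, 1] > 0.5


class TestValidationOfInputs:
    def test_invalid_condition_rejected(self):
        with pytest.raises(UsageError):
            wl.TrialCondition(150.0, 8.0)
        with pytest.raises(UsageError):
            wl.TrialCondition(100.0, -1.0)

    def test_invalid_profile_rejected(self):
        with pytest.raises(UsageError):
            wl.ParticipantProfile(1, mass=-3.0)
        with pytest.raises(UsageError):
            wl.ParticipantProfile(1, mass=70.0, attenuation=1.5)

    def test_invalid_config_rejected(self):
        with pytest.raises(UsageError):
            wl.SimulationConfig(sd_residual=-1.0).validate()
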