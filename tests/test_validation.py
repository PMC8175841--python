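"""Exclusions, model fitting, agreement metrics and bootstrap cross-validation."""

import numpy as np
import pandas as pd
import pytest

import wearload as wl
from wearload.errors import InsufficientDataError, UsageError


def _replica_completion():
    return {12: [c for c in wl.study_conditions() if c.speed_kmh in (5.0, 8.0)]}


def _replica_exclusions():
    return [
        wl.ExclusionRule(participant_id=1),
        wl.ExclusionRule(participant_id=2, speed_kmh=5.0),
    ]


class TestExclusions:
    def test_study_replica_yields_186_trials(self):
        planned = wl.make_roster(12)
        analysed, log = wl.apply_exclusions(planned, _replica_completion(),
                                            _replica_exclusions())
        assert len(analysed) == 186
        assert sum("excluded" in line for line in log) == 24  # 18 + 6
        assert not any(pid == 1 for pid, _ in analysed)

    def test_empty_rules_identity(self):
        planned = wl.make_roster(4)
        analysed, log = wl.apply_exclusions(planned)
        assert analysed == planned
        assert log == []

    def test_excluding_everyone_leaves_nothing(self):
        planned = wl.make_roster(3)
        rules = [wl.ExclusionRule(participant_id=p) for p in (1, 2, 3)]
        analysed, log = wl.apply_exclusions(planned, exclusions=rules)
        assert analysed == []
        assert sum("excluded" in line for line in log) == 54

    def test_rule_matching_nothing_logs_warning(self):
        planned = wl.make_roster(2)
        analysed, log = wl.apply_exclusions(
            planned, exclusions=[wl.ExclusionRule(participant_id=2, speed_kmh=99.0)]
        )
        assert len(analysed) == 36
        assert any("warning" in line for line in log)


class TestFitModel:
    def test_noiseless_line_recovered_by_every_spec(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(5), 10),
                "x": rng.uniform(1000, 20000, 50),
            }
        )
        tab["y"] = 2.0 + 3.0 * tab.x
        for spec in wl.MODEL_SPECS:
            m = wl.fit_model(tab, spec)
            assert m.alpha == pytest.approx(2.0, abs=1e-5)
            assert m.beta == pytest.approx(3.0, rel=1e-9)
            assert all(v == pytest.approx(0.0, abs=1e-6) for v in m.var_components.values())

    def test_m1_matches_normal_equations(self, rng):
        for _ in range(5):
            n = 40
            tab = pd.DataFrame(
                {
                    "participant_id": rng.integers(0, 5, n),
                    "x": rng.uniform(1, 100, n),
                }
            )
            tab["y"] = rng.normal(0, 10, n) + 3 * tab.x
            m = wl.fit_model(tab, "M1")
            A = np.column_stack([np.ones(n), tab.x])
            alpha, beta = np.linalg.solve(A.T @ A, A.T @ tab.y)
            assert m.alpha == pytest.approx(alpha, rel=1e-8, abs=1e-8)
            assert m.beta == pytest.approx(beta, rel=1e-8)

    def test_m3_parameter_recovery_large_cohort(self):
        cfg = wl.SimulationConfig(
            n_participants=100,
            fixed_intercept_alpha=5000.0,
            fixed_slope_beta=0.8,
            sd_intercept=800.0,
            sd_slope=0.1,
            sd_residual=400.0,
            seed=17,
        )
        m = wl.fit_model(wl.simulate_summary_dataset(cfg), "M3")
        assert abs(m.alpha - 5000.0) < 3 * m.alpha_se
        assert abs(m.beta - 0.8) < 3 * m.beta_se
        # variance components land in the right decade
        assert m.var_components["var_intercept"] == pytest.approx(800.0**2, rel=0.6)
        assert m.var_components["var_slope"] == pytest.approx(0.1**2, rel=0.6)

    def test_random_effects_structure(self, summary_table):
        m1 = wl.fit_model(summary_table, "M1")
        assert m1.random_effects == {}
        m2 = wl.fit_model(summary_table, "M2")
        assert all(b == 0.0 for _, b in m2.random_effects.values())
        m3 = wl.fit_model(summary_table, "M3")
        a_vals = [a for a, _ in m3.random_effects.values()]
        # predicted (shrunken) effects centre near zero
        assert abs(np.mean(a_vals)) < 2 * np.std(a_vals)

    def test_mixed_spec_needs_two_participants(self):
        tab = pd.DataFrame({"participant_id": [1] * 10, "x": np.arange(10.0),
                            "y": np.arange(10.0) * 2})
        with pytest.raises(InsufficientDataError):
            wl.fit_model(tab, "M3")

    def test_in_sample_r2_nesting(self):
        # richer nested specifications cannot fit worse (20 seeds)
        for seed in range(20):
            tab = wl.simulate_summary_dataset(wl.SimulationConfig(seed=seed))
            r2 = {}
            for spec in wl.MODEL_SPECS:
                m = wl.fit_model(tab, spec)
                pred, _ = wl.predict(m, tab)
                r2[spec], _ = wl.agreement_metrics(tab.y, pred)
            assert r2["M3"] >= r2["M2"] - 1e-6
            assert r2["M2"] >= r2["M1"] - 1e-6


class TestAgreementMetrics:
    def test_perfect_agreement(self):
        r2, rmser = wl.agreement_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r2 == pytest.approx(1.0)
        assert rmser == 0.0

    def test_hand_worked_example(self):
        r2, rmser = wl.agreement_metrics([100.0, 200.0, 300.0], [110.0, 190.0, 310.0])
        assert rmser == pytest.approx(0.05)
        assert r2 == pytest.approx(0.987, abs=5e-4)

    def test_constant_prediction_r2_missing(self):
        r2, rmser = wl.agreement_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert r2 is None
        assert rmser == pytest.approx(np.sqrt(2.0 / 3.0) / 2.0)

    def test_scale_invariance(self, rng):
        obs = rng.uniform(100, 200, 50)
        pred = obs + rng.normal(0, 5, 50)
        base = wl.agreement_metrics(obs, pred)
        scaled = wl.agreement_metrics(7.3 * obs, 7.3 * pred)
        assert scaled[0] == pytest.approx(base[0], rel=1e-12)
        assert scaled[1] == pytest.approx(base[1], rel=1e-12)


class TestBootstrap:
    def test_noiseless_table_degenerate(self, noiseless_table):
        res = wl.bootstrap_validate(noiseless_table, "M3", B=20, seed=1)
        np.testing.assert_allclose(res.r2_samples, 1.0, atol=1e-9)
        np.testing.assert_allclose(res.rmser_samples, 0.0, atol=1e-9)
        assert res.r2_ci == pytest.approx((1.0, 1.0))

    def test_seed_reproducibility(self, summary_table):
        a = wl.bootstrap_validate(summary_table, "M2", B=15, seed=3)
        b = wl.bootstrap_validate(summary_table, "M2", B=15, seed=3)
        np.testing.assert_array_equal(a.r2_samples, b.r2_samples)
        np.testing.assert_array_equal(a.rmser_samples, b.rmser_samples)

    def test_mean_r2_monotone_in_residual_noise(self):
        # less residual noise -> better out-of-bag agreement (20-seed average)
        means = []
        for sd in (4000.0, 2000.0, 500.0):
            vals = []
            for seed in range(20):
                cfg = wl.SimulationConfig(sd_residual=sd, seed=seed)
                tab = wl.simulate_summary_dataset(cfg)
                vals.append(wl.bootstrap_validate(tab, "M1", B=8, seed=seed).r2_mean)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_ci_width_shrinks_with_table_size(self):
        widths = []
        for n_pid in (6, 12, 24):
            ws = []
            for seed in range(10):
                cfg = wl.SimulationConfig(n_participants=n_pid, seed=seed)
                tab = wl.simulate_summary_dataset(cfg)
                res = wl.bootstrap_validate(tab, "M1", B=25, seed=seed)
                ws.append(res.r2_ci[1] - res.r2_ci[0])
            widths.append(np.mean(ws))
        assert widths[0] > widths[1] > widths[2]

    def test_stratified_by_speed(self, summary_table):
        res = wl.bootstrap_validate(summary_table, "M1", B=10, seed=2,
                                    stratify_by="speed")
        assert set(res) == {"speed=5", "speed=8", "speed=12"}
        for r in res.values():
            assert r.B == 10
            assert r.rmser_ci[0] <= r.rmser_mean <= r.rmser_ci[1] or np.isnan(r.rmser_mean)

    def test_cluster_bootstrap_mode(self, summary_table):
        res = wl.bootstrap_validate(summary_table, "M2", B=10, seed=2, cluster=True)
        assert res.B == 10
        assert np.isfinite(res.r2_mean)

    def test_ci_bounds_ordered_and_contain_mean(self, summary_table):
        res = wl.bootstrap_validate(summary_table, "M3", B=25, seed=6)
        assert res.r2_ci[0] <= res.r2_ci[1]
        assert res.r2_samples.min() <= res.r2_mean <= res.r2_samples.max()
        assert res.rmser_ci[0] <= res.rmser_mean <= res.rmser_ci[1]

    def test_invalid_inputs(self, summary_table):
        with pytest.raises(UsageError):
            wl.bootstrap_validate(summary_table, "M1", B=0, seed=1)
        with pytest.raises(UsageError):
            wl.bootstrap_validate(summary_table, "M1", B=5, seed=1, stratify_by="color")
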