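"""Simulated ERP experiments: generator, tests, prevalence time courses."""

import dataclasses
import logging

import numpy as np
import pytest

from prevalence.simulate import (ScenarioConfig, SimulatedDataset,
                                 WithinParticipantResult,
                                 population_mean_test, prevalence_timecourse,
                                 scenario_presets, simulate_scenario,
                                 within_participant_test)


def small_config(**overrides):
    base = dict(n_participants=6, n_trials=50, n_timepoints=20, noise_sd=1.0,
                amplitude_mean=1.0, amplitude_sd=0.0, latency_mean=10.0,
                latency_sd=0.0, effect_width=2.0, effect_fraction=1.0, seed=0)
    base.update(overrides)
    return ScenarioConfig(**base)


class TestGenerator:
    def test_reproducible_bit_identical(self):
        cfg = small_config(seed=42)
        a, b = simulate_scenario(cfg), simulate_scenario(cfg)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.latencies, b.latencies)
        r1 = within_participant_test(a)
        r2 = within_participant_test(b)
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_effect_fraction_zero_is_pure_noise(self):
        cfg = small_config(effect_fraction=0.0, n_trials=400, seed=1)
        ds = simulate_scenario(cfg)
        assert not ds.has_effect.any()
        # per-timepoint trial means should hover near 0
        se = cfg.noise_sd / np.sqrt(cfg.n_trials * cfg.n_participants)
        assert np.all(np.abs(ds.data.mean(axis=(0, 1))) < 5 * se)

    def test_effect_count_matches_fraction(self):
        ds = simulate_scenario(small_config(effect_fraction=0.5))
        assert ds.has_effect.sum() == 3

    def test_homogeneous_config_gives_identical_effect_parameters(self):
        ds = simulate_scenario(small_config(amplitude_sd=0.0, latency_sd=0.0))
        assert np.allclose(ds.amplitudes, ds.amplitudes[0])
        assert np.all(ds.latencies == ds.latencies[0])

    def test_trial_mean_peak_recovers_amplitude(self):
        cfg = small_config(n_trials=200, amplitude_mean=2.0, seed=3)
        ds = simulate_scenario(cfg)
        tol = 3.0 * cfg.noise_sd / np.sqrt(cfg.n_trials)
        for i in range(ds.n_participants):
            peak = ds.data[i].mean(axis=0)[ds.latencies[i]]
            assert abs(peak - ds.amplitudes[i]) < tol

    def test_latency_clipping_warns(self, caplog):
        cfg = small_config(latency_mean=19.0, latency_sd=10.0, seed=5)
        with caplog.at_level(logging.WARNING, logger="prevalence.simulate"):
            ds = simulate_scenario(cfg)
        assert np.all(ds.latencies[ds.has_effect] <= 19)
        assert any("clipped" in r.message for r in caplog.records)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(noise_sd=0.0)
        with pytest.raises(ValueError):
            small_config(effect_fraction=1.5)
        with pytest.raises(ValueError):
            small_config(latency_mean=25.0)


class TestWithinParticipant:
    def test_overwhelming_effect_always_significant(self):
        cfg = small_config(amplitude_mean=20.0, n_trials=100, seed=7)
        res = within_participant_test(simulate_scenario(cfg), 0.05)
        assert res.overall_significant.all()
        assert res.k_overall == cfg.n_participants

    def test_mask_consistent_with_threshold_and_flag(self):
        res = within_participant_test(simulate_scenario(small_config(seed=9)), 0.05)
        thr = 0.05 / res.n_timepoints
        assert np.array_equal(res.significant_mask, res.p_values < thr)
        assert np.array_equal(res.overall_significant, res.significant_mask.any(axis=1))

    def test_zero_variance_timepoint_gets_p_one(self, caplog):
        cfg = small_config(n_participants=2, n_trials=10)
        ds = simulate_scenario(cfg)
        data = ds.data.copy()
        data[0, :, 0] = 3.0  # constant trials at one timepoint
        frozen = SimulatedDataset(data, ds.has_effect, ds.amplitudes, ds.latencies, cfg)
        with caplog.at_level(logging.WARNING, logger="prevalence.simulate"):
            res = within_participant_test(frozen)
        assert res.p_values[0, 0] == 1.0

    def test_familywise_error_rate_controlled(self):
        # pure-noise participants; Bonferroni FWER must stay at or below
        # family alpha (within a 99% binomial bound)
        reps, trials, times, fam = 2000, 100, 60, 0.05
        rng = np.random.default_rng(101)
        hits = 0
        for _ in range(4):
            cfg = ScenarioConfig(n_participants=reps // 4, n_trials=trials,
                                 n_timepoints=times, effect_fraction=0.0,
                                 seed=int(rng.integers(2**31)))
            res = within_participant_test(simulate_scenario(cfg), fam)
            hits += int(res.overall_significant.sum())
        bound = fam + 2.58 * np.sqrt(fam * (1 - fam) / reps)
        assert hits / reps <= bound

    def test_more_timepoints_do_not_inflate_fwer(self):
        reps, fam = 2000, 0.05
        rng = np.random.default_rng(202)
        hits = 0
        for _ in range(4):
            cfg = ScenarioConfig(n_participants=reps // 4, n_trials=50,
                                 n_timepoints=120, effect_fraction=0.0,
                                 seed=int(rng.integers(2**31)))
            res = within_participant_test(simulate_scenario(cfg), fam)
            hits += int(res.overall_significant.sum())
        bound = fam + 2.58 * np.sqrt(fam * (1 - fam) / reps)
        assert hits / reps <= bound


class TestPopulationMean:
    def test_all_noise_rarely_significant(self):
        # familywise check across 200 independent experiments
        sig = 0
        for seed in range(200):
            cfg = small_config(effect_fraction=0.0, n_participants=8, seed=seed)
            sig += population_mean_test(simulate_scenario(cfg)).any_significant
        assert sig / 200 <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / 200)

    def test_consistent_same_sign_effect_detected(self):
        cfg = small_config(amplitude_mean=3.0, n_participants=10, seed=11)
        ds = simulate_scenario(cfg)
        res = population_mean_test(ds)
        assert res.significant_mask[ds.latencies[0]]


class TestTimecourse:
    def test_no_significant_timepoints_give_zero_floor(self):
        res = WithinParticipantResult(
            t_values=np.zeros((8, 12)), p_values=np.ones((8, 12)),
            significant_mask=np.zeros((8, 12), dtype=bool),
            overall_significant=np.zeros(8, dtype=bool), family_alpha=0.05,
        )
        tc = prevalence_timecourse(res, 0.96)
        assert np.all(tc.k == 0)
        assert np.all(tc.map == 0.0)
        assert np.all(tc.hpdi_lower == 0.0)

    def test_uses_per_timepoint_alpha_and_map_inside_hpdi(self):
        cfg = small_config(amplitude_mean=2.0, effect_fraction=0.5, seed=13)
        res = within_participant_test(simulate_scenario(cfg), 0.05)
        tc = prevalence_timecourse(res, 0.96)
        assert tc.alpha == pytest.approx(0.05 / cfg.n_timepoints)
        assert np.all(tc.k <= cfg.n_participants)
        assert np.all((tc.hpdi_lower <= tc.map) & (tc.map <= tc.hpdi_upper))

    def test_prevalence_recovery_high_snr(self):
        # strong, aligned effects in 30% of 100 participants: overall MAP
        # approaches the generating fraction
        cfg = ScenarioConfig(n_participants=100, n_trials=100, n_timepoints=60,
                             amplitude_mean=2.0, amplitude_sd=0.0,
                             latency_mean=30.0, latency_sd=0.0,
                             effect_fraction=0.3, seed=17)
        res = within_participant_test(simulate_scenario(cfg), 0.05)
        outcomes = res.overall_outcomes()
        map_ = (outcomes.k / outcomes.n - 0.05) / 0.95
        assert abs(map_ - 0.3) < 0.1


class TestPresets:
    def test_preset_fields_match_scenario_descriptions(self):
        presets = scenario_presets()
        assert set(presets) == set("ABCD")
        assert presets["C"].n_participants == 5
        assert presets["D"].effect_fraction == 0.5
        assert presets["D"].n_participants == 20
        assert presets["B"].latency_sd > 0 and presets["B"].amplitude_sd == 0.0
        assert presets["A"].amplitude_mean == 0.0 and presets["A"].amplitude_sd > 0

    def test_with_seed_only_changes_seed(self):
        cfg = scenario_presets()["A"].with_seed(99)
        assert cfg.seed == 99
        assert dataclasses.replace(cfg, seed=0) == scenario_presets()["A"]
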