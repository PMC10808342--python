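"""Synthetic-data generator: design, recall mixture, pupil traces, RT/staircase."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError
from scipy import integrate

from pupilmem import (
    SimConfig,
    generate_design,
    mixture_pdf,
    run_titration,
    simulate_dataset,
    simulate_pupil,
    simulate_recall,
    simulate_rt_and_titration,
    traces_from_long,
    traces_to_long,
    markers_to_table,
)


def rng_for(*key):
    return np.random.default_rng(list(key))


class TestDesign:
    def test_default_is_84_trials_per_participant(self):
        design = generate_design(SimConfig(n_participants=2))
        assert (design.groupby("participant").size() == 84).all()
        assert set(design["block"]) == set(range(1, 7))

    def test_counts_and_balance(self):
        design = generate_design(SimConfig(n_participants=3))
        assert len(design) == 252
        counts = design.groupby(["participant", "condition"]).size()
        assert (counts == 42).all()
        # conditions balanced within every block
        per_block = design.groupby(["participant", "block", "condition"]).size()
        assert (per_block == 7).all()

    def test_angle_constraints(self):
        design = generate_design(SimConfig(n_participants=2))
        t = design["target_angle_deg"].to_numpy()
        p = design["paired_angle_deg"].to_numpy()
        assert np.all((t > 0) & (t <= 360)) and np.all(t % 4 == 0)
        assert np.all((t - p) % 360 == 180)
        # each 4-degree angle used at most once per participant
        assert not design.duplicated(["participant", "target_angle_deg"]).any()

    def test_durations_within_bounds(self):
        design = generate_design(SimConfig(n_participants=2))
        assert design["fixation_s"].between(3, 6).all()
        assert design["anticipation_s"].between(2, 4).all()
        assert design["target_number"].isin([1, 4, 6, 9]).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(n_participants=0)
        with pytest.raises(ValidationError):
            SimConfig(trials_per_block=-2)


class TestRecall:
    def test_degenerate_concentration_all_precise(self):
        cfg = SimConfig(n_participants=2, p_t_reward=1.0, p_t_neutral=1.0,
                        kappa_reward=1e4, kappa_neutral=1e4)
        trials = simulate_recall(generate_design(cfg), cfg, rng_for(1))
        assert (trials["error_deg"].abs() < 5).all()

    def test_pure_guessing_is_circular_uniform(self):
        cfg = SimConfig(p_t_reward=0.0, p_t_neutral=0.0)
        design = pd.DataFrame(
            {
                "participant": 1,
                "trial_index": range(10_000),
                "condition": ["reward", "neutral"] * 5000,
                "target_angle_deg": 100.0,
            }
        )
        trials = simulate_recall(design, cfg, rng_for(2))
        rad = np.deg2rad(trials["error_deg"])
        resultant = np.abs(np.mean(np.exp(1j * rad)))
        assert resultant < 0.03  # ~0 for uniform at n = 10^4

    def test_tail_mass_matches_density_integral(self):
        # fraction |error| > 90 deg vs the numerical integral of the mixture
        cfg = SimConfig(p_t_reward=0.58, kappa_reward=13.67)
        n = 100_000
        design = pd.DataFrame(
            {
                "participant": 1,
                "trial_index": range(n),
                "condition": "reward",
                "target_angle_deg": 0.0,
            }
        )
        trials = simulate_recall(design, cfg, rng_for(3))
        frac = (trials["error_deg"].abs() > 90).mean()
        mass = 2 * integrate.quad(
            lambda x: mixture_pdf(x, 1 - 0.58, 13.67), np.pi / 2, np.pi
        )[0]
        assert mass == pytest.approx(0.21, abs=0.001)
        assert frac == pytest.approx(mass, abs=3 * np.sqrt(mass * (1 - mass) / n))

    def test_guess_fraction_converges_to_one_minus_pt(self):
        cfg = SimConfig(p_t_reward=0.7, p_t_neutral=0.7)
        n = 20_000
        design = pd.DataFrame(
            {
                "participant": 1,
                "trial_index": range(n),
                "condition": "reward",
                "target_angle_deg": 0.0,
            }
        )
        trials = simulate_recall(design, cfg, rng_for(4))
        se = np.sqrt(0.7 * 0.3 / n)
        assert trials["retrieved"].mean() == pytest.approx(0.7, abs=3 * se)

    def test_vonmises_component_has_zero_circular_mean(self):
        cfg = SimConfig(p_t_reward=1.0, p_t_neutral=1.0, kappa_reward=8.0)
        n = 10_000
        design = pd.DataFrame(
            {
                "participant": 1,
                "trial_index": range(n),
                "condition": "reward",
                "target_angle_deg": 0.0,
            }
        )
        trials = simulate_recall(design, cfg, rng_for(5))
        mean_angle = np.angle(
            np.mean(np.exp(1j * np.deg2rad(trials["error_deg"])))
        )
        assert abs(mean_angle) < 0.02  # radians

    def test_classification_accuracy(self):
        cfg = SimConfig(n_participants=5, classification_accuracy=0.93)
        trials = simulate_recall(generate_design(cfg), cfg, rng_for(6))
        assert trials["classified_correct"].mean() == pytest.approx(0.93, abs=0.03)


class TestPupilSimulation:
    def test_all_components_off_gives_constant_baseline(self):
        cfg = SimConfig(
            n_participants=1, blink_rate_hz=0.0, pupil_noise_mm=0.0,
            drift_amplitude_mm=0.0, pupil_baseline_sd_mm=0.0,
            anticip_effect_reward_mm=0.0, anticip_effect_neutral_mm=0.0,
            anticip_participant_sd_mm=0.0, anticip_trial_sd_mm=0.0,
            carryover_reward_mm=0.0,
        )
        traces, _ = simulate_pupil(generate_design(cfg), cfg, rng_for(7))
        for _, _, tr in traces:
            assert np.allclose(tr.diameter_mm, cfg.pupil_baseline_mm)
            assert tr.valid.all()

    def test_sample_count_matches_rate_times_duration(self):
        cfg = SimConfig(n_participants=1)
        traces, _ = simulate_pupil(generate_design(cfg), cfg, rng_for(8))
        for _, _, tr in traces:
            duration = tr.markers["anticip_offset"] + 2.6
            assert len(tr.t_s) == round(duration * 40)
            assert tr.fs_hz == pytest.approx(40.0)

    def test_condition_effects_recovered_through_epoching(self):
        from pupilmem import epochs_table

        cfg = SimConfig(
            n_participants=12, n_blocks=6, trials_per_block=14,
            blink_rate_hz=0.0, pupil_noise_mm=0.005,
            anticip_participant_sd_mm=0.0, anticip_trial_sd_mm=0.02,
        )
        ds_design = generate_design(cfg)
        traces, _ = simulate_pupil(ds_design, cfg, rng_for(9))
        epochs = epochs_table(traces, trial_meta=ds_design.assign(condition=ds_design["condition"]))
        merged = ds_design.merge(epochs, on=["participant", "trial_index"])
        means = merged.groupby("condition")["anticip_change_mm"].mean()
        # ~500 trials per condition: recovery within 0.01 mm
        assert means["reward"] == pytest.approx(0.10, abs=0.01)
        assert means["neutral"] == pytest.approx(0.03, abs=0.01)


class TestRTAndTitration:
    @staticmethod
    def _design(n, condition="reward"):
        return pd.DataFrame(
            {
                "participant": 1,
                "trial_index": range(n),
                "condition": condition,
            }
        )

    def test_noise_free_rts_are_deterministic(self):
        cfg = SimConfig(rt_sd_ms=0.0, rt_pupil_slope_ms_per_mm=0.0)
        out = simulate_rt_and_titration(
            self._design(50), np.zeros(50), cfg, rng_for(10)
        )
        assert (out["rt_ms"] == cfg.rt_mean_ms + cfg.rt_reward_offset_ms).all()

    def test_long_run_positive_feedback_rate(self):
        cfg = SimConfig()
        rts = rng_for(11).normal(400, 60, 10_000)
        _, positive = run_titration(rts, cfg)
        assert 0.65 <= positive.mean() <= 0.75

    def test_staircase_converges_within_2000_trials(self):
        cfg = SimConfig(target_reward_rate=0.70)
        rts = rng_for(12).normal(420, 80, 2000)
        _, positive = run_titration(rts, cfg)
        assert positive.mean() == pytest.approx(0.70, abs=0.05)

    def test_slope_recovery_by_least_squares(self):
        # closed-form OLS recovers the generative -30 ms/mm coupling
        cfg = SimConfig(rt_sd_ms=10.0, rt_pupil_slope_ms_per_mm=-30.0)
        n = 10_000
        anticip = rng_for(13).normal(0.07, 0.2, n)
        out = simulate_rt_and_titration(self._design(n), anticip, cfg, rng_for(14))
        x, y = anticip, out["rt_ms"].to_numpy()
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert slope == pytest.approx(-30.0, abs=2.0)

    def test_missing_pupil_change_flagged_and_uncoupled(self):
        cfg = SimConfig(rt_sd_ms=0.0)
        anticip = np.array([0.1, np.nan, 0.2])
        out = simulate_rt_and_titration(self._design(3), anticip, cfg, rng_for(15))
        assert out["rt_pupil_coupled"].tolist() == [True, False, True]
        assert out.loc[1, "rt_ms"] == cfg.rt_mean_ms + cfg.rt_reward_offset_ms

    def test_feedback_contingency(self):
        cfg = SimConfig(n_participants=2)
        ds = simulate_dataset(cfg)
        t = ds.trials
        neutral = t[t["condition"] == "neutral"]
        reward = t[t["condition"] == "reward"]
        assert (neutral["feedback_cents"] == 0).all()
        assert set(reward["feedback_cents"]) <= {15, -10}
        assert (
            reward["positive_feedback"] == (reward["feedback_cents"] == 15)
        ).all()


class TestReproducibilityAndIO:
    def test_seeded_runs_bit_identical(self):
        cfg = SimConfig(n_participants=2, seed=42)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.trials, d2.trials, check_exact=True)
        for (p1, i1, t1), (p2, i2, t2) in zip(d1.traces, d2.traces):
            assert (p1, i1) == (p2, i2)
            assert np.array_equal(t1.diameter_mm, t2.diameter_mm, equal_nan=True)
            assert np.array_equal(t1.valid, t2.valid)

    def test_different_seed_differs(self):
        t1 = simulate_dataset(SimConfig(n_participants=1, seed=1)).trials
        t2 = simulate_dataset(SimConfig(n_participants=1, seed=2)).trials
        assert not t1["error_deg"].equals(t2["error_deg"])

    def test_trace_long_format_roundtrip(self):
        cfg = SimConfig(n_participants=1, n_blocks=1, trials_per_block=2)
        ds = simulate_dataset(cfg)
        long = traces_to_long(ds.traces)
        markers = markers_to_table(ds.traces)
        rebuilt = traces_from_long(long, markers)
        assert len(rebuilt) == len(ds.traces)
        for (p0, i0, t0), (p1, i1, t1) in zip(ds.traces, rebuilt):
            assert (p0, i0) == (p1, i1)
            assert np.allclose(t0.diameter_mm, t1.diameter_mm, equal_nan=True)
            assert t0.markers == t1.markers
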