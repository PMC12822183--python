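"""Synthetic cohort generator: distributions, monotonicity, determinism."""

import dataclasses

import numpy as np
import pytest

from swaygrade.synthetic import (
    CONDITION_LEVELS,
    CohortConfig,
    ExerciseCondition,
    IntensityParams,
    LatentIntensity,
    ParticipantProfile,
    RatingPanel,
    SwayConfig,
    assign_schedule,
    generate_cohort,
    generate_study,
    latent_intensity,
    rating_category_probabilities,
    simulate_ratings,
    simulate_sway,
    truncated_age_moments,
)

EASIEST = ExerciseCondition("firm", "feet_apart", "open", "none")
HARDEST = ExerciseCondition("bosu", "single_leg", "closed", "vertical")


def profile(ability=0.0, pid=1):
    return ParticipantProfile(pid, 50.0, "F", 165.0, 70.0, ability)


class TestCohort:
    def test_profiles_respect_invariants(self, cohort47):
        assert len(cohort47) == 47
        for p in cohort47:
            assert 18.0 <= p.age <= 90.0
            assert p.sex in ("F", "M")
            assert p.height > 0 and p.weight > 0

    def test_seed_reproducibility(self):
        a = generate_cohort(47, seed=3)
        b = generate_cohort(47, seed=3)
        assert a == b
        assert a != generate_cohort(47, seed=4)

    def test_age_moments_match_truncated_normal_oracle(self):
        # Monte-Carlo check against the configured (truncated) distribution
        ages = np.array([p.age for p in generate_cohort(10000, seed=1)])
        mean, sd = truncated_age_moments(51.0, 18.0)
        assert abs(mean - 51.0) < 1.0  # truncation barely moves the mean
        assert abs(ages.mean() - mean) < 0.5
        assert abs(ages.std() - sd) < 0.5

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=0)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParticipantProfile(1, 10.0, "F", 165.0, 70.0, 0.0)
        with pytest.raises(ValueError):
            ParticipantProfile(1, 50.0, "X", 165.0, 70.0, 0.0)
        with pytest.raises(ValueError):
            ParticipantProfile(1, 50.0, "F", -1.0, 70.0, 0.0)


class TestSchedule:
    def test_full_schedule_has_24_repetitions(self):
        sched = assign_schedule(profile(), n_exercises=8, reps_per_exercise=3)
        assert len(sched) == 24
        assert len({cond for cond, _ in sched}) == 8

    def test_single_repetition(self):
        assert len(assign_schedule(profile(), 1, 1)) == 1

    def test_seed_reproducibility(self):
        a = assign_schedule(profile(), 8, 3, seed=7)
        assert a == assign_schedule(profile(), 8, 3, seed=7)

    @pytest.mark.parametrize("n", [0, 9])
    def test_exercise_count_bounds(self, n):
        with pytest.raises(ValueError):
            assign_schedule(profile(), n_exercises=n)

    def test_schedule_spans_demand_range(self):
        sched = assign_schedule(profile(), 8, 1, seed=0)
        vals = [latent_intensity(profile(), c).value for c, _ in sched]
        assert max(vals) - min(vals) > 2.0


class TestLatentIntensity:
    def test_clamp_floor_for_easy_condition_high_ability(self):
        assert latent_intensity(profile(ability=2.0), EASIEST).value == 1.0

    def test_clamp_ceiling_for_hard_condition_low_ability(self):
        assert latent_intensity(profile(ability=-0.5), HARDEST).value == 5.0

    def test_monotone_in_each_condition_variable(self):
        # seeded sweep of 100 profiles: harder level never lowers intensity
        cohort = generate_cohort(100, seed=5)
        base = {"surface": "foam", "stance": "semi_tandem",
                "eyes": "open", "head_turns": "none"}
        for name, levels in CONDITION_LEVELS.items():
            for lo, hi in zip(levels[:-1], levels[1:]):
                for p in cohort:
                    easy = latent_intensity(
                        p, ExerciseCondition(**{**base, name: lo}))
                    hard = latent_intensity(
                        p, ExerciseCondition(**{**base, name: hi}))
                    assert hard.value >= easy.value

    def test_antitone_in_ability(self):
        cond = ExerciseCondition("foam", "tandem", "closed", "none")
        vals = [latent_intensity(profile(a), cond).value
                for a in np.linspace(-2, 2, 9)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_value_range_enforced(self):
        with pytest.raises(ValueError):
            LatentIntensity(5.5)


class TestSimulateSway:
    def test_sample_count(self):
        recs = simulate_sway(profile(), EASIEST, LatentIntensity(2.0),
                             duration=30, sample_rate=128, seed=0,
                             placements=("lumbar",))
        assert len(recs[0]) == 30 * 128

    def test_null_process_when_amplitude_and_noise_zero(self):
        cfg = SwayConfig(amp_base_deg=0.0, amp_slope_deg=0.0,
                         gyro_noise_sd=0.0, accel_noise_sd=0.0)
        rec, = simulate_sway(profile(), EASIEST, LatentIntensity(3.0),
                             seed=0, config=cfg, placements=("lumbar",))
        assert np.all(rec.true_pitch == 0) and np.all(rec.true_roll == 0)
        assert np.all(rec.gyro == 0)
        np.testing.assert_allclose(rec.accel,
                                   np.tile([0, 0, -9.81], (len(rec), 1)))

    def test_amplitude_scaling_doubles_rms(self):
        base = SwayConfig(amp_base_deg=0.4, amp_slope_deg=0.0)
        double = SwayConfig(amp_base_deg=0.8, amp_slope_deg=0.0)
        r1, = simulate_sway(profile(), EASIEST, LatentIntensity(2.0), seed=3,
                            config=base, placements=("lumbar",))
        r2, = simulate_sway(profile(), EASIEST, LatentIntensity(2.0), seed=3,
                            config=double, placements=("lumbar",))
        rms = lambda x: np.sqrt(np.mean(x ** 2))  # noqa: E731
        assert rms(r2.true_pitch) == pytest.approx(2 * rms(r1.true_pitch),
                                                   rel=0.05)

    def test_placement_gain_ratio_honored(self):
        cfg = SwayConfig(placement_gains={"lumbar": 1.5, "head": 0.5})
        recs = simulate_sway(profile(), EASIEST, LatentIntensity(3.0), seed=2,
                             config=cfg, placements=("lumbar", "head"))
        rms = [np.sqrt(np.mean(r.true_pitch ** 2)) for r in recs]
        assert rms[0] / rms[1] == pytest.approx(3.0, rel=0.05)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_sway(profile(), EASIEST, LatentIntensity(2.0),
                          duration=0)

    def test_step_out_transient_injected_above_threshold(self):
        cfg = SwayConfig(step_out_enabled=True, step_out_threshold=4.0)
        quiet, = simulate_sway(profile(), EASIEST, LatentIntensity(4.5),
                               seed=5, config=dataclasses.replace(
                                   cfg, step_out_enabled=False),
                               placements=("lumbar",))
        lurch, = simulate_sway(profile(), EASIEST, LatentIntensity(4.5),
                               seed=5, config=cfg, placements=("lumbar",))
        diff = lurch.true_pitch - quiet.true_pitch
        assert np.abs(diff).max() == pytest.approx(np.deg2rad(8.0), rel=0.01)


class TestSimulateRatings:
    def test_noiseless_ratings_equal_rounded_intensity(self):
        panel = simulate_ratings(LatentIntensity(3.0), n_pts=5, pt_sd=0.0,
                                 seed=0)
        assert panel.pt_ratings == (3, 3, 3, 3, 3)

    def test_empirical_distribution_matches_enumeration_oracle(self):
        # clamp(round(3 + N(0, 0.5))) category frequencies vs analytic bands
        draws = np.concatenate([
            simulate_ratings(LatentIntensity(3.0), 5, 0.5, seed=s).pt_ratings
            for s in range(2000)])
        expected = rating_category_probabilities(3.0, 0.5)
        for k in range(1, 6):
            assert abs(np.mean(draws == k) - expected[k - 1]) < 0.01

    def test_self_rating_bias_is_downward(self):
        pts, selfs = [], []
        for s in range(1000):
            panel = simulate_ratings(LatentIntensity(3.0), 3, 0.5,
                                     self_bias=-0.5, seed=s)
            pts.extend(panel.pt_ratings)
            selfs.append(panel.self_rating)
        assert np.mean(selfs) < np.mean(pts)

    @pytest.mark.parametrize("n_pts", [0, 6])
    def test_panel_size_bounds(self, n_pts):
        with pytest.raises(ValueError):
            simulate_ratings(LatentIntensity(3.0), n_pts)

    def test_panel_invariants(self):
        with pytest.raises(ValueError):
            RatingPanel(pt_ratings=(), self_rating=3)
        with pytest.raises(ValueError):
            RatingPanel(pt_ratings=(6,), self_rating=3)


class TestStudyDeterminism:
    def test_identical_config_and_seed_give_identical_datasets(self):
        config = CohortConfig(n_participants=3, n_exercises=2,
                              reps_per_exercise=1,
                              placements=("lumbar",))
        a = generate_study(config, seed=11)
        b = generate_study(config, seed=11)
        assert [r.intensity for r in a["repetitions"]] == \
               [r.intensity for r in b["repetitions"]]
        assert [r.panel for r in a["repetitions"]] == \
               [r.panel for r in b["repetitions"]]
        ra = a["recordings"][0][0]
        rb = b["recordings"][0][0]
        assert np.array_equal(ra.accel, rb.accel)
        assert np.array_equal(ra.gyro, rb.gyro)


def test_written_study_roundtrips_via_csv(tmp_path):
    import pandas as pd

    from swaygrade.synthetic import write_study

    config = CohortConfig(n_participants=2, n_exercises=2,
                          reps_per_exercise=1, placements=("lumbar",))
    study = generate_study(config, seed=0)
    write_study(study, tmp_path)
    reps = pd.read_csv(tmp_path / "repetitions.csv")
    assert len(reps) == 4
    first = study["repetitions"][0]
    row = reps.iloc[0]
    assert row["surface"] == first.condition.surface
    assert [int(x) for x in row["pt_ratings"].split("|")] == \
           list(first.panel.pt_ratings)
    imu = pd.read_csv(tmp_path / "imu" / "rep0_lumbar.csv")
    assert list(imu.columns) == ["t", "ax", "ay", "az", "gx", "gy", "gz"]
    assert len(imu) == len(study["recordings"][0][0])
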