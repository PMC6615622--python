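from dataclasses import replace

import numpy as np
import pytest

from lungesim.fencer_sim import (
    ApparatusConfig,
    FencerBehavior,
    crossing_fraction,
    generate_grf,
    plan_reach,
    sample_reaction_time,
    simulate_plan,
    simulate_trial,
    simulate_trial_results,
    sample_cohort,
    perturb_behavior,
)
from lungesim.scenario import Condition, MOVING_LIKE, generate_plan
from lungesim.trigger import DEFAULT_THRESHOLD_BW


class TestReactionTime:
    def test_no_anticipation_respects_floor(self, rng):
        b = FencerBehavior(anticipation_prob=0.0)
        draws = [
            sample_reaction_time(b, Condition.FIXED, rng) for _ in range(2000)
        ]
        assert min(draws) >= 0.10
        assert max(draws) <= 0.60

    def test_pure_anticipation_below_physiological_minimum(self, rng):
        b = FencerBehavior(anticipation_prob=0.499)
        draws = np.array(
            [sample_reaction_time(b, Condition.FIXED, rng) for _ in range(2000)]
        )
        antic = draws[draws < 0.10]
        assert antic.size > 0
        assert np.all(antic >= 0.05)

    def test_mean_tracks_the_median_parameter(self, rng):
        b = FencerBehavior(
            rt_median={c: 0.32 for c in Condition}, anticipation_prob=0.0
        )
        draws = np.array(
            [sample_reaction_time(b, Condition.MOVING, rng) for _ in range(10_000)]
        )
        # lognormal mean exceeds the median slightly; truncation trims the tail
        assert abs(draws.mean() - 0.33) < 0.01

    def test_anticipation_prob_bounded(self):
        with pytest.raises(ValueError):
            FencerBehavior(anticipation_prob=0.6)


class TestGRF:
    def test_quiescent_baseline_noiseless(self, profile, behavior):
        rec = generate_grf(profile, behavior, onset_time=1.0, duration=2.0, rng=None)
        before = rec.t < 0.9
        assert np.all(rec.rear[before, 0] == 0.0)
        assert np.allclose(
            rec.rear[before, 2], behavior.guard_rear_load * profile.bw
        )

    def test_forward_crosses_one_percent_bw_at_onset(self, profile, behavior):
        onset = 0.7123
        rec = generate_grf(profile, behavior, onset, duration=2.0)
        level = 0.01 * profile.bw
        k = np.flatnonzero(rec.rear[:, 0] > level)[0]
        assert abs(rec.t[k] - onset) <= 1.0 / rec.rate + 1e-12

    def test_norm_crosses_threshold_once_upward_during_push(
        self, profile, behavior
    ):
        rec = generate_grf(profile, behavior, onset_time=0.5, duration=2.0)
        norm = np.linalg.norm(rec.rear, axis=1)
        level = DEFAULT_THRESHOLD_BW * profile.bw
        up = np.flatnonzero((norm[:-1] <= level) & (norm[1:] > level))
        assert up.size == 1

    def test_peak_norm_matches_push_peak(self, profile, behavior):
        rec = generate_grf(profile, behavior, onset_time=0.5, duration=2.0)
        norm = np.linalg.norm(rec.rear, axis=1)
        assert norm.max() / profile.bw == pytest.approx(behavior.push_peak, rel=1e-3)

    def test_weak_push_warns_that_trigger_cannot_fire(self, profile, behavior):
        weak = replace(behavior, push_peak=1.0)
        with pytest.warns(UserWarning, match="never fire"):
            generate_grf(profile, weak, onset_time=0.5, duration=2.0)


class TestTrajectory:
    def test_noiseless_fixed_touch_hits_target_centre(self, profile, behavior):
        path = plan_reach(
            profile, behavior, onset_time=1.0, mt_initial=0.8,
            aim_initial=(0.1, 0.9), screen_x=1.5 * profile.height,
        )
        assert path.touch_time == pytest.approx(1.8)
        assert path.touch_point == pytest.approx((0.1, 0.9))

    def test_replanned_crossing_lands_at_the_penalised_touch_time(
        self, profile, behavior
    ):
        path = plan_reach(
            profile, behavior, onset_time=1.0, mt_initial=0.8,
            aim_initial=(0.1, 0.9), screen_x=1.5 * profile.height,
            display_time=1.15, aim_final=(-0.1, 0.5), mt_final=0.9,
        )
        assert path.touch_time == pytest.approx(1.9, abs=1e-6)
        # the replanned path curves, so the touch lands near (not exactly at)
        # the new aim point
        assert path.touch_point[0] == pytest.approx(-0.1, abs=0.02)
        assert path.touch_point[1] == pytest.approx(0.5, abs=0.02)

    def test_display_after_planned_touch_is_ignored(self, profile, behavior):
        path = plan_reach(
            profile, behavior, onset_time=1.0, mt_initial=0.8,
            aim_initial=(0.1, 0.9), screen_x=1.5 * profile.height,
            display_time=2.5, aim_final=(-0.1, 0.5), mt_final=0.9,
        )
        assert path.t_replan is None
        assert path.touch_time == pytest.approx(1.8)

    def test_tip_x_non_decreasing_during_thrust(self, profile, behavior):
        path = plan_reach(
            profile, behavior, onset_time=1.0, mt_initial=0.8,
            aim_initial=(0.0, 0.85), screen_x=1.5 * profile.height,
            display_time=1.2, aim_final=(0.1, 0.6), mt_final=0.9,
        )
        t = np.linspace(1.0, path.touch_time, 400)
        x = path.position(t)[:, 0]
        assert np.all(np.diff(x) > -1e-9)

    def test_crossing_fraction_solves_minjerk(self):
        tau = crossing_fraction(0.02)
        s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        assert s == pytest.approx(1 / 1.02, abs=1e-10)


class TestSimulateTrial:
    def test_event_order_on_every_trial(self, profile, behavior, rng):
        plan = generate_plan(profile, 7)
        sims = simulate_plan(profile, behavior, plan, rng)
        for sim in sims:
            tr = sim.truth
            assert tr.stimulus_time <= tr.onset_time <= tr.touch_time
            if tr.display_time is not None:
                assert tr.trigger_time <= tr.display_time <= tr.touch_time
            assert np.isfinite(tr.touch_time)

    def test_fixed_trials_never_display_a_jump(self, profile, behavior, rng):
        plan = generate_plan(profile, 3)
        sims = simulate_plan(profile, behavior, plan, rng)
        for sim in sims:
            if sim.spec.condition not in MOVING_LIKE:
                assert sim.truth.display_time is None
                assert sim.final_target == sim.initial_target

    def test_trigger_fires_in_every_moving_trial(self, profile, behavior, rng):
        plan = generate_plan(profile, 5)
        sims = simulate_plan(profile, behavior, plan, rng)
        moving = [s for s in sims if s.spec.condition in MOVING_LIKE]
        assert all(s.truth.display_time is not None for s in moving)
        assert all(
            s.truth.display_time < s.truth.touch_time for s in moving
        )

    def test_cohort_replay_is_bit_identical(self, profile, behavior):
        plan = generate_plan(profile, 2)
        a = simulate_plan(profile, behavior, plan, np.random.default_rng(9))
        b = simulate_plan(profile, behavior, plan, np.random.default_rng(9))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.force.rear, sb.force.rear)
            assert np.array_equal(sa.sword.tip, sb.sword.tip)
            assert sa.truth == sb.truth

    def test_injected_mt_penalty_recovered(self, profile, rng):
        b = FencerBehavior(mt_penalty_moving=0.1, anticipation_prob=0.0)
        plan = generate_plan(profile, 4)
        deltas = []
        for _ in range(4):  # 4 x 120 trials
            sims = simulate_plan(profile, b, plan, rng)
            mt_f = [
                s.truth.mt for s in sims if s.spec.condition not in MOVING_LIKE
            ]
            mt_m = [s.truth.mt for s in sims if s.spec.condition in MOVING_LIKE]
            deltas.append(np.mean(mt_m) - np.mean(mt_f))
        se = b.mt_sigma * np.sqrt(1 / (4 * 32) + 1 / (4 * 88))
        assert abs(np.mean(deltas) - 0.1) < max(3 * se, 0.01)


class TestFastPath:
    def test_matches_protocol_shape(self, profile, behavior, rng):
        plan = generate_plan(profile, 1)
        df = simulate_trial_results(profile, behavior, plan, rng)
        assert len(df) == 120
        assert np.allclose(df["rrt"], df["rt"] + df["mt"])
        assert (df["accuracy"] >= 0).all()
        assert (df["msv"] > 0).all()

    def test_success_iff_within_radius(self, profile, behavior, rng):
        plan = generate_plan(profile, 1)
        df = simulate_trial_results(profile, behavior, plan, rng)
        assert (df["success"] == (df["accuracy"] <= df["diameter"] / 2)).all()

    def test_mt_penalty_applies_to_moving_conditions(self, profile, rng):
        b = replace(FencerBehavior(), mt_sigma=1e-9)
        plan = generate_plan(profile, 1)
        df = simulate_trial_results(profile, b, plan, rng)
        moving = df["condition"].isin(["Moving", "UncertainMoving"])
        gap = df.loc[moving, "mt"].mean() - df.loc[~moving, "mt"].mean()
        assert gap == pytest.approx(b.mt_penalty_moving, abs=1e-6)


class TestCohort:
    def test_cohort_profiles_valid_and_mixed_handed(self, rng):
        cohort = sample_cohort(11, rng)
        assert len(cohort) == 11
        hands = {p.handedness for p in cohort}
        assert hands == {"left", "right"}
        assert len({p.id for p in cohort}) == 11

    def test_perturbation_keeps_condition_structure(self, behavior, rng):
        b = perturb_behavior(behavior, rng)
        base_ratio = (
            behavior.rt_median[Condition.MOVING]
            / behavior.rt_median[Condition.FIXED]
        )
        new_ratio = b.rt_median[Condition.MOVING] / b.rt_median[Condition.FIXED]
        assert new_ratio == pytest.approx(base_ratio, rel=1e-9)
        assert b.mt_penalty_moving == behavior.mt_penalty_moving
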