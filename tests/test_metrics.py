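from dataclasses import replace

import numpy as np
import pytest

from lungesim.fencer_sim import (
    FencerBehavior,
    ForceRecording,
    SwordRecording,
    simulate_plan,
    simulate_trial_results,
)
from lungesim.geometry import TargetSpec
from lungesim.metrics import (
    NoOnsetError,
    NoTouchError,
    TrialEvents,
    TrialResult,
    analyze_trial,
    compute_msv,
    detect_movement_onset,
    detect_touch,
    results_frame,
    score_trial,
    summarize,
    rank_fencers,
)
from lungesim.scenario import Condition, MOVING_LIKE, TrialSpec, generate_plan


def _force_step(profile, stimulus, delay, level_bw, rate=1000.0, duration=2.0):
    n = int(duration * rate)
    rear = np.zeros((n, 3))
    t = np.arange(n) / rate
    rear[t >= stimulus + delay, 0] = level_bw * profile.bw
    return ForceRecording(rate=rate, t0=0.0, rear=rear, front=np.zeros((n, 3)))


def _sword_line(x0, v, rate=250.0, duration=2.0, y=0.1, z=0.9):
    n = int(duration * rate)
    t = np.arange(n) / rate
    tip = np.column_stack([x0 + v * t, np.full(n, y), np.full(n, z)])
    return SwordRecording(rate=rate, t0=0.0, base=tip.copy(), tip=tip)


def _spec(condition=Condition.FIXED, diameter=0.10):
    return TrialSpec(
        index=1,
        session=1,
        condition=condition,
        cue_color="green" if condition == Condition.FIXED else "blue",
        initial_zone="UL",
        final_zone=None if condition not in MOVING_LIKE else "LR",
        diameter=diameter,
        foreperiod=0.8,
    )


class TestOnsetDetection:
    def test_step_input_recovers_delay(self, profile):
        rec = _force_step(profile, stimulus=0.5, delay=0.3, level_bw=0.02)
        onset = detect_movement_onset(rec, 0.5, profile)
        assert onset - 0.5 == pytest.approx(0.300, abs=1.0 / rec.rate + 1e-12)

    def test_linear_ramp_crossing_within_one_sample(self, profile):
        rate, duration = 1000.0, 2.0
        n = int(duration * rate)
        t = np.arange(n) / rate
        slope = 0.05 * profile.bw  # N/s; crosses 1% BW at t = 0.2 after ramp start
        rear = np.zeros((n, 3))
        rear[:, 0] = np.clip((t - 1.0) * slope, 0, None)
        rec = ForceRecording(rate=rate, t0=0.0, rear=rear, front=np.zeros((n, 3)))
        t_cross = 1.0 + 0.01 * profile.bw / slope
        onset = detect_movement_onset(rec, 0.5, profile)
        # strict-inequality detection lands on the next sample when the
        # crossing falls exactly on one
        assert abs(onset - t_cross) <= 1.0 / rate + 1e-9

    def test_never_exceeded_raises(self, profile):
        rec = _force_step(profile, stimulus=0.5, delay=0.3, level_bw=0.001)
        with pytest.raises(NoOnsetError):
            detect_movement_onset(rec, 0.5, profile)

    def test_stimulus_outside_recording_rejected(self, profile):
        rec = _force_step(profile, stimulus=0.5, delay=0.3, level_bw=0.02)
        with pytest.raises(ValueError):
            detect_movement_onset(rec, 5.0, profile)


class TestTouchDetection:
    def test_interpolated_crossing_exact_on_a_line(self):
        sword = _sword_line(x0=0.0, v=1.3)
        screen_x = 1.001  # falls between samples
        tt, (y, z) = detect_touch(sword, screen_x)
        assert tt == pytest.approx(screen_x / 1.3, abs=1e-12)
        assert (y, z) == pytest.approx((0.1, 0.9))

    def test_grazing_at_a_sample_returns_that_sample(self):
        sword = _sword_line(x0=0.0, v=1.0, rate=250.0)
        # x reaches exactly 0.5 at sample 125
        tt, _ = detect_touch(sword, 0.5)
        assert tt == pytest.approx(0.5)

    def test_no_crossing_raises(self):
        sword = _sword_line(x0=0.0, v=0.01, duration=1.0)
        with pytest.raises(NoTouchError):
            detect_touch(sword, 2.0)


class TestMSV:
    def test_constant_velocity_recovered_exactly(self):
        sword = _sword_line(x0=0.0, v=2.2)
        assert compute_msv(sword) == pytest.approx(2.2, rel=1e-4)

    def test_stationary_marker_gives_zero(self):
        sword = _sword_line(x0=0.3, v=0.0)
        assert compute_msv(sword) == pytest.approx(0.0, abs=1e-9)

    def test_minimum_jerk_peak_velocity_closed_form(self):
        L, T, rate = 1.2, 0.8, 250.0
        n = int(1.5 * T * rate)
        t = np.arange(n) / rate
        tau = np.clip(t / T, 0, 1)
        x = L * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        tip = np.column_stack([x, np.zeros(n), np.zeros(n)])
        sword = SwordRecording(rate=rate, t0=0.0, base=tip, tip=tip)
        assert compute_msv(sword) == pytest.approx(1.875 * L / T, rel=0.02)

    def test_short_recording_rejected(self):
        tip = np.zeros((3, 3))
        sword = SwordRecording(rate=250.0, t0=0.0, base=tip, tip=tip)
        with pytest.raises(ValueError):
            compute_msv(sword)


class TestScoring:
    def _events(self, touch_point, rt=0.3, mt=0.8):
        return TrialEvents(
            stimulus_time=1.0,
            onset_time=1.0 + rt,
            touch_time=1.0 + rt + mt,
            touch_point=touch_point,
        )

    def test_touch_at_centre_is_perfect(self):
        target = TargetSpec(y=0.1, z=0.9, diameter=0.05, zone="UL")
        r = score_trial(self._events((0.1, 0.9)), _spec(), target, msv=2.5)
        assert r.success and r.accuracy == 0.0
        assert r.rrt == r.rt + r.mt

    def test_boundary_touch_counts_as_success(self):
        d = 0.10
        target = TargetSpec(y=0.0, z=0.9, diameter=d, zone="UL")
        r = score_trial(self._events((d / 2, 0.9)), _spec(diameter=d), target, msv=2.5)
        assert r.accuracy == pytest.approx(d / 2)
        assert r.success

    def test_moving_trial_scored_against_final_position(self):
        # fencer touches the initial target centre but the target jumped
        initial = (0.1, 1.1)
        final = TargetSpec(y=-0.1, z=0.6, diameter=0.10, zone="LR")
        r = score_trial(
            self._events(initial),
            _spec(condition=Condition.MOVING),
            final,
            msv=2.5,
        )
        assert not r.success
        assert r.accuracy == pytest.approx(np.hypot(0.2, 0.5))

    def test_anticipation_flag(self):
        target = TargetSpec(y=0.0, z=0.9, diameter=0.10, zone="UL")
        r = score_trial(self._events((0.0, 0.9), rt=0.08), _spec(), target, msv=2.5)
        assert r.anticipated

    def test_rrt_identity_enforced(self):
        with pytest.raises(ValueError):
            TrialResult(
                success=True,
                accuracy=0.0,
                rt=0.3,
                mt=0.8,
                rrt=1.2,
                msv=2.0,
                anticipated=False,
                condition=Condition.FIXED,
                diameter=0.1,
            )


class TestEndToEndRecovery:
    def test_detected_events_unbiased_vs_ground_truth(self, profile, rng):
        behavior = FencerBehavior(marker_noise=0.0, anticipation_prob=0.0)
        plan = generate_plan(profile, 6)
        sims = simulate_plan(profile, behavior, plan, rng)
        screen_x = 1.5 * profile.height
        results = [analyze_trial(s, profile, screen_x) for s in sims]
        assert all(r.valid for r in results)
        rt_bias = np.mean([r.rt - s.truth.rt for r, s in zip(results, sims)])
        mt_bias = np.mean([r.mt - s.truth.mt for r, s in zip(results, sims)])
        acc_err = np.max(
            [
                abs(
                    r.accuracy
                    - np.hypot(
                        s.truth.touch_point[0] - s.final_target.y,
                        s.truth.touch_point[1] - s.final_target.z,
                    )
                )
                for r, s in zip(results, sims)
            ]
        )
        assert abs(rt_bias) < 1e-3  # one force sample
        assert abs(mt_bias) < 4e-3  # one marker sample
        assert acc_err < 1e-3  # noiseless markers: sub-mm

    def test_perfect_aim_means_full_success_in_fixed(self, profile, rng):
        behavior = FencerBehavior(
            aim_sigma={c: 0.0 for c in Condition}, marker_noise=0.0
        )
        plan = generate_plan(profile, 8)
        sims = simulate_plan(profile, behavior, plan, rng)
        screen_x = 1.5 * profile.height
        for s in sims:
            if s.spec.condition not in MOVING_LIKE:
                r = analyze_trial(s, profile, screen_x)
                assert r.success
                assert r.accuracy < 1e-3


class TestSummaries:
    def test_identical_trials_average_to_themselves(self, profile, behavior, rng):
        plan = generate_plan(profile, 1)
        df = simulate_trial_results(profile, behavior, plan, rng)
        for var in ("accuracy", "rt", "mt", "msv"):
            df[var] = 0.5
        df["success"] = True
        summ = summarize(df)
        assert np.allclose(summ["accuracy"], 0.5)
        assert np.allclose(summ["success"], 100.0)

    def test_pooled_uncertain_is_weighted_cell_mean(self, profile, behavior, rng):
        plan = generate_plan(profile, 2)
        df = simulate_trial_results(profile, behavior, plan, rng)
        summ = summarize(df).set_index("cell")
        uf, um, u = (
            summ.loc["UncertainFixed"],
            summ.loc["UncertainMoving"],
            summ.loc["Uncertain"],
        )
        expected = (16 * uf["accuracy"] + 44 * um["accuracy"]) / 60
        assert u["accuracy"] == pytest.approx(expected)
        assert u["n"] == 60

    def test_injected_aim_effect_orders_condition_accuracy(self, profile, rng):
        behavior = FencerBehavior()
        plan = generate_plan(profile, 3)
        frames = [
            simulate_trial_results(profile, behavior, plan, rng) for _ in range(7)
        ]
        import pandas as pd

        df = pd.concat(frames, ignore_index=True)
        summ = summarize(df).set_index("cell")
        assert summ.loc["Fixed", "accuracy"] < summ.loc["Moving", "accuracy"]
        assert (
            summ.loc["UncertainFixed", "accuracy"]
            < summ.loc["UncertainMoving", "accuracy"]
        )

    def test_fencers_ranked_by_pooled_accuracy(self, profile, behavior, rng):
        import pandas as pd

        frames = []
        for i, scale in enumerate([2.0, 0.5, 1.0]):
            b = replace(
                behavior,
                aim_sigma={c: s * scale for c, s in behavior.aim_sigma.items()},
            )
            p = replace(profile, id=f"F{i:02d}")
            plan = generate_plan(p, i)
            frames.append(simulate_trial_results(p, b, plan, rng))
        summ = summarize(pd.concat(frames, ignore_index=True))
        ranked = rank_fencers(summ)
        assert list(ranked["fencer_id"]) == ["F01", "F02", "F00"]

    def test_results_frame_shape(self, profile, behavior, rng):
        plan = generate_plan(profile, 4)
        sims = simulate_plan(profile, behavior, plan, rng)
        screen_x = 1.5 * profile.height
        results = [analyze_trial(s, profile, screen_x) for s in sims]
        df = results_frame(results, profile.id, list(plan.trials))
        assert len(df) == 120
        assert set(df["condition"]) == {c.value for c in Condition}
        assert np.allclose(df["rrt"], df["rt"] + df["mt"])
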