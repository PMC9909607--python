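"""Schedule generation: counts, lags, practice, durations, session plans."""

import dataclasses

import numpy as np
import pytest

from mstkit.sequencer import (
    PRACTICE_CONTINUOUS,
    PRACTICE_STUDY_TEST,
    DesignSpec,
    LagBand,
    ScheduleError,
    TimingSpec,
    TrialSchedule,
    build_continuous,
    build_practice,
    build_schedule,
    build_study_test,
    check_schedule,
    design_variant,
    estimate_duration,
    plan_sessions,
    variant_duration_minutes,
)


class TestStudyTest:
    def test_full_variant_is_320_trials(self, full_st):
        assert full_st.n_scored == 320
        counts = full_st.condition_counts()
        assert counts == {
            "study_target": 128, "repeat": 64, "lure": 64, "foil": 64,
        }
        check_schedule(full_st)

    def test_reduced_variant_is_148_trials(self, reduced_st):
        assert reduced_st.n_scored == 148
        assert reduced_st.condition_counts() == {
            "study_target": 64, "repeat": 20, "lure": 44, "foil": 20,
        }
        check_schedule(reduced_st)

    def test_minimal_schedule_one_of_each(self, bank):
        spec = DesignSpec(
            format="study_test", n_repeat=1, n_lure=1, n_foil=1, seed=0
        )
        sched = build_study_test(spec, bank.pairs_for_set(5))
        assert sched.n_scored == 5  # 2 study + 3 test
        assert sched.condition_counts() == {
            "study_target": 2, "repeat": 1, "lure": 1, "foil": 1,
        }

    def test_every_probe_was_studied_and_foils_were_not(self, full_st):
        studied = {
            (t.pair.set_id, t.pair.pair_id)
            for t in full_st.scored_trials
            if t.condition == "study_target"
        }
        for t in full_st.scored_trials:
            key = (t.pair.set_id, t.pair.pair_id)
            if t.condition in ("repeat", "lure"):
                assert key in studied
            elif t.condition == "foil":
                assert key not in studied

    def test_exemplar_convention(self, full_st):
        for t in full_st.scored_trials:
            assert t.exemplar == ("b" if t.condition == "lure" else "a")

    def test_mismatched_study_count_rejected(self):
        with pytest.raises(ValueError, match="n_study"):
            DesignSpec(
                format="study_test", n_repeat=2, n_lure=2, n_foil=2, n_study=5
            )

    def test_insufficient_pairs_rejected(self, bank):
        spec = design_variant("full-st")
        with pytest.raises(ValueError, match="pairs"):
            build_study_test(spec, bank.pairs_for_set(1)[:100])


class TestContinuous:
    def test_full_variant_is_256_trials_with_exact_band_counts(self, full_cont):
        assert full_cont.n_scored == 256
        report = check_schedule(full_cont)
        assert report["condition_counts"] == {
            "first": 128, "repeat": 64, "lure": 64,
        }
        assert report["lag_band_counts"] == {
            ("repeat", 4, 11): 32, ("repeat", 20, 99): 32,
            ("lure", 4, 11): 32, ("lure", 20, 99): 32,
        }

    def test_reduced_variant_is_128_trials(self, reduced_cont):
        assert reduced_cont.n_scored == 128
        report = check_schedule(reduced_cont)
        assert report["condition_counts"] == {
            "first": 64, "repeat": 20, "lure": 44,
        }
        assert report["lag_band_counts"] == {
            ("repeat", 4, 11): 10, ("repeat", 20, 99): 10,
            ("lure", 4, 11): 22, ("lure", 20, 99): 22,
        }

    def test_lag_equals_index_difference(self, full_cont):
        first_pos = {}
        for t in full_cont.scored_trials:
            key = (t.pair.set_id, t.pair.pair_id)
            if t.condition == "first":
                first_pos[key] = t.index
            elif t.condition in ("repeat", "lure"):
                assert t.lag == t.index - first_pos[key]

    def test_forced_adjacency_at_unit_lag(self, bank):
        spec = DesignSpec(
            format="continuous", n_repeat=1, n_lure=1, n_foil=None, n_first=2,
            repeat_lags=(LagBand(1, 1, 1),), lure_lags=(LagBand(1, 1, 1),),
            seed=3,
        )
        sched = build_continuous(spec, bank.pairs_for_set(5))
        rep = next(t for t in sched.trials if t.condition == "repeat")
        assert rep.lag == 1
        assert sched.trials[rep.index - 1].pair == rep.pair

    def test_n_foil_forbidden_in_continuous(self):
        with pytest.raises(ValueError, match="foil"):
            DesignSpec(format="continuous", n_repeat=4, n_lure=4, n_foil=4)

    def test_band_counts_must_sum_to_condition_counts(self):
        with pytest.raises(ValueError, match="lag-band"):
            DesignSpec(
                format="continuous", n_repeat=4, n_lure=4, n_foil=None,
                repeat_lags=(LagBand(1, 5, 3),),
            )

    def test_generation_feasible_across_seeds(self, bank):
        # scaled-down version of the feasibility property: the full
        # design must build without error for every tried seed
        pairs = bank.pairs_for_set(1)
        for seed in range(60):
            spec = design_variant("full-cont", seed=seed)
            check_schedule(build_continuous(spec, pairs))

    def test_deterministic_given_seed(self, bank):
        pairs = bank.pairs_for_set(2)
        spec = design_variant("full-cont", seed=42)
        s1 = build_continuous(spec, pairs)
        s2 = build_continuous(spec, pairs)
        assert s1.trials == s2.trials


class TestChecker:
    def test_random_specs_pass_their_own_checker(self, bank):
        # independent re-derivation agrees with the declared spec for
        # randomized small designs of both formats
        rng = np.random.default_rng(0)
        pairs = bank.pairs_for_set(6)
        for i in range(60):
            n_rep = int(rng.integers(2, 12))
            n_lure = int(rng.integers(2, 12))
            if i % 2:
                spec = DesignSpec(
                    format="study_test", n_repeat=n_rep, n_lure=n_lure,
                    n_foil=int(rng.integers(1, 12)), seed=i,
                )
            else:
                spec = DesignSpec(
                    format="continuous", n_repeat=n_rep, n_lure=n_lure,
                    n_foil=None, n_first=n_rep + n_lure + int(rng.integers(0, 6)),
                    seed=i,
                )
            check_schedule(build_schedule(spec, pairs))

    def test_tampered_schedule_is_caught(self, full_st):
        broken = TrialSchedule(
            design=full_st.design,
            trials=full_st.trials[:-1],  # drop one test trial
            variant_label=full_st.variant_label,
        )
        with pytest.raises(ScheduleError):
            check_schedule(broken)

    def test_wrong_lag_is_caught(self, full_cont):
        trials = list(full_cont.trials)
        idx = next(
            i for i, t in enumerate(trials) if t.condition == "repeat"
        )
        trials[idx] = dataclasses.replace(trials[idx], lag=trials[idx].lag + 1)
        broken = TrialSchedule(design=full_cont.design, trials=trials)
        with pytest.raises(ScheduleError):
            check_schedule(broken)


class TestPractice:
    def test_study_test_practice_counts_and_guidance(self, bank):
        trials = build_practice(
            PRACTICE_STUDY_TEST, "study_test", bank.pairs_for_set(1)[:12], seed=0
        )
        study = [t for t in trials if t.phase == "practice_study"]
        test = [t for t in trials if t.phase == "practice_test"]
        assert len(study) == 4
        assert len(test) == 6
        assert sum(t.guided for t in test) == 3

    def test_continuous_practice_counts(self, bank):
        trials = build_practice(
            PRACTICE_CONTINUOUS, "continuous", bank.pairs_for_set(1)[:12], seed=0
        )
        assert len(trials) == 9
        assert sum(t.guided for t in trials) == 5
        assert sum(not t.guided for t in trials) == 4

    def test_practice_pool_never_reused_in_scored_block(self, bank):
        spec = design_variant("reduced-cont", seed=7, practice=True)
        sched = build_continuous(spec, bank.pairs_for_set(3))
        assert any(t.phase == "practice_test" for t in sched.trials)
        check_schedule(sched)  # includes the practice/scored disjointness check


class TestDuration:
    def test_minimum_duration_is_trials_times_floor(self, bank):
        spec = DesignSpec(
            format="study_test", n_repeat=32, n_lure=32, n_foil=0, seed=0
        )
        sched = build_study_test(spec, bank.pairs_for_set(1))
        assert sched.n_scored == 128
        min_s, exp_s = estimate_duration(sched)
        assert min_s == pytest.approx(128 * 2.5)

    def test_zero_trials_zero_duration(self):
        empty = TrialSchedule(
            design=DesignSpec(format="study_test", n_repeat=1, n_lure=1, n_foil=1),
            trials=[],
        )
        assert estimate_duration(empty) == (0.0, 0.0)

    def test_latency_below_floor_leaves_expected_at_minimum(self, bank):
        spec = design_variant(
            "reduced-st",
            timing=TimingSpec(assumed_response_latency_s=1.0),
            practice=False,
        )
        sched = build_study_test(spec, bank.pairs_for_set(2))
        test_trials = [t for t in sched.scored_trials if t.phase == "test"]
        assert len(test_trials) == 84
        test_only = TrialSchedule(design=spec, trials=test_trials)
        min_s, exp_s = estimate_duration(test_only)
        assert exp_s == pytest.approx(210.0)  # 84 x 2.5 s

    def test_slow_responders_stretch_expected_beyond_minimum(self, full_st):
        min_s, exp_s = estimate_duration(
            full_st, TimingSpec(assumed_response_latency_s=3.0)
        )
        assert exp_s == pytest.approx(320 * 3.5)
        assert exp_s > min_s

    def test_measured_component_durations_sum_to_published_totals(self):
        assert round(variant_duration_minutes("baseline"), 2) == 12.24
        assert round(variant_duration_minutes("reduced-st"), 2) == 6.10
        assert round(variant_duration_minutes("reduced-cont"), 2) == 5.26


class TestPlanSessions:
    def test_order_counterbalanced_exactly_for_four_participants(self):
        plans = plan_sessions(4, ["A", "B"], [1, 2], seed=0)
        first = [p[0]["variant"] for p in plans]
        assert sorted(first) == ["A", "A", "B", "B"]
        for p in plans:  # every participant sees both variants once
            assert sorted(s["variant"] for s in p) == ["A", "B"]

    def test_set_assignment_rotates(self):
        plans = plan_sessions(4, ["A", "B"], [1, 2], seed=0)
        a_sets = sorted(
            next(s["set_id"] for s in p if s["variant"] == "A") for p in plans
        )
        assert a_sets == [1, 1, 2, 2]

    def test_repeat_mode_reuses_half_sets_in_adjacent_pairs(self):
        plans = plan_sessions(3, ["half-st"], [1, 2, 3, 4, 5], mode="repeat", seed=1)
        for p in plans:
            keys = [(s["set_id"], s["half"]) for s in p]
            assert keys[0] == keys[1]
            assert keys[2] == keys[3]
            assert keys[0] != keys[2]

    def test_no_repeat_mode_gives_four_distinct_half_sets(self):
        plans = plan_sessions(3, ["half-st"], [1, 2, 3], mode="no_repeat", seed=1)
        for p in plans:
            keys = [(s["set_id"], s["half"]) for s in p]
            assert len(set(keys)) == 4

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            plan_sessions(2, ["A"], [1, 2], mode="bogus")
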