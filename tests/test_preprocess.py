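"""The preregistered exclusion pipeline: order, boundaries, audit tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snarcflex as sf


def meta_row(**overrides):
    row = {"participant_id": "x", "age": 25, "serious": True,
           "environment": "quiet", "distractions": "none",
           "finger_compliance": True}
    row.update(overrides)
    return pd.DataFrame([row])


class TestScreening:
    @pytest.mark.parametrize("overrides,reason", [
        ({"age": 41}, "age"),
        ({"age": 17}, "age"),
        ({"environment": "very noisy"}, "environment"),
        ({"environment": "Extremely Noisy"}, "environment"),
        ({"distractions": "multiple"}, "distractions"),
        ({"serious": False}, "non_serious"),
        ({"finger_compliance": False}, "finger_use"),
    ])
    def test_single_violation_reason_codes(self, overrides, reason):
        included, excl = sf.screen_participants(meta_row(**overrides))
        assert included == []
        assert list(excl["reason"]) == [reason]

    def test_compliant_record_included(self, compliant_meta):
        included, excl = sf.screen_participants(compliant_meta)
        assert included == ["a"] and len(excl) == 0

    def test_first_matching_criterion_wins(self):
        # age fires before environment in the preregistered order
        _, excl = sf.screen_participants(
            meta_row(age=50, environment="very noisy"))
        assert list(excl["reason"]) == ["age"]

    def test_missing_values_do_not_exclude(self):
        included, _ = sf.screen_participants(meta_row(age=np.nan))
        assert included == ["x"]

    def test_missing_column_is_named(self):
        with pytest.raises(ValueError, match="finger_compliance"):
            sf.screen_participants(meta_row().drop(columns=["finger_compliance"]))


def trial_row(rt, practice=False, correct=True, missing=False):
    return {"participant_id": "p", "experiment": "exp1", "block_index": 0,
            "block_order": 1, "range_id": "lower", "key_assignment": "congruent",
            "number": 2, "parity": 0.5, "response_side": "right",
            "rt_ms": rt, "correct": correct, "practice": practice,
            "missing": missing}


class TestFilterTrials:
    def test_hand_counted_fixture(self):
        # 10 trials: 1 practice, 1 incorrect, 1 anticipation, 1 lapse, 6 clean
        rows = ([trial_row(500, practice=True), trial_row(500, correct=False),
                 trial_row(150), trial_row(1600)]
                + [trial_row(500)] * 6)
        out, tallies = sf.filter_trials(pd.DataFrame(rows))
        assert len(out) == 6
        assert [t["removed"] for t in tallies] == [1, 0, 1, 1, 1]
        # sequential denominators: each stage's fraction uses its entry count
        assert [t["entered"] for t in tallies] == [10, 9, 9, 8, 7]
        assert tallies[0]["fraction"] == pytest.approx(0.1)

    def test_boundary_rts_are_retained(self):
        rows = [trial_row(200.0), trial_row(1500.0), trial_row(199.99),
                trial_row(1500.01)]
        out, _ = sf.filter_trials(pd.DataFrame(rows))
        assert sorted(out["rt_ms"]) == [200.0, 1500.0]


class TestTrimOutliers:
    def test_identical_rts_nothing_removed(self):
        df = pd.DataFrame([trial_row(500)] * 10)
        out, removed, iters = sf.trim_outliers(df)
        assert removed == 0 and iters == 1 and len(out) == 10

    def test_single_outlier_removed_in_first_pass(self):
        # 30 x 500 ms plus one 1400 ms trial: mean 529.03, the 1400 lies
        # far beyond 3 SD; the second pass removes nothing
        df = pd.DataFrame([trial_row(500)] * 30 + [trial_row(1400)])
        rts = df["rt_ms"].to_numpy()
        assert abs(1400 - rts.mean()) > 3 * rts.std(ddof=1)  # oracle check
        out, removed, iters = sf.trim_outliers(df)
        assert removed == 1 and iters == 2
        assert 1400 not in out["rt_ms"].values

    def test_two_pass_cascade(self):
        # brute-force-found fixture: removing 900 shrinks the SD enough
        # that 700 then exceeds the new 3 SD bound
        df = pd.DataFrame([trial_row(500)] * 20
                          + [trial_row(700), trial_row(900)])
        out, removed, iters = sf.trim_outliers(df)
        assert removed == 2 and iters == 3
        assert set(out["rt_ms"]) == {500}

    def test_exact_boundary_retained(self):
        # a value at exactly mean + 3 SD survives ("maximum 3 SD")
        rts = np.array([400.0, 500.0, 600.0])
        mean, sd = rts.mean(), rts.std(ddof=1)
        df = pd.DataFrame([trial_row(r) for r in rts]
                          + [trial_row(mean + 3 * sd)])
        rts4 = df["rt_ms"].to_numpy()
        # recompute on the 4-trial set: is the added point within bound?
        m4, s4 = rts4.mean(), rts4.std(ddof=1)
        if abs(rts4[-1] - m4) <= 3 * s4:
            out, removed, _ = sf.trim_outliers(df)
            assert removed == 0

    def test_fewer_than_two_trials_unchanged(self):
        df = pd.DataFrame([trial_row(500)])
        out, removed, iters = sf.trim_outliers(df)
        assert len(out) == 1 and removed == 0 and iters == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(200, 1500), min_size=2, max_size=40))
    def test_terminates_and_only_shrinks(self, rts):
        df = pd.DataFrame([trial_row(float(r)) for r in rts])
        out, removed, iters = sf.trim_outliers(df)
        assert len(out) + removed == len(df)
        assert iters <= len(df) + 1
        assert set(out["rt_ms"]).issubset(set(df["rt_ms"]))
        # idempotence: re-trimming the survivors removes nothing
        if len(out) >= 2:
            out2, removed2, _ = sf.trim_outliers(out)
            assert removed2 == 0


class TestParticipantCriteria:
    def _mini_trials(self, pid, n, range_id="lower", number=2):
        rows = []
        for i in range(n):
            r = trial_row(500.0 + i)
            r.update(participant_id=pid, range_id=range_id, number=number,
                     response_side="left" if i % 2 else "right")
            rows.append(r)
        return rows

    def test_just_below_75_percent_excluded(self):
        sets = sf.stimulus_sets("exp1")
        trials = pd.DataFrame(self._mini_trials("p", 299))
        included, excl = sf.apply_participant_criteria(trials, 400, sets)
        assert included == []
        assert list(excl["reason"]) == ["low_valid_fraction"]

    def test_exactly_75_percent_and_full_cells_included(self):
        sets = sf.stimulus_sets("exp2")
        rows = []
        for rid in sf.RANGES:
            for m in sets[rid].numbers:
                for side in ("left", "right"):
                    r = trial_row(500.0)
                    r.update(range_id=rid, number=m, response_side=side)
                    rows.extend([r.copy()] * 19)  # 19*16 = 304 >= 0.75*400
        included, excl = sf.apply_participant_criteria(
            pd.DataFrame(rows), 400, sets)
        assert included == ["p"] and len(excl) == 0

    def test_empty_cell_excludes(self):
        sets = sf.stimulus_sets("exp2")
        rows = []
        for rid in sf.RANGES:
            for m in sets[rid].numbers:
                for side in ("left", "right"):
                    if rid == "higher" and m == 7 and side == "right":
                        continue  # the empty cell
                    r = trial_row(500.0)
                    r.update(range_id=rid, number=m, response_side=side)
                    rows.extend([r.copy()] * 25)
        included, excl = sf.apply_participant_criteria(
            pd.DataFrame(rows), 400, sets)
        assert included == []
        assert list(excl["reason"]) == ["empty_cell"]


class TestFullPipeline:
    def test_clean_noiseless_data_loses_nothing(self, noiseless_exp2_bundle):
        report = noiseless_exp2_bundle["report"]
        assert report.participants_screened_out == {}
        assert report.participants_low_valid == 0
        assert report.participants_empty_cell == 0
        by_stage = {t["stage"]: t["removed"] for t in report.trial_stages}
        for stage in ("missing", "incorrect", "too_fast", "too_slow", "trimming"):
            assert by_stage[stage] == 0
        assert report.n_analysed == 12

    def test_pipeline_idempotent_on_own_output(self, noisy_exp1_cohort):
        _, trials, meta = noisy_exp1_cohort
        clean, rep1 = sf.preprocess(trials, meta)
        # re-entering the cleaned trials: nothing further is removed
        clean2, rep2 = sf.preprocess(clean, meta)
        assert len(clean2) == len(clean)
        for t in rep2.trial_stages:
            assert t["removed"] == 0

    def test_report_counts_are_consistent(self, noisy_exp1_cohort):
        _, trials, meta = noisy_exp1_cohort
        clean, rep = sf.preprocess(trials, meta)
        total_removed = sum(t["removed"] for t in rep.trial_stages)
        n_from_analysed = clean["participant_id"].nunique()
        assert n_from_analysed == rep.n_analysed
        # entered(stage k+1) = entered(stage k) - removed(stage k)
        for prev, nxt in zip(rep.trial_stages, rep.trial_stages[1:]):
            assert nxt["entered"] == prev["entered"] - prev["removed"]
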