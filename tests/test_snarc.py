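"""dRT computation and the repeated-measures slope regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snarcflex as sf


def trials_for_cell(pid, range_id, number, left_rts, right_rts):
    rows = []
    for side, rts in (("left", left_rts), ("right", right_rts)):
        for rt in rts:
            rows.append({"participant_id": pid, "range_id": range_id,
                         "number": number, "response_side": side,
                         "rt_ms": float(rt)})
    return rows


def drt_frame(numbers, drts, pid="p", range_id="lower"):
    return pd.DataFrame({
        "participant_id": pid, "range_id": range_id,
        "number": list(numbers), "drt_ms": list(drts),
    })


class TestComputeDrt:
    def test_hand_computed_cell_means(self):
        rows = trials_for_cell("p", "lower", 2, [520, 530], [500, 510])
        drt = sf.compute_drt(pd.DataFrame(rows))
        assert drt.loc[0, "drt_ms"] == pytest.approx(-20.0)
        assert drt.loc[0, "mean_rt_left"] == pytest.approx(525.0)
        assert drt.loc[0, "n_left"] == 2 and drt.loc[0, "n_right"] == 2

    def test_side_relabel_negates_drt(self, noiseless_exp2_bundle):
        clean = noiseless_exp2_bundle["clean"]
        flipped = clean.assign(response_side=clean["response_side"].map(
            {"left": "right", "right": "left"}))
        a = sf.compute_drt(clean).set_index(["participant_id", "range_id", "number"])
        b = sf.compute_drt(flipped).set_index(["participant_id", "range_id", "number"])
        assert np.allclose(a["drt_ms"], -b["drt_ms"])

    def test_empty_cell_raises(self):
        rows = trials_for_cell("p", "lower", 2, [520], [])
        with pytest.raises(ValueError, match="empty"):
            sf.compute_drt(pd.DataFrame(rows))


class TestFitRegression:
    def test_exact_line(self):
        fit = sf.fit_participant_regression(
            drt_frame(range(6), [10, 5, 0, -5, -10, -15]))
        assert fit.slope == pytest.approx(-5.0)
        assert fit.intercept_at_zero == pytest.approx(10.0)
        assert fit.smallest_number_intercept == pytest.approx(10.0)
        assert fit.mean_number_intercept == pytest.approx(-2.5)
        assert fit.drt_4 == pytest.approx(-10.0)
        assert fit.drt_5 == pytest.approx(-15.0)

    def test_closed_form_normal_equations(self):
        # independent oracle: two-parameter OLS via the Sigma formulas
        x = np.array([4, 5, 7, 8], float)
        y = np.array([-4, -1, 2, 5], float)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert slope == pytest.approx(2.1)  # frozen from the formulas
        fit = sf.fit_participant_regression(drt_frame(x.astype(int), y))
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept_at_zero == pytest.approx(intercept, abs=1e-9)

    def test_constant_drt(self):
        fit = sf.fit_participant_regression(drt_frame([1, 2, 4, 5], [7.0] * 4))
        assert fit.slope == pytest.approx(0.0)
        assert fit.intercept_at_zero == pytest.approx(7.0)
        assert fit.smallest_number_intercept == pytest.approx(7.0)
        assert fit.mean_number_intercept == pytest.approx(7.0)

    def test_derived_intercepts_consistent(self, noiseless_exp2_bundle):
        fits = noiseless_exp2_bundle["fits"]
        for _, f in fits.iterrows():
            nums = np.array(f["numbers_used"])
            assert f["smallest_number_intercept"] == pytest.approx(
                f["intercept_at_zero"] + f["slope"] * nums.min(), abs=1e-9)
            assert f["mean_number_intercept"] == pytest.approx(
                f["intercept_at_zero"] + f["slope"] * nums.mean(), abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=4))
    def test_ols_matches_normal_equations(self, drts):
        x = np.array([1, 2, 4, 5], float)
        y = np.array(drts)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        fit = sf.fit_participant_regression(drt_frame([1, 2, 4, 5], drts))
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        # OLS passes through the centroid: predicted dRT at the mean
        # magnitude equals the mean observed dRT
        assert fit.mean_number_intercept == pytest.approx(y.mean(), abs=1e-9)

    def test_parity_regressor_orthogonal_in_exp2(self):
        # in the orthogonal stimulus sets, adding the parity contrast
        # never changes the magnitude coefficient
        rng = np.random.default_rng(5)
        for range_id, numbers in (("lower", [1, 2, 4, 5]), ("higher", [4, 5, 7, 8])):
            drts = rng.normal(0, 20, 4)
            plain = sf.fit_participant_regression(
                drt_frame(numbers, drts, range_id=range_id))
            joint = sf.fit_participant_regression(
                drt_frame(numbers, drts, range_id=range_id), include_parity=True)
            assert joint.slope == pytest.approx(plain.slope, abs=1e-9)
            assert joint.marc_coefficient is not None

    def test_single_magnitude_rejected(self):
        with pytest.raises(ValueError, match="2 distinct magnitudes"):
            sf.fit_participant_regression(drt_frame([4, 4], [1.0, 2.0]))

    def test_parity_only_fit(self):
        fit = sf.fit_participant_regression(
            drt_frame([1, 2, 4, 5], [-4.0, 4.0, 4.0, -4.0]), parity_only=True)
        assert fit.marc_coefficient == pytest.approx(8.0)


class TestRefitExcluding:
    def test_exclude_zero_reduces_range(self):
        line = [10 - 5 * m for m in range(6)]
        table = drt_frame(range(6), line)
        fits = sf.refit_excluding_numbers(table, [0])
        f = fits.iloc[0]
        assert f["numbers_used"] == (1, 2, 3, 4, 5)
        assert np.mean(f["numbers_used"]) == 3.0
        assert f["slope"] == pytest.approx(-5.0)

    def test_exclude_nothing_is_identity(self):
        table = drt_frame([1, 2, 4, 5], [3.0, -1.0, 2.0, 0.5])
        a = sf.fit_all(table).drop(columns="numbers_used")
        b = sf.refit_excluding_numbers(table, []).drop(columns="numbers_used")
        pd.testing.assert_frame_equal(a, b)

    def test_outlier_at_zero_distorts_then_restores_slope(self):
        # a clean line dRT = 10 - 5m with a deviant dRT at m = 0: the
        # full-set slope is biased, excluding 0 restores exactly -5
        drts = [60.0] + [10 - 5 * m for m in range(1, 6)]
        table = drt_frame(range(6), drts)
        full = sf.fit_all(table).iloc[0]
        assert full["slope"] != pytest.approx(-5.0, abs=0.5)
        reduced = sf.refit_excluding_numbers(table, [0]).iloc[0]
        assert reduced["slope"] == pytest.approx(-5.0, abs=1e-9)

    def test_too_few_magnitudes_left(self):
        table = drt_frame([1, 2, 4], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 magnitudes"):
            sf.refit_excluding_numbers(table, [1, 2])


class TestGroupEstimates:
    def test_two_participant_mean_sd(self):
        fits = pd.concat([
            sf.fit_all(drt_frame([1, 2, 4, 5], [0, -4, -12, -16], pid="a")),
            sf.fit_all(drt_frame([1, 2, 4, 5], [0, -6, -18, -24], pid="b")),
        ], ignore_index=True)
        g = sf.derive_group_estimates(fits)
        assert g.loc[0, "slope_mean"] == pytest.approx(-5.0)
        assert g.loc[0, "slope_std"] == pytest.approx(np.sqrt(2.0))

    def test_single_fit_per_range_rejected(self):
        fits = sf.fit_all(drt_frame([1, 2, 4, 5], [0, -4, -12, -16]))
        with pytest.raises(ValueError, match=">= 2 fits"):
            sf.derive_group_estimates(fits)

    def test_noiseless_cohort_recovers_generating_betas(self, noiseless_exp2_bundle):
        from conftest import cohort_true_params

        fits = noiseless_exp2_bundle["fits"]
        cohort = cohort_true_params(noiseless_exp2_bundle["params"], 12,
                                    noiseless_exp2_bundle["seed"])
        true = {(p.participant_id, rid): p.beta[rid]
                for p in cohort for rid in sf.RANGES}
        for _, f in fits.iterrows():
            assert f["slope"] == pytest.approx(
                true[(f["participant_id"], f["range_id"])], abs=1e-8)
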