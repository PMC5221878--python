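import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from qctlung import (
    CohortSimSpec,
    classify_agreement,
    cox_univariate,
    forward_conditional_logistic,
    group_compare,
    icc_agreement,
    reproduce_supplementary,
    roc_cindex,
    simulate_cohort,
    univariate_logistic,
)


class TestICC:
    def test_exact_agreement_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_agreement(x, x.copy())
        assert res.estimate("ICC") == pytest.approx(1.0, abs=1e-9)

    def test_variance_components_identity(self, rng):
        subj = rng.normal(0, 1, 500)
        x = subj + rng.normal(0, 1, 500)
        y = subj + rng.normal(0, 1, 500)
        res = icc_agreement(x, y)
        assert res.estimate("ICC") == pytest.approx(0.5, abs=0.05)
        lo, hi = res.table.iloc[0][["lo", "hi"]]
        assert lo <= res.estimate("ICC") <= hi

    def test_symmetric_and_shift_invariant(self, rng):
        subj = rng.normal(0, 2, 100)
        x = subj + rng.normal(0, 0.5, 100)
        y = subj + rng.normal(0, 0.5, 100)
        assert icc_agreement(x, y).estimate("ICC") == pytest.approx(
            icc_agreement(y, x).estimate("ICC"), abs=1e-9
        )
        assert icc_agreement(x + 10, y + 10).estimate("ICC") == pytest.approx(
            icc_agreement(x, y).estimate("ICC"), abs=1e-9
        )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="unequal"):
            icc_agreement([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="zero total variance"):
            icc_agreement([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestAgreementBands:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.98, "excellent"),
            (0.81, "excellent"),
            (0.80, "substantial"),
            (0.61, "substantial"),
            (0.60, "moderate"),
            (0.53, "moderate"),
            (0.40, "fair"),
            (0.21, "fair"),
            (0.20, "poor"),
            (-0.3, "poor"),
        ],
    )
    def test_band_boundaries_as_printed(self, icc, band):
        assert classify_agreement(icc) == band


class TestUnivariateLogistic:
    def test_null_predictor_gives_or_near_one(self, rng):
        df = pd.DataFrame(
            {"x": rng.normal(0, 1, 2000), "recurrence": rng.integers(0, 2, 2000)}
        )
        res = univariate_logistic(df, "x")
        row = res.table.iloc[1]
        assert row["lo"] <= 1.0 <= row["hi"]
        assert row["estimate"] == pytest.approx(1.0, abs=0.15)

    def test_doubling_scale_squares_the_or(self, rng):
        x = rng.normal(0, 1, 500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
        df = pd.DataFrame({"x": x, "recurrence": y})
        or1 = univariate_logistic(df, "x", scale=1.0).table.iloc[1]["estimate"]
        or2 = univariate_logistic(df, "x", scale=2.0).table.iloc[1]["estimate"]
        assert or2 == pytest.approx(or1**2, rel=1e-9)

    def test_complete_separation_raises(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "recurrence": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        with pytest.raises(ValueError, match="separation|converge"):
            univariate_logistic(df, "x")

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "recurrence": [0, 0]})
        with pytest.raises(ValueError, match="single class"):
            univariate_logistic(df, "x")


class TestForwardConditional:
    def test_empty_candidates_yield_intercept_only(self, rng):
        df = pd.DataFrame({"recurrence": rng.integers(0, 2, 50)})
        res = forward_conditional_logistic(df, [])
        assert res.extras["selected"] == []
        assert any("intercept-only" in n for n in res.notes)

    def test_informative_candidate_selected_noise_not(self):
        hits, false_hits = 0, 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            n = 1000
            x = rng.normal(0, 1, (n, 6))
            lp = math.log(2.0) * x[:, 0] - 1.5
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
            df = pd.DataFrame({f"x{i}": x[:, i] for i in range(6)})
            df["recurrence"] = y
            res = forward_conditional_logistic(df, [f"x{i}" for i in range(6)])
            sel = res.extras["selected"]
            hits += "x0" in sel
            false_hits += len(set(sel) - {"x0"}) > 0
        assert hits >= 0.95 * n_rep
        assert false_hits <= 0.25 * n_rep  # ~5% per noise term under the score test

    def test_selection_trace_is_reproducible_and_ordered(self):
        cohort = simulate_cohort(CohortSimSpec(n=2000, seed=3))
        cands = ["area_mm2_1mm", "mean_attenuation_hu_1mm", "entropy_bits_1mm"]
        r1 = forward_conditional_logistic(cohort, cands)
        r2 = forward_conditional_logistic(cohort, cands)
        assert [t["term"] for t in r1.trace] == [t["term"] for t in r2.trace]
        assert all(t["action"] == "enter" for t in r1.trace[:1])

    def test_recovers_design_effects_on_large_cohort(self):
        cohort = simulate_cohort(CohortSimSpec(n=4000, seed=12))
        res = forward_conditional_logistic(
            cohort,
            ["area_mm2_1mm", "mean_attenuation_hu_1mm",
             "skewness_1mm", "entropy_bits_1mm"],
        )
        assert set(res.extras["selected"]) == {"area_mm2_1mm", "mean_attenuation_hu_1mm"}
        area_or = res.estimate("area_mm2_1mm")
        att_or = res.estimate("mean_attenuation_hu_1mm")
        assert area_or == pytest.approx(1.002, abs=0.002)
        assert att_or == pytest.approx(1.005, abs=0.004)


class TestRocCindex:
    def test_perfect_separation_gives_auc_one(self):
        res = roc_cindex([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.estimate("AUC") == 1.0

    def test_null_scores_give_auc_half(self, rng):
        res = roc_cindex(rng.normal(0, 1, 2000), rng.integers(0, 2, 2000))
        assert res.estimate("AUC") == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_concordant_pair_fraction(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            y = np.zeros(n, dtype=int)
            y[: max(1, n // 4)] = 1
            rng.shuffle(y)
            s = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]
            ).sum()
            oracle = pairs / (len(pos) * len(neg))
            assert roc_cindex(s, y).estimate("AUC") == pytest.approx(oracle, abs=1e-12)

    def test_two_variable_model_auc_not_below_single(self):
        cohort = simulate_cohort(CohortSimSpec(n=1000, seed=21))
        y = cohort["recurrence"]
        full = forward_conditional_logistic(
            cohort, ["area_mm2_1mm", "mean_attenuation_hu_1mm"], p_enter=1.0
        )
        auc_full = roc_cindex(full.extras["linear_predictor"], y).estimate("AUC")
        for single in ("area_mm2_1mm", "mean_attenuation_hu_1mm"):
            auc_one = roc_cindex(cohort[single], y).estimate("AUC")
            assert auc_full >= auc_one - 0.005

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_cindex([0.1, 0.2], [1, 1])


class TestGroupCompare:
    def test_identical_numeric_groups_give_t_zero(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0] * 2, "recurrence": [0, 0, 0, 1, 1, 1]})
        res = group_compare(df, "v")
        assert res.test == "t" and res.statistic == pytest.approx(0.0)

    def test_two_by_two_chi_square_matches_closed_form(self):
        # contingency of stage (1 vs 2) by recurrence: 156,13 / 19,6
        rows = (["stage1"] * 156 + ["stage2"] * 13) + (["stage1"] * 19 + ["stage2"] * 6)
        rec = [0] * 169 + [1] * 25
        df = pd.DataFrame({"stage": rows, "recurrence": rec})
        res = group_compare(df, "stage", exact="never")
        # closed form n(ad-bc)^2 / (row1 row2 col1 col2)
        a, b, c, d = 156, 19, 13, 6
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + c) * (b + d) * (a + b) * (c + d))
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(6.56, abs=0.01)
        assert round(res.p, 2) == 0.01

    def test_label_swap_leaves_p_unchanged(self, rng):
        df = pd.DataFrame(
            {"v": rng.normal(0, 1, 60), "recurrence": rng.integers(0, 2, 60)}
        )
        p1 = group_compare(df, "v").p
        df2 = df.assign(recurrence=1 - df["recurrence"])
        assert group_compare(df2, "v").p == pytest.approx(p1, abs=1e-12)

    def test_fisher_used_for_sparse_2x2(self):
        df = pd.DataFrame(
            {"flag": [1, 0, 0, 0, 0, 0, 1, 1, 0, 0],
             "recurrence": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]}
        )
        assert group_compare(df, "flag").test == "fisher"

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"v": [1.0, np.nan], "recurrence": [0, 1]})
        with pytest.raises(ValueError, match="empty group"):
            group_compare(df, "v")


def partial_likelihood_oracle(times, events, x, beta):
    """Enumerated Cox partial log-likelihood for distinct event times."""
    ll = 0.0
    for i in np.argsort(times):
        if not events[i]:
            continue
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxUnivariate:
    def test_null_predictor_hr_near_one(self, rng):
        n = 2000
        t = rng.exponential(1.0, n)
        c = rng.exponential(2.0, n)
        df = pd.DataFrame(
            {"time_to_event_years": np.minimum(t, c),
             "event_observed": (t <= c).astype(int),
             "x": rng.normal(0, 1, n)}
        )
        res = cox_univariate(df, "x")
        row = res.table.iloc[0]
        assert row["lo"] <= 1.0 <= row["hi"]
        assert row["estimate"] == pytest.approx(1.0, abs=0.1)

    def test_recovers_log_hazard_within_ci(self, rng):
        n = 1000
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / np.exp(0.7 * x))
        c = np.quantile(t, 0.7) * np.ones(n)  # ~30% censoring
        df = pd.DataFrame(
            {"time_to_event_years": np.minimum(t, c),
             "event_observed": (t <= c).astype(int), "x": x}
        )
        row = cox_univariate(df, "x").table.iloc[0]
        assert row["lo"] <= math.exp(0.7) <= row["hi"]

    def test_matches_enumerated_partial_likelihood(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        df = pd.DataFrame({"time_to_event_years": times, "event_observed": events,
                           "x": x})
        fit = cox_univariate(df, "x")
        opt = minimize_scalar(
            lambda b: -partial_likelihood_oracle(times, events, x, b),
            bounds=(-5, 5), method="bounded",
        )
        assert fit.extras["coef"] == pytest.approx(opt.x, abs=1e-3)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_to_event_years": [1.0, 2.0],
                           "event_observed": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="no observed events"):
            cox_univariate(df, "x")


class TestReproduceSupplementary:
    def test_runs_headline_analyses_on_cohort_export(self, tmp_path):
        # synthetic stand-in for a per-patient spreadsheet export
        cohort = simulate_cohort(CohortSimSpec(n=600, seed=42))
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path, index=False)
        out = reproduce_supplementary(str(path))
        assert out["n"] == 600
        assert out["recurrence_count"] == int(cohort["recurrence"].sum())
        assert out["icc_diameter"] == pytest.approx(0.98, abs=0.03)
        assert out["or_diameter_per_mm"] > 1.0
        assert "c_index" in out or out["selected"] == []

    def test_column_mapping_renames_source_columns(self):
        cohort = simulate_cohort(CohortSimSpec(n=300, seed=9))
        renamed = cohort.rename(columns={"recurrence": "Recur", "diameter_mm_1mm": "D1"})
        out = reproduce_supplementary(
            renamed, column_map={"Recur": "recurrence", "D1": "diameter_mm_1mm"}
        )
        assert out["recurrence_count"] == int(cohort["recurrence"].sum())
        assert "or_diameter_per_mm" in out
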