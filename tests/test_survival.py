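"""Survival tables, Cox fitting, concordance, FDR, rank tests, landmark."""

import numpy as np
import pandas as pd
import pytest

from hnqi.phantom import CohortSpec, simulate_cohort
from hnqi.survival import (
    CoxSpec,
    bh_fdr,
    build_dffs,
    build_itffr,
    concordance,
    cox_partial_loglik,
    fit_cox,
    landmark_groups,
    rank_test,
)


class TestBuildITFFR:
    def test_censored_at_distant_failure(self, outcome_frame):
        tab = build_itffr(outcome_frame).set_index("unit_id")
        row = tab.loc["P1_T0"]  # DF at 6, no progression, follow-up 24
        assert row["event"] == 0 and row["time"] == 6.0

    def test_event_when_progression_precedes_df(self, outcome_frame):
        tab = build_itffr(outcome_frame).set_index("unit_id")
        row = tab.loc["P2_T0"]  # LF at 10, DF at 14
        assert row["event"] == 1 and row["time"] == 10.0

    def test_censored_at_death(self, outcome_frame):
        tab = build_itffr(outcome_frame).set_index("unit_id")
        row = tab.loc["P7_T0"]
        assert row["event"] == 0 and row["time"] == 9.0

    def test_row_count_equals_tumor_count(self):
        sim = simulate_cohort(CohortSpec(n_patients=54, betas={}, seed=4))
        tab = build_itffr(sim)
        assert len(tab) == len(sim)
        assert set(tab["unit_id"]) == set(sim["tumor_id"])

    def test_no_time_exceeds_patient_censoring_bound(self):
        # censoring correctness: every row's time <= min(DF, death, follow-up)
        sim = simulate_cohort(CohortSpec(n_patients=80, betas={}, seed=9))
        tab = build_itffr(sim)
        bound = sim[["df_time", "death_time", "last_followup"]].min(axis=1, skipna=True)
        assert np.all(tab["time"].to_numpy() <= bound.to_numpy() + 1e-12)

    def test_missing_followup_dropped_with_warning(self, outcome_frame):
        df = outcome_frame.copy()
        df.loc[0, "last_followup"] = np.nan
        with pytest.warns(UserWarning, match="without follow-up"):
            tab = build_itffr(df)
        assert "P1_T0" not in set(tab["unit_id"])


class TestBuildDFFS:
    def test_distant_failure_is_event(self, outcome_frame):
        tab = build_dffs(outcome_frame).set_index("unit_id")
        row = tab.loc["P1"]  # DF at 6 before anything else
        assert row["event"] == 1 and row["time"] == 6.0

    def test_censored_at_preceding_locoregional_failure(self, outcome_frame):
        tab = build_dffs(outcome_frame).set_index("unit_id")
        row = tab.loc["P4"]  # RF at 8, DF at 12: LRF precedes
        assert row["event"] == 0 and row["time"] == 8.0

    def test_no_events_censored_at_followup(self, outcome_frame):
        tab = build_dffs(outcome_frame).set_index("unit_id")
        row = tab.loc["P3"]
        assert row["event"] == 0 and row["time"] == 24.0


def bruteforce_cox_coef(table, grid):
    """Independent oracle: exhaustive search of the written-out Breslow
    partial likelihood over a coefficient grid (single covariate)."""
    t = table["time"].to_numpy(float)
    e = table["event"].to_numpy(int)
    x = table["x"].to_numpy(float)
    best, best_ll = None, -np.inf
    for b in grid:
        ll = 0.0
        for i in np.where(e == 1)[0]:
            risk = t >= t[i]
            ll += b * x[i] - np.log(np.exp(b * x[risk]).sum())
        if ll > best_ll:
            best, best_ll = b, ll
    return best


class TestFitCox:
    def test_six_row_table_matches_bruteforce_grid(self):
        tab = pd.DataFrame(
            {"time": [1, 2, 3, 4, 5, 6], "event": [1, 1, 0, 1, 0, 1],
             "x": [1, 0, 1, 1, 0, 0]}
        )
        oracle = bruteforce_cox_coef(tab, np.arange(-5, 5, 1e-4))
        fit = fit_cox(tab, CoxSpec(covariates=["x"]))
        assert fit.converged
        assert abs(fit.coef("x") - oracle) < 1e-3

    def test_partial_loglik_consistent_with_oracle_formula(self):
        tab = pd.DataFrame(
            {"time": [2, 4, 4, 7, 9], "event": [1, 1, 1, 0, 1], "x": [1, 0, 1, 0, 1]}
        )
        t = tab["time"].to_numpy(float)
        e = tab["event"].to_numpy(int)
        x = tab[["x"]].to_numpy(float)
        for b in (-1.0, 0.0, 0.7):
            manual = 0.0
            for i in np.where(e == 1)[0]:
                risk = t >= t[i]
                manual += b * x[i, 0] - np.log(np.exp(b * x[risk, 0]).sum())
            assert cox_partial_loglik(np.array([b]), x, t, e) == pytest.approx(manual)

    def test_hr_is_exp_of_coef(self):
        rng = np.random.default_rng(2)
        n = 80
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (0.1 * np.exp(0.6 * x)))
        tab = pd.DataFrame({"time": t, "event": 1, "x": x})
        fit = fit_cox(tab, CoxSpec(covariates=["x"]))
        assert fit.hr("x") == pytest.approx(np.exp(fit.coef("x")), rel=1e-12)
        lo, hi = fit.summary.loc["x", ["ci95_lo", "ci95_hi"]]
        assert lo < fit.hr("x") < hi

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(0)
        n = 120
        x1, x2 = rng.standard_normal(n), rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.5 * x1 - 0.8 * x2)))
        c = rng.uniform(0, 15, n)
        tab = pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x1": x1, "x2": x2}
        )
        fit = fit_cox(tab, CoxSpec(covariates=["x1", "x2"]))
        ll = CoxPHFitter().fit(tab, "time", "event")
        for name in ("x1", "x2"):
            assert fit.coef(name) == pytest.approx(ll.summary.loc[name, "coef"], abs=1e-5)
            assert fit.summary.loc[name, "se"] == pytest.approx(
                ll.summary.loc[name, "se(coef)"], abs=1e-5
            )
        assert fit.c_index == pytest.approx(ll.concordance_index_, abs=1e-12)

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(1)
        n = 100
        x = rng.standard_normal(n)
        t = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.5 * x))))  # heavy ties
        tab = pd.DataFrame({"time": t, "event": 1, "x": x})
        fit = fit_cox(tab, CoxSpec(covariates=["x"], ties="efron"))
        ll = CoxPHFitter().fit(tab, "time", "event")  # lifelines uses Efron
        assert fit.coef("x") == pytest.approx(ll.summary.loc["x", "coef"], abs=1e-5)

    def test_constant_covariate_not_identifiable(self):
        tab = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 0], "x": [1, 1, 1, 1]})
        fit = fit_cox(tab, CoxSpec(covariates=["x"]))
        assert not fit.converged
        assert "zero-variance" in fit.message

    def test_per_sd_scaling_scales_coefficient(self):
        rng = np.random.default_rng(3)
        n = 150
        x = rng.standard_normal(n) * 3.0
        t = rng.exponential(1 / (0.1 * np.exp(0.2 * x)))
        tab = pd.DataFrame({"time": t, "event": 1, "x": x})
        raw = fit_cox(tab, CoxSpec(covariates=["x"]))
        per_sd = fit_cox(tab, CoxSpec(covariates=["x"], per_sd=frozenset({"x"})))
        sd = np.std(x, ddof=1)
        assert per_sd.coef("x") == pytest.approx(raw.coef("x") * sd, rel=1e-6)

    def test_interaction_group_effects(self):
        # effect of x in group g=1 must equal beta_x + beta_interaction
        rng = np.random.default_rng(4)
        n = 300
        x = rng.standard_normal(n)
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.7 * x * g - 0.5 * g)))
        tab = pd.DataFrame({"time": t, "event": 1, "x": x, "g": g})
        fit = fit_cox(tab, CoxSpec(covariates=["x", "g"], interactions=[("x", "g")]))
        ge = fit.group_effects
        assert ge.loc["x | g=0", "coef"] == pytest.approx(fit.coef("x"))
        assert ge.loc["x | g=1", "coef"] == pytest.approx(
            fit.coef("x") + fit.coef("x:g")
        )

    def test_cluster_robust_summary_present_and_positive(self):
        sim = simulate_cohort(CohortSpec(n_patients=60, betas={"p16": -1.0}, seed=6))
        tab = build_itffr(sim).merge(
            sim[["tumor_id", "p16"]], left_on="unit_id", right_on="tumor_id"
        )
        fit = fit_cox(tab, CoxSpec(covariates=["p16"], cluster_col="patient_id"))
        assert fit.robust_summary is not None
        assert fit.robust_summary.loc["p16", "se"] > 0
        # coefficients identical, only the SE changes
        assert fit.robust_summary.loc["p16", "coef"] == fit.summary.loc["p16", "coef"]


class TestConcordance:
    def test_perfect_risk_ordering(self):
        t = np.array([1.0, 2, 3, 4])
        assert concordance(t, [1, 1, 1, 1], [4.0, 3, 2, 1]) == 1.0

    def test_independent_risk_near_half(self):
        rng = np.random.default_rng(0)
        n = 400
        t = rng.exponential(1, n)
        assert concordance(t, np.ones(n), rng.standard_normal(n)) == pytest.approx(0.5, abs=0.05)

    def test_four_row_table_matches_pair_enumeration(self):
        t = np.array([2.0, 5.0, 3.0, 8.0])
        e = np.array([1, 0, 1, 1])
        r = np.array([0.9, 0.1, 0.5, 0.2])
        # exhaustive usable pairs, counted by hand in code
        num = den = 0.0
        for i in range(4):
            for j in range(4):
                if i == j or e[i] != 1 or t[j] <= t[i]:
                    continue
                den += 1
                num += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
        assert concordance(t, e, r) == pytest.approx(num / den)


class TestBHFDR:
    def test_single_p_unchanged(self):
        adj, sig = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert sig[0]

    def test_hand_computation(self):
        # {0.01, 0.02, 0.04, 0.8} -> {0.04, 0.04, 0.0533, 0.8}
        adj, _ = bh_fdr([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.8], rtol=1e-10)

    def test_all_equal_stay_equal(self):
        adj, _ = bh_fdr([0.2, 0.2, 0.2])
        np.testing.assert_allclose(adj, 0.2)

    def test_monotone_and_never_below_raw(self):
        p = np.array([0.001, 0.01, 0.02, 0.3, 0.6, 0.9])
        adj, _ = bh_fdr(p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)
        assert np.all(adj >= p)

    def test_flags_stable_under_readjustment(self):
        # re-running the step-up on already-adjusted values inflates the
        # numbers but must not flip the decisions on this reference list
        p = [0.01, 0.02, 0.04, 0.8]
        adj, sig = bh_fdr(p)
        _, sig2 = bh_fdr(adj)
        np.testing.assert_array_equal(sig, sig2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRankTests:
    def test_identical_groups(self):
        _, p = rank_test([[1, 2, 3, 4], [1, 2, 3, 4]], "mann_whitney")
        assert p > 0.9
        stat, _ = rank_test([[1, 2, 3], [1, 2, 3], [1, 2, 3]], "kruskal_wallis")
        assert stat == pytest.approx(0.0)

    def test_separated_groups_exact_enumeration(self):
        # {1,2,3} vs {4,5,6}: U = 0; only 2 of the C(6,3)=20 arrangements are
        # as extreme two-sided, p = 0.1
        u, p = rank_test([[1, 2, 3], [4, 5, 6]], "mann_whitney")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_wilcoxon_rank_alias_two_sample(self):
        u, p = rank_test([[1, 2, 3], [4, 5, 6]], "wilcoxon_rank")
        assert p == pytest.approx(0.1)

    def test_exact_vs_asymptotic_agree_for_n8(self):
        from scipy import stats as ss

        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(50):
            x, y = rng.standard_normal(8), rng.standard_normal(8) + 0.5
            _, p_exact = rank_test([x, y], "mann_whitney")
            p_asym = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            worst = max(worst, abs(p_exact - p_asym))
        assert worst < 0.02

    def test_validation(self):
        with pytest.raises(ValueError):
            rank_test([[1, 2], []], "mann_whitney")
        with pytest.raises(ValueError):
            rank_test([[1], [2]], "kruskal_wallis")
        with pytest.raises(ValueError):
            rank_test([[1], [2]], "median_test")


class TestLandmarkGroups:
    def test_all_branches(self, outcome_frame):
        groups = landmark_groups(outcome_frame, cutoff=18.0).set_index("tumor_id")["group"]
        assert groups["P2_T0"] == "LF"  # LF at 10 <= 18
        assert groups["P4_T0"] == "RF"  # nodal progression at 8
        assert groups["P5_T0"] == "excluded"  # progression after 18 months
        assert groups["P6_T0"] == "excluded"  # follow-up shorter than 18
        assert groups["P1_T0"] == "DF"  # controlled locally, DF at 6
        assert groups["P3_T0"] == "NED"  # no progression, follow-up 24
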