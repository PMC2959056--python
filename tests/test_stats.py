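"""ROC, diagnostics, GEE, model building, kappa, group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from lgeviab import (
    cohens_kappa,
    diagnostics_from_prevalence,
    gee_logistic,
    group_compare,
    model_building,
    roc_threshold,
)


def brute_force_auc(scores, labels):
    """Exhaustive positive x negative pair counting; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        scores = [12, 13, 14, 15, 4, 5, 6]
        labels = [1, 1, 1, 1, 0, 0, 0]
        res = roc_threshold(scores, labels)
        assert res.auc == 1.0
        assert 7 <= res.threshold <= 12
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_all_tied_scores_give_auc_half(self):
        res = roc_threshold([8] * 10, [1] * 5 + [0] * 5)
        assert res.auc == 0.5

    def test_auc_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 17, 40)
        labels = np.concatenate([np.ones(22, bool), np.zeros(18, bool)])
        # make positives stochastically larger so the fixture is realistic
        scores = np.sort(scores)[np.argsort(np.argsort(labels * 8 + rng.random(40)))]
        res = roc_threshold(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_curve_trapezoid_equals_pair_counting(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 17, 50)
        labels = rng.random(50) < 1 / (1 + np.exp(-(scores - 8.0)))
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        res = roc_threshold(scores, labels)
        fpr = 1.0 - res.spec_curve
        order = np.lexsort((res.sens_curve, fpr))  # staircase: ties sorted by sens
        auc_trap = float(np.trapezoid(res.sens_curve[order], fpr[order]))
        assert auc_trap == pytest.approx(res.auc, abs=1e-12)

    def test_one_class_absent_is_an_error(self):
        with pytest.raises(ValueError):
            roc_threshold([1, 2, 3], [1, 1, 1])

    def test_tie_break_prefers_higher_sensitivity(self):
        # two thresholds share the maximal J; the more sensitive one wins
        scores = [10, 11, 12, 9, 5, 6]
        labels = [1, 1, 1, 1, 0, 0]
        res = roc_threshold(scores, labels)
        assert res.sensitivity == 1.0
        assert res.threshold <= 9

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = rng.integers(0, 17, n)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        res = roc_threshold(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


class TestDiagnostics:
    def test_perfect_test(self):
        assert diagnostics_from_prevalence(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_uninformative_test(self):
        ppv, npv = diagnostics_from_prevalence(0.5, 0.5, 0.5)
        assert ppv == npv == 0.5

    def test_printed_predictive_values(self):
        ppv, npv = diagnostics_from_prevalence(0.95, 0.75, 21 / 33)
        assert round(100 * ppv) == 87
        assert round(100 * npv) == 90  # 89.6; the printed 89 rounds 0.8955 down

    def test_agrees_with_direct_2x2_counting(self):
        tp, fp, fn, tn = 20, 3, 1, 9
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        pi = (tp + fn) / (tp + fp + fn + tn)
        ppv, npv = diagnostics_from_prevalence(sens, spec, pi)
        assert ppv == pytest.approx(tp / (tp + fp))
        assert npv == pytest.approx(tn / (tn + fn))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diagnostics_from_prevalence(1.2, 0.5, 0.5)


class TestGEE:
    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(4)
        n_pat, n_seg = 120, 8
        df = pd.DataFrame(
            {
                "patient_id": np.repeat(np.arange(n_pat), n_seg),
                "segment": np.tile(np.arange(1, n_seg + 1), n_pat),
                "grade": rng.integers(0, 5, n_pat * n_seg),
                "recovered": rng.random(n_pat * n_seg) < 0.5,
            }
        )
        fit = gee_logistic(df, working_corr="ar1")
        assert fit.converged
        assert abs(fit.params["grade"]) < 2 * fit.bse["grade"]

    def test_singleton_clusters_match_plain_logistic(self):
        rng = np.random.default_rng(0)
        n = 400
        x = rng.integers(0, 5, n).astype(float)
        p = 1 / (1 + np.exp(-(0.8 - 0.7 * x)))
        y = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"patient_id": np.arange(n), "segment": 1, "grade": x, "recovered": y})
        fit = gee_logistic(df, working_corr="independence")
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.params["grade"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.params["const"] == pytest.approx(ref.params[0], abs=1e-6)

    def test_monotone_cohort_yields_negative_grade_effect(self, large_cohort):
        _, segs = large_cohort
        dys = segs[segs["dysfunctional"]]
        fit = gee_logistic(dys, working_corr="ar1")
        assert fit.converged
        assert fit.params["grade"] < 0
        assert fit.pvalues["grade"] < 0.001

    def test_adjusted_model_accepts_covariates(self, large_cohort):
        pats, segs = large_cohort
        dys = segs[segs["dysfunctional"]].merge(
            pats[["patient_id", "ef_pre", "esvi_pre", "onbeat", "scar_mass_g"]], on="patient_id"
        )
        fit = gee_logistic(
            dys, working_corr="ar1", covariates=("ef_pre", "esvi_pre", "onbeat", "scar_mass_g")
        )
        assert fit.converged
        assert set(fit.params) >= {"grade", "ef_pre", "esvi_pre", "onbeat", "scar_mass_g"}

    def test_separation_reported_not_raised(self):
        df = pd.DataFrame(
            {
                "patient_id": np.repeat(np.arange(10), 4),
                "segment": np.tile(np.arange(1, 5), 10),
                "grade": np.tile([0, 1, 3, 4], 10),
                "recovered": np.tile([1, 1, 0, 0], 10),  # perfectly separated
            }
        )
        fit = gee_logistic(df, working_corr="independence")
        assert not fit.converged
        assert fit.diagnostic


class TestModelBuilding:
    def test_noise_free_outcome_recovers_only_the_true_variable(self):
        rng = np.random.default_rng(6)
        n = 60
        df = pd.DataFrame(
            {
                "n_viable_normal": rng.integers(3, 16, n).astype(float),
                "noise_a": rng.normal(size=n),
                "noise_b": rng.normal(size=n),
            }
        )
        df["delta_ef"] = -10.0 + 1.5 * df["n_viable_normal"]
        screen, multi = model_building(df, ("n_viable_normal", "noise_a", "noise_b"))
        kept = screen.loc[screen["retained"], "variable"].tolist()
        assert kept == ["n_viable_normal"]
        assert multi.params["n_viable_normal"] == pytest.approx(1.5, abs=1e-9)
        assert multi.params["const"] == pytest.approx(-10.0, abs=1e-7)

    def test_null_variables_are_retained_at_the_screen_rate(self):
        # the p < 0.1 screen keeps a null variable ~10% of the time
        rng = np.random.default_rng(7)
        n, reps, k = 40, 400, 3
        kept = 0
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
            df["delta_ef"] = rng.normal(size=n)
            screen, _ = model_building(df, tuple(f"x{i}" for i in range(k)))
            kept += int(screen["retained"].sum())
        rate = kept / (reps * k)
        se = np.sqrt(0.1 * 0.9 / (reps * k))
        assert rate == pytest.approx(0.1, abs=4 * se)

    def test_screen_table_has_univariate_and_multivariate_columns(self, demo_cohort):
        pats, segs = demo_cohort
        from lgeviab.function import patient_counts, score_segments

        counts = patient_counts(score_segments(segs))
        merged = pats.merge(counts, on="patient_id", suffixes=("_gen", ""))
        screen, multi = model_building(
            merged, ("n_viable_normal", "n_viable", "scar_mass_g", "ef_pre")
        )
        assert {"variable", "r", "slope", "p", "retained"} <= set(screen.columns)
        assert screen.loc[screen["variable"] == "n_viable_normal", "retained"].item()
        assert multi is not None and "n_viable_normal" in multi.params


class TestKappa:
    def test_identical_raters(self):
        g = np.array([0, 1, 2, 3, 4, 2, 1])
        assert cohens_kappa(g, g) == 1.0

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 5, 4000)
        b = rng.integers(0, 5, 4000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_2x2_hand_arithmetic(self):
        # table (20, 5; 10, 15): p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert cohens_kappa(a, b) == pytest.approx((0.7 - 0.5) / 0.5)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(9)
        a = rng.integers(0, 5, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 5, 200))
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_single_category_is_undefined(self):
        with pytest.raises(ValueError):
            cohens_kappa([2, 2, 2], [2, 2, 2])


class TestGroupCompare:
    def test_identical_paired_vectors(self):
        res = group_compare([1.0, 2.0, 3.0], pairs=[1.0, 2.0, 3.0], kind="paired_t")
        assert (res.statistic, res.p) == (0.0, 1.0)

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = group_compare(x, pairs=y, kind="paired_t")
        t, p = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t) and res.p == pytest.approx(p)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[8, 2], [1, 9]])
        res = group_compare(table, kind="dichotomous")
        assert res.test == "fisher_exact"  # min expected cell 4.5 < 5
        # two-sided Fisher p: sum of hypergeometric probabilities <= observed
        m = sps.hypergeom(20, 10, 9)  # N, successes (row1 total), draws (col1 total)
        p_obs = m.pmf(8)
        p_exact = sum(m.pmf(k) for k in range(0, 10) if m.pmf(k) <= p_obs + 1e-12)
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_chi2_used_when_cells_are_large(self):
        res = group_compare(np.array([[30, 10], [12, 28]]), kind="dichotomous")
        assert res.test == "chi2"

    def test_mann_whitney_on_fully_separated_samples(self):
        x, y = [10, 11, 12, 13], [1, 2, 3]
        res = group_compare(x, groups=y, kind="mann_whitney")
        # exact two-sided minimum for n=4, m=3: 2 / C(7,3)
        assert res.p == pytest.approx(2 / 35)

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            group_compare([1.0], pairs=[2.0], kind="paired_t")
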