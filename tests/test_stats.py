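"""Descriptive tests, Box-Cox, mixed models, LR tests, FDR, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import dfnckit as dk
from dfnckit import stats as lstats


def _lmm_table(rng, n_subjects, beta_age=0.0, beta_sex=0.0, beta_int=0.0,
               sd_u=0.5, sd_e=0.5, outcome="y"):
    """Generate a two-visit outcome table directly from the LMM generative model."""
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, sd_u)
        sex = "F" if rng.random() < 0.5 else "M"
        female = sex == "F"
        for visit, age in ((1, rng.normal(10.1, 0.6)), (2, rng.normal(13.9, 0.5))):
            age_c = age - 10.1
            y = (2.0 + beta_age * age_c + beta_sex * female
                 + beta_int * age_c * female + u + rng.normal(0, sd_e))
            rows.append((f"s{i}", visit, age, sex, outcome, y))
    df = pd.DataFrame(rows, columns=["subject_id", "visit", "age", "sex",
                                     "outcome", "value"])
    return lstats.make_outcome_table(df)


class TestDescriptiveTests:
    def test_identical_paired_values_degenerate(self):
        rows = []
        for i in range(6):
            for v in (1, 2):
                rows.append((f"s{i}", v, 10.0 + 4 * (v - 1), "M", "y", 1.0 * i))
        table = lstats.make_outcome_table(
            pd.DataFrame(rows, columns=["subject_id", "visit", "age", "sex",
                                        "outcome", "value"])
        )
        out = lstats.descriptive_tests(table)
        row = out[out["comparison"] == "visit_signed_rank"].iloc[0]
        assert row["p_value"] == 1.0 and np.isnan(row["statistic"])

    def test_separated_groups_reach_minimum_rank_sum(self):
        rows = []
        for i in range(5):
            rows.append((f"f{i}", 1, 10.0, "F", "y", float(i)))  # ranks 1..5
            rows.append((f"m{i}", 1, 10.0, "M", "y", 10.0 + i))
        table = lstats.make_outcome_table(
            pd.DataFrame(rows, columns=["subject_id", "visit", "age", "sex",
                                        "outcome", "value"])
        )
        out = lstats.descriptive_tests(table)
        row = out[out["comparison"] == "sex_rank_sum_visit1"].iloc[0]
        assert row["statistic"] == 15.0  # 1+2+3+4+5

    def test_rank_sum_invariant_under_label_shuffle_null(self):
        # exhaustive check at n=3 vs 3: the null distribution of the rank-sum
        # statistic is symmetric under exchanging group labels
        import itertools

        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        stats_fwd, stats_rev = [], []
        for combo in itertools.combinations(range(6), 3):
            g1 = [vals[i] for i in combo]
            g2 = [vals[i] for i in range(6) if i not in combo]
            u1 = sps.mannwhitneyu(g1, g2, alternative="two-sided").statistic
            u2 = sps.mannwhitneyu(g2, g1, alternative="two-sided").statistic
            stats_fwd.append(u1)
            stats_rev.append(u2)
        assert sorted(stats_fwd) == sorted(stats_rev)


class TestBoxCox:
    def test_lambda_one_is_location_shift(self):
        y = np.array([1.0, 2.0, 5.0])
        spec = lstats.TransformSpec(lambda_bc=1.0, offset=0.0, loglik=0.0)
        assert np.allclose(spec.transform(y), y - 1.0)

    def test_lognormal_data_fits_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(0, 0.5, size=5000))
        spec, _ = lstats.boxcox_fit(y)
        assert abs(spec.lambda_bc) < 0.1

    def test_round_trip_inverse(self, rng):
        y = rng.uniform(0.5, 20.0, size=100)
        spec, t = lstats.boxcox_fit(y)
        assert np.allclose(spec.inverse(t), y, atol=1e-10)

    def test_offset_applied_for_zero_values(self):
        y = np.r_[0.0, np.random.default_rng(1).uniform(1, 10, 50)]
        spec, t = lstats.boxcox_fit(y)
        assert spec.offset == 1.0
        assert np.isfinite(t).all()

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            lstats.boxcox_fit(np.full(10, 3.0))

    def test_matches_scipy_profile_likelihood(self, rng):
        y = rng.gamma(2.0, 2.0, size=800) + 0.1
        spec, _ = lstats.boxcox_fit(y)
        lam_scipy = sps.boxcox(y)[1]
        assert abs(spec.lambda_bc - lam_scipy) <= 0.02  # grid resolution


class TestFitLME:
    def test_matches_ols_when_no_random_variance(self):
        rng = np.random.default_rng(3)
        table = _lmm_table(rng, 150, beta_age=0.3, beta_sex=0.2, sd_u=0.0, sd_e=1.0)
        fit = lstats.fit_lme(table, "y", ("age", "sex"))
        import statsmodels.formula.api as smf

        ols = smf.ols("value ~ age_c + female", data=fit.data).fit()
        tab = fit.fixed_table().set_index("term")
        assert tab.loc["age", "estimate"] == pytest.approx(ols.params["age_c"], rel=1e-3)
        assert tab.loc["sex", "estimate"] == pytest.approx(ols.params["female"], rel=1e-3)

    def test_perfect_age_outcome(self):
        rng = np.random.default_rng(4)
        table = _lmm_table(rng, 50)
        table = table.assign(value=table["age_c"])
        fit = lstats.fit_lme(table, "y", ("age",))
        tab = fit.fixed_table().set_index("term")
        assert tab.loc["age", "estimate"] == pytest.approx(1.0, abs=1e-6)
        assert fit.result.scale < 1e-8

    def test_ci_covers_planted_slope(self):
        # simulation-based calibration: 95% CI covers beta=0.2 in >=93% of replicates
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            table = _lmm_table(rng, 120, beta_age=0.2, sd_u=0.4, sd_e=0.4)
            fit = lstats.fit_lme(table, "y", ("age", "sex"))
            row = fit.fixed_table().set_index("term").loc["age"]
            hits += row["ci_low"] <= 0.2 <= row["ci_high"]
        assert hits / n_rep >= 0.93

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(5)
        table = _lmm_table(rng, 30)
        table["age_c"] = 0.0
        table["age_c2"] = 0.0
        with pytest.raises(ValueError, match="singular"):
            lstats.fit_lme(table, "y", ("age", "age2"))


class TestLRCompare:
    def test_identical_models_zero_statistic(self):
        rng = np.random.default_rng(6)
        table = _lmm_table(rng, 60, beta_age=0.1)
        base = lstats.fit_lme(table, "y", ("age", "sex"))
        ext = lstats.fit_lme(table, "y", ("age", "sex", "age2"))
        cmp_same = lstats.lr_compare(base, ext)
        assert cmp_same.lr_stat == pytest.approx(
            2 * (ext.llf_ml - base.llf_ml), abs=1e-8
        )
        assert cmp_same.df_diff == 1

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(7)
        table = _lmm_table(rng, 30)
        a = lstats.fit_lme(table, "y", ("age", "age2"))
        b = lstats.fit_lme(table, "y", ("age", "sex"))
        with pytest.raises(ValueError, match="nested"):
            lstats.lr_compare(a, b)

    def test_null_term_type_one_error_rate(self):
        # LR test of a null quadratic term: rejection rate ~5% at alpha=.05
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            table = _lmm_table(rng, 60, beta_age=0.15)
            base = lstats.fit_lme(table, "y", ("age", "sex"))
            ext = lstats.fit_lme(table, "y", ("age", "sex", "age2"))
            rejections += lstats.lr_compare(base, ext).p_value < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10


class TestModelSuite:
    def test_base_rows_equal_standalone_fits(self, outcome_table_500):
        suite = lstats.model_suite(outcome_table_500, outcomes=("n_transitions",),
                                   boxcox=False)
        standalone = lstats.fit_lme(outcome_table_500, "n_transitions", ("age", "sex"))
        row = suite.base_table.set_index("term").loc["age"]
        exp = standalone.fixed_table().set_index("term").loc["age"]
        assert row["estimate"] == pytest.approx(exp["estimate"], rel=1e-6)

    def test_planted_interaction_triggers_stratified_fit_only_there(self):
        rng = np.random.default_rng(9)
        t1 = _lmm_table(rng, 300, beta_age=0.1, beta_int=-0.25, outcome="mdt_state1")
        t2 = _lmm_table(rng, 300, beta_age=0.1, outcome="mdt_state2")
        t1["value"] = np.exp(t1["value"] / 4)  # keep dwell-like positivity
        t2["value"] = np.exp(t2["value"] / 4)
        table = pd.concat([t1, t2], ignore_index=True)
        table.attrs["mean_age_visit1"] = t1.attrs["mean_age_visit1"]
        suite = lstats.model_suite(table, outcomes=("mdt_state1", "mdt_state2"))
        stratified = set(suite.stratified_table["outcome"])
        assert "mdt_state1" in stratified
        assert "mdt_state2" not in stratified

    def test_null_cohort_rarely_significant(self):
        rng = np.random.default_rng(11)
        tables = [
            _lmm_table(rng, 80, outcome=f"mdt_state{k}") for k in range(1, 4)
        ]
        for t in tables:
            t["value"] = np.exp(t["value"] / 4)
        table = pd.concat(tables, ignore_index=True)
        table.attrs["mean_age_visit1"] = tables[0].attrs["mean_age_visit1"]
        suite = lstats.model_suite(table, outcomes=[f"mdt_state{k}" for k in (1, 2, 3)])
        sig = suite.base_table.query("term == 'age' and p_fdr < 0.05")
        assert len(sig) == 0

    def test_maternal_education_sensitivity_fit(self):
        rng = np.random.default_rng(21)
        table = _lmm_table(rng, 120, beta_age=0.2, outcome="n_transitions")
        me = rng.choice(["low", "secondary", "higher"], size=table["subject_id"].nunique())
        lookup = dict(zip(table["subject_id"].unique(), me))
        table["maternal_education"] = table["subject_id"].map(lookup)
        suite = lstats.model_suite(table, outcomes=("n_transitions",),
                                   boxcox=False, maternal_education=True)
        sens = suite.sensitivity_table
        assert sens is not None
        age_row = sens.query("term == 'age'").iloc[0]
        # the precision covariate is independent of age: estimates agree closely
        base_row = suite.base_table.query("term == 'age'").iloc[0]
        assert age_row["estimate"] == pytest.approx(base_row["estimate"], abs=0.05)

    def test_fdr_adjustment_monotone_and_bounded(self, outcome_table_500):
        suite = lstats.model_suite(outcome_table_500)
        t = suite.base_table
        assert (t["p_fdr"] >= t["p_value"] - 1e-12).all()
        assert (t["p_fdr"] <= 1.0).all()


class TestEdgewise:
    def test_bh_hand_example(self):
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_planted_pair_effects_detected(self):
        rng = np.random.default_rng(12)
        rows = []
        n_pairs, n_affected = 30, 3
        for i in range(150):
            sex = "F" if rng.random() < 0.5 else "M"
            u = rng.normal(0, 0.02)
            for visit, age in ((1, rng.normal(10.1, 0.6)), (2, rng.normal(13.9, 0.5))):
                age_c = age - 10.1
                for p in range(n_pairs):
                    beta = 0.05 if p < n_affected else 0.0
                    y = 0.22 + beta * age_c + u + rng.normal(0, 0.03)
                    rows.append((f"s{i}", visit, age_c, float(sex == "F"), f"p{p:02d}", y))
        pair_table = pd.DataFrame(
            rows, columns=["subject_id", "visit", "age_c", "female", "pair", "value"]
        )
        out = lstats.edgewise_sd_models(pair_table)
        hits = set(out.loc[out["significant"], "pair"])
        affected = {f"p{p:02d}" for p in range(n_affected)}
        assert len(hits & affected) / n_affected >= 0.8
        # false positives controlled
        assert len(hits - affected) <= 3

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(13)
        rows = []
        for i in range(40):
            for p in range(5):
                rows.append((f"s{i}", 1, rng.normal(), float(rng.random() < 0.5),
                             f"p{p}", rng.normal()))
                rows.append((f"s{i}", 2, rng.normal(), 0.0, f"p{p}", rng.normal()))
        pair_table = pd.DataFrame(
            rows, columns=["subject_id", "visit", "age_c", "female", "pair", "value"]
        )
        out = lstats.edgewise_sd_models(pair_table)
        assert (out["p_fdr"] >= out["p_value"] - 1e-12).all()


class TestBootstrapCurves:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(14)
        table = _lmm_table(rng, 60, beta_age=0.2)
        c1 = lstats.bootstrap_curves(table, "y", n_boot=20, seed=3)
        c2 = lstats.bootstrap_curves(table, "y", n_boot=20, seed=3)
        for sex in ("M", "F"):
            assert np.array_equal(c1.curves[sex]["lo"], c2.curves[sex]["lo"])

    def test_bootstrap_mean_close_to_full_fit(self):
        rng = np.random.default_rng(15)
        table = _lmm_table(rng, 150, beta_age=0.25, sd_u=0.3, sd_e=0.3)
        c = lstats.bootstrap_curves(table, "y", n_boot=60, seed=1)
        for sex in ("M", "F"):
            fit = c.curves[sex]["fit"]
            bm = c.curves[sex]["boot_mean"]
            assert np.abs(bm - fit).max() / (np.abs(fit).max() + 1e-9) < 0.05

    def test_bands_shrink_with_sample_size(self):
        rng = np.random.default_rng(16)
        widths = []
        for n in (60, 240):
            table = _lmm_table(rng, n, beta_age=0.2)
            c = lstats.bootstrap_curves(table, "y", n_boot=40, seed=2)
            widths.append(np.mean(c.curves["M"]["hi"] - c.curves["M"]["lo"]))
        assert widths[1] < widths[0]

    def test_back_transformed_dwell_predictions_positive(self, outcome_table_500):
        y = outcome_table_500.query("outcome == 'mdt_state1'")["value"].to_numpy()
        spec, _ = lstats.boxcox_fit(y)
        c = lstats.bootstrap_curves(outcome_table_500, "mdt_state1",
                                    transform=spec, n_boot=25, seed=0)
        for sex in ("M", "F"):
            assert (c.curves[sex]["fit"] > 0).all()
            assert (c.curves[sex]["lo"] > 0).all()
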