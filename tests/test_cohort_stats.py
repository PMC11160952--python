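"""Rank tests, mixed models, and the branch-and-contrast logic."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from octa_intereye import (CohortGenParams, MixedModelSpec, branch_and_contrast,
                           fit_intereye_model, generate_metrics_cohort,
                           kruskal_wallis, wilcoxon_signed_rank)
from octa_intereye.cohort_stats import _design_matrix, stage_summary


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # ranks 1..9 without ties: H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1) = 7.2
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.method == "kruskal_wallis"

    def test_all_tied_reports_p_one(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])

    def test_two_groups_agree_with_mann_whitney(self, rng):
        """With k = 2 the KW decision at alpha = 0.05 matches the two-sided
        Mann-Whitney U decision on tie-free data."""
        from scipy.stats import mannwhitneyu

        agree = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 1, 15)
            kw_p = kruskal_wallis([a, b]).p_value
            mw_p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            agree += (kw_p < 0.05) == (mw_p < 0.05)
        assert agree == n_rep


class TestWilcoxon:
    def test_exact_p_for_five_positive_differences(self):
        # W- = 0; two-sided exact p = 2 / 2^5
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.p_value == pytest.approx(2 / 2 ** 5)

    def test_balanced_differences_give_p_one(self):
        res = wilcoxon_signed_rank(np.array([-2.0, 2.0]))
        assert res.p_value == 1.0

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.n_per_group == (5,)
        assert res.p_value == pytest.approx(0.0625)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(6))

    def test_paired_interface(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0.5, 1, 40)
        res = wilcoxon_signed_rank(x, y)
        assert 0 <= res.p_value <= 1


def _quiet_cohort(**kw):
    """Cohort with only the planted effects (no default stage offsets)."""
    defaults = dict(stage_effects=(0.0,) * 5, side_effect=0.0,
                    interaction_effects=(0.0,) * 5)
    defaults.update(kw)
    return generate_metrics_cohort(CohortGenParams(**defaults))


class TestMixedModel:
    def test_side_effect_recovery(self):
        df = generate_metrics_cohort(CohortGenParams(
            n_per_stage=34, side_effect=-0.009, patient_sd=0.015,
            residual_sd=0.008, seed=101))
        fit = fit_intereye_model(df)
        side = fit.fixed_effects["side[left]"]
        assert side["estimate"] == pytest.approx(-0.009, abs=0.003)
        assert side["ci"][0] <= -0.009 <= side["ci"][1]
        assert side["p_value"] < 0.001

    def test_variance_components_recovered(self):
        df = generate_metrics_cohort(CohortGenParams(
            n_per_stage=60, patient_sd=0.015, residual_sd=0.008, seed=8))
        fit = fit_intereye_model(df)
        assert np.sqrt(fit.variance_patient) == pytest.approx(0.015, rel=0.25)
        assert np.sqrt(fit.variance_residual) == pytest.approx(0.008, rel=0.25)

    def test_zero_patient_variance_detected(self):
        df = _quiet_cohort(patient_sd=0.0, n_per_stage=20, seed=3)
        fit = fit_intereye_model(df)
        assert fit.variance_patient <= 1e-4

    def test_agrees_with_ols_when_patient_variance_zero(self):
        import statsmodels.api as sm

        df = _quiet_cohort(patient_sd=0.0, n_per_stage=20, seed=3)
        fit = fit_intereye_model(df)
        X, names = _design_matrix(df, MixedModelSpec())
        ols = sm.OLS(df["response"].to_numpy(), X).fit()
        j = names.index("side[left]")
        assert abs(fit.estimates[j] - ols.params[j]) < 1e-6

    def test_invariant_to_row_order_and_patient_relabeling(self):
        df = generate_metrics_cohort(CohortGenParams(n_per_stage=10, seed=21))
        fit_a = fit_intereye_model(df)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        relabel = {p: f"Z{i}" for i, p in enumerate(df["patient_id"].unique())}
        shuffled["patient_id"] = shuffled["patient_id"].map(relabel)
        fit_b = fit_intereye_model(shuffled)
        assert np.allclose(fit_a.estimates, fit_b.estimates, atol=1e-8)

    def test_single_sex_cohort_names_collinear_term(self):
        df = generate_metrics_cohort(CohortGenParams(n_per_stage=5, seed=2))
        df["sex"] = "male"
        with pytest.raises(ValueError, match="sex"):
            fit_intereye_model(df)

    def test_missing_hba1c_rows_dropped(self):
        df = generate_metrics_cohort(CohortGenParams(n_per_stage=10, seed=4))
        df.loc[df["patient_id"] == "P0000", "hba1c"] = np.nan
        fit = fit_intereye_model(df)
        assert fit.n_dropped == 2
        assert fit.n_obs == len(df) - 2

    def test_too_few_patients_per_stage_rejected(self):
        df = generate_metrics_cohort(CohortGenParams(n_per_stage=5, seed=2))
        with pytest.raises(ValueError, match=">=2"):
            fit_intereye_model(df[df["stage"] != "pdr"])

    def test_matches_lmer_reference_fit(self, tmp_path):
        """Cross-check against lme4/lmerTest (REML) on the same cohort: fixed
        side estimate and its standard error must agree."""
        df = generate_metrics_cohort(CohortGenParams(n_per_stage=8, seed=33))
        fit = fit_intereye_model(df)
        csv = tmp_path / "cohort.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$stage <- relevel(factor(d$stage), ref = "no_dr")
            d$side <- relevel(factor(d$side), ref = "right")
            d$sex <- relevel(factor(d$sex), ref = "female")
            m <- lmer(response ~ stage + side + age + hba1c + sex + stage:side
                      + (1 | patient_id), data = d, REML = TRUE)
            s <- summary(m)$coefficients
            cat(s["sideleft", "Estimate"], s["sideleft", "Std. Error"], sep = ",")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        est, se = map(float, out.stdout.strip().split(","))
        side = fit.fixed_effects["side[left]"]
        assert side["estimate"] == pytest.approx(est, abs=1e-6)
        assert side["se"] == pytest.approx(se, rel=1e-3)


class TestBranchAndContrast:
    def test_no_interaction_branch_not_taken(self):
        df = _quiet_cohort(n_per_stage=20, side_effect=-0.009, seed=6)
        rep = branch_and_contrast(fit_intereye_model(df))
        assert "side_effect" in rep
        assert "side_by_stage" not in rep

    def test_interaction_in_one_stage_triggers_per_stage_contrasts(self):
        planted = -0.02
        df = _quiet_cohort(n_per_stage=30, interaction_effects=(0, 0, 0, 0, planted),
                           seed=13)
        rep = branch_and_contrast(fit_intereye_model(df))
        assert "side_by_stage" in rep
        pdr = rep["side_by_stage"]["pdr"]
        half_width = (pdr["ci"][1] - pdr["ci"][0]) / 2
        assert abs(pdr["estimate"] - planted) <= half_width
        # null stages: contrast near zero
        assert abs(rep["side_by_stage"]["no_dr"]["estimate"]) < abs(planted) / 2

    def test_stage_contrasts_equal_cell_mean_differences_on_balanced_design(self):
        """With balanced covariates the stage-vs-reference contrast equals the
        difference of model-implied stage means (exact linear identity)."""
        effects = (0.0, 0.004, -0.003, -0.010, -0.015)
        df = _quiet_cohort(n_per_stage=25, stage_effects=effects,
                           patient_sd=0.005, seed=19)
        # identical covariate composition in every stage block (patterns keyed
        # on the patient index within the stage, not the row, so nothing is
        # collinear with side), making stage cell means comparable
        patient_in_stage = np.arange(len(df)) % 50 // 2
        df["age"] = np.where(patient_in_stage % 2 == 0, 50.0, 65.0)
        df["hba1c"] = np.where(patient_in_stage % 3 == 0, 6.5, 8.0)
        df["sex"] = np.where(patient_in_stage % 5 < 3, "male", "female")
        fit = fit_intereye_model(df)
        X, names = _design_matrix(df, MixedModelSpec())
        fitted = X @ fit.estimates
        base = fitted[(df["stage"] == "no_dr").to_numpy()].mean()
        for stage in ("mild", "moderate", "severe", "pdr"):
            cell = fitted[(df["stage"] == stage).to_numpy()].mean()
            contrast = fit.contrast({f"stage[{stage}]": 1.0,
                                     f"stage[{stage}]:side[left]": 0.5})
            assert contrast["estimate"] == pytest.approx(cell - base, abs=1e-8)

    def test_report_structure(self):
        df = generate_metrics_cohort(CohortGenParams(n_per_stage=10, seed=1))
        rep = branch_and_contrast(fit_intereye_model(df))
        assert rep["n_obs"] == 100
        assert rep["n_patients"] == 50
        assert {"fixed_effects", "stage_f_test", "interaction_f_test",
                "variance_components"} <= set(rep)
        for term in rep["fixed_effects"].values():
            assert term["ci"][0] <= term["estimate"] <= term["ci"][1]
        assert rep["variance_components"]["patient"] >= 0


class TestStageSummary:
    def test_linear_interpolation_quartiles(self):
        pairs = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(4)],
            "stage": ["no_dr"] * 4,
            "metric": ["vd"] * 4,
            "right": [0.2] * 4, "left": [0.19] * 4,
            "delta_abs": [1.0, 2.0, 3.0, 4.0],
            "asymmetry_index": [10.0, 20.0, 30.0, 40.0],
        })
        out = stage_summary(pairs)
        row = out[(out["measure"] == "delta_abs")].iloc[0]
        assert row["median"] == pytest.approx(2.5)
        assert row["q1"] == pytest.approx(1.75)
        assert row["q3"] == pytest.approx(3.25)
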