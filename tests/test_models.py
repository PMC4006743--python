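import numpy as np
import pandas as pd
import pytest
import scipy.stats

from qtnvar.exceptions import InvalidInputError
from qtnvar.models import (
    DayResidualizer,
    FactorialAnova,
    fit_day_residuals,
    fit_genotype_model,
    fit_phenotype_model,
    fit_sequential_ols,
)
from qtnvar.panel import build_design_matrix
from qtnvar.simulate import (
    PhenotypeTruth,
    phenotype_truth_from_fractions,
    simulate_phenotypes,
)


def _replicated_design(design, reps):
    idx = np.repeat(np.arange(len(design)), reps)
    return design.iloc[idx].reset_index(drop=True)


class TestDayResiduals:
    def test_single_day_residuals_center_counts(self, rng):
        counts = pd.DataFrame(
            rng.uniform(10, 100, size=(5, 8)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(8)],
        )
        table = pd.DataFrame({"day": ["A"] * 8}, index=counts.columns)
        resid = fit_day_residuals(counts, table.assign(strain_id="x"))
        expected = counts.sub(counts.mean(axis=1), axis=0)
        pd.testing.assert_frame_equal(resid, expected)

    def test_pure_day_offsets_leave_zero_residuals(self, rng):
        days = ["A"] * 3 + ["B"] * 4
        offsets = {"A": 7.0, "B": -4.0}
        base = rng.uniform(50, 60, size=(6, 1))
        counts = pd.DataFrame(
            base + np.array([offsets[d] for d in days]),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(7)],
        )
        table = pd.DataFrame({"day": days, "strain_id": "x"}, index=counts.columns)
        resid = fit_day_residuals(counts, table)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_day_indicators(self, rng):
        days = np.array(["A", "B", "C"] * 7)
        counts = pd.DataFrame(
            rng.normal(100, 20, size=(4, 21)), columns=[f"s{j}" for j in range(21)]
        )
        table = pd.DataFrame({"day": days, "strain_id": "x"}, index=counts.columns)
        resid = fit_day_residuals(counts, table)
        for day in "ABC":
            dots = resid.loc[:, days == day].sum(axis=1)
            assert np.allclose(dots, 0.0, atol=1e-9)

    def test_empty_day_level_rejected(self):
        counts = pd.DataFrame({"s1": [1.0], "s2": [2.0]})
        days = pd.Categorical(["A", "A"], categories=["A", "B"])
        with pytest.raises(InvalidInputError):
            DayResidualizer().fit(counts.T, days)


class TestGenotypeModel:
    def test_zero_response_degenerate_convention(self, design):
        d = _replicated_design(design, 2)
        fit = fit_genotype_model(np.zeros(len(d)), d)
        assert fit.r_squared == 0.0
        assert fit.model_p == 1.0
        assert (fit.coefficients.abs() < 1e-12).all()

    def test_noiseless_recovery_to_machine_precision(self, design, rng):
        d = _replicated_design(design, 2)
        beta = pd.Series(
            rng.normal(size=15), index=[c for c in design.columns if c != "intercept"]
        )
        y = 3.5 + d[beta.index].to_numpy() @ beta.to_numpy()
        fit = fit_genotype_model(y, d)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.coefficients[beta.index], beta, atol=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(3.5)

    def test_mean_shift_only_moves_intercept(self, design, rng):
        d = _replicated_design(design, 3)
        y = rng.normal(size=len(d))
        a = fit_genotype_model(y, d)
        b = fit_genotype_model(y + 100.0, d)
        assert np.allclose(
            a.coefficients.drop("intercept"), b.coefficients.drop("intercept")
        )
        assert b.coefficients["intercept"] - a.coefficients["intercept"] == pytest.approx(100.0)

    def test_null_model_p_uniform(self, panel, samples, rng):
        """On pure-noise responses the overall model p-value is U(0,1)."""
        design = build_design_matrix(panel, samples)
        Y = rng.normal(size=(len(samples), 1500))
        res = fit_sequential_ols(design, Y)
        ks = scipy.stats.kstest(res.model_p.to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_rank_deficient_design_reports_aliased_terms(self, panel, rng):
        half = panel.iloc[:8]  # RME1nc fixed at O: its terms are inestimable
        st = pd.DataFrame({"strain_id": np.repeat(half.index, 3)})
        design = build_design_matrix(half, st)
        fit = fit_genotype_model(rng.normal(size=24), design)
        assert len(fit.aliased) == 8
        assert all("RME1nc" in t for t in fit.aliased)
        assert fit.df_model == 7
        assert fit.coefficients[list(fit.aliased)].isna().all()

    def test_too_few_observations_rejected(self, design, rng):
        with pytest.raises(InvalidInputError):
            fit_genotype_model(rng.normal(size=16), design)  # 16 obs, 16 params

    def test_log_variant_includes_day_covariates(self, panel, samples, rng):
        alleles = panel.loc[samples["strain_id"]].set_axis(samples.index)
        Y = pd.DataFrame(
            rng.poisson(100, size=(len(samples), 3)).astype(float), index=samples.index
        )
        est = FactorialAnova(response_transform="log").fit(
            alleles, Y, days=samples["day"]
        )
        assert [t for t in est.result_.terms if t.startswith("DAY[")] == [
            "DAY[B]", "DAY[C]", "DAY[D]"
        ]
        assert est.df_model_ == 15  # genotype terms only, day adjusted for
        assert est.df_residual_ == len(samples) - 16 - 3

    def test_balanced_panel_main_effect_ss_order_invariant(self, panel, rng):
        """With a complete balanced panel, the main-effect sequential SS do
        not depend on the order in which the loci enter the model."""
        st = pd.DataFrame({"strain_id": np.repeat(panel.index, 2)})
        y = rng.normal(size=len(st))
        base_design = build_design_matrix(panel, st)
        base = fit_genotype_model(y, base_design)
        reordered_panel = panel[["IME1nc", "RSF1c", "IME1c", "RME1nc"]]
        re_design = build_design_matrix(reordered_panel, st)
        re_fit = fit_genotype_model(y, re_design)
        for locus in ["RME1nc", "RSF1c", "IME1c", "IME1nc"]:
            assert base.anova.loc[locus, "ss"] == pytest.approx(
                re_fit.anova.loc[locus, "ss"], rel=1e-9
            )


class TestPhenotypeModel:
    def test_full_panel_four_reps_residual_df(self, panel):
        truth = phenotype_truth_from_fractions()
        pheno = simulate_phenotypes(panel, truth, reps=4, seed=0)
        fit = fit_phenotype_model(pheno, panel)
        assert fit.df_residual == 48
        assert fit.df_model == 15

    def test_zero_noise_phenotypes_fit_perfectly(self, panel):
        truth = PhenotypeTruth(
            intercept=80.0, betas=pd.Series({"RME1nc": -30.0, "RSF1c": -10.0}),
            noise_sd=0.0,
        )
        pheno = simulate_phenotypes(panel, truth, reps=4, seed=0)
        fit = fit_phenotype_model(pheno, panel)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_consistent_with_anova_table(self, panel):
        truth = phenotype_truth_from_fractions()
        pheno = simulate_phenotypes(panel, truth, reps=4, seed=5)
        fit = fit_phenotype_model(pheno, panel)
        table = fit.anova
        ss_res = table.loc["Residuals", "ss"]
        ss_tot = table["ss"].sum()
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
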