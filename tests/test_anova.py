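import numpy as np
import pandas as pd
import pytest

from conftest import nested_refit_sequential_ss
from qtnvar.anova import (
    additive_interaction_split,
    allele_shares,
    allele_shares_by_gene,
    anova_long_table,
    fraction_of_variance,
    sequential_anova,
    summarize_allele_shares,
)
from qtnvar.datasets import sporulation_anova
from qtnvar.exceptions import DegenerateInputError
from qtnvar.models import fit_expression_models, fit_genotype_model
from qtnvar.panel import build_design_matrix, make_full_factorial_panel
from qtnvar.simulate import ExpressionTruth, simulate_expression_counts


class TestSequentialSSOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nested_refit_differences(self, seed):
        """Sequential SS from the QR path equals the drop in residual SS
        between successive nested refits, on random factorial instances."""
        rng = np.random.default_rng(seed)
        n_loci = int(rng.integers(2, 5))
        panel = make_full_factorial_panel([f"L{i}" for i in range(n_loci)])
        reps = int(rng.integers(2, 4))
        st = pd.DataFrame({"strain_id": np.tile(panel.index, reps)})
        design = build_design_matrix(panel, st)
        y = rng.normal(scale=rng.uniform(0.5, 50), size=len(design))
        fit = fit_genotype_model(y, design)
        oracle = nested_refit_sequential_ss(design, y)
        for term in fit.anova.index.drop("Residuals"):
            assert fit.anova.loc[term, "ss"] == pytest.approx(
                oracle[term], rel=1e-8, abs=1e-10
            )

    def test_constant_response_all_term_ss_zero(self, design):
        d = design.iloc[np.repeat(np.arange(16), 2)].reset_index(drop=True)
        fit = fit_genotype_model(np.full(32, 7.0), d)
        assert np.allclose(fit.anova.drop("Residuals")["ss"], 0.0, atol=1e-18)


@pytest.fixture()
def table():
    return sporulation_anova()


class TestPublishedSporulationTable:
    """Re-derivations from the published panel ANOVA's df and SS columns."""

    def test_main_effect_fractions(self, table):
        frac = fraction_of_variance(table).round(2)
        assert frac["RME1nc"] == 34.32
        assert frac["RSF1c"] == 20.13
        assert frac["IME1c"] == 32.13
        assert frac["IME1nc"] == 6.50
        assert frac["Residuals"] == 1.91

    def test_f_statistic_from_mean_squares(self, table):
        assert round(float(table.loc["RME1nc", "f"]), 1) == 864.2

    def test_fractions_sum_to_hundred(self, table):
        assert fraction_of_variance(table).sum() == pytest.approx(100.0)

    def test_additive_total(self, table):
        split = additive_interaction_split(table)
        assert round(split.additive, 2) == 93.08

    def test_total_variance_explained(self, table):
        explained = 100.0 * (1 - table.loc["Residuals", "ss"] / table["ss"].sum())
        assert round(explained) == 98

    def test_rme1nc_allele_share_sums_significant_interactions(self, table):
        shares = allele_shares(table, p_threshold=0.1)
        assert shares.loc["RME1nc", "main_fraction"] == pytest.approx(34.32, abs=0.005)
        # significant RME1nc interactions: SS 293.7, 134.3, 84.6, 161.4, 136.3
        expected = 100 * (293.7 + 134.3 + 84.6 + 161.4 + 136.3) / table["ss"].sum()
        assert shares.loc["RME1nc", "interaction_fraction"] == pytest.approx(
            expected, abs=1e-9
        )
        assert shares.loc["RME1nc", "interaction_fraction"] == pytest.approx(3.61, abs=0.005)

    def test_partition_identity(self, table):
        split = additive_interaction_split(table)
        frac = fraction_of_variance(table)
        nonsig = frac.drop("Residuals")[table.drop("Residuals").p >= 0.1].sum()
        total = split.additive + split.interaction + nonsig + frac["Residuals"]
        assert total == pytest.approx(100.0)


class TestAlleleShares:
    def test_all_insignificant_gives_zero_shares(self):
        table = sporulation_anova()
        table["p"] = 1.0
        shares = allele_shares(table)
        assert (shares[["main_fraction", "interaction_fraction", "total_fraction"]] == 0).all().all()
        split = additive_interaction_split(table)
        assert split == (0.0, 0.0)

    def test_zero_total_ss_is_degenerate(self):
        table = sporulation_anova()
        table["ss"] = 0.0
        with pytest.raises(DegenerateInputError):
            fraction_of_variance(table)

    def test_single_main_effect_recovered(self, panel, samples):
        """A gene whose only effect is an RSF1c main effect gets its share
        credited to RSF1c and ~nothing anywhere else."""
        betas = pd.DataFrame(
            0.0,
            index=pd.Index([f"g{i}" for i in range(40)], name="gene_id"),
            columns=["intercept", "RME1nc", "RSF1c", "IME1c", "IME1nc"],
        )
        betas["intercept"] = 200.0
        betas["RSF1c"] = 40.0
        truth = ExpressionTruth(
            betas=betas, day_effects=pd.Series({d: 0.0 for d in "ABCD"}),
            mode="gaussian", noise_sd=10.0,
        )
        counts, _ = simulate_expression_counts(panel, samples, truth, seed=4)
        est = fit_expression_models(
            counts.sub(counts.mean(axis=1), axis=0), panel, samples
        )
        shares = allele_shares_by_gene(est).groupby("allele").median(numeric_only=True)
        # expected share: c*beta^2 / (c*beta^2 + (n-1)sigma^2), c = n/4
        c = len(samples) / 4
        expected = 100 * c * 40.0**2 / (c * 40.0**2 + (len(samples) - 1) * 10.0**2)
        assert shares.loc["RSF1c", "main_fraction"] == pytest.approx(expected, abs=3.0)
        for other in ["RME1nc", "IME1c", "IME1nc"]:
            assert shares.loc[other, "main_fraction"] < 1.0
            assert shares.loc[other, "interaction_fraction"] < 3.0

    def test_long_table_fractions_sum_to_hundred_per_gene(self, panel, samples, rng):
        counts, _ = simulate_expression_counts(panel, samples, n_genes=15, seed=8)
        est = fit_expression_models(
            counts.sub(counts.mean(axis=1), axis=0), panel, samples
        )
        long = anova_long_table(est)
        sums = long.groupby("gene_id")["fraction"].sum()
        assert np.allclose(sums, 100.0)

    def test_summary_median_matches_configured_share(self, panel, samples):
        """Panel-level median share over genes built with one fixed main
        effect reproduces the configured expected share."""
        n_genes = 60
        betas = pd.DataFrame(
            0.0,
            index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
            columns=["intercept", "IME1c"],
        )
        betas["intercept"] = 300.0
        betas["IME1c"] = 30.0
        truth = ExpressionTruth(
            betas=betas, day_effects=pd.Series({d: 0.0 for d in "ABCD"}),
            mode="gaussian", noise_sd=15.0,
        )
        counts, _ = simulate_expression_counts(panel, samples, truth, seed=14)
        est = fit_expression_models(
            counts.sub(counts.mean(axis=1), axis=0), panel, samples
        )
        shares = allele_shares_by_gene(est)
        summary = summarize_allele_shares(shares)
        c = len(samples) / 4
        expected = 100 * c * 30.0**2 / (c * 30.0**2 + (len(samples) - 1) * 15.0**2)
        assert summary.loc["IME1c", "median_main_pct"] == pytest.approx(expected, abs=3.0)
        assert summary.loc["IME1c", "n_genes_main_effect"] >= 55


class TestSequentialAnovaInterface:
    def test_modelfit_and_estimator_agree(self, panel, samples, rng):
        counts, _ = simulate_expression_counts(panel, samples, n_genes=5, seed=2)
        resid = counts.sub(counts.mean(axis=1), axis=0)
        est = fit_expression_models(resid, panel, samples)
        gene = resid.index[0]
        from_est = sequential_anova(est, gene)
        design = build_design_matrix(panel, samples)
        from_fn = fit_genotype_model(resid.loc[gene], design, name=gene).anova
        pd.testing.assert_frame_equal(from_est, from_fn, check_exact=False, rtol=1e-10)
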