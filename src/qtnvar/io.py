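"""Tabular readers/writers, run configuration, and the end-to-end pipeline.

All artifacts are tab-separated text with header rows: count matrices are
gene-rows (first column ``gene_id``, one column per sample), sample /
genotype / phenotype tables are one row per entity.  Readers validate
cross-references (every sample's strain must exist in the genotype panel,
allele codes must be O or V) and raise :class:`~qtnvar.exceptions.ParseError`
naming the file, line and field of the first offence.

:func:`run_pipeline` composes the analysis stages in their canonical order:
normalize -> filter -> day residuals -> factorial fits -> BH FDR +
permutation null -> variance decomposition -> replicate-noise summaries,
writing each stage's table under the configured output directory together
with a run manifest echoing parameters and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import (
    additive_interaction_split_by_gene,
    allele_shares_by_gene,
    anova_long_table,
    sequential_anova,
)
from .exceptions import InvalidInputError, ParseError
from .models import fit_day_residuals, fit_expression_models, fit_phenotype_model
from .normalize import compute_size_factors, filter_low_expression, normalize_counts
from .panel import ALLELES, validate_panel
from .replicates import cv_table, day_correct_counts
from .significance import bh_adjust, genomewide_percentile_p, permutation_threshold
from .simulate import validate_sample_table

logger = logging.getLogger("qtnvar")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=path)
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(str(exc), path=path) from exc


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path)


def read_counts(path) -> pd.DataFrame:
    """Gene-rows count matrix TSV -> genes x samples DataFrame."""
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise ParseError("first column must be 'gene_id'", path=path, field=df.columns[0])
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.nonzero(df.index.duplicated())[0][0]) + 2
        raise ParseError(f"duplicate gene id {dup!r}", path=path, line=line)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError("non-numeric count values", path=path)
    if (values < 0).any():
        g, s = map(int, np.argwhere(values < 0)[0])
        raise ParseError(
            f"negative count for gene {df.index[g]!r}", path=path, line=g + 2,
            field=df.columns[s],
        )
    df.columns.name = "sample_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "strain_id", "day", "replicate"], path)
    if df["sample_id"].duplicated().any():
        line = int(df.index[df["sample_id"].duplicated()][0]) + 2
        raise ParseError("duplicate sample id", path=path, line=line, field="sample_id")
    return df.set_index("sample_id")


def read_genotypes(path) -> pd.DataFrame:
    """Strain genotype table: strain_id column plus one O/V column per locus."""
    df = _read_tsv(path, dtype=str)
    _require_columns(df, ["strain_id"], path)
    panel = df.set_index("strain_id")
    if panel.shape[1] < 1:
        raise ParseError("genotype table has no locus columns", path=path)
    bad = ~panel.isin(ALLELES)
    if bad.to_numpy().any():
        r, c = map(int, np.argwhere(bad.to_numpy())[0])
        raise ParseError(
            f"invalid allele code {panel.iloc[r, c]!r} (expected one of {ALLELES})",
            path=path, line=r + 2, field=panel.columns[c],
        )
    validate_panel(panel)
    return panel


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["strain_id", "replicate", "efficiency"], path)
    out_of_range = (df["efficiency"] < 0) | (df["efficiency"] > 100)
    if out_of_range.any():
        line = int(df.index[out_of_range][0]) + 2
        raise ParseError(
            "efficiency outside [0, 100]", path=path, line=line, field="efficiency"
        )
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the emulated study protocol."""

    counts: str
    samples: str
    genotypes: str
    phenotypes: str | None = None
    outdir: str = "qtnvar_out"
    filter_quantile: float = 0.20
    fdr: float = 0.10
    term_p_threshold: float = 0.1
    n_perm: int = 1000
    percentile: float = 0.05
    reference_day: str | None = None
    seed: int | None = None
    response_transform: str = "identity"

    def __post_init__(self):
        if not 0 <= self.filter_quantile < 1:
            raise InvalidInputError("filter_quantile must be in [0, 1)")
        for name in ("fdr", "term_p_threshold", "percentile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidInputError(f"{name} must be in (0, 1)")
        if self.n_perm < 0:
            raise InvalidInputError("n_perm must be >= 0")
        if self.response_transform not in ("identity", "log"):
            raise InvalidInputError("response_transform must be 'identity' or 'log'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_tables(config: RunConfig):
    """Load and cross-validate (counts, sample table, panel, phenotypes)."""
    counts = read_counts(config.counts)
    samples = read_sample_table(config.samples)
    panel = read_genotypes(config.genotypes)
    validate_sample_table(samples, panel)
    missing = set(counts.columns) - set(samples.index)
    if missing:
        raise ParseError(
            f"count matrix samples missing from sample table: {sorted(missing)}",
            path=config.samples,
        )
    phenotypes = None
    if config.phenotypes:
        phenotypes = read_phenotypes(config.phenotypes)
        unknown = set(phenotypes["strain_id"]) - set(panel.index)
        if unknown:
            raise ParseError(
                f"phenotype strains missing from panel: {sorted(unknown)}",
                path=config.phenotypes,
            )
    return counts, samples, panel, phenotypes


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write its outputs; returns the bundle.

    Stage order: load -> size factors -> normalize -> filter -> day
    residuals -> per-gene factorial fits -> BH FDR (+ permutation null
    unless ``n_perm == 0``) -> ANOVA decomposition & allele shares ->
    phenotype model (if phenotype table given) -> day-corrected CV ->
    manifest.  Deterministic for a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    current_stage = {"name": "setup"}

    def stage(name):
        current_stage["name"] = name
        logger.info("stage: %s", name)

    try:
        return _run_stages(config, outdir, stage)
    except Exception as exc:
        raise PipelineError(current_stage["name"], exc) from exc


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _run_stages(config: RunConfig, outdir: Path, stage) -> dict:

    stage("load")
    counts, samples, panel, phenotypes = read_tables(config)

    stage("size-factors")
    factors = compute_size_factors(counts)
    write_table(factors.rename_axis("sample_id").to_frame(), outdir / "size_factors.tsv")

    stage("normalize")
    normalized = normalize_counts(counts, factors)

    stage("filter")
    filtered = filter_low_expression(normalized, config.filter_quantile)
    write_counts(filtered, outdir / "filtered_counts.tsv")
    logger.info("filter kept %d of %d genes", filtered.shape[0], normalized.shape[0])

    stage("day-residuals")
    residuals = fit_day_residuals(filtered, samples)
    write_counts(residuals, outdir / "day_residuals.tsv")

    stage("factorial-fits")
    if config.response_transform == "log":
        days = samples.loc[filtered.columns, "day"]
        est = fit_expression_models(
            filtered, panel, samples, response_transform="log", days=days
        )
    else:
        est = fit_expression_models(residuals, panel, samples)
    fits = pd.DataFrame(
        {
            "r_squared": est.r_squared_,
            "model_f": est.model_f_,
            "model_p": est.model_p_,
        }
    )
    fits = pd.concat([est.coef_.T.add_prefix("beta:"), fits], axis=1)
    write_table(fits.rename_axis("gene_id"), outdir / "model_fits.tsv")

    stage("fdr")
    bh = bh_adjust(est.model_p_, config.fdr)
    write_table(bh.rename_axis("gene_id"), outdir / "bh_results.tsv")
    logger.info(
        "BH at FDR %.0f%%: %d significant genes (max unadjusted p %.4g)",
        100 * config.fdr, int(bh["significant"].sum()), bh.attrs["max_significant_p"],
    )

    null = None
    observed_percentile = genomewide_percentile_p(est.model_p_)
    if config.n_perm > 0:
        stage("permutation")
        null = permutation_threshold(
            residuals, panel, samples,
            n_perm=config.n_perm, percentile=config.percentile, seed=config.seed,
        )
        write_table(null.frame(), outdir / "permutation_null.tsv", index=False)
        logger.info(
            "observed %.0fth-percentile model p %.4g; null mean %.4g (sd %.4g)",
            100 * config.percentile, observed_percentile, null.mean, null.sd,
        )
    else:
        logger.info("permutation stage skipped (n_perm = 0)")

    stage("decomposition")
    long_table = anova_long_table(est)
    write_table(long_table, outdir / "anova_long.tsv", index=False)
    shares = allele_shares_by_gene(est, config.term_p_threshold)
    write_table(shares, outdir / "allele_shares.tsv", index=False)
    split = additive_interaction_split_by_gene(est, config.term_p_threshold)
    write_table(split.reset_index(), outdir / "additive_interaction_split.tsv", index=False)

    phenotype_fit = None
    if phenotypes is not None:
        stage("phenotype-model")
        phenotype_fit = fit_phenotype_model(phenotypes, panel)
        write_table(
            sequential_anova(phenotype_fit).rename_axis("term"),
            outdir / "phenotype_anova.tsv",
        )

    stage("cv")
    if config.reference_day is None:
        reference_day = sorted(samples["day"].unique())[0]
        logger.info("no reference day configured; using %r", reference_day)
    else:
        reference_day = config.reference_day
    corrected, flagged = day_correct_counts(normalized, samples, reference_day)
    cvs = cv_table(corrected, samples)
    write_table(cvs, outdir / "cv_table.tsv", index=False)
    logger.info(
        "median replicate CV %.3f (%d genes left uncorrected)",
        float(cvs["cv"].median()), len(flagged),
    )

    stage("manifest")
    manifest = {
        "qtnvar_version": __version__,
        "config": config.to_dict(),
        "n_genes_input": int(counts.shape[0]),
        "n_genes_filtered": int(filtered.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_significant_genes": int(bh["significant"].sum()),
        "observed_percentile_p": float(observed_percentile),
        "permutation_null_mean": None if null is None else null.mean,
        "permutation_null_sd": None if null is None else null.sd,
    }
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return {
        "counts": counts,
        "samples": samples,
        "panel": panel,
        "phenotypes": phenotypes,
        "size_factors": factors,
        "normalized": normalized,
        "filtered": filtered,
        "residuals": residuals,
        "fit": est,
        "model_fits": fits,
        "bh": bh,
        "permutation_null": null,
        "anova_long": long_table,
        "allele_shares": shares,
        "additive_interaction_split": split,
        "phenotype_fit": phenotype_fit,
        "cv": cvs,
        "manifest": manifest,
    }


def write_dataset(dataset: dict, outdir) -> None:
    """Write a synthetic dataset (from :func:`qtnvar.simulate.default_dataset`)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(dataset["counts"], outdir / "counts.tsv")
    write_table(dataset["samples"].reset_index(), outdir / "samples.tsv", index=False)
    write_table(
        dataset["panel"].rename_axis("strain_id").reset_index(),
        outdir / "genotypes.tsv", index=False,
    )
    write_table(dataset["phenotypes"], outdir / "phenotypes.tsv", index=False)
    truth = dataset["expression_truth"]
    write_table(truth.betas.rename_axis("gene_id"), outdir / "expression_truth.tsv")
    manifest = {
        "qtnvar_version": __version__,
        "mode": truth.mode,
        "noise_sd": truth.noise_sd,
        "dispersion": None if np.isinf(truth.dispersion) else float(truth.dispersion),
        "day_effects": {str(k): float(v) for k, v in truth.day_effects.items()},
        "phenotype_truth": {
            "intercept": dataset["phenotype_truth"].intercept,
            "noise_sd": dataset["phenotype_truth"].noise_sd,
            "betas": {k: float(v) for k, v in dataset["phenotype_truth"].betas.items()},
        },
    }
    with open(outdir / "dataset_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
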