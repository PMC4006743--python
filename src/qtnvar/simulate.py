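"""Synthetic factorial expression and phenotype data with known ground truth.

This module emulates the design of the sporulation-QTN study: a full 2^4
allele replacement panel (16 strains), four biological replicates per strain
grown on different days (one strain losing one replicate, for 63 expression
libraries and 64 phenotype observations), day-of-growth batch effects,
genotype main and interaction effects, and count overdispersion.

Every generator returns, alongside the data, a truth record holding the exact
effect sizes used, so downstream estimators can be tested for parameter
recovery rather than merely for not crashing.

Two noise modes are supported for expression counts:

``gaussian``
    counts = max(0, round(intercept + X @ beta + day_offset + N(0, noise_sd))).
    Day effects are *additive*, matching the residual-subtraction batch
    correction used by the modelling pipeline.
``nb``
    counts ~ NegativeBinomial(mean = day_multiplier * exp(intercept + X @ beta),
    size = dispersion), i.e. variance = mu + mu**2/size.  Day effects are
    *multiplicative*, matching the ratio-based day correction used for the
    coefficient-of-variation analysis.  ``intercept`` and ``beta`` are on the
    log scale in this mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .panel import (
    INTERCEPT,
    SPORULATION_LOCI,
    build_design_matrix,
    make_full_factorial_panel,
    term_label,
    term_order,
    validate_panel,
)

#: Genotype (in locus order RME1nc, RSF1c, IME1c, IME1nc) of the strain whose
#: fourth expression library failed in the emulated design: vineyard at
#: RME1nc, RSF1c and IME1nc, oak at IME1c.
DEFAULT_DROPPED_STRAIN = "VVOV"

#: Published per-locus fractions (%) of sporulation-efficiency variance used
#: as the default phenotype effect-size targets.
DEFAULT_PHENOTYPE_FRACTIONS: dict[str, float] = {
    "RME1nc": 34.32,
    "RSF1c": 20.13,
    "IME1c": 32.13,
    "IME1nc": 6.50,
}


@dataclass(frozen=True)
class PhenotypeTruth:
    """True linear model behind simulated sporulation efficiencies.

    ``intercept`` is the expected efficiency (%) of the all-oak strain;
    ``betas`` maps model term labels (``"RME1nc"``, ``"RME1nc:RSF1c"``, ...)
    to effects of the vineyard allele combination under treatment coding;
    ``noise_sd`` is the replicate-level gaussian noise (percentage points).
    """

    intercept: float
    betas: pd.Series
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")

    def main_terms(self) -> pd.Series:
        return self.betas[[t for t in self.betas.index if term_order(t) == 1]]

    def is_main_only(self) -> bool:
        inter = [t for t in self.betas.index if term_order(t) >= 2]
        return bool((self.betas[inter] == 0).all()) if inter else True

    def expected_type1_fractions(self, reps: int) -> pd.Series:
        """Expected sequential-ANOVA variance fractions (%) on a full panel.

        Closed form for main-effects-only truths on a balanced 2^L design
        with ``reps`` replicates: a main term's sum of squares has expectation
        ``c * beta**2 + sigma**2`` with ``c = n_obs / 4`` (the centered V
        indicator has variance 1/4 and main columns are mutually orthogonal
        after centering), every other 1-df term contributes ``sigma**2``, and
        the residual contributes ``(n_obs - 2**L) * sigma**2``.
        """
        if not self.is_main_only():
            raise InvalidInputError(
                "closed-form expected fractions require a main-effects-only truth"
            )
        loci = [t for t in self.betas.index if term_order(t) == 1]
        n_terms = 2 ** len(loci) - 1
        n_obs = reps * 2 ** len(loci)
        c = n_obs / 4.0
        sigma2 = self.noise_sd**2
        ss = pd.Series(sigma2, index=[t for t in self.betas.index], dtype=float)
        for locus in loci:
            ss[locus] = c * self.betas[locus] ** 2 + sigma2
        # terms absent from betas still soak up one sigma^2 each
        missing = n_terms - len(ss)
        residual = (n_obs - 2 ** len(loci)) * sigma2
        total = ss.sum() + missing * sigma2 + residual
        out = 100.0 * ss / total
        out["Residuals"] = 100.0 * residual / total
        return out


def phenotype_truth_from_fractions(
    fractions: Mapping[str, float] = DEFAULT_PHENOTYPE_FRACTIONS,
    reps: int = 4,
    noise_sd: float = 3.0,
    intercept: float = 90.0,
    direction: float = -1.0,
) -> PhenotypeTruth:
    """Build a main-effects-only truth hitting target variance fractions.

    Inverts the expected-sequential-SS closed form (see
    :meth:`PhenotypeTruth.expected_type1_fractions`): given per-locus target
    fractions f_j (%) of total variance on a balanced ``2**L x reps`` design,
    solves for effect sizes beta_j such that the *expected* Type-I ANOVA
    fraction of each main term equals its target.

    ``direction=-1`` makes the vineyard alleles lower the response, matching
    the biology (the all-oak strain sporulates best); the sign does not
    affect any variance fraction.
    """
    f = pd.Series(dict(fractions), dtype=float) / 100.0
    loci = list(f.index)
    n_obs = reps * 2 ** len(loci)
    c = n_obs / 4.0
    m = len(loci)
    fsum = float(f.sum())
    if not 0 < fsum < 1:
        raise InvalidInputError("target fractions must sum to within (0, 100)%")
    # u_j = c beta_j^2 / sigma^2 ; T = sum u ; f_j (T + n-1) = u_j + 1
    big_t = (fsum * (n_obs - 1) - m) / (1 - fsum)
    u = f * (big_t + n_obs - 1) - 1
    if (u <= 0).any():
        raise InvalidInputError("a target fraction is too small to exceed the noise floor")
    betas = direction * noise_sd * np.sqrt(u / c)
    return PhenotypeTruth(intercept=intercept, betas=betas, noise_sd=noise_sd)


def simulate_phenotypes(
    panel: pd.DataFrame,
    truth: PhenotypeTruth,
    reps: int = 4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-replicate sporulation efficiencies (%) for a panel.

    efficiency = clip(intercept + sum_t beta_t * x_t + N(0, noise_sd), 0, 100),
    with x_t the 0/1 V-indicator products of the strain's genotype.
    Reproducible for a fixed seed.
    """
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    design = build_design_matrix(panel)
    mu = truth.intercept + _linear_effect(design, truth.betas)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, reps + 1):
        noise = rng.normal(0.0, truth.noise_sd, size=len(panel)) if truth.noise_sd else 0.0
        eff = np.clip(mu + noise, 0.0, 100.0)
        rows.append(
            pd.DataFrame(
                {"strain_id": panel.index, "replicate": rep, "efficiency": eff}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _linear_effect(design: pd.DataFrame, betas: pd.Series) -> np.ndarray:
    unknown = set(betas.index) - set(design.columns)
    if unknown:
        raise InvalidInputError(f"truth references unknown model terms: {sorted(unknown)}")
    return design[betas.index].to_numpy() @ betas.to_numpy() if len(betas) else np.zeros(len(design))


def default_sample_table(
    panel: pd.DataFrame,
    reps: int = 4,
    days: Sequence[str] | None = None,
    dropped_strain: str | None = DEFAULT_DROPPED_STRAIN,
    dropped_replicate: int | None = None,
) -> pd.DataFrame:
    """Sample table for the emulated study design.

    Each strain gets ``reps`` replicates; replicate r of every strain is
    grown on the same day (days default to "A", "B", ...), so day is a
    batch shared across the panel.  One strain (by default the one with
    vineyard alleles at RME1nc/RSF1c/IME1nc and oak at IME1c) loses one
    replicate (by default the last), giving 63 samples in the default
    16-strain, 4-replicate configuration.  Pass ``dropped_strain=None`` for
    a complete table.
    """
    validate_panel(panel)
    if days is None:
        days = [chr(ord("A") + i) for i in range(reps)]
    if len(days) != reps:
        raise InvalidInputError("need exactly one day label per replicate")
    if dropped_strain is not None and dropped_strain not in panel.index:
        raise InvalidInputError(f"dropped strain {dropped_strain!r} not in panel")
    if dropped_replicate is None:
        dropped_replicate = reps
    rows = []
    for strain in panel.index:
        for rep in range(1, reps + 1):
            if strain == dropped_strain and rep == dropped_replicate:
                continue
            rows.append((f"{strain}_r{rep}", strain, days[rep - 1], rep))
    table = pd.DataFrame(rows, columns=["sample_id", "strain_id", "day", "replicate"])
    return table.set_index("sample_id")


def validate_sample_table(sample_table: pd.DataFrame, panel: pd.DataFrame) -> None:
    if sample_table.index.has_duplicates:
        dup = sample_table.index[sample_table.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"duplicate sample ids: {dup}")
    unknown = set(sample_table["strain_id"]) - set(panel.index)
    if unknown:
        raise InvalidInputError(f"samples reference unknown strains: {sorted(unknown)}")
    if sample_table["day"].nunique() < 1:
        raise InvalidInputError("sample table has no day levels")


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth behind a simulated count matrix.

    ``betas`` is a genes x terms effect table whose columns are ``intercept``
    plus factorial term labels; scale is the count scale in gaussian mode and
    the log scale in nb mode.  ``day_effects`` maps each day label to an
    additive offset (gaussian) or a strictly positive multiplier (nb).
    ``dispersion`` is the negative-binomial size parameter (variance =
    mu + mu**2/size); ``numpy.inf`` gives the Poisson limit.
    """

    betas: pd.DataFrame
    day_effects: pd.Series
    mode: str = "gaussian"
    noise_sd: float = 0.0
    dispersion: float = 10.0

    def __post_init__(self):
        if self.mode not in ("gaussian", "nb"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        if INTERCEPT not in self.betas.columns:
            raise InvalidInputError("betas must contain an 'intercept' column")
        if self.mode == "nb" and (self.day_effects <= 0).any():
            raise InvalidInputError("nb-mode day multipliers must be strictly positive")
        if self.mode == "nb" and not self.dispersion > 0:
            raise InvalidInputError("dispersion must be > 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.betas)

    def genotype_terms(self) -> list[str]:
        return [c for c in self.betas.columns if c != INTERCEPT]

    def affected_genes(self) -> pd.Index:
        """Genes with at least one nonzero genotype effect."""
        g = self.betas[self.genotype_terms()]
        return self.betas.index[(g != 0).any(axis=1)]


def random_expression_truth(
    n_genes: int,
    loci: Sequence[str] = SPORULATION_LOCI,
    mode: str = "gaussian",
    frac_affected: float = 0.05,
    days: Sequence[str] = ("A", "B", "C", "D"),
    day_effect_sd: float = 0.0,
    noise_sd: float = 20.0,
    dispersion: float = 10.0,
    target_r2: float = 0.5,
    n_obs: int = 63,
    seed: int | None = None,
) -> ExpressionTruth:
    """Draw a per-gene effect table emulating the study's expression truth.

    A fraction ``frac_affected`` of genes (default 5%, matching the share of
    the genome with significant genotype models in the emulated study)
    receive nonzero genotype effects spread over one to four randomly chosen
    factorial terms, scaled so the expected fraction of variance explained by
    genotype is roughly ``target_r2``.  The remaining genes are pure noise
    and provide the null background for calibration checks.

    Day effects are drawn per day with ``day_effect_sd`` (additive offsets in
    gaussian mode; in nb mode the offsets act on the log scale, giving
    lognormal multipliers centered on 1).
    """
    if n_genes < 1:
        raise InvalidInputError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    terms = [
        term_label(t)
        for k in range(1, len(loci) + 1)
        for t in itertools.combinations(loci, k)
    ]
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    betas = pd.DataFrame(0.0, index=genes, columns=[INTERCEPT] + terms)

    if mode == "gaussian":
        betas[INTERCEPT] = rng.uniform(50.0, 500.0, size=n_genes)
        sigma2 = noise_sd**2
    else:
        betas[INTERCEPT] = rng.uniform(np.log(20.0), np.log(2000.0), size=n_genes)
        sigma2 = 0.25  # rough log-scale noise proxy for effect sizing

    n_affected = int(round(frac_affected * n_genes))
    affected = rng.choice(n_genes, size=n_affected, replace=False)
    # size effects so genotype SS/(genotype SS + noise SS) ~ target_r2
    ss_target = target_r2 / (1.0 - target_r2) * (n_obs - 1) * sigma2
    c = n_obs / 4.0
    for i in affected:
        k = rng.integers(1, 5)
        chosen = rng.choice(terms, size=k, replace=False)
        mags = np.sqrt(ss_target / (c * k))
        betas.iloc[i, [betas.columns.get_loc(t) for t in chosen]] = (
            rng.choice([-1.0, 1.0], size=k) * mags * rng.uniform(0.6, 1.4, size=k)
        )

    offsets = pd.Series(rng.normal(0.0, day_effect_sd, size=len(days)), index=list(days))
    day_effects = np.exp(offsets) if mode == "nb" else offsets
    return ExpressionTruth(
        betas=betas,
        day_effects=day_effects,
        mode=mode,
        noise_sd=noise_sd,
        dispersion=dispersion,
    )


def simulate_expression_counts(
    panel: pd.DataFrame,
    sample_table: pd.DataFrame,
    truth: ExpressionTruth | None = None,
    n_genes: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Simulate a genes x samples count matrix from a truth record.

    If ``truth`` is omitted it is drawn by :func:`random_expression_truth`
    (``n_genes`` is then required).  Returns the count matrix together with
    the truth actually used, for downstream recovery tests.
    """
    validate_sample_table(sample_table, panel)
    if truth is None:
        if n_genes is None:
            raise InvalidInputError("either truth or n_genes must be given")
        truth = random_expression_truth(
            n_genes,
            loci=tuple(panel.columns),
            days=sorted(sample_table["day"].unique()),
            n_obs=len(sample_table),
            seed=seed,
        )
    unknown_days = set(sample_table["day"]) - set(truth.day_effects.index)
    if unknown_days:
        raise InvalidInputError(f"sample days without a day effect: {sorted(unknown_days)}")

    design = build_design_matrix(panel, sample_table)
    terms = truth.genotype_terms()
    # genes x samples linear predictor
    eta = (
        truth.betas[INTERCEPT].to_numpy()[:, None]
        + truth.betas[terms].to_numpy() @ design[terms].to_numpy().T
    )
    day_vec = truth.day_effects[sample_table["day"]].to_numpy()

    rng = np.random.default_rng(seed)
    if truth.mode == "gaussian":
        mu = eta + day_vec[None, :]
        noise = rng.normal(0.0, truth.noise_sd, size=mu.shape) if truth.noise_sd else 0.0
        values = np.maximum(0.0, np.round(mu + noise))
    else:
        mean = day_vec[None, :] * np.exp(eta)
        if np.isinf(truth.dispersion):
            values = rng.poisson(mean).astype(float)
        else:
            p = truth.dispersion / (truth.dispersion + mean)
            values = rng.negative_binomial(truth.dispersion, p).astype(float)

    counts = pd.DataFrame(values, index=truth.betas.index, columns=sample_table.index)
    counts.columns.name = "sample_id"
    return counts, truth


def default_dataset(
    n_genes: int = 2000,
    seed: int | None = None,
    mode: str = "gaussian",
    frac_affected: float = 0.05,
    day_effect_sd: float | None = None,
    phenotype_truth: PhenotypeTruth | None = None,
):
    """One-call synthetic study: panel, samples, counts, phenotypes, truths.

    Reproduces the emulated design end to end: full 2^4 panel, 63 expression
    samples (one dropped replicate), 64 phenotype observations, day batches.
    Returns a dict with keys ``panel``, ``samples``, ``counts``,
    ``expression_truth``, ``phenotypes``, ``phenotype_truth``.
    """
    panel = make_full_factorial_panel()
    samples = default_sample_table(panel)
    if day_effect_sd is None:
        day_effect_sd = 15.0 if mode == "gaussian" else 0.15
    truth = random_expression_truth(
        n_genes,
        mode=mode,
        frac_affected=frac_affected,
        day_effect_sd=day_effect_sd,
        n_obs=len(samples),
        seed=seed,
    )
    counts, truth = simulate_expression_counts(panel, samples, truth, seed=seed)
    if phenotype_truth is None:
        phenotype_truth = phenotype_truth_from_fractions()
    phenotypes = simulate_phenotypes(panel, phenotype_truth, reps=4, seed=seed)
    return {
        "panel": panel,
        "samples": samples,
        "counts": counts,
        "expression_truth": truth,
        "phenotypes": phenotypes,
        "phenotype_truth": phenotype_truth,
    }
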