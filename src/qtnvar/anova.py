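"""Sequential ANOVA tables and per-allele variance-share statistics.

The central quantity is the *fraction of variance explained* by each
factorial term: 100 * SS_term / SS_total, where the sequential (Type-I) sum
of squares of a term is the drop in residual SS when the term joins the
model in canonical order, and SS_total includes the residual SS.  Fractions
over all terms plus the residual therefore sum to 100.

Per-allele summaries credit a term's fraction to every locus it contains
(so a two-locus interaction counts toward both loci — overlap is intended),
and only terms whose per-term F-test is significant at a permissive
threshold (p < 0.1 by default) contribute.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidInputError
from .models import FactorialAnova, ModelFit
from .panel import loci_in_term, term_order

RESIDUAL_ROW = "Residuals"


def sequential_anova(fit, response=None) -> pd.DataFrame:
    """Type-I ANOVA table from a fitted model.

    ``fit`` is a :class:`~qtnvar.models.FactorialAnova` (pass ``response=``
    for multi-gene fits) or a :class:`~qtnvar.models.ModelFit`.  Rows are
    model terms in sequence order plus a ``Residuals`` row; columns are
    ``df``, ``ss``, ``ms``, ``f``, ``p``.
    """
    if isinstance(fit, ModelFit):
        return fit.anova
    if isinstance(fit, FactorialAnova):
        return fit.anova_table(response)
    raise InvalidInputError(f"cannot extract an ANOVA table from {type(fit).__name__}")


def _genotype_terms(table: pd.DataFrame) -> list[str]:
    terms = table.attrs.get("genotype_terms")
    if terms is None:
        terms = [t for t in table.index if t != RESIDUAL_ROW and "[" not in t]
    return [t for t in terms if t in table.index]


def fraction_of_variance(table: pd.DataFrame) -> pd.Series:
    """Percent of total SS per table row (the residual row included).

    The denominator is the grand total: the sum of every term's SS plus the
    residual SS, so the returned percentages sum to 100.
    """
    total = float(table["ss"].sum())
    if total <= 0:
        raise DegenerateInputError("total sum of squares is zero; fractions undefined")
    return 100.0 * table["ss"] / total


class AdditiveInteractionSplit(NamedTuple):
    additive: float
    interaction: float


def additive_interaction_split(
    table: pd.DataFrame, p_threshold: float = 0.1
) -> AdditiveInteractionSplit:
    """Total explained variance split into significant main vs interaction %.

    Sums the variance fractions of the significant (p < ``p_threshold``)
    genotype main-effect terms and, separately, of the significant
    interaction terms.  Covariate rows (bracketed labels) and the residual
    are excluded from both sums.
    """
    frac = fraction_of_variance(table)
    genotype = _genotype_terms(table)
    sig = table["p"].lt(p_threshold) & table.index.isin(genotype)
    additive = frac[sig & (table.index.map(term_order) == 1)].sum()
    interaction = frac[sig & (table.index.map(term_order) >= 2)].sum()
    return AdditiveInteractionSplit(float(additive), float(interaction))


def allele_shares(
    table: pd.DataFrame, p_threshold: float = 0.1, gene_id: str | None = None
) -> pd.DataFrame:
    """Per-allele main/interaction variance shares from one ANOVA table.

    For each locus: ``main_fraction`` is the variance fraction of its main
    term when that term is significant (else 0); ``interaction_fraction``
    sums the fractions of significant interaction terms containing the
    locus.  A k-locus interaction is credited to each of its k loci.
    """
    frac = fraction_of_variance(table)
    genotype = _genotype_terms(table)
    loci = [t for t in genotype if term_order(t) == 1]
    sig = set(table.index[table["p"].lt(p_threshold) & table.index.isin(genotype)])
    rows = []
    for locus in loci:
        main = float(frac[locus]) if locus in sig else 0.0
        inter_terms = [
            t for t in genotype if term_order(t) >= 2 and locus in loci_in_term(t)
        ]
        inter = float(frac[[t for t in inter_terms if t in sig]].sum())
        n_sig = int(locus in sig) + sum(t in sig for t in inter_terms)
        rows.append(
            {
                "allele": locus,
                "main_fraction": main,
                "interaction_fraction": inter,
                "total_fraction": main + inter,
                "n_significant_terms": n_sig,
            }
        )
    out = pd.DataFrame(rows).set_index("allele")
    if gene_id is not None:
        out.insert(0, "gene_id", gene_id)
    return out


# ---------------------------------------------------------------------------
# Vectorized per-gene summaries for multi-response fits
# ---------------------------------------------------------------------------

def anova_long_table(est: FactorialAnova) -> pd.DataFrame:
    """Long-format per-gene ANOVA: gene, term, df, ss, ms, f, p, fraction."""
    terms = [t for t in est.result_.terms if t != "intercept" and t not in est.aliased_]
    ss = est.sequential_ss_.loc[terms]
    total = ss.sum(axis=0) + est.residual_ss_
    frames = []
    for t in terms:
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": ss.columns,
                    "term": t,
                    "df": 1,
                    "ss": ss.loc[t].to_numpy(),
                    "f": est.result_.term_f.loc[t].to_numpy(),
                    "p": est.result_.term_p.loc[t].to_numpy(),
                    "fraction": 100.0 * ss.loc[t].to_numpy() / total.to_numpy(),
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "gene_id": ss.columns,
                "term": RESIDUAL_ROW,
                "df": est.df_residual_,
                "ss": est.residual_ss_.to_numpy(),
                "f": np.nan,
                "p": np.nan,
                "fraction": 100.0 * est.residual_ss_.to_numpy() / total.to_numpy(),
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


def allele_shares_by_gene(
    est: FactorialAnova, p_threshold: float = 0.1
) -> pd.DataFrame:
    """Per gene x allele variance shares for a multi-gene factorial fit.

    Vectorized equivalent of applying :func:`allele_shares` to every gene's
    ANOVA table; returns a long frame with one row per (gene, allele).
    """
    genotype = est.genotype_terms_
    loci = [t for t in genotype if term_order(t) == 1]
    ss = est.sequential_ss_.loc[genotype]                      # terms x genes
    covars = [
        t for t in est.result_.terms
        if t not in genotype and t != "intercept" and t not in est.aliased_
    ]
    total = (
        ss.sum(axis=0)
        + (est.sequential_ss_.loc[covars].sum(axis=0) if covars else 0.0)
        + est.residual_ss_
    )
    frac = 100.0 * ss.div(total, axis=1)
    sig = est.result_.term_p.loc[genotype] < p_threshold
    sig_frac = frac.where(sig, 0.0)

    frames = []
    for locus in loci:
        inter_terms = [
            t for t in genotype if term_order(t) >= 2 and locus in loci_in_term(t)
        ]
        main = sig_frac.loc[locus]
        inter = sig_frac.loc[inter_terms].sum(axis=0)
        n_sig = sig.loc[[locus] + inter_terms].sum(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": frac.columns,
                    "allele": locus,
                    "main_fraction": main.to_numpy(),
                    "interaction_fraction": inter.to_numpy(),
                    "total_fraction": main.to_numpy() + inter.to_numpy(),
                    "n_significant_terms": n_sig.to_numpy(dtype=int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def additive_interaction_split_by_gene(
    est: FactorialAnova, p_threshold: float = 0.1
) -> pd.DataFrame:
    """Per-gene significant main vs interaction explained-variance percents."""
    genotype = est.genotype_terms_
    ss = est.sequential_ss_.loc[genotype]
    covars = [
        t for t in est.result_.terms
        if t not in genotype and t != "intercept" and t not in est.aliased_
    ]
    total = (
        ss.sum(axis=0)
        + (est.sequential_ss_.loc[covars].sum(axis=0) if covars else 0.0)
        + est.residual_ss_
    )
    frac = 100.0 * ss.div(total, axis=1)
    sig = est.result_.term_p.loc[genotype] < p_threshold
    sig_frac = frac.where(sig, 0.0)
    orders = pd.Series({t: term_order(t) for t in genotype})
    additive = sig_frac.loc[orders[orders == 1].index].sum(axis=0)
    interaction = sig_frac.loc[orders[orders >= 2].index].sum(axis=0)
    return pd.DataFrame(
        {"additive": additive, "interaction": interaction},
        index=pd.Index(frac.columns, name="gene_id"),
    )


def summarize_allele_shares(
    shares: pd.DataFrame, genes: pd.Index | None = None
) -> pd.DataFrame:
    """Panel-level per-allele summary over a set of genes.

    For each allele: the number of genes where it has any significant term,
    the number (and fraction, %) where its *main* effect contributes, and
    the median total/main/interaction variance shares.  ``genes`` restricts
    the summary (typically to genes with significant overall models).
    """
    df = shares if genes is None else shares[shares["gene_id"].isin(genes)]
    rows = []
    for allele, grp in df.groupby("allele", sort=False):
        any_sig = grp["n_significant_terms"] > 0
        main_sig = grp["main_fraction"] > 0
        rows.append(
            {
                "allele": allele,
                "n_genes_any_effect": int(any_sig.sum()),
                "n_genes_main_effect": int(main_sig.sum()),
                "pct_genes_main_effect": 100.0 * main_sig.mean() if len(grp) else np.nan,
                "median_total_pct": float(grp["total_fraction"].median()),
                "median_main_pct": float(grp["main_fraction"].median()),
                "median_interaction_pct": float(grp["interaction_fraction"].median()),
            }
        )
    return pd.DataFrame(rows).set_index("allele")
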