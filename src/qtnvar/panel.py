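"""Allele-replacement panels and factorial model design matrices.

An allele replacement panel is a set of isogenic strains that differ only at a
small number of engineered quantitative trait nucleotides (QTN).  Each locus
carries one of two alleles, coded ``O`` (oak) and ``V`` (vineyard) after the
natural *S. cerevisiae* isolates the variants come from.  A *full* panel
contains every one of the ``2**L`` allele combinations, which makes the loci a
complete two-level factorial design: per-locus main effects and all
interaction effects are estimable from a single experiment.

The model parameterization used throughout the package is treatment (dummy)
coding with the oak allele as the reference level: the indicator for a locus
is 1 when the strain carries the vineyard allele and 0 otherwise, and an
interaction column is the elementwise product of its constituent main-effect
columns.  The intercept is therefore the expected response of the all-oak
strain, and each coefficient is the effect of swapping oak for vineyard at
that locus (or combination of loci) in the all-oak background.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

#: The four sporulation-efficiency QTN, in canonical model order.
#: RME1nc = RME1(indel-308A), RSF1c = RSF1(D181G), IME1c = IME1(L325M),
#: IME1nc = IME1(A-548G).
SPORULATION_LOCI: tuple[str, ...] = ("RME1nc", "RSF1c", "IME1c", "IME1nc")

#: Allele codes: O = oak (reference), V = vineyard (indicator 1).
ALLELES: tuple[str, str] = ("O", "V")

INTERCEPT = "intercept"


def make_full_factorial_panel(loci: Sequence[str] = SPORULATION_LOCI) -> pd.DataFrame:
    """Enumerate every O/V allele combination at the given loci.

    Parameters
    ----------
    loci : sequence of str
        Distinct locus labels, between 1 and 8 of them.

    Returns
    -------
    pandas.DataFrame
        One row per strain, indexed by strain id (the allele string, e.g.
        ``"OVOO"``), one column per locus holding ``"O"`` or ``"V"``.
        Rows are in deterministic order: O before V, last locus fastest,
        so the first strain is all-O and the last is all-V.
    """
    loci = tuple(loci)
    if not 1 <= len(loci) <= 8:
        raise InvalidInputError(f"need between 1 and 8 loci, got {len(loci)}")
    if len(set(loci)) != len(loci):
        raise InvalidInputError(f"duplicate locus labels in {loci}")
    rows = list(itertools.product(ALLELES, repeat=len(loci)))
    panel = pd.DataFrame(rows, columns=list(loci))
    panel.index = pd.Index(["".join(r) for r in rows], name="strain_id")
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    """Check panel invariants: distinct strains, known allele codes."""
    if panel.index.has_duplicates:
        dup = panel.index[panel.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"duplicate strain ids: {dup}")
    bad = ~panel.isin(ALLELES)
    if bad.to_numpy().any():
        where = [(s, l) for s, l in zip(*np.nonzero(bad.to_numpy()))]
        s, l = where[0]
        raise InvalidInputError(
            f"allele code {panel.iloc[s, l]!r} at strain "
            f"{panel.index[s]!r}, locus {panel.columns[l]!r} (expected O or V)"
        )


def model_terms(loci: Sequence[str]) -> list[tuple[str, ...]]:
    """All factorial model terms in canonical order.

    Order is: intercept (empty tuple), then main effects in locus order, then
    interactions grouped by order (all two-way, then three-way, ...), each
    group enumerated in lexicographic combination order of the loci.  For the
    four sporulation QTN this reproduces the conventional ANOVA row order.
    """
    loci = tuple(loci)
    terms: list[tuple[str, ...]] = [()]
    for k in range(1, len(loci) + 1):
        terms.extend(itertools.combinations(loci, k))
    return terms


def term_label(term: Iterable[str]) -> str:
    """Human-readable column label: ``intercept`` or ``"A:B"``."""
    term = tuple(term)
    return INTERCEPT if not term else ":".join(term)


def loci_in_term(label: str) -> tuple[str, ...]:
    """Inverse of :func:`term_label` (the intercept maps to an empty tuple)."""
    return () if label == INTERCEPT else tuple(label.split(":"))


def term_order(label: str) -> int:
    """Interaction order of a term label: 0 intercept, 1 main, >=2 interaction."""
    return len(loci_in_term(label))


def build_design_matrix(
    panel: pd.DataFrame,
    sample_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full-factorial 0/1 design matrix under V-indicator treatment coding.

    Parameters
    ----------
    panel : DataFrame
        Strains x loci allele table (``"O"``/``"V"`` entries), as produced by
        :func:`make_full_factorial_panel` or read from a genotype table.
    sample_table : DataFrame, optional
        If given, must contain a ``strain_id`` column; the design has one row
        per sample (indexed by the sample table's index) with the design row
        of that sample's strain.  Without it the design has one row per
        strain.

    Returns
    -------
    DataFrame
        Columns ordered intercept, main effects in panel-column order,
        then interactions grouped by order (see :func:`model_terms`).
        ``2**L`` columns for L loci; entries are 0/1 products of the
        V-allele indicators.
    """
    validate_panel(panel)
    loci = tuple(panel.columns)
    indicators = (panel == "V").astype(float)

    if sample_table is not None:
        unknown = set(sample_table["strain_id"]) - set(panel.index)
        if unknown:
            raise InvalidInputError(f"sample table references unknown strains: {sorted(unknown)}")
        indicators = indicators.loc[sample_table["strain_id"]].set_axis(sample_table.index)

    cols = {}
    for term in model_terms(loci):
        if not term:
            cols[INTERCEPT] = np.ones(len(indicators))
        else:
            cols[term_label(term)] = indicators[list(term)].prod(axis=1).to_numpy()
    return pd.DataFrame(cols, index=indicators.index)
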