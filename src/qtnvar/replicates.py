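"""Replicate-noise quantification and rank-based allele comparisons.

The coefficient of variation (CV = sigma/mu) across biological replicates is
a scale-free measure of measurement noise.  Because replicates were grown on
different days, a multiplicative day correction is applied first so that the
CV reflects replicate noise on the original count scale rather than batch
shifts: each gene's counts on a day are divided by the ratio of that day's
mean to the reference day's mean.

Rank-based comparison of per-gene variance-share profiles between two
alleles uses the two-sample Wilcoxon rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import InvalidInputError


class DayCorrected(NamedTuple):
    counts: pd.DataFrame
    uncorrected_genes: pd.Index


def day_correct_counts(
    counts: pd.DataFrame, sample_table: pd.DataFrame, reference_day
) -> DayCorrected:
    """Multiplicative day correction of a genes x samples count matrix.

    value'_{gs} = value_{gs} / (mean_{g, day(s)} / mean_{g, ref_day});
    samples grown on the reference day are unchanged.  Genes with a
    nonpositive mean on some day cannot be corrected; they are returned
    unchanged and listed in ``uncorrected_genes``.
    """
    missing = set(counts.columns) - set(sample_table.index)
    if missing:
        raise InvalidInputError(f"samples missing from sample table: {sorted(missing)}")
    days = sample_table.loc[counts.columns, "day"]
    if reference_day not in set(days):
        raise InvalidInputError(f"reference day {reference_day!r} has no samples")

    day_means = counts.T.groupby(days.to_numpy(), observed=True).mean().T  # genes x days
    correctable = (day_means > 0).all(axis=1)
    ratios = day_means.div(day_means[reference_day], axis=0)          # genes x days
    factors = ratios.loc[:, days.to_numpy()].set_axis(counts.columns, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = counts / factors
    flagged = counts.index[~correctable]
    corrected.loc[flagged] = counts.loc[flagged]
    return DayCorrected(corrected, flagged)


class CVRow(NamedTuple):
    sigma: float
    mu: float
    cv: float
    defined: bool


def coefficient_of_variation(values) -> CVRow:
    """Sample CV of a replicate vector: sd (n-1 denominator) over mean.

    Undefined (flagged, cv = NaN) when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("CV requires at least 2 replicate values")
    mu = float(v.mean())
    sigma = float(v.std(ddof=1))
    if mu == 0:
        return CVRow(sigma, mu, float("nan"), False)
    return CVRow(sigma, mu, sigma / mu, True)


def cv_table(counts: pd.DataFrame, sample_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-strain CV across biological replicates.

    ``counts`` should normally be day-corrected first (see
    :func:`day_correct_counts`).  Returns a long frame with columns
    ``gene_id``, ``strain_id``, ``sigma``, ``mu``, ``cv``; strains with a
    single replicate are skipped, genes with zero mean get cv = NaN.
    """
    strains = sample_table.loc[counts.columns, "strain_id"]
    frames = []
    for strain, cols in counts.columns.to_series().groupby(strains.to_numpy()):
        if len(cols) < 2:
            continue
        block = counts[cols.to_numpy()]
        mu = block.mean(axis=1)
        sigma = block.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mu.to_numpy() != 0, sigma.to_numpy() / mu.to_numpy(), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.index,
                    "strain_id": strain,
                    "sigma": sigma.to_numpy(),
                    "mu": mu.to_numpy(),
                    "cv": cv,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class RankComparison(NamedTuple):
    statistic: float
    p_value: float


def compare_allele_rankings(
    shares_a, shares_b, method: str = "asymptotic"
) -> RankComparison:
    """Two-sample Wilcoxon rank-sum test between two share vectors.

    Default is the normal approximation with tie correction and continuity
    correction, two-sided; ``method="exact"`` uses the exact U distribution
    (valid without ties).  Returns the Mann-Whitney U statistic of the first
    sample and the two-sided p-value.  If every value in both samples is
    identical the test is degenerate and p = 1.
    """
    a = np.asarray(shares_a, dtype=float)
    b = np.asarray(shares_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both share vectors must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankComparison(float(a.size * b.size / 2.0), 1.0)
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return RankComparison(float(res.statistic), float(min(res.pvalue, 1.0)))
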