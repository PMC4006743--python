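"""Multiple-testing control: BH FDR and a permutation genome-wide threshold.

Two complementary significance devices operate on the per-gene model
p-values from the factorial fits:

* the Benjamini-Hochberg step-up procedure controls the false discovery
  rate across genes (default 10%);
* a genotype-permutation null: sample-to-strain assignments are shuffled as
  intact multi-locus genotype vectors, the full factorial model is refit to
  every gene, and the 5th percentile of the genome-wide model p-values is
  recorded per permutation.  The distribution of that percentile tells
  whether the observed genome-wide signal (and the largest unadjusted
  p-value among BH rejections) is stronger than chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError
from .models import fit_sequential_ols
from .panel import build_design_matrix

logger = logging.getLogger("qtnvar")


def bh_adjust(p_values, fdr: float = 0.10) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment of per-gene model p-values.

    Returns a frame indexed like the input with columns ``model_p``,
    ``adjusted_p`` and ``significant`` (adjusted p <= ``fdr``).  The largest
    unadjusted p-value among the rejections — the effective genome-wide
    threshold implied by the FDR level — is stored in
    ``result.attrs["max_significant_p"]`` (NaN when nothing is rejected).
    """
    if not 0 < fdr < 1:
        raise InvalidInputError("fdr must be in (0, 1)")
    p = pd.Series(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    if p.empty:
        out = pd.DataFrame(columns=["model_p", "adjusted_p", "significant"])
        out.attrs["max_significant_p"] = float("nan")
        return out
    reject, adjusted, _, _ = multipletests(p.to_numpy(), alpha=fdr, method="fdr_bh")
    out = pd.DataFrame(
        {"model_p": p.to_numpy(), "adjusted_p": adjusted, "significant": reject},
        index=p.index,
    )
    out.attrs["max_significant_p"] = (
        float(p.to_numpy()[reject].max()) if reject.any() else float("nan")
    )
    return out


@dataclass
class PermutationNull:
    """Distribution of the genome-wide 5th-percentile model p under the null."""

    percentiles: pd.Series          # one value per permutation replicate
    percentile: float               # which quantile of the p-values was taken
    n_genes: int

    @property
    def mean(self) -> float:
        return float(self.percentiles.mean())

    @property
    def sd(self) -> float:
        return float(self.percentiles.std(ddof=1)) if len(self.percentiles) > 1 else float("nan")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": self.percentiles.index, "percentile_p": self.percentiles.to_numpy()}
        )

    def z_score(self, observed_p: float) -> float:
        """Standardized position of an observed percentile p in the null."""
        return (observed_p - self.mean) / self.sd

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.percentiles.to_numpy(), [alpha, 1.0 - alpha])
        return float(lo), float(hi)


def genomewide_percentile_p(model_p) -> float:
    """The 5th-percentile (by default usage) helper: see numpy.quantile."""
    return float(np.quantile(np.asarray(model_p, dtype=float), 0.05))


def permutation_threshold(
    residuals: pd.DataFrame,
    panel: pd.DataFrame,
    sample_table: pd.DataFrame,
    n_perm: int = 1000,
    percentile: float = 0.05,
    seed: int | None = None,
    stratify_by_day: bool = False,
) -> PermutationNull:
    """Permutation null of the genome-wide ``percentile`` of model p-values.

    Each replicate permutes the sample-to-strain assignment — every sample
    keeps its full multi-locus genotype vector, so the multiset of genotype
    vectors is preserved exactly — refits the full factorial model to every
    gene of the (already day-residualized) matrix, and records the requested
    percentile of the per-gene model p-values.

    ``stratify_by_day=True`` permutes within day strata instead (off by
    default).  One master seed spawns independent per-replicate streams, so
    results are reproducible and order-insensitive.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    if not 0 < percentile < 1:
        raise InvalidInputError("percentile must be in (0, 1)")
    design = build_design_matrix(panel, sample_table.loc[residuals.columns])
    X = design.to_numpy(dtype=float)
    Y = residuals.T  # samples x genes
    n = len(X)
    genotype_rows = [tuple(r) for r in X]

    if stratify_by_day:
        day = sample_table.loc[residuals.columns, "day"].to_numpy()
        strata = [np.flatnonzero(day == d) for d in pd.unique(day)]
    else:
        strata = [np.arange(n)]

    columns = list(design.columns)
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    values = np.empty(n_perm)
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        perm = np.arange(n)
        for idx in strata:
            perm[idx] = idx[rng.permutation(len(idx))]
        Xp = X[perm]
        # permutation must preserve the multiset of genotype vectors
        assert sorted(map(tuple, Xp)) == sorted(genotype_rows)
        res = fit_sequential_ols(
            pd.DataFrame(Xp, index=Y.index, columns=columns), Y
        )
        values[r] = np.quantile(res.model_p.to_numpy(), percentile)
        if (r + 1) % 100 == 0:
            logger.info("permutation %d/%d", r + 1, n_perm)

    return PermutationNull(
        percentiles=pd.Series(values, index=pd.RangeIndex(1, n_perm + 1, name="replicate")),
        percentile=percentile,
        n_genes=residuals.shape[0],
    )
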