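"""Small reference datasets bundled with the package."""

from __future__ import annotations

import pandas as pd
import scipy.stats

_SPORULATION_ANOVA_ROWS = [
    # term, df, sum of squares
    ("RME1nc", 1, 7702.0),
    ("RSF1c", 1, 4517.0),
    ("IME1c", 1, 7212.0),
    ("IME1nc", 1, 1459.1),
    ("RME1nc:RSF1c", 1, 293.7),
    ("RME1nc:IME1c", 1, 134.3),
    ("RME1nc:IME1nc", 1, 84.6),
    ("RSF1c:IME1c", 1, 118.6),
    ("RSF1c:IME1nc", 1, 32.9),
    ("IME1c:IME1nc", 1, 124.6),
    ("RME1nc:RSF1c:IME1c", 1, 161.4),
    ("RME1nc:RSF1c:IME1nc", 1, 4.4),
    ("RME1nc:IME1c:IME1nc", 1, 136.3),
    ("RSF1c:IME1c:IME1nc", 1, 34.6),
    ("RME1nc:RSF1c:IME1c:IME1nc", 1, 0.1),
    ("Residuals", 48, 427.8),
]


def sporulation_anova() -> pd.DataFrame:
    """Published sporulation-efficiency ANOVA for the 16-strain oak/vineyard panel.

    The sequential ANOVA (df and sums of squares) of sporulation efficiency
    on the four QTN — RME1nc = RME1(indel-308A), RSF1c = RSF1(D181G),
    IME1c = IME1(L325M), IME1nc = IME1(A-548G) — measured on the full 2^4
    allele replacement panel with four biological replicates per strain
    (64 observations, residual df 48).  Mean squares, F statistics, p-values
    and variance fractions are recomputed from df and SS by the package's
    own routines rather than stored.
    """
    table = pd.DataFrame(
        _SPORULATION_ANOVA_ROWS, columns=["term", "df", "ss"]
    ).set_index("term")
    table["ms"] = table["ss"] / table["df"]
    resid_ms = table.loc["Residuals", "ms"]
    terms = table.index != "Residuals"
    table.loc[terms, "f"] = table.loc[terms, "ms"] / resid_ms
    table.loc[terms, "p"] = scipy.stats.f.sf(
        table.loc[terms, "f"], 1, int(table.loc["Residuals", "df"])
    )
    genotype = [t for t in table.index if t != "Residuals"]
    table.attrs["genotype_terms"] = genotype
    table.attrs["response"] = "sporulation_efficiency"
    return table
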