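"""Day residualization and full-factorial linear models of expression/phenotype.

The modelling pipeline is two-stage, mirroring how batch and genotype effects
are separated in the emulated study design:

1. per gene, ordinary least squares of the normalized counts on day-of-growth
   indicators removes the additive batch effect (``DayResidualizer`` /
   :func:`fit_day_residuals`);
2. per gene (or for the phenotype), the residuals are regressed on the full
   2^L factorial design of V-allele indicators — all main effects and all
   interactions (``FactorialAnova`` / :func:`fit_genotype_model`).

An alternative single-stage model regresses log-transformed counts on day
indicators *and* the factorial genotype terms jointly
(``response_transform="log"``); its model p-value is the partial F-test of
the genotype terms given the day covariates, so that it measures genotype
significance in both variants.

All fits go through one QR-based engine that also produces sequential
(Type-I) sums of squares per term: the SS attributed to a term is the drop
in residual SS when it is appended to the model in the fixed canonical
order, which for the factorial design reproduces conventional ANOVA tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import InvalidInputError
from .panel import INTERCEPT, build_design_matrix

#: Relative floor below which a response's centered total SS is treated as
#: zero variance (R^2 reported as 0, model p as 1).
_ZERO_VAR_RTOL = 1e-12


# ---------------------------------------------------------------------------
# QR engine
# ---------------------------------------------------------------------------

@dataclass
class SequentialOLS:
    """Multi-response OLS fit with sequential (Type-I) sums of squares.

    Arrays are indexed by (term, response) for coefficients and per-term SS
    and by response for scalar summaries.  ``tested_terms`` are the columns
    whose joint significance the model F-test measures (genotype terms;
    day covariates, when present, are adjusted for but not tested).
    """

    terms: list
    responses: list
    tested_terms: list
    coef: pd.DataFrame
    sequential_ss: pd.DataFrame
    residual_ss: pd.Series
    total_ss: pd.Series
    r_squared: pd.Series
    model_f: pd.Series
    model_p: pd.Series
    df_model: int
    df_residual: int
    n_obs: int
    aliased: tuple
    term_f: pd.DataFrame
    term_p: pd.DataFrame


def fit_sequential_ols(
    design: pd.DataFrame,
    Y,
    tested_terms: list | None = None,
) -> SequentialOLS:
    """Fit Y on the design (intercept first) with sequential SS per term.

    ``Y`` may be a Series (one response) or a DataFrame / 2-D array with one
    response per column.  Rank-deficient designs are handled by dropping
    aliased columns in sequence order; dropped terms are reported in
    ``aliased`` with NaN coefficients and zero sequential SS.
    """
    if design.columns[0] != INTERCEPT:
        raise InvalidInputError("design must start with an intercept column")
    y_frame = pd.DataFrame(Y)
    if len(y_frame) != len(design):
        raise InvalidInputError("response and design have different numbers of rows")
    X = design.to_numpy(dtype=float)
    Yv = y_frame.to_numpy(dtype=float)
    n, p = X.shape

    keep = np.ones(p, dtype=bool)
    while True:
        Q, R = np.linalg.qr(X[:, keep])
        diag = np.abs(np.diag(R))
        tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        bad = diag <= tol
        if not bad.any():
            break
        keep[np.flatnonzero(keep)[bad]] = False
    rank = int(keep.sum())
    if n <= rank:
        raise InvalidInputError(
            f"need more observations ({n}) than estimable model columns ({rank})"
        )
    aliased = tuple(design.columns[~keep])

    C = Q.T @ Yv                                   # (rank, k) projections
    resid = Yv - Q @ C
    rss = np.einsum("ij,ij->j", resid, resid)
    seq_ss = np.zeros((p, y_frame.shape[1]))
    seq_ss[keep] = C**2
    coef = np.full((p, y_frame.shape[1]), np.nan)
    coef[keep] = scipy.linalg.solve_triangular(R, C)

    col_mean = Yv.mean(axis=0)
    centered = Yv - col_mean
    tss = np.einsum("ij,ij->j", centered, centered)
    uncentered = np.einsum("ij,ij->j", Yv, Yv)
    zero_var = tss <= _ZERO_VAR_RTOL * np.maximum(uncentered, 1.0)

    terms = list(design.columns)
    if tested_terms is None:
        tested_terms = [t for t in terms if t != INTERCEPT]
    tested_kept = [t for t in tested_terms if t not in aliased]
    tested_idx = [terms.index(t) for t in tested_kept]
    df_model = len(tested_kept)
    df_residual = n - rank

    model_ss = seq_ss[tested_idx].sum(axis=0) if tested_idx else np.zeros_like(rss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(zero_var, 0.0, np.clip(1.0 - rss / np.where(tss > 0, tss, 1.0), 0.0, 1.0))
        if df_residual > 0 and df_model > 0:
            f = (model_ss / df_model) / (rss / df_residual)
            pval = scipy.stats.f.sf(f, df_model, df_residual)
            tf = seq_ss / (rss / df_residual)
            tp = scipy.stats.f.sf(tf, 1, df_residual)
        else:
            f = np.full_like(rss, np.nan)
            pval = np.full_like(rss, np.nan)
            tf = np.full(seq_ss.shape, np.nan)
            tp = np.full(seq_ss.shape, np.nan)
    f = np.where(zero_var, 0.0, f)
    pval = np.where(zero_var, 1.0, pval)

    responses = list(y_frame.columns)
    return SequentialOLS(
        terms=terms,
        responses=responses,
        tested_terms=tested_kept,
        coef=pd.DataFrame(coef, index=terms, columns=responses),
        sequential_ss=pd.DataFrame(seq_ss, index=terms, columns=responses),
        residual_ss=pd.Series(rss, index=responses),
        total_ss=pd.Series(tss, index=responses),
        r_squared=pd.Series(r2, index=responses),
        model_f=pd.Series(f, index=responses),
        model_p=pd.Series(pval, index=responses),
        df_model=df_model,
        df_residual=df_residual,
        n_obs=n,
        aliased=aliased,
        term_f=pd.DataFrame(tf, index=terms, columns=responses),
        term_p=pd.DataFrame(tp, index=terms, columns=responses),
    )


def _day_dummies(days, index) -> pd.DataFrame:
    """Treatment-coded day indicator columns, labelled ``DAY[<level>]``.

    Bracketed labels mark covariate (non-genotype) terms throughout the
    package; the first day level is the reference and gets no column.
    """
    if isinstance(days, pd.Series):
        days = days.set_axis(index)
    else:
        days = pd.Series(days, index=index, name="day")
    if isinstance(days.dtype, pd.CategoricalDtype):
        counts = days.value_counts()
        empty = counts[counts == 0].index.tolist()
        if empty:
            raise InvalidInputError(f"day levels with no samples: {empty}")
    levels = sorted(pd.unique(days))
    return pd.DataFrame(
        {f"DAY[{lev}]": (days == lev).astype(float) for lev in levels[1:]},
        index=index,
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class DayResidualizer(TransformerMixin, BaseEstimator):
    """Remove additive day-of-growth batch effects, one OLS per gene.

    OLS on day-level indicators (with intercept) is equivalent to
    subtracting, per gene, the mean over the samples grown on the same day;
    ``transform`` therefore returns residuals that sum to ~0 within each day
    level.  This is an in-sample transformer: day labels are given at ``fit``
    and ``transform`` must be called on the same samples.
    """

    def fit(self, X, days):
        X = pd.DataFrame(X)
        if len(days) != len(X):
            raise InvalidInputError("one day label per sample is required")
        if isinstance(days, pd.Series):
            days = days.set_axis(X.index)
        else:
            days = pd.Series(days, index=X.index)
        _ = _day_dummies(days, X.index)  # validates empty levels
        self.days_ = days
        self.day_means_ = X.groupby(days, observed=True).mean()
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = pd.DataFrame(X)
        if X.shape != (len(self.days_), self.n_features_in_):
            raise InvalidInputError("transform must be applied to the fitted samples")
        fitted = self.day_means_.loc[self.days_].to_numpy()
        return pd.DataFrame(X.to_numpy(dtype=float) - fitted, index=X.index, columns=X.columns)


class FactorialAnova(BaseEstimator):
    """Full-factorial OLS of responses on O/V genotypes with Type-I ANOVA.

    Parameters
    ----------
    response_transform : {"identity", "log"}
        ``"log"`` fits ``log(y + 1)`` (a pseudocount of 1 accommodates zero
        counts) and is intended for the joint day+genotype model.
    term_p_threshold : float
        Per-term F-test significance threshold used when summarising which
        terms count toward explained-variance shares (default 0.1).

    ``fit(X, y, days=None)`` takes a samples x loci allele frame (entries
    ``"O"``/``"V"``); the full design of main and interaction indicator
    columns is built internally in canonical order.  ``y`` may be a single
    response or a samples x genes frame.  If ``days`` is given, day
    indicator covariates enter the model (sequentially before genotype) and
    the model F becomes the partial F of the genotype terms.

    Fitted attributes include ``coef_``, ``sequential_ss_``, ``r_squared_``,
    ``model_f_``, ``model_p_``, ``df_model_``, ``df_residual_``, and
    ``anova_table()`` renders per-response ANOVA tables.
    """

    def __init__(self, response_transform: str = "identity", term_p_threshold: float = 0.1):
        self.response_transform = response_transform
        self.term_p_threshold = term_p_threshold

    def fit(self, X, y, days=None):
        if self.response_transform not in ("identity", "log"):
            raise InvalidInputError(
                f"unknown response_transform {self.response_transform!r}"
            )
        X = pd.DataFrame(X)
        genotype_design = build_design_matrix(X)
        parts = [genotype_design[[INTERCEPT]]]
        if days is not None:
            parts.append(_day_dummies(days, genotype_design.index))
        parts.append(genotype_design.drop(columns=INTERCEPT))
        design = pd.concat(parts, axis=1)

        y_frame = pd.DataFrame(y)
        if self.response_transform == "log":
            if (y_frame.to_numpy() < 0).any():
                raise InvalidInputError("log transform requires nonnegative responses")
            y_frame = np.log(y_frame + 1.0)

        tested = [c for c in genotype_design.columns if c != INTERCEPT]
        res = fit_sequential_ols(design, y_frame, tested_terms=tested)

        self.design_ = design
        self.genotype_terms_ = tested
        self.result_ = res
        self.coef_ = res.coef
        self.sequential_ss_ = res.sequential_ss
        self.residual_ss_ = res.residual_ss
        self.total_ss_ = res.total_ss
        self.r_squared_ = res.r_squared
        self.model_f_ = res.model_f
        self.model_p_ = res.model_p
        self.df_model_ = res.df_model
        self.df_residual_ = res.df_residual
        self.aliased_ = res.aliased
        self.n_obs_ = res.n_obs
        return self

    def predict(self, X, days=None):
        """Fitted values on the (possibly log) model scale."""
        check_is_fitted(self, "result_")
        X = pd.DataFrame(X)
        design = build_design_matrix(X)
        parts = [design[[INTERCEPT]]]
        if days is not None:
            parts.append(_day_dummies(days, design.index))
        parts.append(design.drop(columns=INTERCEPT))
        full = pd.concat(parts, axis=1)
        missing = [t for t in self.result_.terms if t not in full.columns]
        if missing:
            raise InvalidInputError(f"prediction design lacks model terms: {missing}")
        coef = self.coef_.fillna(0.0)
        out = full[self.result_.terms].to_numpy() @ coef.to_numpy()
        return pd.DataFrame(out, index=full.index, columns=self.result_.responses).squeeze(axis=1)

    def anova_table(self, response=None) -> pd.DataFrame:
        """Sequential ANOVA table (df, ss, ms, f, p) for one response.

        Rows follow model order (covariates first when present, then
        genotype terms) and end with ``Residuals``; aliased terms are
        omitted.  With zero residual df, F and p are missing.
        """
        check_is_fitted(self, "result_")
        res = self.result_
        if response is None:
            if len(res.responses) != 1:
                raise InvalidInputError("response= is required for multi-response fits")
            response = res.responses[0]
        rows = [t for t in res.terms if t != INTERCEPT and t not in res.aliased]
        ss = res.sequential_ss.loc[rows, response]
        table = pd.DataFrame(
            {
                "df": 1,
                "ss": ss,
                "ms": ss,
                "f": res.term_f.loc[rows, response],
                "p": res.term_p.loc[rows, response],
            }
        )
        table.index.name = "term"
        resid = pd.DataFrame(
            {
                "df": [res.df_residual],
                "ss": [res.residual_ss[response]],
                "ms": [res.residual_ss[response] / res.df_residual
                       if res.df_residual > 0 else np.nan],
                "f": [np.nan],
                "p": [np.nan],
            },
            index=pd.Index(["Residuals"], name="term"),
        )
        out = pd.concat([table, resid])
        out.attrs["genotype_terms"] = list(self.genotype_terms_)
        out.attrs["response"] = response
        return out


# ---------------------------------------------------------------------------
# Functional interface (gene-rows matrices, spec-shaped signatures)
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Summary of one fitted factorial model (one response)."""

    response: str
    coefficients: pd.Series
    r_squared: float
    model_f: float
    model_p: float
    df_model: int
    df_residual: int
    residual_ss: float
    total_ss: float
    aliased: tuple
    anova: pd.DataFrame


def _model_fit_from(res: SequentialOLS, table: pd.DataFrame, response) -> ModelFit:
    return ModelFit(
        response=str(response),
        coefficients=res.coef[response],
        r_squared=float(res.r_squared[response]),
        model_f=float(res.model_f[response]),
        model_p=float(res.model_p[response]),
        df_model=res.df_model,
        df_residual=res.df_residual,
        residual_ss=float(res.residual_ss[response]),
        total_ss=float(res.total_ss[response]),
        aliased=res.aliased,
        anova=table,
    )


def fit_day_residuals(counts: pd.DataFrame, sample_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene residuals after removing the additive day effect.

    ``counts`` is genes x samples (normalized); ``sample_table`` must cover
    every sample column and provide a ``day`` label.  Returns a genes x
    samples residual matrix.
    """
    missing = set(counts.columns) - set(sample_table.index)
    if missing:
        raise InvalidInputError(f"samples missing from sample table: {sorted(missing)}")
    days = sample_table.loc[counts.columns, "day"]
    resid = DayResidualizer().fit(counts.T, days).transform(counts.T)
    return resid.T


def fit_genotype_model(
    response,
    design: pd.DataFrame,
    response_transform: str = "identity",
    days=None,
    name: str | None = None,
) -> ModelFit:
    """Fit one response on a prebuilt factorial design matrix.

    ``design`` must start with the intercept column (as produced by
    :func:`qtnvar.panel.build_design_matrix`); day covariates, if given, are
    inserted after the intercept, and the model F tests the genotype terms
    only.  ``response_transform="log"`` fits ``log(response + 1)``.
    """
    y = pd.Series(np.asarray(response, dtype=float), index=design.index)
    if response_transform == "log":
        if (y < 0).any():
            raise InvalidInputError("log transform requires nonnegative responses")
        y = np.log(y + 1.0)
    elif response_transform != "identity":
        raise InvalidInputError(f"unknown response_transform {response_transform!r}")

    parts = [design[[INTERCEPT]]]
    if days is not None:
        parts.append(_day_dummies(days, design.index))
    parts.append(design.drop(columns=INTERCEPT))
    full = pd.concat(parts, axis=1)
    tested = [c for c in design.columns if c != INTERCEPT]
    label = name if name is not None else (y.name or "response")
    res = fit_sequential_ols(full, y.rename(label), tested_terms=tested)
    table = _anova_from_result(res, label)
    return _model_fit_from(res, table, label)


def _anova_from_result(res: SequentialOLS, response) -> pd.DataFrame:
    rows = [t for t in res.terms if t != INTERCEPT and t not in res.aliased]
    table = pd.DataFrame(
        {
            "df": 1,
            "ss": res.sequential_ss.loc[rows, response],
            "ms": res.sequential_ss.loc[rows, response],
            "f": res.term_f.loc[rows, response],
            "p": res.term_p.loc[rows, response],
        }
    )
    table.index.name = "term"
    resid_ms = res.residual_ss[response] / res.df_residual if res.df_residual else np.nan
    resid = pd.DataFrame(
        {"df": [res.df_residual], "ss": [res.residual_ss[response]],
         "ms": [resid_ms], "f": [np.nan], "p": [np.nan]},
        index=pd.Index(["Residuals"], name="term"),
    )
    out = pd.concat([table, resid])
    out.attrs["genotype_terms"] = list(res.tested_terms)
    out.attrs["response"] = str(response)
    return out


def fit_phenotype_model(phenotypes: pd.DataFrame, panel: pd.DataFrame) -> ModelFit:
    """Factorial model of per-replicate phenotype values (e.g. sporulation %).

    ``phenotypes`` needs ``strain_id`` and ``efficiency`` columns, one row
    per replicate measurement.  With a full 16-strain panel and 4 replicates
    the residual degrees of freedom are 64 - 16 = 48.
    """
    design = build_design_matrix(panel, phenotypes)
    return fit_genotype_model(
        phenotypes["efficiency"], design, name="phenotype"
    )


def fit_expression_models(
    residuals: pd.DataFrame,
    panel: pd.DataFrame,
    sample_table: pd.DataFrame,
    response_transform: str = "identity",
    days=None,
) -> FactorialAnova:
    """Fit the factorial model to every gene of a genes x samples matrix.

    ``residuals`` is the day-residualized matrix for the identity variant, or
    the normalized count matrix for the log variant (pass ``days`` to include
    the day covariates in the joint model).
    """
    alleles = panel.loc[sample_table.loc[residuals.columns, "strain_id"]]
    alleles = alleles.set_axis(residuals.columns)
    est = FactorialAnova(response_transform=response_transform)
    return est.fit(alleles, residuals.T, days=days)
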