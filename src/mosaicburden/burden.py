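"""Somatic variant burden: tables, enrichment GLM, and summaries.

The per-sample count of somatic-classified calls (total, per allele-fraction
bin, per gene) joined to the sample sheet is the input of the enrichment
analysis: a negative-binomial GLM of counts on disease group (control as the
reference level) with sex, age, origin and log total coverage as covariates,
plus a Welch two-sample t-test on the group totals and Benjamini-Hochberg
adjustment across tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import GROUPS, SampleMeta
from .nbglm import NBGLMResults, fit_nb_glm

__all__ = [
    "DEFAULT_AF_BINS",
    "build_burden",
    "BurdenGLM",
    "GroupSummary",
    "summary_t_test",
    "fdr_adjust",
    "gene_burden_ratio",
]

#: Default allele-fraction bin edges inside the mosaic window.
DEFAULT_AF_BINS = (0.015, 0.05, 0.15, 0.35)


def build_burden(
    calls: pd.DataFrame,
    metadata: list[SampleMeta] | pd.DataFrame,
    af_bin_edges: tuple[float, ...] = DEFAULT_AF_BINS,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate somatic-classified calls into a per-sample burden table.

    One row per sample (zero rows retained), columns ``n_somatic``, one
    ``bin_(lo,hi]`` column per left-open/right-closed AF bin, one
    ``gene_<symbol>`` column per panel gene, joined to the sample metadata.
    Somatic calls whose VAF falls outside every bin are counted in
    ``n_somatic`` only.
    """
    edges = np.asarray(af_bin_edges, float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0) or edges[0] <= 0 or edges[-1] >= 0.5:
        raise ValueError("af_bin_edges must be strictly increasing within (0, 0.5)")
    meta_df = (
        pd.DataFrame([m.__dict__ for m in metadata])
        if not isinstance(metadata, pd.DataFrame)
        else metadata.copy()
    )
    if calls.empty:
        som = calls
    else:
        if calls.classification.isna().any():
            raise ValueError("every call must be classified before burden building")
        som = calls[calls.classification == "somatic"]
    if genes is None:
        genes = sorted(g for g in som.get("gene_symbol", pd.Series(dtype=object)).dropna().unique())

    table = meta_df.set_index("sample_id")
    table["n_somatic"] = 0
    bin_labels = [f"bin_({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    for lbl in bin_labels:
        table[lbl] = 0
    for g in genes:
        table[f"gene_{g}"] = 0

    if not som.empty:
        totals = som.groupby("sample_id").size()
        table.loc[totals.index, "n_somatic"] = totals
        which = pd.cut(som.vaf, bins=edges, right=True, labels=bin_labels)
        for lbl in bin_labels:
            cnt = som[which == lbl].groupby("sample_id").size()
            table.loc[cnt.index, lbl] = cnt
        for g in genes:
            cnt = som[som.gene_symbol == g].groupby("sample_id").size()
            table.loc[cnt.index, f"gene_{g}"] = cnt
    return table.reset_index()


def _design_matrix(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "age", "origin", "total_coverage"),
) -> pd.DataFrame:
    """Treatment-coded design: intercept, group (control reference), covariates.

    ``origin`` is treatment-coded against its most frequent level (ties
    broken alphabetically); ``total_coverage`` enters log-transformed.
    """
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for g in GROUPS:
        if g == "control":
            continue
        if (table.group == g).any():
            X[f"group[{g}]"] = (table.group == g).astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex[M]"] = (table.sex == "M").astype(float)
        elif cov == "age":
            X["age"] = table.age.astype(float)
        elif cov == "total_coverage":
            X["log_total_coverage"] = np.log(table.total_coverage.astype(float))
        elif cov == "origin":
            counts = table.origin.value_counts()
            ref = sorted(counts[counts == counts.max()].index)[0]
            for lvl in sorted(set(table.origin) - {ref}):
                X[f"origin[{lvl}]"] = (table.origin == lvl).astype(float)
        else:
            X[cov] = table[cov].astype(float)
    # drop constant dummy columns (unused levels) to keep the design full rank
    keep = [c for c in X.columns if c == "Intercept" or X[c].nunique() > 1]
    return X[keep]


@dataclass
class BurdenGLM:
    """Negative-binomial burden-enrichment model.

    Model: ``count ~ NB(mu, theta)``, ``log mu = b0 + b_group + covariates``
    with control as the reference disease category. Construct with
    :meth:`from_dataframe` and call :meth:`fit`; the returned
    :class:`~mosaicburden.nbglm.NBGLMResults` carries coefficients,
    Wald tests and the dispersion estimate.
    """

    endog: np.ndarray
    exog: pd.DataFrame
    response: str = "n_somatic"

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        response: str = "n_somatic",
        covariates: tuple[str, ...] = ("sex", "age", "origin", "total_coverage"),
        drop_collinear: bool = False,
    ) -> "BurdenGLM":
        """Build the model from a burden table.

        With ``drop_collinear`` the constructor removes collinear covariate
        columns (never the intercept or group effects) with a warning —
        useful for small cohorts where a categorical covariate can coincide
        with another column by chance; otherwise a rank-deficient design
        raises at fit time, naming the offending columns.
        """
        for g in sorted(table.group.unique()):
            if (table.group == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        used = [c for c in ("group",) + covariates if c in table.columns]
        if table[used + [response]].isna().any().any():
            raise ValueError("missing values in response or covariates")
        X = _design_matrix(table, covariates)
        if drop_collinear:
            import logging

            protected = [c for c in X.columns if c == "Intercept" or c.startswith("group[")]
            while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                droppable = [c for c in X.columns if c not in protected]
                if not droppable:
                    break
                dropped = droppable[-1]
                X = X.drop(columns=dropped)
                logging.getLogger(__name__).warning(
                    "dropping collinear covariate column %r", dropped
                )
        return cls(endog=table[response].to_numpy(), exog=X, response=response)

    def fit(self, theta: float | None = None, **kwargs) -> NBGLMResults:
        return fit_nb_glm(self.exog, self.endog, theta=theta, **kwargs)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean/SD of total counts with the two-sample t-test."""

    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    p: float


def summary_t_test(
    table: pd.DataFrame,
    group_a: str = "sALS",
    group_b: str = "control",
    response: str = "n_somatic",
    welch: bool = True,
) -> GroupSummary:
    """Two-sample t-test on per-sample totals (Welch by default).

    Reports each group's mean and sample SD alongside the statistic, the
    form in which cohort-level burden differences are usually quoted.
    """
    a = table.loc[table.group == group_a, response].to_numpy(float)
    b = table.loc[table.group == group_b, response].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each compared group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupSummary(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
        t=float(t),
        p=float(p),
    )


def fdr_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (empty input passes through)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def gene_burden_ratio(
    table: pd.DataFrame,
    group_a: str = "sALS",
    group_b: str = "control",
    pseudo_count: float = 0.5,
    covariates: tuple[str, ...] = ("sex", "age", "origin", "total_coverage"),
) -> pd.DataFrame:
    """Per-gene burden ratio between two groups with NB GLM p/q values.

    ratio = (mean_a + c) / (mean_b + c) with pseudo-count ``c`` guarding
    sparse genes; the per-gene p-value is the Wald test of the ``group_a``
    coefficient in a per-gene NB GLM on the two groups, and q-values are BH
    across genes. Genes whose per-gene fit is degenerate (e.g. all-zero
    counts) report p = NaN.
    """
    gene_cols = [c for c in table.columns if c.startswith("gene_")]
    sub = table[table.group.isin([group_a, group_b])].copy()
    rows = []
    for col in gene_cols:
        gene = col[len("gene_"):]
        mean_a = float(sub.loc[sub.group == group_a, col].mean())
        mean_b = float(sub.loc[sub.group == group_b, col].mean())
        ratio = (mean_a + pseudo_count) / (mean_b + pseudo_count)
        p = np.nan
        try:
            fit = BurdenGLM.from_dataframe(
                sub, response=col, covariates=covariates, drop_collinear=True
            ).fit()
            coef = f"group[{group_a}]"
            if coef in fit.params.index:
                p = float(fit.pvalues[coef])
        except (ValueError, np.linalg.LinAlgError):
            pass
        rows.append(
            {"gene_symbol": gene, "mean_a": mean_a, "mean_b": mean_b,
             "ratio": ratio, "p": p}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = np.nan
        ok = out.p.notna()
        if ok.any():
            out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p"])
    return out


def plot_group_burden(table: pd.DataFrame, response: str = "n_somatic", ax=None):
    """Strip/box plot of per-sample burden by disease group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    groups = [g for g in GROUPS if (table.group == g).any()]
    data = [table.loc[table.group == g, response] for g in groups]
    ax.boxplot(data, tick_labels=groups, showfliers=False)
    for i, vals in enumerate(data, start=1):
        x = np.random.default_rng(0).normal(i, 0.04, size=len(vals))
        ax.plot(x, vals, "o", alpha=0.6, ms=4)
    ax.set_ylabel(f"{response} per sample")
    return ax
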