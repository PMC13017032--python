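"""Cell-type-aware somatic SNV calling from single-cell pileups.

A simplified cell-type-contrast caller in the spirit of cell-type-stratified
somatic callers for single-cell RNA data: per-cell base counts are
aggregated by annotated cell type, and at each site every cell type's
alternate-allele excess is tested (beta-binomial upper tail) against the
error background estimated from the *other* cell types. A variant is somatic
when at least one type passes after BH adjustment across types, at most
``max_host_types`` types pass (ubiquitous signals are artifact-like or
germline), and the pooled alternate fraction outside the host types stays
below the germline screen. Per-cell burden counts carrier cells by >= 1
alternate read at a somatic site, and cell-type burden differences are
tested with the package's negative-binomial GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import betabinom_pvalues
from .nbglm import fit_nb_glm
from .burden import fdr_adjust

__all__ = [
    "ScCallerConfig",
    "ScVariant",
    "aggregate_by_celltype",
    "call_sc_variant",
    "call_sc_variants",
    "per_cell_burden",
    "compare_celltype_burden",
    "cluster_burden",
]

BASE_COLS = ["A", "C", "G", "T"]
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class ScCallerConfig:
    """Thresholds of the cell-type-contrast caller (all explicit config)."""

    min_cells: int = 5  # covered cells required to test a type
    min_depth: int = 20  # aggregated reads required to test a type
    alpha: float = 0.01  # per-site BH level across cell types
    max_host_types: int = 2
    germline_screen_af: float = 0.05  # max pooled non-host alt fraction
    germline_like_af: float = 0.2  # alt fraction calling a type "high"
    germline_like_types: int = 3  # "high" in >= this many types => germline_like
    error_rate_floor: float = 1e-4
    rho: float = 0.01  # beta-binomial overdispersion of the error background


@dataclass
class ScVariant:
    """A called (or screened) single-cell variant at one site."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    status: str  # somatic | germline_like | artifact | untested
    host_cell_types: tuple[str, ...] = ()
    alt_fraction: dict[str, float] | None = None
    p_values: dict[str, float] | None = None
    q_values: dict[str, float] | None = None


def aggregate_by_celltype(
    pileup: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Sum per-cell base counts into per-(site, cell type) rows.

    Every barcode in the pileup must be annotated; offenders are listed in
    the raised error. Output columns: ``chrom, pos, ref, cell_type, A, C, G,
    T, depth, n_cells_covered``; cell types with no covered cell at a site
    are retained as zero rows so downstream contrasts see the full census.
    """
    known = set(annotations.cell_barcode)
    offenders = sorted(set(pileup.cell_barcode) - known)
    if offenders:
        raise ValueError(f"unannotated cell barcode(s): {offenders[:10]}")
    df = pileup.merge(
        annotations[["cell_barcode", "cell_type"]], on="cell_barcode", how="left",
        suffixes=("", "_ann"),
    )
    if "cell_type_ann" in df.columns:
        df["cell_type"] = df.pop("cell_type_ann")
    df["depth"] = df[BASE_COLS].sum(axis=1)
    df["covered"] = (df.depth > 0).astype(int)
    agg = (
        df.groupby(["chrom", "pos", "ref", "cell_type"], observed=True)
        .agg(
            A=("A", "sum"), C=("C", "sum"), G=("G", "sum"), T=("T", "sum"),
            n_cells_covered=("covered", "sum"),
        )
        .reset_index()
    )
    # zero rows for absent (site, cell type) combinations
    sites = agg[["chrom", "pos", "ref"]].drop_duplicates()
    types = annotations.cell_type.unique()
    full = sites.merge(pd.DataFrame({"cell_type": types}), how="cross")
    agg = full.merge(agg, on=["chrom", "pos", "ref", "cell_type"], how="left").fillna(0)
    for c in BASE_COLS + ["n_cells_covered"]:
        agg[c] = agg[c].astype(int)
    agg["depth"] = agg[BASE_COLS].sum(axis=1)
    return agg.sort_values(["chrom", "pos", "cell_type"], ignore_index=True)


def call_sc_variant(site_ctp: pd.DataFrame, cfg: ScCallerConfig | None = None) -> ScVariant:
    """Test one site's cell-type pileup block for a somatic variant.

    ``site_ctp`` holds the rows of :func:`aggregate_by_celltype` for a
    single ``(chrom, pos)``. The alternate base is the overall top non-
    reference base. Each testable cell type (enough covered cells and
    aggregated depth) is tested against a beta-binomial error background
    whose rate is estimated from all *other* cell types at the site.
    """
    cfg = cfg or ScCallerConfig()
    row0 = site_ctp.iloc[0]
    chrom, pos, ref = str(row0.chrom), int(row0.pos), str(row0.ref)
    counts = site_ctp[BASE_COLS].to_numpy(dtype=np.int64)
    total = counts.sum(axis=0)
    alt_choices = [i for i, b in enumerate(BASE_COLS) if b != ref]
    alt_idx = max(alt_choices, key=lambda i: (total[i], -i))
    alt_base = BASE_COLS[alt_idx]

    types = site_ctp.cell_type.to_numpy()
    depth = counts.sum(axis=1)
    alt = counts[:, alt_idx]
    covered = site_ctp.n_cells_covered.to_numpy()
    with np.errstate(invalid="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    alt_fraction = {t: float(f) for t, f in zip(types, frac)}

    testable = (covered >= cfg.min_cells) & (depth >= cfg.min_depth)
    if not testable.any():
        return ScVariant(chrom, pos, ref, alt_base, "untested", alt_fraction=alt_fraction)

    # germline screen: high alternate fraction across many covered types
    high = (frac >= cfg.germline_like_af) & (depth > 0)
    if high.sum() >= cfg.germline_like_types:
        return ScVariant(chrom, pos, ref, alt_base, "germline_like",
                         alt_fraction=alt_fraction)

    p = np.ones(len(types))
    for i in np.flatnonzero(testable):
        others = np.arange(len(types)) != i
        d_o = depth[others].sum()
        a_o = alt[others].sum()
        e = max(a_o / d_o if d_o > 0 else 0.0, cfg.error_rate_floor)
        e = min(e, 0.5 - 1e-9)
        p[i] = float(betabinom_pvalues(np.array([alt[i]]), np.array([depth[i]]),
                                       e, cfg.rho)[0])
    q = np.ones(len(types))
    q[testable] = fdr_adjust(p[testable])
    passing = testable & (q <= cfg.alpha)
    p_values = {t: float(v) for t, v in zip(types, p)}
    q_values = {t: float(v) for t, v in zip(types, q)}

    if not passing.any():
        return ScVariant(chrom, pos, ref, alt_base, "artifact",
                         alt_fraction=alt_fraction, p_values=p_values, q_values=q_values)
    if passing.sum() > cfg.max_host_types:
        return ScVariant(chrom, pos, ref, alt_base, "artifact",
                         host_cell_types=tuple(types[passing]),
                         alt_fraction=alt_fraction, p_values=p_values, q_values=q_values)
    non_host = ~passing
    d_nh = depth[non_host].sum()
    pooled = alt[non_host].sum() / d_nh if d_nh > 0 else 0.0
    if pooled >= cfg.germline_screen_af:
        return ScVariant(chrom, pos, ref, alt_base, "artifact",
                         host_cell_types=tuple(types[passing]),
                         alt_fraction=alt_fraction, p_values=p_values, q_values=q_values)
    return ScVariant(chrom, pos, ref, alt_base, "somatic",
                     host_cell_types=tuple(sorted(types[passing])),
                     alt_fraction=alt_fraction, p_values=p_values, q_values=q_values)


def call_sc_variants(
    ctp: pd.DataFrame, cfg: ScCallerConfig | None = None
) -> list[ScVariant]:
    """Run the cell-type-contrast caller over every site of an aggregate."""
    cfg = cfg or ScCallerConfig()
    return [
        call_sc_variant(block, cfg)
        for _, block in ctp.groupby(["chrom", "pos"], sort=True)
    ]


def per_cell_burden(
    variants: list[ScVariant], pileup: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell somatic-variant burden.

    A cell carries a somatic variant iff it has >= 1 read of the alternate
    base at that site; ``n_variants`` counts carried somatic variants. Also
    reports ``n_covered_sites`` (pileup rows with positive depth per cell),
    the exposure used by the cell-type comparison. All annotated cells are
    retained, including cells with zero coverage.
    """
    som = [v for v in variants if v.status == "somatic"]
    burden = annotations[["cell_barcode", "cell_type", "cluster_id", "condition"]].copy()
    depth = pileup[BASE_COLS].sum(axis=1)
    cov = pileup.loc[depth > 0].groupby("cell_barcode").size()
    burden["n_covered_sites"] = burden.cell_barcode.map(cov).fillna(0).astype(int)
    n_var = pd.Series(0, index=burden.cell_barcode)
    for v in som:
        rows = pileup[(pileup.chrom == v.chrom) & (pileup.pos == v.pos)]
        carriers = rows.loc[rows[v.alt_base] > 0, "cell_barcode"]
        n_var.loc[n_var.index.isin(carriers)] += 1
    burden["n_variants"] = n_var.to_numpy()
    return burden


def compare_celltype_burden(
    burden: pd.DataFrame,
    min_cells: int = 10,
    size_adjustment: str = "offset",
) -> pd.DataFrame:
    """All pairwise cell-type burden contrasts from one NB GLM.

    Fits per-cell ``n_variants`` on cell type (treatment coding,
    alphabetically first type as reference), adjusted for each cell's
    covered-site count, and Wald-tests every pairwise coefficient
    difference, BH-adjusted across contrasts. Cell types with fewer than
    ``min_cells`` cells are excluded (with a warning).

    ``size_adjustment`` controls how coverage enters:

    * ``"offset"`` (default) — ``log(covered sites)`` as an exposure offset
      (unit coefficient), so contrasts compare variants *per covered site*.
      Covered-site counts differ far more between cell types than within
      them, so a freely estimated coefficient is nearly collinear with the
      type effects and inflates contrast variance; the offset avoids that.
    * ``"covariate"`` — ``log(covered sites)`` with a free coefficient.
    * ``"cells_per_type"`` — rejected: a per-type cell count is constant
      within each type and exactly collinear with the type effects.
    """
    if size_adjustment == "cells_per_type":
        raise ValueError(
            "cells_per_type is constant within each cell type and collinear "
            "with the cell-type fixed effects; use 'offset' or 'covariate'"
        )
    if size_adjustment not in {"offset", "covariate"}:
        raise ValueError(f"unknown size_adjustment {size_adjustment!r}")
    sizes = burden.cell_type.value_counts()
    keep_types = sorted(sizes[sizes >= min_cells].index)
    dropped = sorted(set(sizes.index) - set(keep_types))
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "excluding cell type(s) with < %d cells: %s", min_cells, dropped
        )
    if len(keep_types) < 2:
        raise ValueError("need at least 2 cell types with enough cells")
    sub = burden[burden.cell_type.isin(keep_types)].copy()
    sub = sub[sub.n_covered_sites > 0]

    X = pd.DataFrame({"Intercept": np.ones(len(sub))}, index=sub.index)
    ref_type = keep_types[0]
    for t in keep_types[1:]:
        X[f"celltype[{t}]"] = (sub.cell_type == t).astype(float)
    log_sites = np.log(sub.n_covered_sites.astype(float).to_numpy())
    if size_adjustment == "offset":
        fit = fit_nb_glm(X, sub.n_variants.to_numpy(), offset=log_sites)
    else:
        X["log_covered_sites"] = log_sites
        fit = fit_nb_glm(X, sub.n_variants.to_numpy())

    def coef_name(t: str) -> str | None:
        return None if t == ref_type else f"celltype[{t}]"

    rows = []
    for i, a in enumerate(keep_types):
        for b in keep_types[i + 1:]:
            ca, cb = coef_name(a), coef_name(b)
            if ca is None:
                est = -fit.params[cb]
                se = fit.bse[cb]
                z = est / se
                from scipy import stats as _st

                p = float(2.0 * _st.norm.sf(abs(z)))
            elif cb is None:
                est = fit.params[ca]
                se = fit.bse[ca]
                z = est / se
                from scipy import stats as _st

                p = float(2.0 * _st.norm.sf(abs(z)))
            else:
                est, z, p = fit.contrast(ca, cb)
            rows.append(
                {"cell_type_a": a, "cell_type_b": b,
                 "log_ratio": float(est), "z": float(z), "p": p}
            )
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out.p)
    return out


def cluster_burden(burden: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster burden summary and condition composition.

    Returns one row per cluster with mean/median ``n_variants``, cell count,
    and one ``frac_<condition>`` column per condition (fractions sum to 1
    within each cluster).
    """
    g = burden.groupby("cluster_id")
    out = g.n_variants.agg(mean_burden="mean", median_burden="median").reset_index()
    out["n_cells"] = g.size().to_numpy()
    comp = (
        burden.groupby(["cluster_id", "condition"], observed=True).size().unstack(fill_value=0)
    )
    comp = comp.div(comp.sum(axis=1), axis=0)
    for cond in comp.columns:
        out[f"frac_{cond}"] = out.cluster_id.map(comp[cond]).fillna(0.0)
    return out.sort_values("mean_burden", ascending=False, ignore_index=True)
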