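"""Low-allele-fraction somatic SNV calling from consensus pileups.

Two independent callers test each site's top alternate base against a
background error model estimated from non-variant sites:

* a binomial caller — alternate count vs ``Binomial(depth, e)``;
* a beta-binomial caller — the same tail under site-to-site overdispersion
  of the error rate (``rho``), which contains the binomial caller as its
  ``rho -> 0`` limit.

Candidate calls are integrated across callers (intersection by default),
classified by the mosaic allele-fraction window — somatic iff
``af_low < VAF < af_high`` with the open default window (0.015, 0.35),
germline above it, filtered below — and annotated with genomic region and
gene from the panel's gene model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GeneModel

__all__ = [
    "ErrorModel",
    "CallerConfig",
    "VariantCall",
    "estimate_error_model",
    "binomial_pvalues",
    "betabinom_pvalues",
    "call_binomial",
    "call_betabinom",
    "integrate_calls",
    "classify_call",
    "annotate_region",
    "call_pileup",
]

E_FLOOR = 1e-6
BASE_COLS = ["A", "C", "G", "T"]


@dataclass(frozen=True)
class ErrorModel:
    """Background per-base error rate and its beta-binomial overdispersion."""

    e: float
    rho: float = 0.0
    n_sites: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.e < 0.5:
            raise ValueError("e must be in (0, 0.5)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")


@dataclass
class CallerConfig:
    """Caller thresholds and the somatic allele-fraction window."""

    alpha_binomial: float = 1e-6
    alpha_betabinom: float = 1e-6
    min_depth: int = 500
    af_low: float = 0.015
    af_high: float = 0.35
    integration_rule: str = "intersection"  # intersection | union | at_least_k
    at_least_k: int = 1
    mask_alt_fraction: float = 0.005  # candidate-site exclusion for error fitting

    def __post_init__(self) -> None:
        if not 0.0 < self.af_low < self.af_high < 0.5:
            raise ValueError("need 0 < af_low < af_high < 0.5")
        if self.integration_rule not in {"intersection", "union", "at_least_k"}:
            raise ValueError(f"unknown integration rule {self.integration_rule!r}")

    def alpha(self, caller: str) -> float:
        return {"binomial": self.alpha_binomial, "betabinom": self.alpha_betabinom}[
            caller
        ]


@dataclass
class VariantCall:
    """An emitted SNV call with caller provenance and classification."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    callers: tuple[str, ...]
    p_values: dict[str, float]
    classification: str = "somatic"
    region: str = "intergenic"
    gene_symbol: str | None = None
    sample_id: str | None = None

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


def _top_alt(pileup: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (depth, top-alt count, top-alt base), vectorized."""
    counts = pileup[BASE_COLS].to_numpy(dtype=np.int64)
    depth = counts.sum(axis=1)
    ref_idx = pd.Categorical(pileup.ref, categories=BASE_COLS).codes
    alt_counts = counts.copy()
    alt_counts[np.arange(len(pileup)), ref_idx] = -1
    alt_idx = alt_counts.argmax(axis=1)
    alt_n = counts[np.arange(len(pileup)), alt_idx]
    return depth, alt_n, np.array(BASE_COLS)[alt_idx]


def estimate_error_model(
    pileup: pd.DataFrame, exclude_mask: np.ndarray | None = None
) -> ErrorModel:
    """Fit the background error model from non-variant sites.

    ``e`` is the pooled non-reference fraction over non-excluded sites with
    positive depth; ``rho`` comes from the method of moments on the per-site
    top-alternate fractions (excess of their variance over binomial
    sampling). Both are clamped to their valid ranges; a pileup with no
    usable site raises.
    """
    depth, alt_n, _ = _top_alt(pileup)
    counts = pileup[BASE_COLS].to_numpy(dtype=np.int64)
    ref_idx = pd.Categorical(pileup.ref, categories=BASE_COLS).codes
    nonref = depth - counts[np.arange(len(pileup)), ref_idx]

    keep = depth > 0
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, dtype=bool)
    if keep.sum() == 0:
        raise ValueError("all sites excluded; cannot estimate the error model")
    if keep.sum() < 100:
        import logging

        logging.getLogger(__name__).warning(
            "error model fitted on only %d sites", int(keep.sum())
        )

    e = float(nonref[keep].sum() / depth[keep].sum())
    e = min(max(e, E_FLOOR), 0.5 - E_FLOOR)

    # method of moments on per-site alt fractions f_i = alt_i / n_i:
    # Var(f) = e(1-e) [ rho + (1-rho) E(1/n) ]  under the beta-binomial
    n = depth[keep].astype(float)
    f = alt_n[keep] / n
    s2 = float(np.var(f, ddof=1)) if keep.sum() > 1 else 0.0
    inv_n = float(np.mean(1.0 / n))
    denom = e * (1.0 - e) * (1.0 - inv_n)
    rho = 0.0 if denom <= 0 else (s2 - e * (1.0 - e) * inv_n) / denom
    rho = min(max(rho, 0.0), 1.0 - 1e-9)
    return ErrorModel(e=e, rho=float(rho), n_sites=int(keep.sum()))


def binomial_pvalues(alt: np.ndarray, depth: np.ndarray, e: float) -> np.ndarray:
    """Upper-tail P(X >= alt) under Binomial(depth, e)."""
    return stats.binom.sf(np.asarray(alt) - 1, np.asarray(depth), e)


def betabinom_pvalues(
    alt: np.ndarray, depth: np.ndarray, e: float, rho: float
) -> np.ndarray:
    """Upper-tail P(X >= alt) under BetaBinomial(depth, a, b) with mean ``e``
    and intraclass correlation ``rho``; reduces to the binomial tail as
    ``rho -> 0``."""
    # below ~1e-8 the beta parameters overflow scipy's stable range and the
    # distribution is numerically binomial anyway
    if rho < 1e-8:
        return binomial_pvalues(alt, depth, e)
    s = (1.0 - rho) / rho
    return stats.betabinom.sf(np.asarray(alt) - 1, np.asarray(depth), e * s, (1 - e) * s)


def _call_single(
    site, model: ErrorModel, cfg: CallerConfig, caller: str
) -> VariantCall | None:
    """Shared single-site caller logic (``site`` is a pileup row)."""
    counts = {b: int(site[b]) for b in BASE_COLS}
    depth = sum(counts.values())
    if depth < cfg.min_depth:
        return None
    alt_base, alt_n = max(
        ((b, c) for b, c in counts.items() if b != site["ref"]),
        key=lambda kv: (kv[1], kv[0]),
    )
    if caller == "binomial":
        p = float(binomial_pvalues(np.array([alt_n]), np.array([depth]), model.e)[0])
    else:
        p = float(
            betabinom_pvalues(
                np.array([alt_n]), np.array([depth]), model.e, model.rho
            )[0]
        )
    if p > cfg.alpha(caller):
        return None
    return VariantCall(
        chrom=site["chrom"],
        pos=int(site["pos"]),
        ref_base=site["ref"],
        alt_base=alt_base,
        alt_count=alt_n,
        depth=depth,
        callers=(caller,),
        p_values={caller: p},
    )


def call_binomial(site, model: ErrorModel, cfg: CallerConfig) -> VariantCall | None:
    """Binomial caller on one pileup site (dict-like row); None if no call."""
    return _call_single(site, model, cfg, "binomial")


def call_betabinom(site, model: ErrorModel, cfg: CallerConfig) -> VariantCall | None:
    """Beta-binomial caller on one pileup site; None if no call."""
    return _call_single(site, model, cfg, "betabinom")


def integrate_calls(
    candidates: dict[str, list[VariantCall]], cfg: CallerConfig
) -> list[VariantCall]:
    """Merge per-caller candidate lists keyed by (chrom, pos, alt).

    ``intersection`` keeps variants emitted by every caller, ``union`` any,
    ``at_least_k`` at least ``cfg.at_least_k`` callers. Caller provenance and
    per-caller p-values are retained on the merged call.
    """
    n_callers = len(candidates)
    merged: dict[tuple, VariantCall] = {}
    support: dict[tuple, set[str]] = {}
    for caller, calls in candidates.items():
        for call in calls:
            key = (call.chrom, call.pos, call.alt_base, call.sample_id)
            if key in merged:
                merged[key].p_values.update(call.p_values)
            else:
                merged[key] = call
            support.setdefault(key, set()).add(caller)

    if cfg.integration_rule == "intersection":
        need = n_callers
    elif cfg.integration_rule == "union":
        need = 1
    else:
        need = cfg.at_least_k

    out = []
    for key, call in sorted(merged.items(), key=lambda kv: kv[0][:3]):
        if len(support[key]) >= need:
            call.callers = tuple(sorted(support[key]))
            out.append(call)
    return out


def classify_call(call: VariantCall, cfg: CallerConfig) -> str:
    """Somatic / germline / filtered by the mosaic AF window (open interval)."""
    vaf = call.vaf
    if cfg.af_low < vaf < cfg.af_high:
        cls = "somatic"
    elif vaf >= cfg.af_high:
        cls = "germline"
    else:
        cls = "filtered"
    call.classification = cls
    return cls


def annotate_region(call: VariantCall, gene_model: GeneModel) -> VariantCall:
    """Attach genomic region (exonic > UTR > intronic > intergenic) and gene."""
    region, gene = gene_model.region_at(call.chrom, call.pos)
    call.region = region
    call.gene_symbol = gene
    return call


def call_pileup(
    pileup: pd.DataFrame,
    cfg: CallerConfig | None = None,
    gene_model: GeneModel | None = None,
    error_model: ErrorModel | None = None,
    sample_id: str | None = None,
) -> list[VariantCall]:
    """Full calling stage on one sample's pileup (vectorized).

    Estimates the error model (excluding candidate sites whose top-alternate
    fraction exceeds ``cfg.mask_alt_fraction``) unless one is supplied, runs
    both callers, integrates, classifies, and annotates.
    """
    cfg = cfg or CallerConfig()
    depth, alt_n, alt_base = _top_alt(pileup)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(depth > 0, alt_n / np.maximum(depth, 1), 0.0)
    if error_model is None:
        error_model = estimate_error_model(pileup, alt_frac > cfg.mask_alt_fraction)

    testable = depth >= cfg.min_depth
    p_bin = np.ones(len(pileup))
    p_bb = np.ones(len(pileup))
    p_bin[testable] = binomial_pvalues(alt_n[testable], depth[testable], error_model.e)
    p_bb[testable] = betabinom_pvalues(
        alt_n[testable], depth[testable], error_model.e, error_model.rho
    )

    candidates: dict[str, list[VariantCall]] = {"binomial": [], "betabinom": []}
    hit = testable & ((p_bin <= cfg.alpha_binomial) | (p_bb <= cfg.alpha_betabinom))
    idx = np.flatnonzero(hit)
    chroms = pileup.chrom.to_numpy()
    poss = pileup.pos.to_numpy()
    refs = pileup.ref.to_numpy()
    for i in idx:
        base = VariantCall(
            chrom=str(chroms[i]),
            pos=int(poss[i]),
            ref_base=str(refs[i]),
            alt_base=str(alt_base[i]),
            alt_count=int(alt_n[i]),
            depth=int(depth[i]),
            callers=(),
            p_values={},
            sample_id=sample_id,
        )
        if p_bin[i] <= cfg.alpha_binomial:
            c = VariantCall(**{**base.__dict__, "callers": ("binomial",),
                               "p_values": {"binomial": float(p_bin[i])}})
            candidates["binomial"].append(c)
        if p_bb[i] <= cfg.alpha_betabinom:
            c = VariantCall(**{**base.__dict__, "callers": ("betabinom",),
                               "p_values": {"betabinom": float(p_bb[i])}})
            candidates["betabinom"].append(c)

    calls = integrate_calls(candidates, cfg)
    for call in calls:
        classify_call(call, cfg)
        if gene_model is not None:
            annotate_region(call, gene_model)
    return calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """Tabulate calls (one row per call) for burden building and I/O."""
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref_base,
            "alt": c.alt_base,
            "alt_count": c.alt_count,
            "depth": c.depth,
            "vaf": c.vaf,
            "callers": ",".join(c.callers),
            "p_binomial": c.p_values.get("binomial", np.nan),
            "p_betabinom": c.p_values.get("betabinom", np.nan),
            "classification": c.classification,
            "region": c.region,
            "gene_symbol": c.gene_symbol,
        }
        for c in calls
    ]
    cols = [
        "sample_id", "chrom", "pos", "ref", "alt", "alt_count", "depth", "vaf",
        "callers", "p_binomial", "p_betabinom", "classification", "region",
        "gene_symbol",
    ]
    return pd.DataFrame(rows, columns=cols)
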