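"""Weighted permutation test of gene-set somatic SNV burden.

Observed burden of a gene set is the number of somatic SNVs landing in its
genes. The null redistributes the same number of SNVs over all genes with
probability proportional to a per-gene weight (by default the gene's covered
panel length, since longer targets accrue more SNVs by chance alone).
Empirical p-values use the standard pseudo-count construction
``p = (1 + #{null >= observed}) / (n_perm + 1)``, so they are never 0, and
are BH-adjusted across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .burden import fdr_adjust

__all__ = ["GeneSetResult", "geneset_burden_test"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetResult:
    """Permutation enrichment result for one gene set."""

    set_name: str
    observed: int
    null_mean: float
    p: float
    q: float = np.nan
    n_genes: int = 0


def geneset_burden_test(
    snv_genes: list[str] | pd.Series,
    gene_sets: dict[str, list[str]],
    gene_weights: dict[str, float] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> list[GeneSetResult]:
    """Permutation burden enrichment for each gene set.

    ``snv_genes`` assigns each somatic SNV to a gene (one entry per SNV;
    entries not present in ``gene_weights`` are ignored with a warning).
    Empty sets (no weighted gene) report p = 1 with a warning.
    """
    weights = pd.Series(gene_weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("gene weights must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("gene weights must not all be zero")
    genes = weights.index.to_numpy()
    probs = (weights / weights.sum()).to_numpy()

    snv_genes = pd.Series(list(snv_genes), dtype=object)
    known = snv_genes.isin(weights.index)
    if (~known).any():
        logger.warning(
            "%d SNV(s) assigned to genes without weights were dropped",
            int((~known).sum()),
        )
    snv_genes = snv_genes[known]
    n_snv = len(snv_genes)

    rng = child_rng(seed, "geneset_null")
    # one shared null ensemble: n_perm draws of n_snv genes
    gene_index = pd.Series(np.arange(len(genes)), index=genes)
    null_draws = rng.choice(len(genes), size=(n_perm, n_snv), p=probs)

    results = []
    for name, members in gene_sets.items():
        member_idx = set(gene_index[gene_index.index.isin(members)])
        n_genes = len(member_idx)
        observed = int(snv_genes.isin(set(members)).sum())
        if n_genes == 0:
            logger.warning("gene set %r has no weighted genes; p = 1", name)
            results.append(GeneSetResult(name, observed, 0.0, 1.0, n_genes=0))
            continue
        member_mask = np.zeros(len(genes), dtype=bool)
        member_mask[list(member_idx)] = True
        null = member_mask[null_draws].sum(axis=1) if n_snv else np.zeros(n_perm, int)
        p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
        results.append(
            GeneSetResult(name, observed, float(null.mean()), p, n_genes=n_genes)
        )
    qs = fdr_adjust([r.p for r in results])
    return [
        GeneSetResult(r.set_name, r.observed, r.null_mean, r.p, float(q), r.n_genes)
        for r, q in zip(results, qs)
    ]
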