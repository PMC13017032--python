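"""Synthetic targeted-panel construction.

The deep-sequencing arm of the analysis operates on a targeted enrichment
panel of ALS-associated genes. This module builds a fully synthetic stand-in:
one random reference contig on which each requested gene is laid out with a
toy exon/intron/UTR geometry, plus the BED-style target intervals covering
each gene footprint (with a small intergenic flank so that every genomic
region class is represented).

All coordinates are 0-based, half-open. Conversion to 1-based happens only at
VCF boundaries (see :mod:`mosaicburden.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._rng import child_rng

__all__ = [
    "PanelTarget",
    "ExonGeometry",
    "GeneModel",
    "Panel",
    "generate_panel",
    "DEFAULT_PANEL_GENES",
]

#: Genes with the strongest sporadic-vs-control variant enrichment in the
#: targeted panel; default synthetic panel gene set.
DEFAULT_PANEL_GENES = ("VAPB", "MAPT", "FUS", "NEFH", "CCNF", "NEK1", "TBK1")

BASES = np.array(["A", "C", "G", "T"])

REGION_PRECEDENCE = ("exonic", "5UTR", "3UTR", "intronic", "intergenic")


@dataclass(frozen=True)
class PanelTarget:
    """One targeted interval (0-based, half-open)."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"target {self.gene_symbol}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class ExonGeometry:
    """Toy gene geometry: UTRs flanking ``n_exons`` exons separated by introns."""

    n_exons: int = 3
    exon_len: int = 300
    intron_len: int = 400
    utr5_len: int = 150
    utr3_len: int = 200
    flank_len: int = 150
    intergenic_gap: int = 600

    def gene_span(self) -> int:
        return (
            self.utr5_len
            + self.n_exons * self.exon_len
            + (self.n_exons - 1) * self.intron_len
            + self.utr3_len
        )


class GeneModel:
    """Interval lookup over gene features with region-precedence annotation.

    ``features`` is a DataFrame with columns
    ``gene_symbol, chrom, start, end, feature, strand`` where ``feature`` is
    one of ``exon, intron, 5UTR, 3UTR``. Queries resolve overlaps with the
    precedence exonic > 5UTR/3UTR > intronic > intergenic.
    """

    FEATURE_TO_REGION = {
        "exon": "exonic",
        "5UTR": "5UTR",
        "3UTR": "3UTR",
        "intron": "intronic",
    }

    def __init__(self, features: pd.DataFrame):
        required = {"gene_symbol", "chrom", "start", "end", "feature", "strand"}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"gene model missing columns: {sorted(missing)}")
        self.features = features.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.features.groupby("chrom"):
            tree = IntervalTree()
            for row in sub.itertuples():
                tree.addi(row.start, row.end, (row.feature, row.gene_symbol))
            self._trees[chrom] = tree
            gtree = IntervalTree()
            for gene, gsub in sub.groupby("gene_symbol"):
                gtree.addi(int(gsub.start.min()), int(gsub.end.max()), gene)
            self._gene_trees[chrom] = gtree

    @property
    def genes(self) -> list[str]:
        return sorted(self.features.gene_symbol.unique())

    def region_at(self, chrom: str, pos: int) -> tuple[str, str | None]:
        """Return ``(region, gene_symbol or None)`` for a 0-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            # chromosome absent from the model: degrade to intergenic
            return "intergenic", None
        hits = tree[pos]
        gene = None
        ghits = self._gene_trees[chrom][pos]
        if ghits:
            gene = sorted(iv.data for iv in ghits)[0]
        if not hits:
            return "intergenic", gene
        regions = {self.FEATURE_TO_REGION[iv.data[0]] for iv in hits}
        for region in REGION_PRECEDENCE:
            if region in regions:
                return region, gene
        return "intergenic", gene  # pragma: no cover


@dataclass
class Panel:
    """Synthetic reference + targets + gene model bundle."""

    reference: dict[str, str]
    targets: list[PanelTarget]
    gene_model: GeneModel
    seed: int = 0
    _positions: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def target_positions(self) -> pd.DataFrame:
        """All targeted sites as ``(chrom, pos, ref)`` rows (cached)."""
        if self._positions is None:
            rows = []
            for t in self.targets:
                seq = self.reference[t.chrom]
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": t.chrom,
                            "pos": np.arange(t.start, t.end),
                            "ref": list(seq[t.start : t.end]),
                        }
                    )
                )
            self._positions = pd.concat(rows, ignore_index=True).drop_duplicates(
                subset=["chrom", "pos"], ignore_index=True
            )
        return self._positions

    @property
    def n_target_bases(self) -> int:
        return len(self.target_positions())

    def gene_lengths(self) -> pd.Series:
        """Covered (targeted) length per gene; the default gene-set null weight."""
        spans = self.gene_model.features.groupby("gene_symbol").agg(
            start=("start", "min"), end=("end", "max")
        )
        return (spans.end - spans.start).astype(float)


def generate_panel(
    gene_names: list[str] | tuple[str, ...] = DEFAULT_PANEL_GENES,
    geometry: ExonGeometry | None = None,
    seed: int = 0,
) -> Panel:
    """Build a deterministic synthetic panel for the given genes.

    Genes are laid out sequentially on one contig, each with 5'UTR,
    alternating exons/introns, 3'UTR, and an untargeted intergenic gap
    between genes. Targets extend ``flank_len`` past the gene span so that
    intergenic positions are sequenced too.

    Raises ``ValueError`` on an empty list or duplicate gene names.
    """
    gene_names = list(gene_names)
    if not gene_names:
        raise ValueError("gene_names must be non-empty")
    if len(set(gene_names)) != len(gene_names):
        dupes = sorted({g for g in gene_names if gene_names.count(g) > 1})
        raise ValueError(f"duplicate gene name(s): {dupes}")
    geom = geometry or ExonGeometry()
    rng = child_rng(seed, "panel")

    chrom = "panel_1"
    features = []
    targets = []
    cursor = geom.intergenic_gap
    strands = rng.choice(["+", "-"], size=len(gene_names))
    for gene, strand in zip(gene_names, strands):
        gstart = cursor
        pos = gstart
        features.append((gene, chrom, pos, pos + geom.utr5_len, "5UTR", strand))
        pos += geom.utr5_len
        for i in range(geom.n_exons):
            features.append((gene, chrom, pos, pos + geom.exon_len, "exon", strand))
            pos += geom.exon_len
            if i < geom.n_exons - 1:
                features.append(
                    (gene, chrom, pos, pos + geom.intron_len, "intron", strand)
                )
                pos += geom.intron_len
        features.append((gene, chrom, pos, pos + geom.utr3_len, "3UTR", strand))
        pos += geom.utr3_len
        targets.append(
            PanelTarget(
                gene_symbol=gene,
                chrom=chrom,
                start=max(0, gstart - geom.flank_len),
                end=pos + geom.flank_len,
                strand=str(strand),
            )
        )
        cursor = pos + geom.intergenic_gap

    total_len = cursor + geom.intergenic_gap
    seq = "".join(rng.choice(BASES, size=total_len))
    model = GeneModel(
        pd.DataFrame(
            features,
            columns=["gene_symbol", "chrom", "start", "end", "feature", "strand"],
        )
    )
    return Panel(reference={chrom: seq}, targets=targets, gene_model=model, seed=seed)
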