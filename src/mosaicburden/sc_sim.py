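"""Synthetic single-cell pileup cohort with planted clonal variants.

Emulates the substrate of cell-type-aware somatic calling from single-cell
RNA data: per-cell, per-site base counts for a set of annotated cortical
cell types, sparse expression-like coverage (zero-inflated Poisson depth
with cell-type-specific means), background errors, and clonal somatic
variants carried by a stated fraction of the cells of one host cell type —
by default concentrated in excitatory neurons, the cell type that
accumulates the highest somatic burden in diseased motor cortex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .panel import Panel

__all__ = [
    "CellTypeSpec",
    "CloneSpec",
    "ScSimConfig",
    "ScTruthVariant",
    "DEFAULT_CELL_TYPES",
    "default_cell_types",
    "default_clones",
    "simulate_sc_cohort",
]

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}

#: Annotated cortical cell types of the single-cell cohort.
DEFAULT_CELL_TYPES = (
    "excitatory_neurons",
    "inhibitory_neurons",
    "astrocytes",
    "oligodendrocytes",
    "OPC",
    "microglia",
    "endothelial",
    "pericytes",
    "VLMC",
    "fibroblasts",
)


@dataclass(frozen=True)
class CellTypeSpec:
    """One annotated cell type: size, coverage sparsity, cluster label."""

    name: str
    n_cells: int = 100
    coverage_rate: float = 0.25  # probability a cell covers a site at all
    mean_depth: float = 6.0  # reads per covered cell-site
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage_rate <= 1.0:
            raise ValueError("coverage_rate must be in (0, 1]")
        if self.n_cells < 1 or self.mean_depth <= 0:
            raise ValueError("need n_cells >= 1 and mean_depth > 0")


@dataclass(frozen=True)
class CloneSpec:
    """A clonal somatic variant restricted to one host cell type."""

    cell_type: str
    n_variants: int = 1
    carrier_fraction: float = 0.25
    vaf_in_carrier: float = 0.5  # heterozygous in carrier cells

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")
        if not 0.0 < self.vaf_in_carrier <= 1.0:
            raise ValueError("vaf_in_carrier must be in (0, 1]")


@dataclass
class ScSimConfig:
    """Single-cell simulation conditions."""

    n_sites: int = 400
    error_rate: float = 1e-3
    condition: str = "sALS"
    n_germline: int = 0  # ubiquitous het variants (germline screen tests)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass(frozen=True)
class ScTruthVariant:
    """Ground truth for one planted single-cell variant."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    origin: str  # clonal | germline
    host_cell_type: str | None
    carrier_barcodes: tuple[str, ...]


def default_cell_types(
    excitatory_boost: float = 1.5, n_cells: int = 100
) -> list[CellTypeSpec]:
    """The default ten-cell-type cortical census.

    Excitatory neurons are the most numerous type (boosted cell count, as in
    cortical snRNA censuses), neurons get denser site coverage than
    glia/vascular types (expression breadth), and excitatory neurons carry
    the high-burden cluster label.
    """
    specs = []
    for i, name in enumerate(DEFAULT_CELL_TYPES):
        neuronal = "neurons" in name
        specs.append(
            CellTypeSpec(
                name=name,
                n_cells=int(n_cells * (excitatory_boost if name == "excitatory_neurons" else 1.0)),
                coverage_rate=0.35 if neuronal else 0.2,
                mean_depth=7.0 if neuronal else 5.0,
                cluster_id=(5 if name == "excitatory_neurons" else i + 10),
            )
        )
    return specs


def default_clones(excitatory_factor: int = 3, base_variants: int = 12) -> list[CloneSpec]:
    """Default clonal census: burden in several cell types, concentrated in
    excitatory neurons (``excitatory_factor`` times the base rate)."""
    return [
        CloneSpec("excitatory_neurons", n_variants=excitatory_factor * base_variants),
        CloneSpec("inhibitory_neurons", n_variants=base_variants),
        CloneSpec("astrocytes", n_variants=base_variants),
        CloneSpec("oligodendrocytes", n_variants=base_variants),
        CloneSpec("microglia", n_variants=base_variants),
    ]


def simulate_sc_cohort(
    panel: Panel,
    cell_types: list[CellTypeSpec] | None = None,
    clones: list[CloneSpec] | None = None,
    cfg: ScSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ScTruthVariant]]:
    """Simulate per-cell pileups over panel sites.

    Returns ``(pileup, annotations, truth)``:

    * ``pileup`` — rows ``(cell_barcode, cell_type, chrom, pos, ref,
      A, C, G, T)`` for covered cell-sites only (sparse);
    * ``annotations`` — ``(cell_barcode, cell_type, cluster_id, condition)``;
    * ``truth`` — planted clonal/germline variants with their carrier cells.

    Per cell and site, coverage is Bernoulli(coverage_rate); covered depth is
    ``1 + Poisson(mean_depth - 1)``. Carrier cells read the alternate base at
    ``vaf_in_carrier``; every read is error-prone at ``error_rate``.
    """
    cfg = cfg or ScSimConfig()
    cell_types = cell_types if cell_types is not None else default_cell_types()
    clones = clones if clones is not None else default_clones()
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    names = [ct.name for ct in cell_types]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell type names")
    for clone in clones:
        if clone.cell_type not in names:
            raise ValueError(f"clone host {clone.cell_type!r} not among cell types")

    rng = child_rng(cfg.seed, "sc_cohort")
    sites_all = panel.target_positions()
    take = rng.choice(len(sites_all), size=min(cfg.n_sites, len(sites_all)), replace=False)
    sites = sites_all.iloc[np.sort(take)].reset_index(drop=True)
    n_sites = len(sites)
    ref_idx = np.array([_BASE_IDX[b] for b in sites.ref])

    annotations = []
    for ct in cell_types:
        for i in range(ct.n_cells):
            annotations.append(
                {
                    "cell_barcode": f"{ct.name}_{i:04d}",
                    "cell_type": ct.name,
                    "cluster_id": ct.cluster_id,
                    "condition": cfg.condition,
                }
            )
    ann = pd.DataFrame(annotations)

    # plant variants: clonal per host type, plus ubiquitous germline-like
    n_planted = sum(c.n_variants for c in clones) + cfg.n_germline
    if n_planted > n_sites:
        raise ValueError("more planted variants than simulated sites")
    var_sites = rng.choice(n_sites, size=n_planted, replace=False)
    truth: list[ScTruthVariant] = []
    # per-site, per-cell alt VAF matrix built sparsely as dicts
    alt_base_at: dict[int, int] = {}
    carrier_vaf: dict[int, dict[str, float]] = {}
    cursor = 0
    for clone in clones:
        host_cells = ann.loc[ann.cell_type == clone.cell_type, "cell_barcode"].to_numpy()
        n_carr = max(1, int(round(clone.carrier_fraction * len(host_cells))))
        for _ in range(clone.n_variants):
            s = int(var_sites[cursor]); cursor += 1
            alt = (ref_idx[s] + int(rng.integers(1, 4))) % 4
            carriers = rng.choice(host_cells, size=n_carr, replace=False)
            alt_base_at[s] = alt
            carrier_vaf[s] = {bc: clone.vaf_in_carrier for bc in carriers}
            truth.append(
                ScTruthVariant(
                    chrom=str(sites.chrom[s]),
                    pos=int(sites.pos[s]),
                    ref_base=str(sites.ref[s]),
                    alt_base="ACGT"[alt],
                    origin="clonal",
                    host_cell_type=clone.cell_type,
                    carrier_barcodes=tuple(sorted(carriers)),
                )
            )
    for _ in range(cfg.n_germline):
        s = int(var_sites[cursor]); cursor += 1
        alt = (ref_idx[s] + int(rng.integers(1, 4))) % 4
        alt_base_at[s] = alt
        carrier_vaf[s] = {bc: 0.5 for bc in ann.cell_barcode}
        truth.append(
            ScTruthVariant(
                chrom=str(sites.chrom[s]),
                pos=int(sites.pos[s]),
                ref_base=str(sites.ref[s]),
                alt_base="ACGT"[alt],
                origin="germline",
                host_cell_type=None,
                carrier_barcodes=tuple(sorted(ann.cell_barcode)),
            )
        )

    e = cfg.error_rate
    frames = []
    for ct in cell_types:
        cells = ann.loc[ann.cell_type == ct.name, "cell_barcode"].to_numpy()
        n_cells = len(cells)
        covered = rng.random((n_cells, n_sites)) < ct.coverage_rate
        depth = np.where(covered, 1 + rng.poisson(ct.mean_depth - 1.0, (n_cells, n_sites)), 0)
        ci, si = np.nonzero(depth)
        d = depth[ci, si]
        probs = np.full((len(d), 4), e / 3.0)
        probs[np.arange(len(d)), ref_idx[si]] = 1.0 - e
        for k in range(len(d)):
            s = si[k]
            vaf = carrier_vaf.get(s, {}).get(cells[ci[k]])
            if vaf is not None:
                p = np.full(4, (1.0 - vaf) * e / 3.0)
                p[alt_base_at[s]] = vaf * (1.0 - e) + (1.0 - vaf) * e / 3.0
                p[ref_idx[s]] = (1.0 - vaf) * (1.0 - e) + vaf * e / 3.0
                probs[k] = p / p.sum()
        counts = rng.multinomial(d, probs)
        frames.append(
            pd.DataFrame(
                {
                    "cell_barcode": cells[ci],
                    "cell_type": ct.name,
                    "chrom": sites.chrom.to_numpy()[si],
                    "pos": sites.pos.to_numpy()[si],
                    "ref": sites.ref.to_numpy()[si],
                    "A": counts[:, 0],
                    "C": counts[:, 1],
                    "G": counts[:, 2],
                    "T": counts[:, 3],
                }
            )
        )
    pileup = pd.concat(frames, ignore_index=True)
    return pileup, ann, truth
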