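"""Synthetic deep-sequencing cohort generator.

Emulates UMI-consensus pileups from deep targeted sequencing of motor-cortex
DNA: per-sample consensus depth around a design target of 2000-fold, a
per-base background error rate, planted somatic variants at low allele
fraction (log-uniform over the mosaic detection window) and germline
variants near 0.5 / 1.0, for samples labelled sALS / fALS / control with
sex, age, origin and coverage metadata.

Two fidelity levels are provided:

* pileup-level (:func:`simulate_sample`) — consensus base counts drawn
  directly per site; used for cohort-scale experiments;
* read-level (:func:`simulate_tagged_reads`) — UMI-tagged reads with
  per-base errors over a small locus; the substrate of the UMI-consensus
  module and its error-suppression tests.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_rng
from .panel import BASES, Panel

__all__ = [
    "SampleMeta",
    "PlantedVariant",
    "SimConfig",
    "TaggedRead",
    "simulate_sample",
    "simulate_cohort",
    "simulate_metadata",
    "simulate_tagged_reads",
    "sample_somatic_vaf",
]

GROUPS = ("sALS", "fALS", "control")

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata; the covariates of the burden GLM."""

    sample_id: str
    group: str
    sex: str
    age: float
    origin: str
    total_coverage: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in {"M", "F"}:
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if not self.total_coverage > 0:
            raise ValueError("total_coverage must be > 0")


@dataclass(frozen=True)
class PlantedVariant:
    """Ground-truth variant planted by the simulator."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    true_vaf: float
    origin: str  # somatic | germline
    sample_id: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base must differ from alt_base")
        if self.origin not in {"somatic", "germline"}:
            raise ValueError(f"origin must be somatic|germline, got {self.origin!r}")
        if not 0.0 < self.true_vaf <= 1.0:
            raise ValueError("true_vaf must be in (0, 1]")
        if self.origin == "somatic" and not self.true_vaf < 0.5:
            raise ValueError("somatic variants must have true_vaf < 0.5")


@dataclass(frozen=True)
class TaggedRead:
    """A UMI-tagged read positioned on the reference (0-based start)."""

    umi: str
    chrom: str
    start: int
    strand: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the targeted-sequencing study design: group sizes
    9 sALS / 4 fALS / 6 control; consensus depth targeting 2000-fold;
    mean somatic variant counts per sample of 80 (sALS) versus 40
    (fALS and control), i.e. a two-fold sporadic-disease excess.
    """

    n_samples: dict[str, int] = field(
        default_factory=lambda: {"sALS": 9, "fALS": 4, "control": 6}
    )
    target_depth: int = 2000
    error_rate: float = 1e-3
    umi_length: int = 8
    mean_family_size: float = 5.0
    somatic_mean: dict[str, float] = field(
        default_factory=lambda: {"sALS": 80.0, "fALS": 40.0, "control": 40.0}
    )
    germline_mean: float = 8.0
    vaf_low: float = 0.015
    vaf_high: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.target_depth < 1:
            raise ValueError("target_depth must be >= 1")
        if not 0 < self.vaf_low < self.vaf_high < 0.5:
            raise ValueError("need 0 < vaf_low < vaf_high < 0.5")
        for g, n in self.n_samples.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("n_samples must be >= 0")
        if any(m < 0 for m in self.somatic_mean.values()) or self.germline_mean < 0:
            raise ValueError("variant count means must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def sample_somatic_vaf(rng: np.random.Generator, cfg: SimConfig, size: int) -> np.ndarray:
    """Somatic true-VAF prior: log-uniform over (vaf_low, vaf_high).

    Reproduces the low-AF-heavy allele-fraction spectrum of bulk mosaic
    variants without asserting any particular empirical distribution.
    """
    lo, hi = np.log(cfg.vaf_low), np.log(cfg.vaf_high)
    return np.exp(rng.uniform(lo, hi, size=size))


def _alt_base_for(rng: np.random.Generator, ref: np.ndarray) -> np.ndarray:
    """Uniform alternate base differing from the reference base."""
    shift = rng.integers(1, 4, size=len(ref))
    ref_idx = np.array([_BASE_IDX[b] for b in ref])
    return BASES[(ref_idx + shift) % 4]


def _plant_variants(
    panel: Panel, meta: SampleMeta, cfg: SimConfig, rng: np.random.Generator
) -> list[PlantedVariant]:
    sites = panel.target_positions()
    n_som = rng.poisson(cfg.somatic_mean.get(meta.group, 0.0))
    n_germ = rng.poisson(cfg.germline_mean)
    n_total = min(n_som + n_germ, len(sites))
    idx = rng.choice(len(sites), size=n_total, replace=False)
    chosen = sites.iloc[idx]
    alts = _alt_base_for(rng, chosen.ref.to_numpy())
    som_vaf = sample_somatic_vaf(rng, cfg, n_total)
    # germline: heterozygous near 0.5 or homozygous near 1.0
    hom = rng.random(n_total) < 0.3
    germ_vaf = np.where(
        hom,
        np.clip(1.0 - np.abs(rng.normal(0.0, 0.002, n_total)), 0.6, 1.0),
        np.clip(rng.normal(0.5, 0.01, n_total), 0.4, 0.6),
    )
    out = []
    for i, (row, alt) in enumerate(zip(chosen.itertuples(), alts)):
        somatic = i < min(n_som, n_total)
        out.append(
            PlantedVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_base=row.ref,
                alt_base=str(alt),
                true_vaf=float(som_vaf[i] if somatic else germ_vaf[i]),
                origin="somatic" if somatic else "germline",
                sample_id=meta.sample_id,
            )
        )
    return out


def simulate_sample(
    panel: Panel,
    meta: SampleMeta,
    cfg: SimConfig,
    variants: list[PlantedVariant] | None = None,
) -> tuple[pd.DataFrame, list[PlantedVariant]]:
    """Simulate a consensus pileup over the panel for one sample.

    Returns ``(pileup, truth)`` where ``pileup`` has one row per targeted
    site with columns ``chrom, pos, ref, A, C, G, T, n_masked`` and truth is
    the list of planted variants. Site depth is Poisson around the sample's
    ``total_coverage``; at a planted site the alternate count is binomial
    with success probability ``vaf*(1-e) + (1-vaf)*e/3``; elsewhere base
    counts are multinomial with total error rate ``e`` spread evenly over
    the three non-reference bases.

    ``variants`` overrides the planting step (used by targeted experiments);
    by default variants are drawn from the config's group-specific rates.
    """
    rng = child_rng(cfg.seed, f"sample:{meta.sample_id}")
    sites = panel.target_positions().copy()
    n = len(sites)
    depth = rng.poisson(meta.total_coverage, size=n)

    e = cfg.error_rate
    probs = np.full((n, 4), e / 3.0)
    ref_idx = np.array([_BASE_IDX[b] for b in sites.ref])
    probs[np.arange(n), ref_idx] = 1.0 - e

    if variants is None:
        variants = _plant_variants(panel, meta, cfg, rng)
    site_key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    locator = pd.Series(np.arange(n), index=site_key)
    for v in variants:
        i = locator.get((v.chrom, v.pos))
        if i is None:
            raise ValueError(f"variant at {v.chrom}:{v.pos} outside the panel")
        p = np.full(4, (1.0 - v.true_vaf) * e / 3.0)
        p[_BASE_IDX[v.alt_base]] = v.true_vaf * (1.0 - e) + (1.0 - v.true_vaf) * e / 3.0
        p[_BASE_IDX[v.ref_base]] = (1.0 - v.true_vaf) * (1.0 - e) + v.true_vaf * e / 3.0
        probs[i] = p / p.sum()

    counts = rng.multinomial(depth, probs)
    pileup = sites.assign(
        A=counts[:, 0], C=counts[:, 1], G=counts[:, 2], T=counts[:, 3], n_masked=0
    )
    return pileup, variants


def simulate_metadata(cfg: SimConfig) -> list[SampleMeta]:
    """Draw the cohort's sample sheet (groups, sex, age, origin, coverage)."""
    rng = child_rng(cfg.seed, "metadata")
    metas = []
    for group in GROUPS:
        for i in range(cfg.n_samples.get(group, 0)):
            sid = f"{group}_{i + 1:02d}"
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    group=group,
                    sex=str(rng.choice(["M", "F"])),
                    age=float(np.round(rng.uniform(45, 85), 1)),
                    origin=str(rng.choice(["Umea", "NBB"])),
                    total_coverage=float(
                        np.round(cfg.target_depth * rng.lognormal(0.0, 0.08), 1)
                    ),
                )
            )
    return metas


def simulate_cohort(
    panel: Panel, cfg: SimConfig
) -> tuple[list[SampleMeta], dict[str, pd.DataFrame], list[PlantedVariant]]:
    """Simulate the full cohort: metadata, per-sample pileups, pooled truth."""
    metas = simulate_metadata(cfg)
    pileups: dict[str, pd.DataFrame] = {}
    truth: list[PlantedVariant] = []
    for meta in metas:
        pileup, variants = simulate_sample(panel, meta, cfg)
        pileups[meta.sample_id] = pileup
        truth.extend(variants)
    return metas, pileups, truth


def simulate_tagged_reads(
    reference: dict[str, str],
    chrom: str,
    start: int,
    end: int,
    cfg: SimConfig,
    n_molecules: int = 200,
    read_length: int = 100,
    variant: PlantedVariant | None = None,
    seed_label: str = "reads",
) -> tuple[list[TaggedRead], list[str]]:
    """Simulate UMI-tagged reads over ``[start, end)`` of one contig.

    Each source molecule gets a random UMI, a start position, and a template
    (reference, or carrying ``variant`` with probability ``variant.true_vaf``);
    its UMI family has ``1 + Poisson(mean_family_size - 1)`` reads, each an
    error-prone copy of the template at per-base error ``cfg.error_rate``.

    Returns ``(reads, templates)`` where ``templates[i]`` is the true
    template sequence of molecule ``i`` (reads carry ``umi`` tags; the
    molecule index is recoverable from read order only in tests that
    need it via the returned grouping of consecutive reads).
    """
    rng = child_rng(cfg.seed, seed_label)
    seq = reference[chrom]
    if end > len(seq):
        raise ValueError("locus extends past the reference contig")
    reads: list[TaggedRead] = []
    templates: list[str] = []
    hi = max(start + 1, end - read_length)
    for _ in range(n_molecules):
        mstart = int(rng.integers(start, hi))
        template = list(seq[mstart : mstart + read_length])
        if variant is not None and mstart <= variant.pos < mstart + len(template):
            if rng.random() < variant.true_vaf:
                template[variant.pos - mstart] = variant.alt_base
        template = "".join(template)
        templates.append(template)
        umi = "".join(rng.choice(BASES, size=cfg.umi_length))
        fam_size = 1 + rng.poisson(max(cfg.mean_family_size - 1.0, 0.0))
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(fam_size):
            errs = rng.random(len(template)) < cfg.error_rate
            bases = np.array(list(template))
            if errs.any():
                shift = rng.integers(1, 4, size=int(errs.sum()))
                idx = np.array([_BASE_IDX[b] for b in bases[errs]])
                bases[errs] = BASES[(idx + shift) % 4]
            reads.append(
                TaggedRead(
                    umi=umi,
                    chrom=chrom,
                    start=mstart,
                    strand=strand,
                    bases="".join(bases),
                    quals=tuple([30] * len(template)),
                )
            )
    return reads, templates
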