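"""UMI-based error correction.

Reads sharing a start coordinate and (near-)identical unique molecular
identifier derive from one source molecule; collapsing each such family to a
consensus sequence suppresses independent per-read sequencing errors. This
module groups tagged reads into UMI families (greedy directional merging),
calls count-based consensus sequences with an agreement threshold, and
tallies consensus observations into per-site pileups — the substrate of all
downstream variant calling.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TaggedRead

__all__ = [
    "UmiFamily",
    "ConsensusRead",
    "ConsensusPileupSite",
    "group_by_umi",
    "consensus_call",
    "build_pileup",
    "consensus_pileup",
]

logger = logging.getLogger(__name__)

_VALID_UMI = frozenset("ACGT")
MASK = "N"


@dataclass
class UmiFamily:
    """Reads collapsed under one (start coordinate, merged UMI) label."""

    family_id: str
    chrom: str
    start: int
    umi: str
    reads: list[TaggedRead] = field(default_factory=list)

    @property
    def family_size(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class ConsensusRead:
    """Per-offset consensus of one UMI family; masked offsets hold ``N``."""

    chrom: str
    start: int
    bases: str
    family_size: int


@dataclass
class ConsensusPileupSite:
    """Per-site consensus base counts (the caller substrate)."""

    chrom: str
    pos: int
    ref_base: str
    counts: dict[str, int]
    n_masked: int = 0

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def group_by_umi(
    reads: list[TaggedRead], max_umi_edit_distance: int = 1
) -> tuple[list[UmiFamily], int]:
    """Partition reads into UMI families.

    Reads are first bucketed by exact ``(chrom, start)``; within a bucket,
    UMIs are merged greedily in descending order of read count (ties broken
    lexicographically by UMI): each UMI joins the first already-accepted
    family whose seed UMI is within ``max_umi_edit_distance`` (Hamming), so
    larger families absorb smaller ones. Reads with malformed (non-ACGT)
    UMIs are rejected and counted.

    Returns ``(families, n_rejected)``.
    """
    n_rejected = 0
    buckets: dict[tuple[str, int], Counter] = defaultdict(Counter)
    members: dict[tuple[str, int, str], list[TaggedRead]] = defaultdict(list)
    for read in reads:
        if not set(read.umi) <= _VALID_UMI:
            n_rejected += 1
            continue
        buckets[(read.chrom, read.start)][read.umi] += 1
        members[(read.chrom, read.start, read.umi)].append(read)
    if n_rejected:
        logger.warning("rejected %d reads with malformed UMIs", n_rejected)

    families: list[UmiFamily] = []
    for (chrom, start), umi_counts in sorted(buckets.items()):
        order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
        seeds: list[str] = []
        assignment: dict[str, str] = {}
        for umi in order:
            for seed in seeds:
                if _hamming(umi, seed) <= max_umi_edit_distance:
                    assignment[umi] = seed
                    break
            else:
                seeds.append(umi)
                assignment[umi] = umi
        by_seed: dict[str, list[TaggedRead]] = defaultdict(list)
        for umi in order:
            by_seed[assignment[umi]].extend(members[(chrom, start, umi)])
        for seed in seeds:
            families.append(
                UmiFamily(
                    family_id=f"{chrom}:{start}:{seed}",
                    chrom=chrom,
                    start=start,
                    umi=seed,
                    reads=by_seed[seed],
                )
            )
    return families, n_rejected


def consensus_call(
    family: UmiFamily, min_family_size: int = 3, min_agreement: float = 0.75
) -> ConsensusRead | None:
    """Collapse one family to a consensus read, or drop it.

    Families below ``min_family_size`` are dropped. At each offset the modal
    base is emitted iff its within-family fraction is at least
    ``min_agreement`` (which must exceed 0.5, so the modal base is unique
    whenever it passes); otherwise — including exact ties — the offset is
    masked. Consensus is purely count-based; qualities are not consulted.
    """
    if not min_agreement > 0.5:
        raise ValueError("min_agreement must be > 0.5")
    if family.family_size < min_family_size:
        return None
    length = max(len(r.bases) for r in family.reads)
    out = []
    for offset in range(length):
        calls = Counter(
            r.bases[offset] for r in family.reads if offset < len(r.bases)
        )
        total = sum(calls.values())
        base, count = max(calls.items(), key=lambda kv: (kv[1], kv[0]))
        top = [b for b, c in calls.items() if c == count]
        if len(top) > 1 or count / total < min_agreement:
            out.append(MASK)
        else:
            out.append(base)
    return ConsensusRead(
        chrom=family.chrom,
        start=family.start,
        bases="".join(out),
        family_size=family.family_size,
    )


def build_pileup(
    consensus_reads: list[ConsensusRead],
    reference: dict[str, str],
    positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tally consensus reads into a per-site pileup DataFrame.

    Columns: ``chrom, pos, ref, A, C, G, T, n_masked``. Masked offsets
    contribute to ``n_masked`` only, so at every site
    ``A+C+G+T+n_masked`` equals the number of consensus reads covering it.
    ``positions`` restricts/extends the output to the given ``(chrom, pos)``
    sites (zero rows are retained for uncovered sites); by default the
    covered span of the reads is reported.
    """
    counts: dict[tuple[str, int], np.ndarray] = defaultdict(lambda: np.zeros(5, int))
    for cr in consensus_reads:
        seq = reference.get(cr.chrom)
        if seq is None:
            raise ValueError(f"contig {cr.chrom!r} absent from reference")
        if cr.start + len(cr.bases) > len(seq):
            raise ValueError(
                f"consensus read at {cr.chrom}:{cr.start} extends past the reference"
            )
        for offset, base in enumerate(cr.bases):
            key = (cr.chrom, cr.start + offset)
            if base == MASK:
                counts[key][4] += 1
            else:
                counts[key]["ACGT".index(base)] += 1

    if positions is None:
        keys = sorted(counts)
        rows = pd.DataFrame(
            {"chrom": [k[0] for k in keys], "pos": [k[1] for k in keys]}
        )
    else:
        rows = positions[["chrom", "pos"]].reset_index(drop=True)
    data = np.zeros((len(rows), 5), dtype=int)
    for i, (chrom, pos) in enumerate(zip(rows.chrom, rows.pos)):
        if (chrom, pos) in counts:
            data[i] = counts[(chrom, pos)]
    refs = [reference[c][p] for c, p in zip(rows.chrom, rows.pos)]
    return rows.assign(
        ref=refs,
        A=data[:, 0],
        C=data[:, 1],
        G=data[:, 2],
        T=data[:, 3],
        n_masked=data[:, 4],
    )


def consensus_pileup(
    reads: list[TaggedRead],
    reference: dict[str, str],
    max_umi_edit_distance: int = 1,
    min_family_size: int = 3,
    min_agreement: float = 0.75,
    positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """End-to-end UMI stage: group, collapse, and pile up tagged reads."""
    families, _ = group_by_umi(reads, max_umi_edit_distance)
    consensus = [
        cr
        for fam in families
        if (cr := consensus_call(fam, min_family_size, min_agreement)) is not None
    ]
    return build_pileup(consensus, reference, positions=positions)
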