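"""Shared file I/O.

All in-memory coordinates are 0-based, half-open; conversion to VCF's
1-based convention happens only inside the VCF reader/writer (pysam handles
this via its 0-based ``start`` attribute). Malformed lines raise with a line
number — never a silent skip.

Formats: FASTA (Biopython), 6-column BED, GFF3-like gene-model TSV,
uncompressed VCF (pysam) for truth and calls, TSV tables (pandas), GMT gene
sets.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import VariantCall
from .cohort import PlantedVariant, SampleMeta
from .panel import GeneModel, Panel, PanelTarget

__all__ = [
    "read_fasta", "write_fasta",
    "read_bed", "write_bed",
    "read_gene_model", "write_gene_model",
    "read_metadata", "write_metadata",
    "write_truth_vcf", "read_truth_vcf",
    "write_calls_vcf", "read_calls_vcf",
    "read_gmt", "write_gmt",
    "read_panel", "write_panel",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
META_COLUMNS = ["sample_id", "group", "sex", "age", "origin", "total_coverage"]
MODEL_COLUMNS = ["gene_symbol", "chrom", "start", "end", "feature", "strand"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------ BED

def write_bed(targets: list[PanelTarget], path) -> None:
    df = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.gene_symbol, 0, t.strand) for t in targets],
        columns=BED_COLUMNS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> list[PanelTarget]:
    targets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            try:
                targets.append(
                    PanelTarget(
                        gene_symbol=fields[3], chrom=fields[0],
                        start=int(fields[1]), end=int(fields[2]), strand=fields[5],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return targets


# ----------------------------------------------------------- gene model

def write_gene_model(model: GeneModel, path) -> None:
    model.features[MODEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_model(path) -> GeneModel:
    df = pd.read_csv(path, sep="\t")
    return GeneModel(df)


def write_panel(panel: Panel, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "targets": outdir / "targets.bed",
        "gene_model": outdir / "gene_model.tsv",
    }
    write_fasta(panel.reference, paths["reference"])
    write_bed(panel.targets, paths["targets"])
    write_gene_model(panel.gene_model, paths["gene_model"])
    return paths


def read_panel(outdir) -> Panel:
    outdir = Path(outdir)
    return Panel(
        reference=read_fasta(outdir / "reference.fasta"),
        targets=read_bed(outdir / "targets.bed"),
        gene_model=read_gene_model(outdir / "gene_model.tsv"),
    )


# ------------------------------------------------------------- metadata

def write_metadata(metas: list[SampleMeta], path) -> None:
    pd.DataFrame([m.__dict__ for m in metas])[META_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {sorted(missing)}")
    return [SampleMeta(**row._asdict()) for row in df[META_COLUMNS].itertuples(index=False)]


# ------------------------------------------------------------------ VCF

def _vcf_header(reference: dict[str, str], info_lines: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, seq in reference.items():
        header.contigs.add(name, length=len(seq))
    for line in info_lines:
        header.add_line(line)
    return header


def write_truth_vcf(variants: list[PlantedVariant], reference: dict[str, str], path) -> None:
    """Planted-truth VCF with INFO keys TRUE_VAF, ORIGIN, SAMPLE."""
    header = _vcf_header(
        reference,
        [
            '##INFO=<ID=TRUE_VAF,Number=1,Type=Float,Description="Planted allele fraction">',
            '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="somatic or germline">',
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample carrying the variant">',
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt_base, v.sample_id)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos, stop=v.pos + 1,
                alleles=(v.ref_base, v.alt_base),
            )
            rec.info["TRUE_VAF"] = float(v.true_vaf)
            rec.info["ORIGIN"] = v.origin
            rec.info["SAMPLE"] = v.sample_id
            vcf.write(rec)


def read_truth_vcf(path) -> list[PlantedVariant]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append(
                PlantedVariant(
                    chrom=rec.chrom, pos=rec.start,
                    ref_base=rec.ref, alt_base=rec.alts[0],
                    # htslib stores INFO floats as float32; restore the
                    # written decimal precision
                    true_vaf=round(float(rec.info["TRUE_VAF"]), 6),
                    origin=str(rec.info["ORIGIN"]),
                    sample_id=str(rec.info["SAMPLE"]),
                )
            )
    return out


CALL_INFO_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Consensus depth">',
    '##INFO=<ID=AD,Number=R,Type=Integer,Description="Consensus counts (ref, top alt)">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Alternate allele fraction">',
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">',
    '##INFO=<ID=CLASS,Number=1,Type=String,Description="somatic, germline or filtered">',
    '##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">',
]


def write_calls_vcf(calls: list[VariantCall], reference: dict[str, str], path) -> None:
    """Emitted calls as uncompressed VCF (internal 0-based pos -> VCF 1-based)."""
    header = _vcf_header(reference, CALL_INFO_LINES)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt_base, c.sample_id or "")):
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos, stop=c.pos + 1,
                alleles=(c.ref_base, c.alt_base),
            )
            rec.info["DP"] = c.depth
            rec.info["AD"] = (c.depth - c.alt_count, c.alt_count)
            rec.info["VAF"] = float(c.vaf)
            rec.info["CALLERS"] = list(c.callers)
            rec.info["CLASS"] = c.classification
            rec.info["REGION"] = c.region
            if c.gene_symbol:
                rec.info["GENE"] = c.gene_symbol
            if c.sample_id:
                rec.info["SAMPLE"] = c.sample_id
            vcf.write(rec)


def read_calls_vcf(path) -> list[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            callers = rec.info.get("CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            out.append(
                VariantCall(
                    chrom=rec.chrom, pos=rec.start,
                    ref_base=rec.ref, alt_base=rec.alts[0],
                    alt_count=int(rec.info["AD"][1]), depth=int(rec.info["DP"]),
                    callers=tuple(callers), p_values={},
                    classification=str(rec.info["CLASS"]),
                    region=str(rec.info.get("REGION", "intergenic")),
                    gene_symbol=rec.info.get("GENE"),
                    sample_id=rec.info.get("SAMPLE"),
                )
            )
    return out


# ------------------------------------------------------------------ GMT

def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ----------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
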