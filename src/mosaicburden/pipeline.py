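"""Pipeline driver: simulate -> call -> burden -> sc-call -> signatures -> enrich.

Stages run in dependency order, each persisting text outputs under the run
directory; every stage is rerunnable from its persisted inputs, and the whole
run is a pure function of (config, seed). A manifest records the config hash,
per-file SHA-256 checksums, row counts and timestamps, written at completion
(or with partial state if a stage fails).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as mio
from ._rng import child_seed
from .burden import BurdenGLM, build_burden, fdr_adjust, gene_burden_ratio, summary_t_test
from .calling import call_pileup, calls_to_frame
from .config import RunConfig
from .genesets import geneset_burden_test
from .panel import generate_panel
from .sc import (
    aggregate_by_celltype,
    call_sc_variants,
    cluster_burden,
    compare_celltype_burden,
    per_cell_burden,
)
from .sc_sim import simulate_sc_cohort
from .signatures import compare_condition_fractions, synthetic_catalog
from .cohort import simulate_cohort

__all__ = ["run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "burden", "sc_call", "sc_burden", "signatures", "enrich")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.path = outdir / "manifest.json"
        self.data = {
            "tool": "mosaicburden 0.1.0",
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": {},
            "status": "running",
        }

    def record(self, stage: str, files: dict[str, Path], counts: dict[str, int]):
        self.data["stages"][stage] = {
            "files": {k: str(p) for k, p in files.items()},
            "checksums": {k: _sha256(p) for k, p in files.items()},
            "row_counts": counts,
            "completed_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        self._write()

    def finish(self, status: str):
        self.data["status"] = status
        self._write()

    def _write(self):
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = _Manifest(outdir, config)
    config.to_yaml(outdir / "config.yaml")
    try:
        _run_stages(config, outdir, manifest)
    except Exception:
        manifest.finish("failed")
        raise
    manifest.finish("completed")
    return manifest.data


def _run_stages(config: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    # ---- simulate -------------------------------------------------------
    panel = generate_panel(config.genes, seed=child_seed(config.seed, "panel"))
    sim_cfg = config.sim.with_seed(child_seed(config.seed, "cohort"))
    metas, pileups, truth = simulate_cohort(panel, sim_cfg)
    sim_dir = outdir / "simulate"
    files = mio.write_panel(panel, sim_dir)
    mio.write_metadata(metas, sim_dir / "metadata.tsv")
    files["metadata"] = sim_dir / "metadata.tsv"
    for sid, pileup in pileups.items():
        p = sim_dir / f"pileup_{sid}.tsv"
        pileup.to_csv(p, sep="\t", index=False)
        files[f"pileup_{sid}"] = p
    mio.write_truth_vcf(truth, panel.reference, sim_dir / "truth.vcf")
    files["truth"] = sim_dir / "truth.vcf"
    manifest.record("simulate", files, {"samples": len(metas), "truth_variants": len(truth)})

    # ---- call -----------------------------------------------------------
    call_dir = outdir / "call"
    call_dir.mkdir(exist_ok=True)
    all_calls = []
    for meta in metas:
        calls = call_pileup(
            pileups[meta.sample_id], config.caller,
            gene_model=panel.gene_model, sample_id=meta.sample_id,
        )
        all_calls.extend(calls)
    mio.write_calls_vcf(all_calls, panel.reference, call_dir / "calls.vcf")
    calls_df = calls_to_frame(all_calls)
    calls_df.to_csv(call_dir / "calls.tsv", sep="\t", index=False)
    manifest.record(
        "call",
        {"calls_vcf": call_dir / "calls.vcf", "calls_tsv": call_dir / "calls.tsv"},
        {"calls": len(all_calls)},
    )

    # ---- burden ---------------------------------------------------------
    burden_dir = outdir / "burden"
    burden_dir.mkdir(exist_ok=True)
    table = build_burden(
        calls_df, metas, af_bin_edges=tuple(config.af_bins), genes=config.genes
    )
    table.to_csv(burden_dir / "burden_table.tsv", sep="\t", index=False)
    fit = BurdenGLM.from_dataframe(table, drop_collinear=True).fit()
    report = fit.to_dict()
    group_ps = {k: v for k, v in report["p_values"].items() if k.startswith("group[")}
    report["q_values_group"] = dict(
        zip(group_ps, (float(q) for q in fdr_adjust(list(group_ps.values()))))
    )
    ts = summary_t_test(table)
    report["t_test"] = ts.__dict__
    mio.write_json(report, burden_dir / "glm_report.json")
    ratios = gene_burden_ratio(table)
    ratios.to_csv(burden_dir / "gene_ratios.tsv", sep="\t", index=False)
    manifest.record(
        "burden",
        {
            "table": burden_dir / "burden_table.tsv",
            "glm": burden_dir / "glm_report.json",
            "gene_ratios": burden_dir / "gene_ratios.tsv",
        },
        {"samples": len(table), "genes": len(ratios)},
    )

    # ---- sc_call --------------------------------------------------------
    sc_dir = outdir / "sc"
    sc_dir.mkdir(exist_ok=True)
    sc_cfg = config.sc_sim
    sc_cfg.seed = child_seed(config.seed, "sc_cohort")
    sc_pileup, annotations, sc_truth = simulate_sc_cohort(
        panel, clones=config.sc_clones, cfg=sc_cfg
    )
    sc_pileup.to_csv(sc_dir / "sc_pileup.tsv", sep="\t", index=False)
    annotations.to_csv(sc_dir / "sc_annotations.tsv", sep="\t", index=False)
    ctp = aggregate_by_celltype(sc_pileup, annotations)
    variants = call_sc_variants(ctp, config.sc_caller)
    var_df = pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref_base, "alt": v.alt_base,
                "status": v.status, "host_cell_types": ",".join(v.host_cell_types),
            }
            for v in variants
        ]
    )
    var_df.to_csv(sc_dir / "sc_variants.tsv", sep="\t", index=False)
    manifest.record(
        "sc_call",
        {
            "pileup": sc_dir / "sc_pileup.tsv",
            "annotations": sc_dir / "sc_annotations.tsv",
            "variants": sc_dir / "sc_variants.tsv",
        },
        {
            "cells": len(annotations),
            "somatic": int((var_df.status == "somatic").sum()) if len(var_df) else 0,
        },
    )

    # ---- sc_burden ------------------------------------------------------
    burden_cells = per_cell_burden(variants, sc_pileup, annotations)
    burden_cells.to_csv(sc_dir / "sc_cell_burden.tsv", sep="\t", index=False)
    contrasts = compare_celltype_burden(burden_cells)
    contrasts.to_csv(sc_dir / "sc_celltype_contrasts.tsv", sep="\t", index=False)
    clusters = cluster_burden(burden_cells)
    clusters.to_csv(sc_dir / "sc_cluster_burden.tsv", sep="\t", index=False)
    manifest.record(
        "sc_burden",
        {
            "cell_burden": sc_dir / "sc_cell_burden.tsv",
            "contrasts": sc_dir / "sc_celltype_contrasts.tsv",
            "clusters": sc_dir / "sc_cluster_burden.tsv",
        },
        {"cells": len(burden_cells), "contrasts": len(contrasts)},
    )

    # ---- signatures -----------------------------------------------------
    sig_dir = outdir / "signatures"
    sig_dir.mkdir(exist_ok=True)
    catalog = synthetic_catalog(config.n_signatures)
    catalog.to_cosmic_tsv(sig_dir / "catalog.tsv")
    som_calls = calls_df[calls_df.classification == "somatic"]
    groups = {m.sample_id: m.group for m in metas}
    snvs_by_cond = {}
    for cond in sorted(set(groups.values())):
        sids = [s for s, g in groups.items() if g == cond]
        snvs_by_cond[cond] = som_calls[som_calls.sample_id.isin(sids)][
            ["chrom", "pos", "ref", "alt"]
        ].reset_index(drop=True)
    fracs = compare_condition_fractions(
        snvs_by_cond, panel.reference, catalog,
        n_boot=config.n_boot, seed=child_seed(config.seed, "signature_boot"),
    )
    fracs.to_csv(sig_dir / "condition_fractions.tsv", sep="\t", index=False)
    manifest.record(
        "signatures",
        {"catalog": sig_dir / "catalog.tsv", "fractions": sig_dir / "condition_fractions.tsv"},
        {"conditions": len(snvs_by_cond)},
    )

    # ---- enrich ---------------------------------------------------------
    enrich_dir = outdir / "enrich"
    enrich_dir.mkdir(exist_ok=True)
    genes = config.genes
    half = max(1, len(genes) // 2)
    gene_sets = {"synapse_organization": genes[:half], "cell_junction": genes[half:]}
    mio.write_gmt(gene_sets, enrich_dir / "gene_sets.gmt")
    weights = panel.gene_lengths()
    snv_genes = som_calls.gene_symbol.dropna().tolist()
    results = geneset_burden_test(
        snv_genes, gene_sets, weights,
        n_perm=config.n_perm, seed=child_seed(config.seed, "enrich"),
    )
    res_df = pd.DataFrame([r.__dict__ for r in results])
    res_df.to_csv(enrich_dir / "geneset_enrichment.tsv", sep="\t", index=False)
    manifest.record(
        "enrich",
        {"gene_sets": enrich_dir / "gene_sets.gmt",
         "results": enrich_dir / "geneset_enrichment.tsv"},
        {"sets": len(results)},
    )
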