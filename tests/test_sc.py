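"""Cell-type aggregation, the contrast caller, per-cell burden, comparisons."""

import numpy as np
import pandas as pd
import pytest

import mosaicburden as mb
from mosaicburden.sc import (
    ScCallerConfig,
    aggregate_by_celltype,
    call_sc_variant,
    call_sc_variants,
    cluster_burden,
    compare_celltype_burden,
    per_cell_burden,
)
from mosaicburden.sc_sim import CellTypeSpec, CloneSpec, ScSimConfig, simulate_sc_cohort


def cell_rows(barcode, ctype, pos, counts):
    base = {"A": 0, "C": 0, "G": 0, "T": 0}
    base.update(counts)
    return {"cell_barcode": barcode, "cell_type": ctype, "chrom": "c1",
            "pos": pos, "ref": "A", **base}


def annotations(barcodes_types):
    return pd.DataFrame(
        [{"cell_barcode": b, "cell_type": t, "cluster_id": 0, "condition": "sALS"}
         for b, t in barcodes_types]
    )


class TestAggregation:
    def test_exact_summation_and_cell_counting(self):
        pl = pd.DataFrame([
            cell_rows("e1", "excitatory", 5, {"A": 3}),
            cell_rows("e2", "excitatory", 5, {"A": 2, "G": 1}),
            cell_rows("i1", "inhibitory", 5, {"A": 4}),
        ])
        ann = annotations([("e1", "excitatory"), ("e2", "excitatory"),
                           ("i1", "inhibitory"), ("i2", "inhibitory")])
        agg = aggregate_by_celltype(pl, ann).set_index("cell_type")
        exc = agg.loc["excitatory"]
        assert exc.A == 5 and exc.G == 1 and exc.n_cells_covered == 2

    def test_type_without_coverage_keeps_zero_row(self):
        pl = pd.DataFrame([cell_rows("e1", "excitatory", 5, {"A": 3})])
        ann = annotations([("e1", "excitatory"), ("m1", "microglia")])
        agg = aggregate_by_celltype(pl, ann).set_index("cell_type")
        assert agg.loc["microglia"].depth == 0
        assert agg.loc["microglia"].n_cells_covered == 0

    def test_aggregate_equals_backtrace_sums(self, panel):
        pl, ann, _ = simulate_sc_cohort(
            panel, clones=[CloneSpec("excitatory_neurons", n_variants=5)],
            cfg=ScSimConfig(seed=3, n_sites=50),
        )
        agg = aggregate_by_celltype(pl, ann)
        manual = (
            pl.merge(ann[["cell_barcode"]], on="cell_barcode")
            .groupby(["chrom", "pos", "cell_type"], observed=True)[["A", "C", "G", "T"]]
            .sum()
        )
        merged = agg.set_index(["chrom", "pos", "cell_type"])[["A", "C", "G", "T"]]
        joined = manual.join(merged, rsuffix="_agg")
        for b in "ACGT":
            assert (joined[b] == joined[f"{b}_agg"]).all()

    def test_unannotated_barcode_errors(self):
        pl = pd.DataFrame([cell_rows("ghost", "excitatory", 5, {"A": 3})])
        ann = annotations([("e1", "excitatory"), ("e2", "other")])
        with pytest.raises(ValueError, match="ghost"):
            aggregate_by_celltype(pl, ann)


def site_block(per_type):
    """Build one site's aggregated block: {type: (alt, depth, n_cells)}."""
    rows = []
    for t, (alt, depth, n_cells) in per_type.items():
        rows.append({"chrom": "c1", "pos": 9, "ref": "A", "cell_type": t,
                     "A": depth - alt, "C": 0, "G": alt, "T": 0,
                     "depth": depth, "n_cells_covered": n_cells})
    return pd.DataFrame(rows)


class TestScCaller:
    cfg = ScCallerConfig()

    def test_clonal_signal_in_one_type_is_somatic(self):
        block = site_block({
            "excitatory": (30, 100, 10),
            "inhibitory": (0, 80, 9),
            "astrocytes": (0, 60, 8),
            "microglia": (1, 70, 8),
        })
        v = call_sc_variant(block, self.cfg)
        assert v.status == "somatic"
        assert v.host_cell_types == ("excitatory",)
        assert v.alt_base == "G"

    def test_ubiquitous_het_signal_is_germline_like(self):
        block = site_block({t: (50, 100, 10) for t in
                            ("excitatory", "inhibitory", "astrocytes", "microglia")})
        assert call_sc_variant(block, self.cfg).status == "germline_like"

    def test_low_coverage_everywhere_is_untested(self):
        block = site_block({t: (0, 5, 2) for t in ("excitatory", "inhibitory")})
        assert call_sc_variant(block, self.cfg).status == "untested"

    def test_signal_in_too_many_types_is_artifact(self):
        block = site_block({
            "excitatory": (15, 100, 10),
            "inhibitory": (15, 100, 10),
            "astrocytes": (15, 100, 10),
            "microglia": (0, 100, 10),
        })
        v = call_sc_variant(block, ScCallerConfig(germline_like_af=0.5))
        assert v.status == "artifact"

    def test_clean_background_is_artifact_free_no_call(self):
        block = site_block({t: (0, 100, 10) for t in ("excitatory", "inhibitory")})
        assert call_sc_variant(block, self.cfg).status == "artifact"


class TestPerCellBurden:
    def test_carrier_counting(self):
        pl = pd.DataFrame([
            cell_rows("e1", "excitatory", p, {"A": 3, "G": 2}) for p in (1, 2, 3)
        ] + [cell_rows("e2", "excitatory", p, {"A": 5}) for p in (1, 2, 3)])
        ann = annotations([("e1", "excitatory"), ("e2", "excitatory")])
        variants = [
            mb.ScVariant(chrom="c1", pos=p, ref_base="A", alt_base="G",
                         status="somatic") for p in (1, 2, 3)
        ]
        burden = per_cell_burden(variants, pl, ann).set_index("cell_barcode")
        assert burden.loc["e1", "n_variants"] == 3
        assert burden.loc["e2", "n_variants"] == 0

    def test_noiseless_simulation_matches_truth_carriers(self, panel):
        cfg = ScSimConfig(seed=5, n_sites=60, error_rate=0.0)
        types = [CellTypeSpec("excitatory_neurons", n_cells=30, coverage_rate=1.0,
                              mean_depth=8.0, cluster_id=5),
                 CellTypeSpec("astrocytes", n_cells=30, coverage_rate=1.0,
                              mean_depth=8.0, cluster_id=10)]
        clones = [CloneSpec("excitatory_neurons", n_variants=3, carrier_fraction=0.3,
                            vaf_in_carrier=1.0)]
        pl, ann, truth = simulate_sc_cohort(panel, types, clones, cfg)
        variants = [
            mb.ScVariant(chrom=t.chrom, pos=t.pos, ref_base=t.ref_base,
                         alt_base=t.alt_base, status="somatic")
            for t in truth
        ]
        burden = per_cell_burden(variants, pl, ann)
        # with full coverage and VAF 1 in carriers, carrier counts match truth
        for t in truth:
            rows = pl[(pl.pos == t.pos) & (pl[t.alt_base] > 0)]
            assert set(rows.cell_barcode) == set(t.carrier_barcodes)
        assert burden.n_variants.sum() == sum(len(t.carrier_barcodes) for t in truth)


class TestCompare:
    def make_burden(self, rng, means, n_cells=120):
        rows = []
        for t, mu in means.items():
            for i in range(n_cells):
                rows.append({"cell_barcode": f"{t}_{i}", "cell_type": t,
                             "cluster_id": 0, "condition": "sALS",
                             "n_covered_sites": int(rng.integers(80, 120)),
                             "n_variants": rng.poisson(mu)})
        return pd.DataFrame(rows)

    def test_planted_excess_is_flagged(self):
        rng = np.random.default_rng(31)
        burden = self.make_burden(rng, {"exc": 3.0, "inh": 1.0, "ast": 1.0})
        out = compare_celltype_burden(burden)
        exc = out[(out.cell_type_a == "exc") | (out.cell_type_b == "exc")]
        assert (exc.q < 0.05).all()

    def test_null_burden_rarely_flagged(self):
        rng = np.random.default_rng(37)
        hits = 0
        reps = 20
        for _ in range(reps):
            burden = self.make_burden(rng, {"a": 1.0, "b": 1.0}, n_cells=80)
            out = compare_celltype_burden(burden)
            hits += int((out.p < 0.05).any())
        assert hits / reps < 0.25

    def test_single_type_errors_and_small_types_excluded(self):
        rng = np.random.default_rng(41)
        burden = self.make_burden(rng, {"a": 1.0})
        with pytest.raises(ValueError, match="at least 2"):
            compare_celltype_burden(burden)
        mixed = pd.concat(
            [self.make_burden(rng, {"a": 1.0, "b": 1.0}),
             self.make_burden(rng, {"tiny": 1.0}, n_cells=3)],
            ignore_index=True,
        )
        out = compare_celltype_burden(mixed)
        assert "tiny" not in set(out.cell_type_a) | set(out.cell_type_b)

    def test_cells_per_type_covariate_rejected_as_collinear(self):
        rng = np.random.default_rng(43)
        burden = self.make_burden(rng, {"a": 1.0, "b": 1.0})
        with pytest.raises(ValueError, match="collinear"):
            compare_celltype_burden(burden, size_adjustment="cells_per_type")


class TestClusterBurden:
    def test_means_and_composition(self):
        burden = pd.DataFrame({
            "cell_barcode": list("abcd"),
            "cell_type": ["t"] * 4,
            "cluster_id": [1, 1, 2, 2],
            "condition": ["sALS", "control", "sALS", "sALS"],
            "n_covered_sites": [10] * 4,
            "n_variants": [1, 1, 5, 7],
        })
        out = cluster_burden(burden).set_index("cluster_id")
        assert out.loc[1, "mean_burden"] == pytest.approx(1.0)
        assert out.loc[2, "mean_burden"] == pytest.approx(6.0)
        frac_cols = [c for c in out.columns if c.startswith("frac_")]
        np.testing.assert_allclose(out[frac_cols].sum(axis=1), 1.0)
        # the planted high-burden cluster ranks first
        assert cluster_burden(burden).iloc[0].cluster_id == 2

    def test_high_burden_subpopulation_ranks_first(self, panel):
        pl, ann, _ = simulate_sc_cohort(panel, cfg=ScSimConfig(seed=9))
        ctp = aggregate_by_celltype(pl, ann)
        variants = call_sc_variants(ctp)
        burden = per_cell_burden(variants, pl, ann)
        out = cluster_burden(burden)
        # cluster 5 is the excitatory (high clone load) cluster
        assert out.iloc[0].cluster_id == 5
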