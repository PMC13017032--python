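"""Burden tables, the enrichment model surface, t-test, FDR, gene ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mosaicburden as mb
from mosaicburden.burden import BurdenGLM, build_burden, fdr_adjust, gene_burden_ratio


def meta_frame(groups, origins=None):
    n = len(groups)
    origins = origins or ["Umea" if i % 3 == 0 else "NBB" for i in range(n)]
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group": groups,
            "sex": ["M" if i % 2 else "F" for i in range(n)],
            "age": 60.0 + np.arange(n),
            "origin": origins,
            "total_coverage": 2000.0 + 10 * np.arange(n),
        }
    )


def calls_frame(rows):
    cols = ["sample_id", "vaf", "classification", "gene_symbol"]
    df = pd.DataFrame(rows, columns=cols)
    df["chrom"] = "c1"
    df["pos"] = np.arange(len(df))
    return df


class TestBuildBurden:
    def test_af_binning_matches_brute_force(self):
        vafs = [0.02, 0.02, 0.10, 0.20, 0.34]
        calls = calls_frame([("s0", v, "somatic", "FUS") for v in vafs])
        table = build_burden(calls, meta_frame(["sALS", "control"]),
                            af_bin_edges=(0.015, 0.05, 0.15, 0.35))
        row = table.set_index("sample_id").loc["s0"]
        assert row["n_somatic"] == 5
        assert [row["bin_(0.015,0.05]"], row["bin_(0.05,0.15]"], row["bin_(0.15,0.35]"]] == [2, 1, 2]
        # brute force oracle
        edges = [0.015, 0.05, 0.15, 0.35]
        brute = [sum(lo < v <= hi for v in vafs) for lo, hi in zip(edges, edges[1:])]
        assert brute == [2, 1, 2]

    def test_sample_without_calls_keeps_zero_row(self):
        calls = calls_frame([("s0", 0.1, "somatic", "FUS")])
        table = build_burden(calls, meta_frame(["sALS", "control"]))
        assert table.set_index("sample_id").loc["s1", "n_somatic"] == 0

    def test_per_gene_counts_conserve_total(self):
        rng = np.random.default_rng(2)
        genes = ["FUS", "TBK1", "NEK1"]
        rows = [
            (f"s{rng.integers(0, 3)}", float(rng.uniform(0.02, 0.34)), "somatic",
             genes[rng.integers(0, 3)])
            for _ in range(60)
        ]
        table = build_burden(calls_frame(rows), meta_frame(["sALS", "sALS", "control"]),
                            genes=genes)
        gene_cols = [c for c in table.columns if c.startswith("gene_")]
        assert (table[gene_cols].sum(axis=1) == table.n_somatic).all()

    def test_non_somatic_calls_ignored(self):
        calls = calls_frame([("s0", 0.5, "germline", "FUS"),
                             ("s0", 0.01, "filtered", "FUS")])
        table = build_burden(calls, meta_frame(["sALS", "control"]))
        assert table.n_somatic.sum() == 0

    def test_bad_bin_edges_rejected(self):
        calls = calls_frame([("s0", 0.1, "somatic", "FUS")])
        with pytest.raises(ValueError, match="increasing"):
            build_burden(calls, meta_frame(["sALS", "control"]),
                         af_bin_edges=(0.05, 0.05))


class TestTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        meta = meta_frame(["sALS"] * 3 + ["control"] * 3)
        table = meta.assign(n_somatic=[5, 6, 7, 5, 6, 7])
        res = mb.summary_t_test(table)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computed_welch(self):
        """{1,2,3} vs {4,5,6}: t = -3/sqrt(2/3), df = 4."""
        meta = meta_frame(["sALS"] * 3 + ["control"] * 3)
        table = meta.assign(n_somatic=[1, 2, 3, 4, 5, 6])
        res = mb.summary_t_test(table)
        t_hand = (2.0 - 5.0) / np.sqrt(1.0 / 3 + 1.0 / 3)
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.p == pytest.approx(p_hand, abs=1e-12)
        assert (res.mean_a, res.mean_b) == (2.0, 5.0)
        assert res.sd_a == pytest.approx(1.0)

    def test_group_with_one_sample_errors(self):
        meta = meta_frame(["sALS", "control", "control"])
        table = meta.assign(n_somatic=[1, 2, 3])
        with pytest.raises(ValueError, match="at least 2"):
            mb.summary_t_test(table)


class TestFdr:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_inputs(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
        assert fdr_adjust([]).size == 0

    def test_matches_brute_force_step_up(self):
        """q_i = min over j: p_(j) >= p_i of (m * p_(j) / j), capped at 1."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                (m * p[order] / np.arange(1, m + 1))[::-1]
            )[::-1]
            brute = np.empty(m)
            brute[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(fdr_adjust(p), brute, atol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestBurdenGLMSurface:
    def test_model_results_roundtrip(self):
        rng = np.random.default_rng(23)
        meta = meta_frame(["sALS"] * 9 + ["control"] * 6)
        mu = np.where(meta.group == "sALS", 80.0, 40.0)
        table = meta.assign(n_somatic=rng.poisson(mu))
        fit = BurdenGLM.from_dataframe(table).fit()
        assert fit.converged
        assert fit.params["group[sALS]"] > 0
        d = fit.to_dict()
        assert set(d["coefficients"]) == set(fit.params.index)
        assert "group[sALS]" in fit.summary()

    def test_missing_covariates_rejected(self):
        meta = meta_frame(["sALS"] * 3 + ["control"] * 3)
        table = meta.assign(n_somatic=1)
        table.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            BurdenGLM.from_dataframe(table)

    def test_tiny_group_rejected(self):
        meta = meta_frame(["sALS"] + ["control"] * 4)
        table = meta.assign(n_somatic=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            BurdenGLM.from_dataframe(table)


class TestGeneRatios:
    def test_equal_means_give_ratio_one(self):
        meta = meta_frame(["sALS"] * 4 + ["control"] * 4)
        table = meta.assign(n_somatic=4, gene_FUS=[2, 2, 2, 2, 2, 2, 2, 2],
                            gene_TBK1=0)
        out = gene_burden_ratio(table).set_index("gene_symbol")
        assert out.loc["FUS", "ratio"] == pytest.approx(1.0)
        # all-zero gene: pseudo-count keeps the ratio defined at 1
        assert out.loc["TBK1", "ratio"] == pytest.approx(1.0)

    def test_detects_planted_twofold_gene(self):
        rng = np.random.default_rng(29)
        meta = meta_frame(["sALS"] * 12 + ["control"] * 12)
        table = meta.assign(
            gene_FUS=rng.poisson(np.where(meta.group == "sALS", 30, 15)),
            gene_TBK1=rng.poisson(15, size=24),
        )
        table["n_somatic"] = table.gene_FUS + table.gene_TBK1
        out = gene_burden_ratio(table).set_index("gene_symbol")
        assert out.loc["FUS", "ratio"] == pytest.approx(2.0, rel=0.25)
        assert out.loc["TBK1", "ratio"] == pytest.approx(1.0, abs=0.25)
        assert out.loc["FUS", "q"] < 0.05
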