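"""Error model estimation, the two callers, integration and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mosaicburden as mb
from mosaicburden.calling import (
    CallerConfig,
    ErrorModel,
    betabinom_pvalues,
    binomial_pvalues,
    call_pileup,
    classify_call,
    estimate_error_model,
    integrate_calls,
)


def pileup_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T", "n_masked"])


def null_pileup(rng, n_sites, depth, e):
    counts = rng.multinomial(depth, [1 - e, e / 3, e / 3, e / 3], size=n_sites)
    return pileup_frame(
        [("c1", i, "A", *counts[i], 0) for i in range(n_sites)]
    )


class TestErrorModel:
    def test_noiseless_pileup_clamps_to_floor(self):
        pu = pileup_frame([("c1", i, "A", 1000, 0, 0, 0, 0) for i in range(200)])
        model = estimate_error_model(pu)
        assert model.e == pytest.approx(1e-6)
        assert model.rho == 0.0

    def test_recovers_simulated_error_rate_within_ten_percent(self):
        rng = np.random.default_rng(12)
        pu = null_pileup(rng, 10_000, 2000, 0.001)
        model = estimate_error_model(pu)
        assert abs(model.e - 0.001) / 0.001 < 0.10

    def test_masked_variant_site_does_not_contaminate(self):
        rng = np.random.default_rng(13)
        pu = null_pileup(rng, 500, 2000, 0.001)
        spiked = pu.copy()
        spiked.loc[0, "G"] = 100  # a 5% variant site
        mask = np.zeros(len(pu), bool)
        mask[0] = True
        clean = estimate_error_model(pu.iloc[1:])
        masked = estimate_error_model(spiked, mask)
        assert masked.e == pytest.approx(clean.e, rel=1e-9)

    def test_all_excluded_errors(self):
        pu = pileup_frame([("c1", 0, "A", 10, 0, 0, 0, 0)])
        with pytest.raises(ValueError, match="excluded"):
            estimate_error_model(pu, np.array([True]))


class TestCallerOracles:
    def test_binomial_tail_matches_closed_form(self):
        """P(X>=k) for Binomial(n, e) vs explicit pmf summation, to 1e-10."""
        e = 0.001
        for n, k in [(10, 1), (2000, 3), (2000, 100), (500, 0)]:
            p = binomial_pvalues(np.array([k]), np.array([n]), e)[0]
            closed = sum(stats.binom.pmf(j, n, e) for j in range(k, min(n, k + 200) + 1))
            if k == 0:
                closed = 1.0
            assert p == pytest.approx(closed, abs=1e-10)
        # the n=10, k=1 case has an elementary form 1 - (1-e)^10
        assert binomial_pvalues(np.array([1]), np.array([10]), e)[0] == pytest.approx(
            1 - (1 - e) ** 10, abs=1e-12
        )

    def test_betabinom_reduces_to_binomial_at_zero_rho(self):
        alt = np.array([0, 1, 5, 50, 100])
        depth = np.full(5, 2000)
        bb = betabinom_pvalues(alt, depth, 0.001, 0.0)
        bn = binomial_pvalues(alt, depth, 0.001)
        np.testing.assert_allclose(bb, bn, atol=1e-10)

    def test_overdispersion_fattens_the_tail(self):
        p0 = betabinom_pvalues(np.array([10]), np.array([2000]), 0.001, 0.0)[0]
        p1 = betabinom_pvalues(np.array([10]), np.array([2000]), 0.001, 0.05)[0]
        assert p1 > p0


class TestSingleSiteCalls:
    model = ErrorModel(e=0.001, rho=0.0)
    cfg = CallerConfig(min_depth=10, alpha_binomial=1e-6, alpha_betabinom=1e-6)

    def site(self, depth, alt, ref="A", alt_base="G"):
        row = {"chrom": "c1", "pos": 5, "ref": ref, "A": 0, "C": 0, "G": 0, "T": 0}
        row[ref] = depth - alt
        row[alt_base] = alt
        return row

    def test_no_alternate_no_call(self):
        assert mb.call_binomial(self.site(2000, 0), self.model, self.cfg) is None

    def test_single_alt_at_low_depth_not_significant(self):
        # P(X>=1 | n=10, e=0.001) = 1 - 0.999^10 ~ 0.00995 > 1e-6
        assert mb.call_binomial(self.site(10, 1), self.model, self.cfg) is None

    def test_strong_signal_called_by_both(self):
        for caller in (mb.call_binomial, mb.call_betabinom):
            call = caller(self.site(2000, 100), self.model, self.cfg)
            assert call is not None
            assert call.alt_count == 100 and call.vaf == pytest.approx(0.05)

    def test_below_min_depth_untested(self):
        assert mb.call_binomial(self.site(5, 5), self.model, self.cfg) is None


class TestIntegration:
    cfg_int = CallerConfig(integration_rule="intersection")
    cfg_uni = CallerConfig(integration_rule="union")

    def call(self, pos, caller):
        return mb.VariantCall(chrom="c1", pos=pos, ref_base="A", alt_base="G",
                              alt_count=50, depth=1000, callers=(caller,),
                              p_values={caller: 1e-9})

    def test_intersection_vs_union(self):
        cands = {
            "binomial": [self.call(1, "binomial"), self.call(2, "binomial")],
            "betabinom": [self.call(1, "betabinom")],
        }
        both = integrate_calls(cands, self.cfg_int)
        assert [c.pos for c in both] == [1]
        assert both[0].callers == ("betabinom", "binomial")
        assert set(both[0].p_values) == {"binomial", "betabinom"}
        any_ = integrate_calls(cands, self.cfg_uni)
        assert [c.pos for c in any_] == [1, 2]

    def test_at_least_k_brackets_union_and_intersection(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cands = {
                c: [self.call(int(p), c) for p in np.flatnonzero(rng.random(8) < 0.5)]
                for c in ("binomial", "betabinom")
            }
            k1 = integrate_calls(cands, CallerConfig(integration_rule="at_least_k", at_least_k=1))
            k2 = integrate_calls(cands, CallerConfig(integration_rule="at_least_k", at_least_k=2))
            uni = integrate_calls(cands, self.cfg_uni)
            inter = integrate_calls(cands, self.cfg_int)
            assert {c.pos for c in k1} == {c.pos for c in uni}
            assert {c.pos for c in k2} == {c.pos for c in inter}
            assert {c.pos for c in inter} <= {c.pos for c in uni}

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown integration rule"):
            CallerConfig(integration_rule="majority")


class TestClassification:
    cfg = CallerConfig()

    def vaf_call(self, vaf, depth=1000):
        return mb.VariantCall(chrom="c1", pos=1, ref_base="A", alt_base="G",
                              alt_count=int(round(vaf * depth)), depth=depth,
                              callers=("binomial",), p_values={})

    @pytest.mark.parametrize(
        "vaf, expected",
        [
            (0.07, "somatic"),    # the scale of a validated mosaic hotspot variant
            (0.50, "germline"),
            (0.01, "filtered"),
            (0.35, "germline"),   # open interval: boundary is outside the window
            (0.015, "filtered"),
        ],
    )
    def test_af_window(self, vaf, expected):
        assert classify_call(self.vaf_call(vaf), self.cfg) == expected

    def test_vaf_is_exactly_alt_over_depth(self):
        call = self.vaf_call(0.123, depth=1000)
        assert call.vaf == call.alt_count / call.depth


class TestAnnotation:
    def test_region_and_gene_assignment(self, panel):
        feats = panel.gene_model.features
        exon = feats[feats.feature == "exon"].iloc[0]

        def call_at(pos):
            return mb.VariantCall(chrom=exon.chrom, pos=int(pos), ref_base="A",
                                  alt_base="G", alt_count=10, depth=100,
                                  callers=("binomial",), p_values={})

        c = mb.annotate_region(call_at(exon.start + 1), panel.gene_model)
        assert c.region == "exonic" and c.gene_symbol == exon.gene_symbol
        c = mb.annotate_region(call_at(0), panel.gene_model)
        assert c.region == "intergenic" and c.gene_symbol is None


class TestPileupCalling:
    def test_union_never_smaller_than_intersection(self, small_panel):
        cfg = mb.SimConfig(seed=21)
        meta = mb.SampleMeta(sample_id="s", group="sALS", sex="M", age=60,
                             origin="Umea", total_coverage=2000)
        pileup, _ = mb.simulate_sample(small_panel, meta, cfg)
        inter = call_pileup(pileup, CallerConfig(integration_rule="intersection"))
        union = call_pileup(pileup, CallerConfig(integration_rule="union"))
        assert len(union) >= len(inter)
        keys = lambda calls: {(c.chrom, c.pos, c.alt_base) for c in calls}
        assert keys(inter) <= keys(union)

    def test_end_to_end_precision_recall(self, small_panel):
        """Somatic-classified calls recover planted truth at >= 0.9 / 0.9."""
        cfg = mb.SimConfig(seed=31)
        meta = mb.SampleMeta(sample_id="s", group="sALS", sex="M", age=60,
                             origin="Umea", total_coverage=2000)
        pileup, truth = mb.simulate_sample(small_panel, meta, cfg)
        calls = call_pileup(pileup, gene_model=small_panel.gene_model, sample_id="s")
        som = {(c.chrom, c.pos, c.alt_base) for c in calls if c.classification == "somatic"}
        true_som = {
            (v.chrom, v.pos, v.alt_base) for v in truth
            if v.origin == "somatic" and 0.015 < v.true_vaf < 0.35
        }
        tp = len(som & true_som)
        assert tp / len(som) >= 0.9
        assert tp / len(true_som) >= 0.9
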