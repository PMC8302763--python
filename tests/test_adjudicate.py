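"""Scoring rubric, colocalization rule boundaries, testis specificity."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import postgwas as pg
from postgwas.adjudicate import (
    ColocPosterior,
    GeneEvidence,
    capc_score,
    capture_c_connections,
    eqtl_score,
    expression_score,
    expression_tertiles,
    location_score,
    region_score,
)


def _pp(pp3, pp4, gene="g", tissue="lung", is_testis=False):
    rest = 1.0 - pp3 - pp4
    return ColocPosterior(
        gene=gene, tissue=tissue, is_testis=is_testis,
        pp0=rest, pp1=0.0, pp2=0.0, pp3=pp3, pp4=pp4,
    )


class TestColocRule:
    def test_clear_pass(self):
        assert pg.coloc_significant(_pp(0.05, 0.90)) is True

    def test_ratio_failure(self):
        # sum 0.95 passes but 0.85/0.95 = 0.894... < 0.9
        assert pg.coloc_significant(_pp(0.10, 0.85)) is False

    def test_pp4_zero_fails(self):
        assert pg.coloc_significant(_pp(0.85, 0.0)) is False

    def test_sum_boundary_is_strict(self):
        # PP3 + PP4 == 0.8 exactly must fail
        assert pg.coloc_significant(_pp(0.05, 0.75)) is False

    def test_ratio_boundary_is_strict(self):
        # ratio exactly 0.9: PP4 = 0.81, PP3 = 0.09
        assert pg.coloc_significant(_pp(0.09, 0.81)) is False

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ValueError):
            ColocPosterior(gene="g", tissue="t", is_testis=False,
                           pp0=0.5, pp1=0.5, pp2=0.5, pp3=0.0, pp4=0.0)


class TestEqtlScore:
    def test_two_nontestis_plus_testis_is_two(self):
        pps = [
            _pp(0.05, 0.9, tissue="lung"),
            _pp(0.05, 0.9, tissue="liver"),
            _pp(0.05, 0.9, tissue="testis", is_testis=True),
        ]
        assert eqtl_score(pps) == 2.0

    def test_one_nontestis_half(self):
        assert eqtl_score([_pp(0.05, 0.9, tissue="lung")]) == 0.5

    def test_none_significant_zero(self):
        assert eqtl_score([_pp(0.5, 0.1, tissue="lung")]) == 0.0

    def test_testis_only_is_one(self):
        assert eqtl_score([_pp(0.05, 0.9, tissue="testis", is_testis=True)]) == 1.0

    def test_same_tissue_counted_once(self):
        pps = [_pp(0.05, 0.9, tissue="lung"), _pp(0.04, 0.92, tissue="lung")]
        assert eqtl_score(pps) == 0.5


class TestExpression:
    FIXTURE = (698.0, 2348.0)

    @pytest.mark.parametrize("value,score", [
        (500, 0.0), (698, 0.0), (699, 0.5), (2348, 0.5), (2349, 1.0), (9000, 1.0),
    ])
    def test_published_cutoffs(self, value, score):
        assert expression_score(value, self.FIXTURE) == score

    def test_tertiles_split_evenly(self):
        lo, hi = expression_tertiles(np.arange(1.0, 10.0))
        vals = np.arange(1.0, 10.0)
        scores = [expression_score(v, (lo, hi)) for v in vals]
        assert scores.count(0.0) == 3 and scores.count(0.5) == 3 and scores.count(1.0) == 3

    def test_constant_values_warn(self):
        with pytest.warns(UserWarning):
            lo, hi = expression_tertiles(np.full(10, 5.0))
        assert lo == hi

    def test_packaged_cutoffs_load(self):
        from postgwas.io import load_expression_cutoffs

        assert load_expression_cutoffs() == (698.0, 2348.0)


class TestComponentMaps:
    @pytest.mark.parametrize("n,score", [(0, 0.0), (1, 2.0), (2, 1.0), (5, 1.0)])
    def test_region(self, n, score):
        assert region_score(n) == score

    @pytest.mark.parametrize("cls,score", [
        ("exonic", 1.0), ("intronic", 1.0), ("within_10kb", 1.0), ("outside", 0.0),
    ])
    def test_location(self, cls, score):
        assert location_score(cls) == score

    @pytest.mark.parametrize("n,score", [(0, 0.0), (1, 0.5), (2, 1.0), (4, 1.0)])
    def test_capture_c(self, n, score):
        assert capc_score(n) == score


class TestAdjudicate:
    def _ev(self, n_genes, loc, pps=(), expr=None, conn=None):
        return GeneEvidence(
            gene="g", n_genes_in_region=n_genes, location_class=loc,
            posteriors=list(pps), fetal_expression=expr, connection_count=conn,
        )

    def test_full_evidence_highly(self):
        pps = [
            _pp(0.05, 0.9, tissue="lung"), _pp(0.05, 0.9, tissue="liver"),
            _pp(0.05, 0.9, tissue="testis", is_testis=True),
        ]
        score = pg.adjudicate(
            self._ev(1, "intronic", pps, expr=3000, conn=3),
            expression_cutoffs=(698, 2348),
        )
        assert (score.s_region, score.s_location, score.s_eqtl,
                score.s_expr, score.s_capc) == (2, 1, 2, 1, 1)
        assert score.total == 7.0 and score.category == "highly"

    def test_total_two_is_moderately(self):
        score = pg.adjudicate(self._ev(2, "intronic"), expression_cutoffs=(698, 2348))
        assert score.total == 2.0 and score.category == "moderately"

    def test_total_below_two_unlikely(self):
        score = pg.adjudicate(
            self._ev(0, "intronic", expr=1000, conn=0),
            expression_cutoffs=(698, 2348),
        )
        assert score.total == 1.5 and score.category == "unlikely"

    def test_missing_evidence_flagged(self):
        score = pg.adjudicate(self._ev(1, "intronic"))
        assert set(score.missing) == {"eqtl", "expression", "capture_c"}

    def test_posterior_order_invariance(self):
        pps = [
            _pp(0.05, 0.9, tissue="lung"),
            _pp(0.5, 0.1, tissue="liver"),
            _pp(0.05, 0.9, tissue="testis", is_testis=True),
        ]
        a = pg.adjudicate(self._ev(1, "intronic", pps))
        b = pg.adjudicate(self._ev(1, "intronic", pps[::-1]))
        assert a.total == b.total


class TestCaptureC:
    def _tables(self):
        proxies = pd.DataFrame({"chrom": ["1"], "pos": [5000]})
        contacts = pd.DataFrame({
            "cell_line": ["NT2-D1"], "chrom": ["1"],
            "start": [4900], "end": [5100], "promoter_gene": ["G1"],
        })
        promoters = pd.DataFrame({
            "gene": ["G1"], "chrom": ["1"], "start": [20_000], "end": [21_000],
        })
        return proxies, contacts, promoters

    def test_full_connection_counts_one_line(self):
        proxies, contacts, promoters = self._tables()
        peaks = pd.DataFrame({
            "cell_line": ["L1", "L1"], "chrom": ["1", "1"],
            "start": [4950, 20_500], "end": [5050, 20_600],
        })
        counts = capture_c_connections(proxies, peaks, contacts, promoters)
        assert counts["G1"] == 1

    def test_snp_outside_peaks_no_connection(self):
        proxies, contacts, promoters = self._tables()
        peaks = pd.DataFrame({
            "cell_line": ["L1"], "chrom": ["1"], "start": [20_500], "end": [20_600],
        })
        counts = capture_c_connections(proxies, peaks, contacts, promoters)
        assert counts["G1"] == 0

    def test_one_bp_edge_overlap_counts(self):
        proxies, contacts, promoters = self._tables()
        peaks = pd.DataFrame({
            "cell_line": ["L1", "L1"], "chrom": ["1", "1"],
            "start": [5000, 21_000], "end": [5000, 21_000],  # single-bp peaks at edges
        })
        counts = capture_c_connections(proxies, peaks, contacts, promoters)
        assert counts["G1"] == 1

    def test_missing_cell_line_warns_and_contributes_zero(self):
        proxies, contacts, promoters = self._tables()
        peaks = pd.DataFrame({
            "cell_line": ["L1", "L1"], "chrom": ["1", "1"],
            "start": [4950, 20_500], "end": [5050, 20_600],
        })
        with pytest.warns(UserWarning):
            counts = capture_c_connections(
                proxies, peaks, contacts, promoters, cell_lines=["L1", "L2"]
            )
        assert counts["G1"] == 1


class TestTestisSpecificity:
    def test_enriched(self):
        p = pd.Series({"testis": 10.0, "lung": 2.0, "liver": 1.0})
        assert pg.testis_specificity(p) == "enriched"

    def test_enhanced_by_mean_not_max(self):
        p = pd.Series({"testis": 10.0, "lung": 3.0, "liver": 0.0})
        # 10 < 5*3 but 10 >= 5*1.5
        assert pg.testis_specificity(p) == "enhanced"

    def test_minimum_tpm_gate(self):
        p = pd.Series({"testis": 0.5, "lung": 0.01, "liver": 0.01})
        assert pg.testis_specificity(p) == "neither"

    def test_partition_property(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            vals = rng.uniform(0, 20, size=5)
            p = pd.Series(vals, index=["testis", "a", "b", "c", "d"])
            assert pg.testis_specificity(p) in {"enriched", "enhanced", "neither"}

    def test_missing_testis_rejected(self):
        with pytest.raises(ValueError):
            pg.testis_specificity(pd.Series({"lung": 1.0, "liver": 2.0}))


class TestSetEnrichment:
    def test_strong_enrichment_matches_exact_hypergeometric(self):
        background = {f"g{i}" for i in range(1000)}
        trait = {f"g{i}" for i in range(100)}         # 10% trait rate
        selected = {f"g{i}" for i in range(10)}        # all have the trait
        p = pg.set_enrichment(selected, background, trait)
        # exact upper-tail sum: P(X >= 10) with M=1000, K=100, n=10
        oracle = sum(
            comb(100, k, exact=True) * comb(900, 10 - k, exact=True)
            for k in range(10, 11)
        ) / comb(1000, 10, exact=True)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-9

    def test_zero_overlap_gives_one(self):
        background = {f"g{i}" for i in range(100)}
        trait = {f"g{i}" for i in range(50, 60)}
        selected = {f"g{i}" for i in range(10)}
        assert pg.set_enrichment(selected, background, trait) == 1.0

    def test_selected_equals_background(self):
        bg = {f"g{i}" for i in range(30)}
        assert pg.set_enrichment(bg, bg, {"g0", "g1"}) == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            pg.set_enrichment({"x"}, set(), {"x"})
        with pytest.raises(ValueError):
            pg.set_enrichment({"x"}, {"y"}, set())
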