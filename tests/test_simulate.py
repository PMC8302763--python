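"""Generator properties: LD structure, prevalence calibration, truth recovery."""

import numpy as np
import pytest
from scipy.special import expit

import postgwas as pg
from postgwas.simulate import genotypes_from_panel


def _adjacent_r(panel, skip_block_edges=True):
    H = panel.haplotypes.astype(float)
    rs = []
    for j in range(panel.n_variants - 1):
        if skip_block_edges and (j + 1) % 10 == 0:
            continue
        sd0, sd1 = H[:, j].std(), H[:, j + 1].std()
        if sd0 == 0 or sd1 == 0:
            continue
        rs.append(np.corrcoef(H[:, j], H[:, j + 1])[0, 1])
    return np.array(rs)


class TestPanel:
    def test_rho_zero_gives_independence(self):
        spec = pg.PanelSpec(n_haplotypes=10_000, n_variants=50, block_size=10,
                            within_block_rho=0.0, seed=1)
        panel = pg.simulate_panel(spec)
        assert np.mean(np.abs(_adjacent_r(panel, skip_block_edges=False))) < 0.05

    def test_determinism(self):
        spec = pg.PanelSpec(n_haplotypes=500, n_variants=30, seed=7)
        p1, p2 = pg.simulate_panel(spec), pg.simulate_panel(spec)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert np.array_equal(p1.freqs, p2.freqs)

    def test_ld_increases_with_rho(self):
        kw = dict(n_haplotypes=10_000, n_variants=50, block_size=10, seed=3)
        r2_hi = _adjacent_r(pg.simulate_panel(pg.PanelSpec(within_block_rho=0.9, **kw))) ** 2
        r2_mid = _adjacent_r(pg.simulate_panel(pg.PanelSpec(within_block_rho=0.5, **kw))) ** 2
        assert np.median(r2_hi) > np.median(r2_mid)

    def test_block_boundaries_uncorrelated(self):
        spec = pg.PanelSpec(n_haplotypes=20_000, n_variants=40, block_size=10,
                            within_block_rho=0.9, seed=5)
        H = pg.simulate_panel(spec).haplotypes.astype(float)
        edge_r = [np.corrcoef(H[:, j - 1], H[:, j])[0, 1] for j in (10, 20, 30)]
        assert np.max(np.abs(edge_r)) < 0.05

    @pytest.mark.parametrize("bad", [
        dict(n_variants=0),
        dict(within_block_rho=1.0),
        dict(allele_freq_range=(0.0, 0.5)),
    ])
    def test_degenerate_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            pg.PanelSpec(**bad)


class TestIntercept:
    def test_null_model_closed_form(self, small_panel):
        m = pg.DiseaseModel(causal_effects={}, k=0.005)
        assert pg.solve_intercept(m, small_panel) == pytest.approx(
            np.log(0.005 / 0.995), abs=1e-10
        )
        m50 = pg.DiseaseModel(causal_effects={}, k=0.5)
        assert pg.solve_intercept(m50, small_panel) == pytest.approx(0.0, abs=1e-10)

    def test_calibrates_monte_carlo_prevalence(self):
        spec = pg.PanelSpec(n_haplotypes=20_000, n_variants=1, block_size=1,
                            within_block_rho=0.0, allele_freq_range=(0.4, 0.4), seed=9)
        panel = pg.simulate_panel(spec)
        model = pg.DiseaseModel(causal_effects={"var00000": float(np.log(1.3))}, k=0.005)
        b0 = pg.solve_intercept(model, panel)
        rng = np.random.default_rng(99)
        G = genotypes_from_panel(panel, 400_000, rng).astype(float)
        frac = np.mean(rng.random(len(G)) < expit(b0 + G[:, 0] * np.log(1.3)))
        assert frac == pytest.approx(0.005, abs=0.001)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            pg.DiseaseModel(causal_effects={}, k=1.5)


class TestCohort:
    def test_exact_counts_and_disjoint_studies(self, small_panel):
        model = pg.DiseaseModel(causal_effects={}, k=0.01)
        cohorts, truth = pg.simulate_cohort(small_panel, model, 50, 70, 3, seed=17)
        assert [c.study_id for c in cohorts] == ["S1", "S2", "S3"]
        ids = set()
        for c in cohorts:
            assert int(c.phenotype.sum()) == 50
            assert len(c.phenotype) == 120
            assert set(c.covariates["center"]) == {c.study_id}
            sample_ids = set(c.covariates.index)
            assert not (ids & sample_ids)
            ids |= sample_ids

    def test_determinism(self, small_panel):
        model = pg.DiseaseModel(causal_effects={}, k=0.01)
        a, _ = pg.simulate_cohort(small_panel, model, 30, 30, 2, seed=5)
        b, _ = pg.simulate_cohort(small_panel, model, 30, 30, 2, seed=5)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.dosage, cb.dosage, equal_nan=True)

    def test_control_frequency_conserved(self, small_panel):
        """Pooled control allele frequency approaches the panel frequency."""
        model = pg.DiseaseModel(causal_effects={}, k=0.005)
        cohorts, _ = pg.simulate_cohort(small_panel, model, 100, 2000, 1, seed=23)
        ctrl = cohorts[0].dosage[cohorts[0].phenotype == 0]
        emp = np.nanmean(ctrl, axis=0) / 2.0
        # referent is the panel's realised haplotype frequency: controls are
        # drawn from the panel itself, so panel sampling noise is shared
        f = small_panel.haplotypes.mean(axis=0)
        tol = 3.0 * np.sqrt(f * (1 - f) / (2 * len(ctrl)))
        assert np.mean(np.abs(emp - f) < tol + 1e-12) > 0.97

    def test_unreachable_counts_fail_loudly(self, small_panel):
        model = pg.DiseaseModel(causal_effects={}, k=0.005)
        with pytest.raises((ValueError, RuntimeError)):
            pg.simulate_cohort(small_panel, model, 10_000, 10, 1, seed=3,
                               max_draws=10_000)

    def test_x_linked_dosages_are_hemizygous(self, small_panel):
        """X mode codes male dosages {0, 2} and recovers the per-allele effect
        on the same scale as autosomes."""
        causal = small_panel.variants["id"][5]
        model = pg.DiseaseModel(causal_effects={causal: float(np.log(1.5))}, k=0.005)
        cohorts, truth = pg.simulate_cohort(
            small_panel, model, 1500, 1500, 1, seed=91, x_linked=True
        )
        c = cohorts[0]
        assert set(np.unique(c.dosage)) <= {0.0, 2.0}
        s = pg.logistic_assoc(c, causal)
        assert abs(s.beta - np.log(1.5)) < 3.5 * s.se

    def test_effect_recovery_single_study(self, causal_cohorts):
        cohorts, truth, causal = causal_cohorts
        s = pg.logistic_assoc(cohorts[0], causal)
        assert abs(s.beta - np.log(1.5)) < 3 * s.se


class TestEvidence:
    def test_all_null_scores_zero_except_region(self):
        genes = [f"g{i}" for i in range(10)]
        tables = pg.simulate_evidence(genes, "all-null", seed=1)
        from postgwas.pipeline import score_evidence_tables

        scored = score_evidence_tables(tables)
        assert (scored["s_eqtl"] == 0).all()
        assert (scored["s_expr"] == 0).all()
        assert (scored["s_capc"] == 0).all()
        assert (scored["s_location"] == 0).all()
        assert (scored["s_region"] > 0).all()

    def test_pp_vectors_normalised(self):
        tables = pg.simulate_evidence(["a", "b"], "all-null", seed=2)
        s = tables.coloc[["pp0", "pp1", "pp2", "pp3", "pp4"]].sum(axis=1)
        assert np.allclose(s, 1.0, atol=1e-9)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            pg.simulate_evidence(["a"], "no-such-scenario", seed=0)
        with pytest.raises(ValueError):
            pg.simulate_evidence(["a"], {"assignments": {"a": "impossible"}}, seed=0)

    def test_categories_recovered_by_adjudication(self):
        """End-to-end: generated evidence scores back to its assigned category."""
        from postgwas.pipeline import score_evidence_tables

        genes = [f"G{i:03d}" for i in range(200)]
        rng = np.random.default_rng(5)
        cats = rng.choice(["highly", "moderately", "unlikely"], 200)
        tables = pg.simulate_evidence(
            genes, {"assignments": dict(zip(genes, cats))}, seed=5
        )
        scored = score_evidence_tables(tables)
        merged = scored.merge(tables.truth, on="gene", suffixes=("", "_truth"))
        agree = (merged["category"] == merged["category_truth"]).mean()
        assert agree >= 0.95
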