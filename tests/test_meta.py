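"""Fixed-effects pooling identities, heterogeneity, allele alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import postgwas as pg
from postgwas.assoc import StudySummary
from postgwas.meta import align_alleles, meta_fixed, meta_scan


def _study(beta, se, snp="rs1", study="S1", freq=0.3, n=1000):
    return StudySummary(
        snp=snp, a1="A", a2="G", freq1=freq, beta=beta, se=se,
        p=1.0, n=n, study=study,
    )


class TestMetaFixed:
    def test_single_study_identity(self):
        m = meta_fixed([_study(0.13, 0.041)])
        assert m.beta == pytest.approx(0.13, abs=1e-15)
        assert m.se == pytest.approx(0.041, abs=1e-15)
        assert m.k == 1 and m.q == 0.0 and m.i2 == 0.0

    def test_hand_computed_two_studies(self):
        """w = (400, 100): beta = (400*0.1+100*0.2)/500 = 0.12,
        SE = 1/sqrt(500), Q = 400*(0.02)^2 + 100*(0.08)^2 = 0.8, I2 = 0."""
        m = meta_fixed([_study(0.1, 0.05), _study(0.2, 0.1, study="S2")])
        assert m.beta == pytest.approx(0.12, abs=1e-12)
        assert m.se == pytest.approx(1 / np.sqrt(500), abs=1e-12)
        assert m.q == pytest.approx(0.8, abs=1e-12)
        assert m.i2 == 0.0

    def test_equal_studies_symmetry(self):
        k, b, s = 5, 0.07, 0.03
        m = meta_fixed([_study(b, s, study=f"S{i}") for i in range(k)])
        assert m.beta == pytest.approx(b, abs=1e-14)
        assert m.se == pytest.approx(s / np.sqrt(k), abs=1e-14)
        assert m.direction == "+" * k

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([])

    def test_heterogeneity_flag_blocks_significance(self):
        """Strongly discordant precise studies: Q-test P < 0.001 removes the
        variant from the significant set even if pooled P is tiny."""
        m = meta_fixed([_study(0.5, 0.01), _study(-0.5, 0.01, study="S2"),
                        _study(0.5, 0.01, study="S3")])
        assert m.heterogeneity_fail
        assert not m.significant
        assert m.i2 > 50

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-0.5, 0.5), st.floats(0.01, 0.5)
            ),
            min_size=1, max_size=8,
        )
    )
    def test_ivw_identities(self, pairs):
        studies = [_study(b, s, study=f"S{i}") for i, (b, s) in enumerate(pairs)]
        m = meta_fixed(studies)
        betas = [s.beta for s in studies]
        ses = [s.se for s in studies]
        assert m.q >= -1e-12
        assert 0.0 <= m.i2 <= 100.0
        assert min(betas) - 1e-10 <= m.beta <= max(betas) + 1e-10
        assert m.se <= min(ses) + 1e-12
        # order invariance
        m2 = meta_fixed(studies[::-1])
        assert m2.beta == pytest.approx(m.beta, abs=1e-12)
        assert m2.q == pytest.approx(m.q, abs=1e-9)


def _table(rows, study="S1"):
    return pd.DataFrame(
        rows,
        columns=["SNP", "CHR", "POS", "A1", "A2", "FREQ1", "BETA", "SE", "P", "N", "STUDY"],
    )


class TestAlignAlleles:
    def test_swap_flips_beta_and_freq(self):
        s1 = _table([["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S1"]])
        s2 = _table([["rs1", "1", 100, "G", "A", 0.7, -0.1, 0.05, 0.04, 1000, "S2"]])
        aligned, drops = align_alleles([s1, s2])
        assert len(drops) == 0
        assert aligned[1].iloc[0]["BETA"] == pytest.approx(0.1)
        assert aligned[1].iloc[0]["FREQ1"] == pytest.approx(0.3)
        assert aligned[1].iloc[0]["A1"] == "A"

    def test_strand_flip_resolved(self):
        s1 = _table([["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S1"]])
        s2 = _table([["rs1", "1", 100, "T", "C", 0.3, 0.1, 0.05, 0.04, 1000, "S2"]])
        aligned, drops = align_alleles([s1, s2])
        assert len(drops) == 0
        assert aligned[1].iloc[0]["BETA"] == pytest.approx(0.1)

    def test_variant_missing_in_one_study_dropped(self):
        s1 = _table([
            ["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S1"],
            ["rs2", "1", 200, "A", "G", 0.4, 0.2, 0.05, 0.01, 1000, "S1"],
        ])
        s2 = _table([["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S2"]])
        s3 = _table([
            ["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S3"],
            ["rs2", "1", 200, "A", "G", 0.4, 0.2, 0.05, 0.01, 1000, "S3"],
        ])
        aligned, drops = align_alleles([s1, s2, s3])
        assert drops.set_index("SNP").loc["rs2", "reason"] == "not_in_all_studies"
        assert all(list(a["SNP"]) == ["rs1"] for a in aligned)

    def test_ambiguous_dropped_strict_kept_permissive(self):
        s1 = _table([["rs1", "1", 100, "A", "T", 0.2, 0.1, 0.05, 0.04, 1000, "S1"]])
        s2 = _table([["rs1", "1", 100, "A", "T", 0.22, 0.1, 0.05, 0.04, 1000, "S2"]])
        _, drops = align_alleles([s1, s2], strict_ambiguous=True)
        assert drops.iloc[0]["reason"] == "strand_ambiguous"
        aligned, drops2 = align_alleles([s1, s2], strict_ambiguous=False)
        assert len(drops2) == 0
        assert aligned[1].iloc[0]["BETA"] == pytest.approx(0.1)

    def test_irreconcilable_dropped(self):
        s1 = _table([["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S1"]])
        s2 = _table([["rs1", "1", 100, "A", "C", 0.3, 0.1, 0.05, 0.04, 1000, "S2"]])
        _, drops = align_alleles([s1, s2])
        assert drops.iloc[0]["reason"] == "irreconcilable_alleles"

    def test_multiallelic_dropped(self):
        s1 = _table([
            ["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S1"],
            ["rs1", "1", 100, "A", "C", 0.1, 0.2, 0.05, 0.01, 1000, "S1"],
        ])
        s2 = _table([["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.04, 1000, "S2"]])
        _, drops = align_alleles([s1, s2])
        assert drops.iloc[0]["reason"] == "multiallelic"


class TestMetaScan:
    def test_matches_meta_fixed_per_variant(self):
        rng = np.random.default_rng(1)
        rows1, rows2 = [], []
        for i in range(20):
            b = rng.normal(0, 0.1)
            rows1.append([f"rs{i}", "1", i, "A", "G", 0.3, b, 0.05, 0.5, 1000, "S1"])
            rows2.append([f"rs{i}", "1", i, "A", "G", 0.3, b + rng.normal(0, 0.02),
                          0.07, 0.5, 1200, "S2"])
        t1, t2 = _table(rows1), _table(rows2, "S2")
        scan = meta_scan([t1, t2])
        for i in range(20):
            m = meta_fixed([
                _study(t1.iloc[i]["BETA"], t1.iloc[i]["SE"], snp=f"rs{i}"),
                _study(t2.iloc[i]["BETA"], t2.iloc[i]["SE"], snp=f"rs{i}", study="S2"),
            ])
            assert scan.iloc[i]["BETA"] == pytest.approx(m.beta, abs=1e-12)
            assert scan.iloc[i]["SE"] == pytest.approx(m.se, abs=1e-12)
            assert scan.iloc[i]["Q"] == pytest.approx(m.q, abs=1e-9)
            assert scan.iloc[i]["I2"] == pytest.approx(m.i2, abs=1e-9)
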