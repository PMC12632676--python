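"""Instrument selection, clumping and harmonization rules."""

import numpy as np
import pandas as pd
import pytest

from renalmr.instruments import LDReference, clump, harmonize, select_cis_pqtls
from renalmr.io import SummaryStats


def _stats(rows, trait="protein"):
    rec = pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pvalue",
    ])
    return SummaryStats(trait_name=trait, trait_type="quantitative", n=1000, records=rec)


GENE = {"gene": "PROT1", "chrom": "1", "tss": 1_000_000}


class TestSelection:
    def test_window_boundary_inclusive(self):
        ss = _stats([
            ("a", "1", 1_500_000, "A", "G", 0.3, 0.1, 0.02, 1e-6),   # exactly +500kb
            ("b", "1", 1_500_001, "A", "G", 0.3, 0.1, 0.02, 1e-6),   # 1 bp beyond
            ("c", "1", 500_000, "A", "G", 0.3, 0.1, 0.02, 1e-6),     # exactly -500kb
        ])
        kept = select_cis_pqtls(ss, GENE, maf_min=0.01, window_bp=500_000)
        assert set(kept["variant_id"]) == {"a", "c"}

    def test_low_maf_removed_both_tails(self):
        ss = _stats([
            ("low", "1", 1_000_000, "A", "G", 0.005, 0.1, 0.02, 1e-6),
            ("high", "1", 1_000_100, "A", "G", 0.995, 0.1, 0.02, 1e-6),
            ("ok", "1", 1_000_200, "A", "G", 0.30, 0.1, 0.02, 1e-6),
        ])
        kept = select_cis_pqtls(ss, GENE, maf_min=0.01, window_bp=500_000)
        assert list(kept["variant_id"]) == ["ok"]

    def test_wrong_chromosome_excluded(self):
        ss = _stats([("x", "2", 1_000_000, "A", "G", 0.3, 0.1, 0.02, 1e-6)])
        assert select_cis_pqtls(ss, GENE).empty


class TestClump:
    def test_greedy_p_ordered(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.3, size=(2000, 1)).astype(float)
        # v0 and v1 nearly identical (high LD); v2 independent
        G = np.column_stack([base[:, 0], base[:, 0], rng.binomial(2, 0.3, 2000)])
        flip = rng.uniform(size=2000) < 0.02
        G[flip, 1] = 2 - G[flip, 1]
        ld = LDReference(G, ["v0", "v1", "v2"])
        records = pd.DataFrame({
            "variant_id": ["v0", "v1", "v2"],
            "pvalue": [1e-8, 1e-10, 1e-4],
        })
        kept = clump(records, ld, r2_max=0.1)
        assert list(kept["variant_id"]) == ["v1", "v2"]  # v0 linked to stronger v1


def _exp_records(rows):
    return pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pvalue",
    ])


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        exp = _exp_records([("v", "1", 100, "A", "G", 0.3, 0.30, 0.05, 1e-9)])
        out = _exp_records([("v", "1", 100, "G", "A", 0.7, -0.10, 0.02, 1e-6)])
        inst = harmonize(exp, out)
        assert inst.n_snp == 1
        assert inst.snps["beta_out"].iloc[0] == pytest.approx(+0.10)
        assert inst.accounting["flipped"] == 1

    def test_same_orientation_retained(self):
        exp = _exp_records([("v", "1", 100, "A", "G", 0.3, 0.30, 0.05, 1e-9)])
        out = _exp_records([("v", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1e-6)])
        inst = harmonize(exp, out)
        assert inst.snps["beta_out"].iloc[0] == pytest.approx(0.10)
        assert inst.accounting["retained"] == 1

    def test_strand_complement_resolved(self):
        exp = _exp_records([("v", "1", 100, "A", "G", 0.3, 0.30, 0.05, 1e-9)])
        out = _exp_records([("v", "1", 100, "T", "C", 0.3, 0.10, 0.02, 1e-6)])
        inst = harmonize(exp, out)
        assert inst.snps["beta_out"].iloc[0] == pytest.approx(0.10)

    def test_proxy_substituted_when_strong_and_similar_maf(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.30, size=4000).astype(float)
        noise = rng.uniform(size=4000) < 0.01
        g2 = np.where(noise, 2 - g, g)  # r2 ~ 0.96
        ld = LDReference(np.column_stack([g, g2]), ["v", "p"])
        assert ld.r2("v", "p") >= 0.9
        exp = _exp_records([("v", "1", 100, "A", "G", 0.30, 0.30, 0.05, 1e-9)])
        out = _exp_records([("p", "1", 500, "A", "G", 0.31, 0.12, 0.02, 1e-6)])
        inst = harmonize(exp, out, ld=ld, r2_min=0.9, maf_tol=0.02)
        assert inst.n_snp == 1
        assert bool(inst.snps["proxy_used"].iloc[0])
        assert inst.accounting["proxied"] == 1

    def test_weak_proxy_not_substituted(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.30, size=4000).astype(float)
        noise = rng.uniform(size=4000) < 0.06
        g2 = np.where(noise, 2 - g, g)  # r2 ~ 0.8
        ld = LDReference(np.column_stack([g, g2]), ["v", "p"])
        assert ld.r2("v", "p") < 0.9
        exp = _exp_records([("v", "1", 100, "A", "G", 0.30, 0.30, 0.05, 1e-9)])
        out = _exp_records([("p", "1", 500, "A", "G", 0.31, 0.12, 0.02, 1e-6)])
        inst = harmonize(exp, out, ld=ld, r2_min=0.9)
        assert inst.n_snp == 0
        assert inst.accounting["dropped"] == 1

    def test_dissimilar_maf_proxy_rejected(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.30, size=4000).astype(float)
        ld = LDReference(np.column_stack([g, g]), ["v", "p"])
        exp = _exp_records([("v", "1", 100, "A", "G", 0.30, 0.30, 0.05, 1e-9)])
        out = _exp_records([("p", "1", 500, "A", "G", 0.40, 0.12, 0.02, 1e-6)])
        inst = harmonize(exp, out, ld=ld, r2_min=0.9, maf_tol=0.02)
        assert inst.n_snp == 0

    def test_palindromic_ambiguous_dropped(self):
        exp = _exp_records([("v", "1", 100, "A", "T", 0.48, 0.30, 0.05, 1e-9)])
        out = _exp_records([("v", "1", 100, "A", "T", 0.52, 0.10, 0.02, 1e-6)])
        inst = harmonize(exp, out)
        assert inst.n_snp == 0
        assert inst.accounting["dropped"] == 1

    def test_palindromic_resolved_by_frequency(self):
        exp = _exp_records([("v", "1", 100, "A", "T", 0.20, 0.30, 0.05, 1e-9)])
        out = _exp_records([("v", "1", 100, "A", "T", 0.21, 0.10, 0.02, 1e-6)])
        inst = harmonize(exp, out)
        assert inst.n_snp == 1
        assert inst.snps["beta_out"].iloc[0] == pytest.approx(0.10)
        # opposite-side frequency implies the labels refer to opposite alleles
        out2 = _exp_records([("v", "1", 100, "A", "T", 0.79, 0.10, 0.02, 1e-6)])
        inst2 = harmonize(exp, out2)
        assert inst2.snps["beta_out"].iloc[0] == pytest.approx(-0.10)

    def test_allele_mismatch_dropped(self):
        exp = _exp_records([("v", "1", 100, "A", "G", 0.3, 0.30, 0.05, 1e-9)])
        out = _exp_records([("v", "1", 100, "A", "C", 0.3, 0.10, 0.02, 1e-6)])
        inst = harmonize(exp, out)
        assert inst.n_snp == 0

    def test_accounting_is_exact(self):
        exp = _exp_records([
            ("v1", "1", 100, "A", "G", 0.3, 0.30, 0.05, 1e-9),   # retained
            ("v2", "1", 200, "T", "C", 0.2, 0.25, 0.05, 1e-8),   # flipped
            ("v3", "1", 300, "A", "C", 0.3, 0.20, 0.05, 1e-7),   # mismatch -> dropped
            ("v4", "1", 400, "A", "G", 0.3, 0.15, 0.05, 1e-6),   # absent -> dropped
        ])
        out = _exp_records([
            ("v1", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1e-6),
            ("v2", "1", 200, "C", "T", 0.8, 0.10, 0.02, 1e-6),
            ("v3", "1", 300, "G", "C", 0.3, 0.10, 0.02, 1e-6),
        ])
        inst = harmonize(exp, out)
        a = inst.accounting
        assert a["n_input"] == 4
        assert a["retained"] + a["flipped"] + a["proxied"] + a["dropped"] == 4
        assert a["retained"] == 1 and a["flipped"] == 1 and a["dropped"] == 2

    def test_idempotent(self):
        exp = _exp_records([
            ("v1", "1", 100, "A", "G", 0.3, 0.30, 0.05, 1e-9),
            ("v2", "1", 200, "T", "C", 0.2, 0.25, 0.05, 1e-8),
        ])
        out = _exp_records([
            ("v1", "1", 100, "G", "A", 0.7, -0.10, 0.02, 1e-6),
            ("v2", "1", 200, "T", "C", 0.2, 0.08, 0.02, 1e-5),
        ])
        first = harmonize(exp, out)
        # re-express the harmonized outcome on the exposure's alleles and
        # harmonize again: nothing changes
        aligned = exp.copy()
        aligned["beta"] = first.snps["beta_out"].to_numpy()
        aligned["se"] = first.snps["se_out"].to_numpy()
        second = harmonize(exp, aligned)
        np.testing.assert_allclose(second.snps["beta_out"], first.snps["beta_out"])
        np.testing.assert_allclose(second.snps["se_out"], first.snps["se_out"])
        assert second.accounting["flipped"] == 0
        assert second.accounting["dropped"] == 0
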