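"""IO, QC filters, conflict pruning, trait derivation, imputation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import diallelgen as dg
from diallelgen import gio
from diallelgen.relmat import RelationshipMatrix

from conftest import make_genotypes


class TestVcfRoundTrip:
    def test_dosages_survive_write_read(self, small_sim, tmp_path):
        g = small_sim.genotypes
        # plant some missing genotypes
        d = g.dosages.copy()
        d[3, 5] = np.nan
        d[0, 0] = np.nan
        g2 = dg.GenotypeMatrix(d, g.snp_info, g.sample_info)
        path = tmp_path / "x.vcf"
        gio.write_vcf(g2, path)
        back = gio.read_vcf(path)
        np.testing.assert_array_equal(back.dosages, g2.dosages)
        assert list(back.sample_info["group"]) == list(g2.sample_info["group"])

    def test_multiallelic_and_indel_records_dropped(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tWW_1\tYY_1\n"
            "1\t100\ta\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
            "1\t200\tb\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "1\t300\tc\tAT\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n")
        g = gio.read_vcf(path)
        assert g.n_snps == 1
        assert list(g.snp_info["id"]) == ["a"]
        np.testing.assert_array_equal(g.dosages[:, 0], [1.0, 2.0])


class TestHweExact:
    def brute_force(self, n_het, n_hom1, n_hom2):
        """Independent oracle: direct conditional probabilities via comb."""
        n = n_het + n_hom1 + n_hom2
        rare = 2 * min(n_hom1, n_hom2) + n_het

        def prob(h):
            # multinomial count of genotype configurations x 2^h phase
            # choices, conditioned on the allele counts
            rr = (rare - h) // 2
            cc = (2 * n - rare - h) // 2
            return (math.factorial(n) // (math.factorial(rr) * math.factorial(h)
                                          * math.factorial(cc)) * 2**h
                    * math.factorial(rare) * math.factorial(2 * n - rare)
                    / math.factorial(2 * n))

        hs = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
        probs = {h: prob(h) for h in hs}
        total = sum(probs.values())
        p_obs = probs[n_het] / total
        return sum(v / total for v in probs.values()
                   if v / total <= p_obs * (1 + 1e-12))

    @pytest.mark.parametrize("het,h1,h2", [
        (50, 25, 25), (10, 40, 2), (0, 30, 5), (21, 10, 10), (5, 0, 95)])
    def test_matches_enumeration_oracle(self, het, h1, h2):
        assert gio.hwe_exact_pvalue(het, h1, h2) == pytest.approx(
            self.brute_force(het, h1, h2), rel=1e-9)

    def test_equilibrium_not_rejected(self):
        assert gio.hwe_exact_pvalue(50, 25, 25) > 0.01

    def test_all_het_strongly_rejected(self):
        assert gio.hwe_exact_pvalue(100, 0, 0) < 1e-10


class TestMinorAlleleCount:
    def test_cohort_of_1004_implies_10_copies(self):
        assert gio.minor_allele_count_threshold(1004, 0.005) == 10

    def test_exact_product(self):
        assert gio.minor_allele_count_threshold(100, 0.05) == 10

    def test_floor_applied(self):
        assert gio.minor_allele_count_threshold(986, 0.005) == 9

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
    def test_invalid_maf(self, maf):
        with pytest.raises(ValueError):
            gio.minor_allele_count_threshold(100, maf)


def _qc_fixture():
    """100 SNPs over 200 purebreds: 5 low call rate, 3 low MAF, 2 HWE fails."""
    rng = np.random.default_rng(3)
    n = 200
    d = rng.binomial(2, 0.5, size=(n, 100)).astype(float)
    for j in range(5):        # call rate 0.9 < 0.95
        miss = rng.choice(n, size=20, replace=False)
        d[miss, j] = np.nan
    for j in range(5, 8):     # single ALT copy: freq 1/400 = 0.0025 < 0.005
        d[:, j] = 0.0
        d[0, j] = 1.0
    for j in range(8, 10):    # every bird heterozygous: extreme HWE failure
        d[:, j] = 1.0
    groups = ["WW"] * 100 + ["YY"] * 100
    return make_genotypes(d, groups=groups)


class TestQcFilter:
    def test_planted_failures_are_removed(self):
        g, report = gio.qc_filter(_qc_fixture(), return_report=True)
        assert report == {"snp_call_rate": 5, "ind_call_rate": 0,
                          "maf": 3, "hwe": 2}
        assert g.n_snps == 90

    def test_idempotent(self):
        once = gio.qc_filter(_qc_fixture())
        twice = gio.qc_filter(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_monomorphic_removed_by_maf(self):
        d = np.ones((40, 2))
        d[:, 0] = 0.0  # monomorphic ref
        d[:, 1] = np.random.default_rng(0).binomial(2, 0.5, 40)
        g = make_genotypes(d, groups=["WW"] * 20 + ["YY"] * 20)
        out = gio.qc_filter(g)
        assert out.n_snps == 1

    def test_all_removed_raises(self):
        d = np.zeros((20, 3))
        g = make_genotypes(d, groups=["WW"] * 10 + ["YY"] * 10)
        with pytest.raises(gio.QcError):
            gio.qc_filter(g)


class TestGroupClassFilter:
    def _fixture(self, n_bad=6):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.5, size=(120, 20)).astype(float)
        # violations: het class present in both lines with <=5 carriers each
        for j in range(n_bad):
            col = np.concatenate([
                rng.choice([0.0, 2.0], size=60),   # WW
                rng.choice([0.0, 2.0], size=60)])  # YY
            col[rng.choice(60, 3, replace=False)] = 1.0
            col[60 + rng.choice(60, 4, replace=False)] = 1.0
            d[:, j] = col
        return make_genotypes(d, groups=["WW"] * 60 + ["YY"] * 60)

    def test_planted_violations_removed(self):
        out, n_removed = gio.group_genotype_class_filter(
            self._fixture(), return_report=True)
        assert n_removed == 6
        assert out.n_snps == 14

    def test_one_sided_rarity_retained(self):
        # WW has only 3 hets but YY has 25: retained (one line is abundant)
        ww = np.repeat([1.0, 0.0, 2.0], [3, 14, 13])
        yy = np.repeat([1.0, 0.0, 2.0], [25, 3, 2])
        d = np.concatenate([ww, yy])[:, None]
        g = make_genotypes(d, groups=["WW"] * 30 + ["YY"] * 30)
        out = gio.group_genotype_class_filter(g)
        assert out.n_snps == 1


class TestConflictPruning:
    def _mats(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"i{i}" for i in range(n)]
        return (RelationshipMatrix(a, "A", ids),
                RelationshipMatrix(a.copy(), "G", ids))

    def test_identical_matrices_nothing_removed(self):
        a, g = self._mats()
        assert gio.conflict_pruning(a, g) == []

    def test_corrupted_individual_removed_first(self):
        a, g = self._mats()
        gv = g.values.copy()
        gv[3, :] += 2.0
        gv[:, 3] += 2.0
        gv[3, 3] = g.values[3, 3]
        g2 = RelationshipMatrix((gv + gv.T) / 2, "G", g.ids)
        removed = gio.conflict_pruning(a, g2, top_k=20)
        assert removed[0] == "i3"

    def test_deterministic(self):
        a, g = self._mats(seed=1)
        noise = np.random.default_rng(2).normal(scale=0.1,
                                                size=g.values.shape)
        g = RelationshipMatrix(g.values + (noise + noise.T) / 2, "G", g.ids)
        assert gio.conflict_pruning(a, g) == gio.conflict_pruning(a, g)

    def test_never_removes_uninvolved_individual(self):
        a, g = self._mats(seed=4)
        gv = g.values.copy()
        gv[0, 1] = gv[1, 0] = gv[0, 1] + 5.0
        g2 = RelationshipMatrix(gv, "G", g.ids)
        removed = gio.conflict_pruning(a, g2, top_k=1)
        assert set(removed) <= {"i0", "i1"}


class TestDeriveTraits:
    @given(st.lists(st.integers(min_value=0, max_value=120),
                    min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_identities_hold_exactly(self, counts):
        df = pd.DataFrame([counts], columns=["CEN200", "EN300", "EN400",
                                             "EN500", "EN600", "EN700"])
        out = gio.derive_traits(df)
        assert out.loc[0, "CEN300"] == counts[0] + counts[1]
        assert out.loc[0, "CEN700"] == sum(counts)
        assert out.loc[0, "EN300_500"] == counts[2] + counts[3]
        assert out.loc[0, "EN500_700"] == counts[4] + counts[5]

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([{"CEN200": 10, "EN300": -1, "EN400": 0,
                            "EN500": 0, "EN600": 0, "EN700": 0}])
        with pytest.raises(ValueError, match="negative"):
            gio.derive_traits(df)


class TestMeanImpute:
    def test_missing_replaced_by_snp_mean(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        g = make_genotypes(d, groups=["WW", "YY", "WY"])
        out = gio.mean_impute(g)
        assert out.dosages[2, 0] == pytest.approx(1.0)
        assert out.imputed_mask[2, 0] and not out.imputed_mask[0, 0]

    def test_no_missing_is_identity(self, small_sim):
        out = gio.mean_impute(small_sim.genotypes)
        np.testing.assert_array_equal(out.dosages, small_sim.genotypes.dosages)

    def test_column_means_preserved(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.4, (50, 20)).astype(float)
        miss = rng.random((50, 20)) < 0.1
        d[miss] = np.nan
        g = make_genotypes(d, groups=["WW"] * 50)
        out = gio.mean_impute(g)
        np.testing.assert_allclose(out.dosages.mean(axis=0),
                                   np.nanmean(d, axis=0), atol=1e-12)

    def test_fully_missing_snp_raises(self):
        d = np.full((5, 1), np.nan)
        g = make_genotypes(d, groups=["WW"] * 5)
        with pytest.raises(gio.QcError):
            gio.mean_impute(g)


def test_autosomal_drops_sex_chromosomes():
    d = np.zeros((4, 3))
    d[:, 1] = 1.0
    g = make_genotypes(d, chrom=["1", "Z", "W"], groups=["WW"] * 4)
    assert list(g.autosomal().snp_info["chrom"]) == ["1"]
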