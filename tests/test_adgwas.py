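"""Single-SNP scans: GLS oracle, FDR ladders, gene action, LD pruning."""

import numpy as np
import pandas as pd
import pytest

import diallelgen as dg
from diallelgen import adgwas, relmat, varcomp

from conftest import make_genotypes


@pytest.fixture(scope="module")
def planted_scan():
    """n=480 diallel with one strong additive QTL; both scans fitted."""
    cfg = dg.SimConfig(n_snps=500, n_qtl=1, additive_effect_sd=0.0,
                       dominance_effect_sd=0.0, polygenic_var=5.0,
                       residual_var=25.0, round_counts=False,
                       group_sizes={"WW": 120, "YY": 120, "WY": 120, "YW": 120},
                       seed=21)
    freqs = dg.draw_line_frequencies(cfg)
    k = 250
    freqs.p_W[k] = 0.55
    freqs.p_Y[k] = 0.45
    g = dg.simulate_genotypes(freqs, cfg)
    a = 0.8 * np.sqrt(30.0)  # 0.8 phenotypic SD
    eff = dg.QtlEffects(np.array([k]), np.array([a]), np.array([0.0]))
    pheno, truth = dg.simulate_phenotypes(g, eff, cfg)
    X = varcomp.design_matrix(pheno)
    y = pheno["EN400"].to_numpy(float)
    G = relmat.compute_grm(g)
    D = relmat.compute_drm(g)
    null = adgwas.fit_null(y, X, G, D)
    table = adgwas.scan(g, null, model="AD")
    return dict(g=g, y=y, X=X, G=G, D=D, null=null, table=table, k=k, a=a)


class TestScan:
    def test_planted_additive_qtl_recovered(self, planted_scan):
        row = planted_scan["table"].iloc[planted_scan["k"]]
        assert row["alpha_hat"] == pytest.approx(
            planted_scan["a"], abs=2 * row["se_alpha"])
        assert abs(row["t_dom"]) < 3.5

    def test_gls_equals_joint_refit_oracle(self, planted_scan):
        # per-SNP joint GLS with the full V must equal the whitened fast path
        null, g = planted_scan["null"], planted_scan["g"]
        V = null.V()
        Vinv = np.linalg.inv(V)
        y = planted_scan["y"]
        for j in (0, 100, planted_scan["k"]):
            jvec = g.dosages[:, j]
            kvec = (jvec == 1).astype(float)
            W = np.column_stack([null.X, jvec, kvec])
            beta = np.linalg.solve(W.T @ Vinv @ W, W.T @ Vinv @ y)
            cov = np.linalg.inv(W.T @ Vinv @ W)
            row = planted_scan["table"].iloc[j]
            assert row["alpha_hat"] == pytest.approx(beta[-2], abs=1e-8)
            assert row["beta_hat"] == pytest.approx(beta[-1], abs=1e-8)
            assert row["se_alpha"] == pytest.approx(np.sqrt(cov[-2, -2]),
                                                    abs=1e-8)
            assert row["se_beta"] == pytest.approx(np.sqrt(cov[-1, -1]),
                                                   abs=1e-8)

    def test_allele_flip_negates_alpha_keeps_beta(self, planted_scan):
        g = planted_scan["g"]
        flipped = dg.GenotypeMatrix(2.0 - g.dosages, g.snp_info.copy(),
                                    g.sample_info.copy())
        t2 = adgwas.scan(flipped, planted_scan["null"], model="AD")
        t1 = planted_scan["table"]
        np.testing.assert_allclose(t2["alpha_hat"], -t1["alpha_hat"], atol=1e-8)
        np.testing.assert_allclose(t2["beta_hat"], t1["beta_hat"], atol=1e-8)

    def test_monomorphic_snp_flagged(self, planted_scan):
        g = planted_scan["g"]
        d = g.dosages.copy()
        d[:, 0] = 2.0
        g2 = dg.GenotypeMatrix(d, g.snp_info.copy(), g.sample_info.copy())
        t = adgwas.scan(g2, planted_scan["null"], model="AD")
        assert bool(t.iloc[0]["not_testable"])

    def test_no_heterozygotes_flags_dominance(self, planted_scan):
        g = planted_scan["g"]
        d = g.dosages.copy()
        rng = np.random.default_rng(0)
        d[:, 1] = rng.choice([0.0, 2.0], size=d.shape[0])
        g2 = dg.GenotypeMatrix(d, g.snp_info.copy(), g.sample_info.copy())
        t = adgwas.scan(g2, planted_scan["null"], model="AD")
        assert bool(t.iloc[1]["dominance_flagged"])
        assert not bool(t.iloc[1]["not_testable"])

    def test_sex_chromosome_snps_excluded_in_ad(self, planted_scan):
        g = planted_scan["g"]
        info = g.snp_info.copy()
        info.loc[0:9, "chrom"] = "Z"
        info = info.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        # rebuild with the Z-labelled SNPs (order preserved within chrom)
        idx = info.index.to_numpy()
        g2 = dg.GenotypeMatrix(g.dosages[:, idx], info, g.sample_info.copy())
        t = adgwas.scan(g2, planted_scan["null"], model="AD")
        assert len(t) == g.n_snps - 10
        assert not t["chrom"].isin(["Z", "W"]).any()


class TestFdr:
    def test_all_ones(self):
        np.testing.assert_allclose(adgwas.compute_fdr(np.ones(5)), np.ones(5))

    def test_bh_ladder_hand_computed(self):
        q = adgwas.compute_fdr(np.array([0.001, 0.01, 0.02, 0.8]), method="bh")
        np.testing.assert_allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.8])

    def test_uniform_null_yields_no_discoveries(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=5000)
        for method in ("bh", "storey"):
            q = adgwas.compute_fdr(p, method=method)
            assert (q < 0.01).sum() == 0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=300) ** 2
        q = adgwas.compute_fdr(p, method="storey")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adgwas.compute_fdr([])
        with pytest.raises(ValueError):
            adgwas.compute_fdr([0.5, 1.2])


class TestGeneAction:
    @pytest.mark.parametrize("t_add,t_dom,expected", [
        (-2.0, 2.0, "complete_dominance"),
        (5.0, 0.5, "additive"),
        (1.0, 2.0, "over_dominance"),
        (10.0, 2.0, "additive"),        # r = 0.2 boundary -> lower class
        (10.0, 8.0, "partial_dominance"),  # r = 0.8 boundary
        (10.0, 12.0, "complete_dominance"),  # r = 1.2 boundary
        (0.0, 2.0, "over_dominance"),   # undefined ratio
    ])
    def test_classes(self, t_add, t_dom, expected):
        r, cls = adgwas.classify_gene_action(t_add, t_dom)
        assert cls[0] == expected

    def test_ratio_values(self):
        r, _ = adgwas.classify_gene_action([-2.0, 4.0], [2.0, -1.0])
        np.testing.assert_allclose(r, [1.0, 0.25])


class TestAlleleSubstitution:
    def test_pure_additive(self):
        assert adgwas.allele_substitution_effect(1.0, 0.0, 0.3) == 1.0

    def test_pure_dominance_blind_at_half(self):
        assert adgwas.allele_substitution_effect(0.0, 1.0, 0.5) == 0.0

    def test_formula(self):
        assert adgwas.allele_substitution_effect(0.5, 0.4, 0.2) == pytest.approx(
            0.5 + 0.6 * 0.4)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            adgwas.allele_substitution_effect(1.0, 1.0, 1.5)


class TestLdPrune:
    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.5, size=(200, 12)).astype(float)
        g = make_genotypes(d, groups=["WW"] * 200)
        ids = list(g.snp_info["id"])
        retained, _ = adgwas.ld_prune_significant(g, ids)
        assert retained == ids

    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(7)
        col = rng.binomial(2, 0.5, 100).astype(float)
        d = np.column_stack([col, col, rng.binomial(2, 0.5, 100)])
        g = make_genotypes(d, groups=["WW"] * 100)
        retained, _ = adgwas.ld_prune_significant(g, ["s0", "s1", "s2"])
        assert retained == ["s0", "s2"]

    def test_three_blocks_give_three_regions(self):
        rng = np.random.default_rng(8)
        cols = []
        for _ in range(3):
            c = rng.binomial(2, 0.5, 300).astype(float)
            cols.extend([c] * 10)
        d = np.column_stack(cols)
        chrom = ["1"] * 10 + ["2"] * 10 + ["3"] * 10
        g = make_genotypes(d, chrom=chrom, groups=["WW"] * 300)
        retained, n_regions = adgwas.ld_prune_significant(
            g, list(g.snp_info["id"]))
        assert len(retained) == 3
        assert n_regions == 3


def test_null_model_v_reconstruction(planted_scan):
    null = planted_scan["null"]
    comp = null.components.components
    V_direct = (comp["sigma_a2"] * planted_scan["G"].values
                + comp["sigma_d2"] * planted_scan["D"].values
                + comp["sigma_e2"] * np.eye(len(planted_scan["y"])))
    np.testing.assert_allclose(null.V(), V_direct, atol=1e-8)


def test_snpscan_results_object(planted_scan):
    model = adgwas.SnpScan(planted_scan["g"], planted_scan["y"],
                           planted_scan["X"], planted_scan["G"],
                           planted_scan["D"], model="AD")
    res = model.fit(fdr_method="bh")
    assert {"q_add", "q_dom", "snp_ratio", "gene_action"} <= set(res.table.columns)
    assert "significant" in res.summary()


class TestExactRefit:
    def test_two_stage_close_to_exact_per_snp_refits(self):
        """With a small SNP effect the two-stage GLS estimates agree with
        full per-SNP REML refits to within 1% of the standard error."""
        # both genetic components well away from the boundary, so the
        # per-SNP refits stay in the same likelihood basin as the null fit
        cfg = dg.SimConfig(n_snps=400, n_qtl=1, additive_effect_sd=0.2,
                           dominance_effect_sd=0.2, polygenic_var=4.0,
                           polygenic_dominance_var=4.0,
                           residual_var=8.0, round_counts=False,
                           group_sizes={"WW": 300, "YY": 300,
                                        "WY": 300, "YW": 300}, seed=33)
        data = dg.simulate_diallel(cfg)
        g = data.genotypes
        X = varcomp.design_matrix(data.phenotypes)
        y = data.phenotypes["EN400"].to_numpy(float)
        G = relmat.compute_grm(g)
        D = relmat.compute_drm(g)
        null = adgwas.fit_null(y, X, G, D)
        fast = adgwas.scan(g, null, model="AD")
        snps = [5, 200, 340]
        comps = null.components.components
        exact = adgwas.scan_exact(
            g, y, X, G, D, model="AD", snps=snps,
            start=[comps["sigma_a2"], comps["sigma_d2"], comps["sigma_e2"]])
        for row_e, j in zip(exact.itertuples(), snps):
            row_f = fast.iloc[j]
            if row_f["not_testable"] or row_f["dominance_flagged"]:
                continue
            assert abs(row_e.alpha_hat - row_f["alpha_hat"]) < \
                0.01 * row_f["se_alpha"] + 1e-9
            assert abs(row_e.beta_hat - row_f["beta_hat"]) < \
                0.01 * row_f["se_beta"] + 1e-9
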