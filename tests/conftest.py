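import numpy as np
import pandas as pd
import pytest

import diallelgen as dg


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete diallel simulation shared by fast tests."""
    cfg = dg.SimConfig(n_snps=400, n_qtl=20,
                       group_sizes={"WW": 40, "YY": 40, "WY": 40, "YW": 40},
                       n_genes=40, seed=42)
    return dg.simulate_diallel(cfg)


@pytest.fixture(scope="session")
def hwe_panel():
    """Single-population HWE panel (no line divergence, no families)."""
    cfg = dg.SimConfig(n_snps=3000, n_qtl=1, divergence=1e-3,
                       family_structure=False,
                       group_sizes={"WW": 120, "YY": 120, "WY": 80, "YW": 80},
                       seed=7)
    freqs = dg.draw_line_frequencies(cfg)
    return dg.simulate_genotypes(freqs, cfg)


def make_genotypes(dosages, chrom=None, groups=None):
    """Build a GenotypeMatrix from a raw dosage array with minimal metadata."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    if chrom is None:
        chrom = ["1"] * m
    snp_info = pd.DataFrame({
        "id": [f"s{j}" for j in range(m)], "chrom": chrom,
        "pos": _positions(chrom), "ref": ["A"] * m, "alt": ["G"] * m})
    if groups is None:
        groups = (["WW", "YY", "WY", "YW"] * n)[:n]
    sample_info = pd.DataFrame({"id": [f"i{i}" for i in range(n)],
                                "group": groups})
    return dg.GenotypeMatrix(dosages, snp_info, sample_info)


def _positions(chrom):
    pos, seen = [], {}
    for c in chrom:
        seen[c] = seen.get(c, 0) + 1000
        pos.append(seen[c])
    return pos
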