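"""Covariate-adjusted eQTL mapping with a 1 Mb cis/trans partition.

Every SNP x gene pair is tested by least-squares regression of expression
(TPM scale) on the covariates plus the allele-count dosage; the fast path
residualizes both sides against the covariate design once and recovers the
per-pair t statistic from the residual correlation, which is algebraically
identical to refitting the full regression per pair.  A pair is cis when
the SNP lies on the gene's chromosome within 1 Mb (inclusive) of the
transcription start site, trans otherwise; q-values are computed
separately within the cis and the trans sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adgwas import compute_fdr
from .gio import GenotypeMatrix

CIS_WINDOW = 1_000_000


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with gene annotation and sample covariates."""

    values: pd.DataFrame          # genes x samples, non-negative
    gene_info: pd.DataFrame       # id, chrom, tss, strand
    covariates: pd.DataFrame      # id plus covariate columns (group, age, ...)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if set(self.values.index) != set(self.gene_info["id"]):
            raise ValueError("gene_info does not match expression rows")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def classify_locality(snp_chrom, snp_pos, gene_chrom, gene_tss) -> np.ndarray:
    """Vectorized cis/trans call: cis iff same chromosome and |pos - TSS| <= 1 Mb."""
    snp_chrom = np.asarray(snp_chrom, dtype=object)
    gene_chrom = np.asarray(gene_chrom, dtype=object)
    tss = np.asarray(gene_tss, float)
    if np.any(np.isnan(tss)):
        raise ValueError("missing TSS for one or more genes")
    same = snp_chrom == gene_chrom
    near = np.abs(np.asarray(snp_pos, float) - tss) <= CIS_WINDOW
    return np.where(same & near, "cis", "trans")


def tss_from_annotation(start, end, strand):
    """TSS respecting strand: feature start on '+', feature end on '-'."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    return np.where(np.asarray(strand) == "-", end, start)


def filter_expressed(e: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose expression is zero in every sample (count logged)."""
    import logging

    keep = (e.values.to_numpy() != 0).any(axis=1)
    logging.getLogger(__name__).info(
        "filter_expressed: removed %d all-zero genes", int((~keep).sum()))
    vals = e.values.loc[keep]
    info = e.gene_info[e.gene_info["id"].isin(vals.index)].reset_index(drop=True)
    return ExpressionMatrix(vals, info, e.covariates)


def _covariate_design(cov: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(cov))]
    for c in cov.columns:
        if c == "id":
            continue
        s = cov[c]
        if s.dtype == object or str(s.dtype) == "category":
            dummies = pd.get_dummies(s.astype(str), drop_first=True)
            cols.extend(dummies[k].to_numpy(float) for k in dummies.columns)
        else:
            cols.append(s.to_numpy(float))
    return np.column_stack(cols)


@dataclass
class EqtlResult:
    """Tested pairs (optionally truncated at a p ceiling) plus full accounting."""

    pairs: pd.DataFrame            # snp, gene, locality, estimate, t, p, q, significant
    n_cis_pairs: int
    n_trans_pairs: int
    cis_p_threshold: float
    trans_p_threshold: float
    fdr: float

    def significant(self, locality: str | None = None) -> pd.DataFrame:
        sub = self.pairs[self.pairs["significant"]]
        if locality is not None:
            sub = sub[sub["locality"] == locality]
        return sub


def map_eqtl(g: GenotypeMatrix, e: ExpressionMatrix, fdr: float = 0.01,
             fdr_method: str = "storey", p_ceiling: float = 1.0,
             log1p: bool = False) -> EqtlResult:
    """Test every SNP against every gene's expression with covariates.

    Returns an :class:`EqtlResult` whose ``pairs`` table keeps rows with
    p <= ``p_ceiling``; cis/trans pair totals are reported regardless so
    the partition always accounts for #SNPs x #genes.
    """
    samples = list(e.values.columns)
    order = {s: i for i, s in enumerate(g.sample_info["id"])}
    missing = [s for s in samples if s not in order]
    if missing:
        raise ValueError(f"expression samples absent from genotypes: {missing[:5]}")
    gsub = g.subset(individuals=[order[s] for s in samples])
    if np.isnan(gsub.dosages).any():
        raise ValueError("missing dosages; impute before eQTL mapping")

    C = _covariate_design(e.covariates)
    n = len(samples)
    dfree = n - C.shape[1] - 1
    if dfree <= 1:
        raise ValueError("too few samples for the covariate design")

    Q, _ = np.linalg.qr(C)
    Gd = gsub.dosages  # n x S
    Gr = Gd - Q @ (Q.T @ Gd)
    E = e.values.to_numpy().T  # n x genes
    if log1p:
        E = np.log1p(E)
    Er = E - Q @ (Q.T @ E)

    g_ss = np.einsum("ij,ij->j", Gr, Gr)
    e_ss = np.einsum("ij,ij->j", Er, Er)
    # SNPs without residual genotype variance carry no information; their
    # rows are reported with NaN estimates and p = 1
    mono = g_ss <= 1e-8 * n
    cross = Gr.T @ Er  # S x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cross / g_ss[:, None]
        rden = np.sqrt(np.outer(g_ss, e_ss))
        r = np.where(rden > 0, cross / rden, 0.0)
        r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
        t = r * np.sqrt(dfree / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), dfree)
    beta[mono, :] = np.nan
    t[mono, :] = np.nan
    p[mono, :] = 1.0

    snp_chrom = gsub.snp_info["chrom"].to_numpy()
    snp_pos = gsub.snp_info["pos"].to_numpy()
    gene_chrom = e.gene_info.set_index("id").loc[e.values.index, "chrom"].to_numpy()
    gene_tss = e.gene_info.set_index("id").loc[e.values.index, "tss"].to_numpy()
    cis_mask = ((snp_chrom[:, None] == gene_chrom[None, :])
                & (np.abs(snp_pos[:, None] - gene_tss[None, :].astype(float))
                   <= CIS_WINDOW))
    n_cis = int(cis_mask.sum())
    n_trans = cis_mask.size - n_cis

    q = np.empty_like(p)
    thresholds = {}
    for name, mask in (("cis", cis_mask), ("trans", ~cis_mask)):
        if mask.any():
            qv = compute_fdr(p[mask], method=fdr_method)
            q[mask] = qv
            sig_p = p[mask][qv < fdr]
            thresholds[name] = float(sig_p.max()) if sig_p.size else 0.0
        else:
            thresholds[name] = 0.0

    keep = p <= p_ceiling
    si, gi = np.nonzero(keep)
    pairs = pd.DataFrame({
        "snp": gsub.snp_info["id"].to_numpy()[si],
        "gene": e.values.index.to_numpy()[gi],
        "locality": np.where(cis_mask[si, gi], "cis", "trans"),
        "estimate": beta[si, gi],
        "t": t[si, gi],
        "p": p[si, gi],
        "q": q[si, gi],
    })
    pairs["significant"] = pairs["q"] < fdr
    return EqtlResult(pairs=pairs, n_cis_pairs=n_cis, n_trans_pairs=n_trans,
                      cis_p_threshold=thresholds["cis"],
                      trans_p_threshold=thresholds["trans"], fdr=fdr)


def pleiotropy_summary(res: EqtlResult, hotspot_genes: int = 10) -> dict:
    """Per-SNP gene counts among significant pairs, separately cis and trans.

    For each locality, reports the number of eQTL SNPs, the fraction (in %)
    associated with the expression of 2 or more genes, and the SNPs
    associated with more than ``hotspot_genes`` genes (hotspot candidates).
    """
    out = {}
    for loc in ("cis", "trans"):
        sub = res.significant(loc)
        counts = sub.groupby("snp")["gene"].nunique()
        n_eqtl = int(len(counts))
        n_multi = int((counts >= 2).sum())
        hotspots = counts[counts > hotspot_genes]
        out[loc] = {
            "n_eqtl_snps": n_eqtl,
            "n_pleiotropic": n_multi,
            "pct_pleiotropic": round(100.0 * n_multi / n_eqtl, 2) if n_eqtl else 0.0,
            "hotspots": sorted(hotspots.index.tolist()),
        }
    return out


def pleiotropy_percentage(n_multi: int, n_total: int) -> float:
    """Percentage of eQTLs associated with >=2 genes, two-decimal rounding."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_multi / n_total, 2)


def combination_accounting(n_snps: int, n_genes: int, n_cis_pairs: int) -> int:
    """Trans pair count implied by the totals: n_snps * n_genes - n_cis_pairs."""
    total = int(n_snps) * int(n_genes)
    if n_cis_pairs > total:
        raise ValueError("cis pairs exceed the total number of combinations")
    return total - int(n_cis_pairs)
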