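"""Genotype/phenotype IO, quality control, and trait derivation.

Core containers are thin dataclasses around numpy/pandas objects.  Dosages
are stored as a float matrix (individuals x SNPs) holding the count of the
alternative allele, with ``nan`` marking missing genotypes.  Genetic groups
follow the diallel-cross design: two pure lines (WW, YY) and their
reciprocal F1 crosses (WY, YW).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("WW", "YY", "WY", "YW")
PURE_LINES = ("WW", "YY")
CROSSES = ("WY", "YW")
SEX_CHROMOSOMES = ("Z", "W")

#: per-stage egg-number traits, in chronological order
STAGE_TRAITS = ("EN300", "EN400", "EN500", "EN600", "EN700")
#: cumulative egg-number traits
CUMULATIVE_TRAITS = ("CEN200", "CEN300", "CEN400", "CEN500", "CEN600", "CEN700")
#: pooled mid/late-stage traits
POOLED_TRAITS = ("EN300_500", "EN500_700")
ALL_TRAITS = CUMULATIVE_TRAITS + STAGE_TRAITS + POOLED_TRAITS


class QcError(ValueError):
    """Raised when quality control empties the data or inputs are invalid."""


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix with SNP and sample metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_individuals, n_snps)
        Entries in {0, 1, 2} or nan for missing.
    snp_info : DataFrame
        Columns ``id, chrom, pos, ref, alt``; positions are 1-based and
        strictly increasing within each chromosome.
    sample_info : DataFrame
        Columns ``id, group`` with group in :data:`GROUPS`.
    imputed_mask : ndarray or None
        Boolean mask marking cells filled by :func:`mean_impute`.
    """

    dosages: np.ndarray
    snp_info: pd.DataFrame
    sample_info: pd.DataFrame
    imputed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n_ind, n_snp = self.dosages.shape
        if len(self.snp_info) != n_snp:
            raise ValueError(
                f"snp_info has {len(self.snp_info)} rows for {n_snp} SNPs"
            )
        if len(self.sample_info) != n_ind:
            raise ValueError(
                f"sample_info has {len(self.sample_info)} rows for {n_ind} individuals"
            )
        bad = set(self.sample_info["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown genetic groups: {sorted(bad)}")
        for chrom, sub in self.snp_info.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def groups(self) -> np.ndarray:
        return self.sample_info["group"].to_numpy()

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per SNP from non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays/masks."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if snp.dtype == bool:
            snp = np.flatnonzero(snp)
        mask = None
        if self.imputed_mask is not None:
            mask = self.imputed_mask[np.ix_(ind, snp)]
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ind, snp)],
            snp_info=self.snp_info.iloc[snp].reset_index(drop=True),
            sample_info=self.sample_info.iloc[ind].reset_index(drop=True),
            imputed_mask=mask,
        )

    def autosomal(self) -> "GenotypeMatrix":
        """Drop SNPs on the sex chromosomes (Z, W)."""
        keep = ~self.snp_info["chrom"].astype(str).isin(SEX_CHROMOSOMES)
        return self.subset(snps=keep.to_numpy())


@dataclass
class Pedigree:
    """Pedigree table: one row per individual with sire/dam ids (None=unknown).

    Parents must precede offspring in row order.
    """

    table: pd.DataFrame  # columns: id, sire, dam

    def __post_init__(self) -> None:
        ids = list(self.table["id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        seen: set = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent is not None and not (isinstance(parent, float) and math.isnan(parent)):
                    if parent == row.id:
                        raise ValueError(f"individual {row.id} is its own parent")
                    if parent not in seen:
                        raise ValueError(
                            f"parent {parent} of {row.id} not defined earlier "
                            "(pedigree must be sorted parents-first)"
                        )
            seen.add(row.id)


# ---------------------------------------------------------------------------
# VCF / TSV readers and writers
# ---------------------------------------------------------------------------

def read_vcf(path, group_map: dict | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Indels and multi-allelic records are dropped (count logged).  Dosage is
    the number of ALT alleles; missing genotypes become nan.  ``group_map``
    maps sample id to genetic group; without it, groups are parsed from ids
    of the form ``<GROUP>_<number>``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, recs = [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        recs.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS,
                     var.REF, var.ALT[0]))
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not rows:
        raise QcError("no biallelic SNPs in VCF")
    dosages = np.column_stack(rows)
    snp_info = pd.DataFrame(recs, columns=["id", "chrom", "pos", "ref", "alt"])
    if group_map is None:
        group_map = {s: s.split("_")[0] for s in samples}
    sample_info = pd.DataFrame({"id": samples,
                                "group": [group_map[s] for s in samples]})
    return GenotypeMatrix(dosages, snp_info, sample_info)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file (GT field only)."""
    chroms = list(dict.fromkeys(g.snp_info["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=diallelgen\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_info["id"]) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in enumerate(g.snp_info.itertuples(index=False)):
            col = g.dosages[:, j]
            gts = "\t".join("./." if np.isnan(d) else code[d] for d in col)
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    """Write dosages as TSV: rows = SNPs (id, chrom, pos, ref, alt, samples...)."""
    df = g.snp_info.copy()
    dos = pd.DataFrame(g.dosages.T, columns=g.sample_info["id"].tolist())
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path, group_map: dict | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    snp_info = df[meta_cols].copy()
    snp_info["chrom"] = snp_info["chrom"].astype(str)
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=float).T
    if group_map is None:
        group_map = {s: s.split("_")[0] for s in samples}
    sample_info = pd.DataFrame({"id": samples,
                                "group": [group_map[s] for s in samples]})
    return GenotypeMatrix(dosages, snp_info, sample_info)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["group"] = df["group"].astype(str)
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value (two-sided).

    Conditional probability of the observed heterozygote count given the
    allele counts, summed over outcomes no more probable than the observed
    one (the standard exact SNP-HWE test).
    """
    n_rare_hom = min(n_hom1, n_hom2)
    n = n_het + n_hom1 + n_hom2
    rare = 2 * n_rare_hom + n_het
    if n == 0:
        return 1.0
    # heterozygote counts share parity with the rare-allele count
    het_values = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logprob = np.zeros(len(het_values))
    # unnormalized log-probabilities via lgamma recurrences
    from scipy.special import gammaln

    for i, h in enumerate(het_values):
        rr = (rare - h) // 2
        cc = (2 * n - rare - h) // 2
        logprob[i] = (h * math.log(2)
                      - gammaln(h + 1) - gammaln(rr + 1) - gammaln(cc + 1))
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = np.flatnonzero(het_values == n_het)
    if len(obs) == 0:  # inconsistent counts
        return 1.0
    p_obs = prob[obs[0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def minor_allele_count_threshold(n_individuals: int, maf: float) -> int:
    """Minimum minor-allele copy count implied by a MAF cutoff.

    For ``n`` diploid individuals and a minor-allele-frequency threshold
    ``maf``, a locus passing the filter carries at least
    ``floor(2 * n * maf)`` copies of the minor allele.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return int(math.floor(2 * n_individuals * maf))


def qc_filter(g: GenotypeMatrix, snp_call_rate: float = 0.95,
              ind_call_rate: float = 0.95, maf: float = 0.005,
              hwe_p: float = 1e-4, return_report: bool = False):
    """Apply the standard SNP/individual QC filters, in a fixed order.

    Order: SNP call rate -> individual call rate -> minor allele frequency
    -> Hardy-Weinberg exact test.  The HWE test is computed within each pure
    line only (crossbred genotype frequencies deviate from HWE by design);
    a SNP is removed if it fails in either line.  Removal counts are logged
    and optionally returned.
    """
    if g.n_snps == 0 or g.n_individuals == 0:
        raise QcError("empty genotype matrix")
    report: dict[str, int] = {}

    called = ~np.isnan(g.dosages)
    keep_snp = called.mean(axis=0) >= snp_call_rate
    report["snp_call_rate"] = int((~keep_snp).sum())
    g = g.subset(snps=keep_snp)

    called = ~np.isnan(g.dosages)
    keep_ind = called.mean(axis=1) >= ind_call_rate if g.n_snps else np.ones(g.n_individuals, bool)
    report["ind_call_rate"] = int((~keep_ind).sum())
    g = g.subset(individuals=keep_ind)

    freq = g.allele_frequencies()
    minor = np.minimum(freq, 1 - freq)
    keep_snp = minor >= maf
    report["maf"] = int((~keep_snp).sum())
    g = g.subset(snps=keep_snp)

    fail = np.zeros(g.n_snps, bool)
    for line in PURE_LINES:
        sub = g.dosages[g.group_mask(line)]
        if sub.shape[0] == 0:
            continue
        for j in range(g.n_snps):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            n_het = int((col == 1).sum())
            n_hom_ref = int((col == 0).sum())
            n_hom_alt = int((col == 2).sum())
            if hwe_exact_pvalue(n_het, n_hom_ref, n_hom_alt) < hwe_p:
                fail[j] = True
    report["hwe"] = int(fail.sum())
    g = g.subset(snps=~fail)

    logger.info("qc_filter removals: %s", report)
    if g.n_snps == 0:
        raise QcError("all SNPs removed by QC filters")
    if return_report:
        return g, report
    return g


def group_genotype_class_filter(g: GenotypeMatrix, min_count: int = 5,
                                return_report: bool = False):
    """Remove SNPs whose genotype classes confound genetic group.

    A SNP is removed when some genotype class (0, 1 or 2) is present in both
    pure lines but with ``min_count`` or fewer carriers in each — such a
    class cannot be separated from the line contrast in a model with group
    fixed effects.
    """
    ww = g.dosages[g.group_mask("WW")]
    yy = g.dosages[g.group_mask("YY")]
    remove = np.zeros(g.n_snps, bool)
    for cls in (0.0, 1.0, 2.0):
        n_ww = (ww == cls).sum(axis=0)
        n_yy = (yy == cls).sum(axis=0)
        remove |= (n_ww >= 1) & (n_yy >= 1) & (n_ww <= min_count) & (n_yy <= min_count)
    logger.info("group_genotype_class_filter: removed %d SNPs", int(remove.sum()))
    out = g.subset(snps=~remove)
    if return_report:
        return out, int(remove.sum())
    return out


def conflict_pruning(a, g, top_k: int = 100, atol: float = 1e-8) -> list:
    """Prune individuals whose pedigree and genomic relationships disagree.

    Among the ``top_k`` off-diagonal pairs with the largest absolute
    difference between the pedigree (A) and genomic (G) relationship, the
    individual involved in the most pairs is removed (ties broken by larger
    mean |A-G| over its pairs, then by id order); its pairs are dropped and
    the count repeated until no pairs remain.  Pairs with |A-G| <= ``atol``
    are never considered conflicts.

    Parameters are :class:`~diallelgen.relmat.RelationshipMatrix` objects
    over the same individuals (typically one genetic group at a time).
    Returns removed ids in removal order.
    """
    av, gv = np.asarray(a.values), np.asarray(g.values)
    if av.shape != gv.shape:
        raise ValueError("relationship matrices differ in shape")
    if list(a.ids) != list(g.ids):
        raise ValueError("relationship matrices are over different individuals")
    ids = list(a.ids)
    n = av.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = np.abs(av - gv)[iu, ju]
    keep = diff > atol
    iu, ju, diff = iu[keep], ju[keep], diff[keep]
    order = np.argsort(-diff, kind="stable")[:top_k]
    pairs = list(zip(iu[order], ju[order], diff[order]))
    removed: list = []
    while pairs:
        counts: dict[int, list] = {}
        for i, j, d in pairs:
            counts.setdefault(i, []).append(d)
            counts.setdefault(j, []).append(d)
        # most pairs; ties -> larger mean |A-G|; ties -> id order
        best = min(counts, key=lambda k: (-len(counts[k]), -float(np.mean(counts[k])), ids[k]))
        removed.append(ids[best])
        pairs = [(i, j, d) for i, j, d in pairs if i != best and j != best]
    return removed


# ---------------------------------------------------------------------------
# Traits and imputation
# ---------------------------------------------------------------------------

def derive_traits(pheno: pd.DataFrame) -> pd.DataFrame:
    """Derive cumulative and pooled egg-number traits from stage counts.

    CEN(x) = CEN(x-100) + EN(x) for x in 300..700;
    EN300_500 = EN400 + EN500; EN500_700 = EN600 + EN700.
    Requires CEN200 and EN300..EN700; all counts must be non-negative.
    """
    out = pheno.copy()
    needed = ["CEN200", *STAGE_TRAITS]
    for c in needed:
        if c not in out.columns:
            raise ValueError(f"missing required trait column {c}")
        if (out[c] < 0).any():
            raise ValueError(f"negative egg counts in {c}")
    for x in (300, 400, 500, 600, 700):
        out[f"CEN{x}"] = out[f"CEN{x - 100}"] + out[f"EN{x}"]
    out["EN300_500"] = out["EN400"] + out["EN500"]
    out["EN500_700"] = out["EN600"] + out["EN700"]
    return out


def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-SNP mean of observed dosages.

    An approximation standing in for genotype imputation when only the
    relationship matrices are needed; the imputed cells are flagged in
    ``imputed_mask``.
    """
    miss = np.isnan(g.dosages)
    if miss.all(axis=0).any():
        raise QcError("SNP with all genotypes missing; run qc_filter first")
    if not miss.any():
        return replace(g, imputed_mask=np.zeros_like(miss))
    means = np.nanmean(g.dosages, axis=0)
    dosages = np.where(miss, means[None, :], g.dosages)
    return GenotypeMatrix(dosages, g.snp_info.copy(), g.sample_info.copy(),
                          imputed_mask=miss)
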