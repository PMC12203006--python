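"""Genomic (G), dominance (D) and pedigree (A) relationship matrices.

G follows the first VanRaden parameterization: dosages centered per SNP by
twice the allele frequency, G = ZZ' / (2 * sum p_i (1 - p_i)).  D follows
Vitezica's orthogonal dominance parameterization: the heterozygosity
indicator (0/1/0) centered by 2 p_i (1 - p_i), D = MM' / sum (2 p_i (1-p_i))^2.
A is built by the standard tabular recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix, Pedigree


@dataclass
class RelationshipMatrix:
    """Symmetric individual x individual relationship matrix."""

    values: np.ndarray
    kind: str  # "G", "D" or "A"
    ids: list
    freq_source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ids length does not match matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.kind in ("G", "A") and np.any(np.diag(self.values) < -1e-10):
            raise ValueError(f"negative diagonal in {self.kind} matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, mask) -> "RelationshipMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], self.kind,
                                  [self.ids[i] for i in idx], self.freq_source)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), kind, list(df.index))

    def to_packed(self, path) -> None:
        """Write the lower triangle as packed float64 with an id sidecar."""
        tri = self.values[np.tril_indices(self.n)]
        tri.astype("<f8").tofile(str(path))
        with open(f"{path}.ids", "w") as fh:
            fh.write("\n".join(str(i) for i in self.ids) + "\n")

    @classmethod
    def from_packed(cls, path, kind: str) -> "RelationshipMatrix":
        with open(f"{path}.ids") as fh:
            ids = [line.strip() for line in fh if line.strip()]
        n = len(ids)
        tri = np.fromfile(str(path), dtype="<f8")
        if tri.size != n * (n + 1) // 2:
            raise ValueError("packed file size does not match id sidecar")
        values = np.zeros((n, n))
        il = np.tril_indices(n)
        values[il] = tri
        values = values + values.T - np.diag(np.diag(values))
        return cls(values, kind, ids)


def _check_complete(g: GenotypeMatrix) -> None:
    if np.isnan(g.dosages).any():
        raise ValueError("missing dosages; run mean_impute first")


def _frequencies(g: GenotypeMatrix, freqs) -> tuple[np.ndarray, str]:
    if freqs is None:
        return g.dosages.mean(axis=0) / 2.0, "analyzed individuals"
    freqs = np.asarray(freqs, float)
    if freqs.shape != (g.n_snps,):
        raise ValueError("freqs length does not match SNP count")
    return freqs, "user supplied"


def compute_grm(g: GenotypeMatrix, freqs=None) -> RelationshipMatrix:
    """Additive genomic relationship matrix (VanRaden method I).

    Z = dosages - 2 p_i per SNP; G = ZZ' / (2 sum p_i (1 - p_i)).  SNPs
    fixed in the analyzed set (p in {0, 1}) contribute nothing.  When
    ``freqs`` is None the allele frequencies come from the supplied
    individuals themselves.
    """
    _check_complete(g)
    p, source = _frequencies(g, freqs)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; GRM denominator is zero")
    Z = g.dosages - 2.0 * p[None, :]
    values = (Z @ Z.T) / denom
    return RelationshipMatrix(values, "G", list(g.sample_info["id"]), source)


def compute_drm(g: GenotypeMatrix, freqs=None) -> RelationshipMatrix:
    """Dominance relationship matrix (Vitezica parameterization).

    Genotypes are coded -2p^2 (reference homozygote), 2pq (heterozygote)
    and -2q^2 (alternative homozygote), with p the alternative-allele
    frequency and q = 1 - p, giving D = MM' / sum_i (2 p_i q_i)^2.  This
    coding has mean zero and variance (2pq)^2 under HWE, so the diagonal
    averages one and dominance relationships are orthogonal to the additive
    ones; at p = 0.5 it reduces to the familiar heterozygosity code minus
    2pq.
    """
    _check_complete(g)
    p, source = _frequencies(g, freqs)
    q = 1.0 - p
    two_pq = 2.0 * p * q
    denom = float(np.sum(two_pq**2))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; DRM denominator is zero")
    dos = g.dosages
    M = np.where(dos == 1, two_pq[None, :],
                 np.where(dos == 0, (-2.0 * p * p)[None, :],
                          (-2.0 * q * q)[None, :]))
    values = (M @ M.T) / denom
    return RelationshipMatrix(values, "D", list(g.sample_info["id"]), source)


def pedigree_numerator(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    A_jj = 1 + 0.5 * A_sire,dam; A_ij = 0.5 (A_i,sire(j) + A_i,dam(j));
    unknown parents contribute zero.
    """
    ids = list(ped.table["id"])
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))

    def _idx(parent):
        if parent is None or (isinstance(parent, float) and np.isnan(parent)):
            return None
        return index[parent]

    for j, row in enumerate(ped.table.itertuples(index=False)):
        s, d = _idx(row.sire), _idx(row.dam)
        A[j, j] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        for i in range(j):
            val = 0.0
            if s is not None:
                val += 0.5 * A[i, s]
            if d is not None:
                val += 0.5 * A[i, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(A, "A", ids, "pedigree")
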