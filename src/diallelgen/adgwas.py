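"""Single-SNP association under additive (A) and additive-dominance (AD) models.

Per SNP the fixed part of the mixed model gains an allele-count covariate j
(0/1/2) and, in model AD, a heterozygosity indicator k (0/1/0); the
polygenic (and dominance) background covariance is fixed from a null REML
fit and each SNP is tested by generalized least squares against that
covariance — the two-stage strategy commonly used for genome-wide scans.

The k covariate is deliberately the 0/1/0 heterozygosity indicator: coding
it 0/1/2 would duplicate j exactly and make the dominance effect
unidentifiable; 0/1/0 matches the coding that builds the dominance
relationship matrix.

Gene action per SNP is classified from the ratio r = |t_Dom / t_Add|:
additive (r <= 0.2), partial dominance (0.2 < r <= 0.8), complete dominance
(0.8 < r <= 1.2), over-dominance (r > 1.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .gio import GenotypeMatrix, SEX_CHROMOSOMES
from .varcomp import (VarianceComponentModel, VarianceComponentResults,
                      fit_model_a, fit_model_ad)

GENE_ACTION_CLASSES = ("additive", "partial_dominance", "complete_dominance",
                       "over_dominance")


@dataclass
class NullModel:
    """Null mixed-model fit with the phenotypic covariance factorized once."""

    y: np.ndarray
    X: np.ndarray
    components: VarianceComponentResults
    chol_V: np.ndarray  # lower Cholesky factor of V
    model: str          # "A" | "AD"

    @property
    def n(self) -> int:
        return len(self.y)

    def whiten(self, M: np.ndarray) -> np.ndarray:
        """Apply L^-1 (V = LL') to a vector or column block."""
        return linalg.solve_triangular(self.chol_V, M, lower=True,
                                       check_finite=False)

    def V(self) -> np.ndarray:
        return self.chol_V @ self.chol_V.T


def fit_null(y, X, G, D=None) -> NullModel:
    """Estimate background variance components without SNP terms and cache V.

    With ``D`` given, the AD covariance V = G sa2 + D sd2 + I se2 is
    assembled; otherwise the additive-only V.  The Cholesky factor is
    computed once and reused for every SNP (and every scan over the same
    phenotype); a tiny diagonal ridge is added only if factorization fails.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    Gv = G.values if hasattr(G, "values") else np.asarray(G, float)
    if D is None:
        res = fit_model_a(y, X, Gv)
        V = res.components["sigma_a2"] * Gv
        tag = "A"
    else:
        Dv = D.values if hasattr(D, "values") else np.asarray(D, float)
        res = fit_model_ad(y, X, Gv, Dv)
        V = res.components["sigma_a2"] * Gv + res.components["sigma_d2"] * Dv
        tag = "AD"
    V = V + res.components["sigma_e2"] * np.eye(len(y))
    try:
        L = linalg.cholesky(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        ridge = 1e-6 * float(np.trace(V)) / len(y)
        L = linalg.cholesky(V + ridge * np.eye(len(y)), lower=True,
                            check_finite=False)
    model = VarianceComponentModel(y, X, {}, name=f"null-{tag}")
    return NullModel(y=y, X=model.X, components=res, chol_V=L, model=tag)


def scan(g: GenotypeMatrix, null: NullModel, model: str = "AD") -> pd.DataFrame:
    """GLS scan of every SNP against the cached null covariance.

    Model "A" regresses y on [X, j]; model "AD" on [X, j, k].  Estimates and
    standard errors come from the GLS information matrix; p-values are
    two-sided from the t distribution with df = n - rank of the full
    design.  Monomorphic SNPs (or SNPs collinear with the fixed effects)
    are flagged ``not_testable``; SNPs without a usable heterozygote
    contrast get the dominance columns flagged.  For model AD,
    sex-chromosome SNPs are excluded up front.
    """
    if model not in ("A", "AD"):
        raise ValueError("model must be 'A' or 'AD'")
    if model == "AD":
        g = g.autosomal()
    dos = g.dosages
    if np.isnan(dos).any():
        raise ValueError("missing dosages; impute before scanning")
    n = null.n
    if dos.shape[0] != n:
        raise ValueError("genotypes and null model differ in individuals")

    yw = null.whiten(null.y)
    Xw = null.whiten(null.X)
    Q, _ = np.linalg.qr(Xw)
    resid = lambda M: M - Q @ (Q.T @ M)
    yr = resid(yw)
    p_fix = null.X.shape[1]

    Jw = null.whiten(dos)
    Jr = resid(Jw)
    out = {
        "snp": g.snp_info["id"].to_numpy(),
        "chrom": g.snp_info["chrom"].to_numpy(),
        "pos": g.snp_info["pos"].to_numpy(),
        "ref": g.snp_info["ref"].to_numpy(),
        "alt": g.snp_info["alt"].to_numpy(),
        "alt_freq": dos.mean(axis=0) / 2.0,
    }
    tol = 1e-10 * n

    if model == "A":
        df = n - p_fix - 1
        sjj = np.einsum("ij,ij->j", Jr, Jr)
        testable = sjj > tol
        sjy = Jr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(testable, sjy / sjj, np.nan)
            se = np.where(testable, np.sqrt(1.0 / sjj), np.nan)
        t = alpha / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        out.update(alpha_hat=alpha, se_alpha=se, t_add=t, p_add=p,
                   not_testable=~testable)
        res = pd.DataFrame(out)
        res["model"] = "A"
        return res

    het = (dos == 1).astype(float)
    Kw = null.whiten(het)
    Kr = resid(Kw)
    df = n - p_fix - 2
    s11 = np.einsum("ij,ij->j", Jr, Jr)
    s22 = np.einsum("ij,ij->j", Kr, Kr)
    s12 = np.einsum("ij,ij->j", Jr, Kr)
    b1 = Jr.T @ yr
    b2 = Kr.T @ yr
    det = s11 * s22 - s12**2
    testable = s11 > tol
    dom_ok = testable & (det > tol * np.maximum(s11 * s22, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(dom_ok, (s22 * b1 - s12 * b2) / det,
                         np.where(testable, b1 / s11, np.nan))
        beta = np.where(dom_ok, (s11 * b2 - s12 * b1) / det, np.nan)
        se_a = np.where(dom_ok, np.sqrt(s22 / det),
                        np.where(testable, np.sqrt(1.0 / s11), np.nan))
        se_b = np.where(dom_ok, np.sqrt(s11 / det), np.nan)
    t_add = alpha / se_a
    t_dom = beta / se_b
    out.update(alpha_hat=alpha, se_alpha=se_a, t_add=t_add,
               p_add=2.0 * stats.t.sf(np.abs(t_add), df),
               beta_hat=beta, se_beta=se_b, t_dom=t_dom,
               p_dom=2.0 * stats.t.sf(np.abs(t_dom), df),
               not_testable=~testable, dominance_flagged=~dom_ok)
    res = pd.DataFrame(out)
    res["model"] = "AD"
    return res


class SnpScan:
    """Model object bundling a null fit and per-SNP GLS scans.

    Statsmodels-style: construct from data, ``fit()`` returns a
    :class:`SnpScanResults` carrying the per-SNP table, q-values and
    significant counts.
    """

    def __init__(self, genotypes: GenotypeMatrix, y, X, G, D=None,
                 model: str = "AD"):
        self.genotypes = genotypes
        self.model = model
        self.null = fit_null(y, X, G, D if model == "AD" else None)

    def fit(self, fdr_method: str = "storey",
            fdr_threshold: float = 0.01) -> "SnpScanResults":
        table = scan(self.genotypes, self.null, model=self.model)
        ok = ~table["not_testable"]
        q_add = np.full(len(table), np.nan)
        q_add[ok.to_numpy()] = compute_fdr(table.loc[ok, "p_add"].to_numpy(),
                                           method=fdr_method)
        table["q_add"] = q_add
        if self.model == "AD":
            dok = ~table["dominance_flagged"]
            q_dom = np.full(len(table), np.nan)
            q_dom[dok.to_numpy()] = compute_fdr(
                table.loc[dok, "p_dom"].to_numpy(), method=fdr_method)
            table["q_dom"] = q_dom
            r, cls = classify_gene_action(table["t_add"].to_numpy(),
                                          table["t_dom"].to_numpy())
            table["snp_ratio"] = r
            table["gene_action"] = cls
        return SnpScanResults(self, table, fdr_threshold)


@dataclass
class SnpScanResults:
    scan_model: SnpScan
    table: pd.DataFrame
    fdr_threshold: float

    def significant(self, effect: str = "add") -> pd.DataFrame:
        q = self.table[f"q_{effect}"]
        return self.table[q < self.fdr_threshold]

    def summary(self) -> str:
        lines = [f"Single-SNP scan, model {self.scan_model.model}, "
                 f"{len(self.table)} SNPs tested",
                 self.scan_model.null.components.summary(),
                 f"  significant additive SNPs (FDR<{self.fdr_threshold}): "
                 f"{len(self.significant('add'))}"]
        if self.scan_model.model == "AD":
            lines.append(
                f"  significant dominance SNPs (FDR<{self.fdr_threshold}): "
                f"{len(self.significant('dom'))}")
        return "\n".join(lines)


def scan_exact(g: GenotypeMatrix, y, X, G, D=None, model: str = "AD",
               snps=None, start=None) -> pd.DataFrame:
    """Per-SNP mixed-model refits: variance components re-estimated per SNP.

    The validation-grade counterpart of the two-stage :func:`scan` — each
    SNP's covariates join the fixed effects and the REML fit is repeated,
    so the background components can adapt to the tested SNP.  ``start``
    warm-starts every refit (typically the null-model components, so the
    per-SNP optimizations explore the same likelihood basin).  Quadratic
    cost per SNP; intended for small instances only.
    """
    if model == "AD":
        g = g.autosomal()
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    Gv = G.values if hasattr(G, "values") else np.asarray(G, float)
    covs = {"sigma_a2": Gv}
    if model == "AD":
        Dv = D.values if hasattr(D, "values") else np.asarray(D, float)
        covs["sigma_d2"] = Dv
    idx = range(g.n_snps) if snps is None else snps
    rows = []
    for j in idx:
        jvec = g.dosages[:, j]
        cols = [X, jvec[:, None]]
        if model == "AD":
            cols.append((jvec == 1).astype(float)[:, None])
        W = np.hstack(cols)
        vc_model = VarianceComponentModel(y, W, covs, name=f"exact-{model}")
        res = vc_model.fit(start=start)
        V = res.components["sigma_e2"] * np.eye(len(y))
        for name, K in covs.items():
            V += res.components[name] * K
        Vinv = np.linalg.inv(V)
        info = np.linalg.inv(W.T @ Vinv @ W)
        beta = info @ (W.T @ Vinv @ y)
        n_extra = 2 if model == "AD" else 1
        row = {"snp": g.snp_info["id"].iloc[j],
               "alpha_hat": beta[-n_extra],
               "se_alpha": float(np.sqrt(info[-n_extra, -n_extra]))}
        if model == "AD":
            row["beta_hat"] = beta[-1]
            row["se_beta"] = float(np.sqrt(info[-1, -1]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def compute_fdr(pvalues, method: str = "bh") -> np.ndarray:
    """q-values by Benjamini-Hochberg or Storey's method.

    Storey estimates the null proportion pi0 on the lambda grid
    0.05..0.95 (step 0.05) with a cubic smoother evaluated at the largest
    lambda, then scales the BH ladder; monotonicity is enforced from the
    largest p-value down.  With few tests or an unstable estimate pi0
    falls back to 1 (plain BH).
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
        if m >= 100:
            coef = np.polyfit(lam, pi0_lam, deg=3)
            pi0 = float(np.polyval(coef, lam.max()))
        else:
            pi0 = float(pi0_lam.mean())
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Gene action and effect identities
# ---------------------------------------------------------------------------

def classify_gene_action(t_add, t_dom):
    """Classify gene action from the t-ratio r = |t_dom / t_add|.

    Boundary values fall in the lower-r class (r=0.2 -> additive, r=0.8 ->
    partial, r=1.2 -> complete).  t_add = 0 gives an undefined ratio,
    reported as inf and classed over_dominance.
    Returns ``(r, classes)`` arrays.
    """
    t_add = np.atleast_1d(np.asarray(t_add, float))
    t_dom = np.atleast_1d(np.asarray(t_dom, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(t_dom / t_add)
    r = np.where((t_add == 0) & (t_dom != 0), np.inf, r)
    cls = np.select(
        [r <= 0.2, r <= 0.8, r <= 1.2],
        ["additive", "partial_dominance", "complete_dominance"],
        default="over_dominance")
    cls = np.where(np.isnan(r), "undefined", cls)
    return r, cls


def allele_substitution_effect(a, d, p):
    """Average allele-substitution effect alpha = a + (q - p) d, q = 1 - p.

    The quantity a purely additive scan estimates at a locus with additive
    effect a, dominance d and allele frequency p — opposite-signed a and d
    can cancel here while remaining separately estimable in model AD.
    """
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    return np.asarray(a, float) + (1.0 - 2.0 * p) * np.asarray(d, float)


# ---------------------------------------------------------------------------
# LD pruning of significant SNPs
# ---------------------------------------------------------------------------

def ld_prune_significant(g: GenotypeMatrix, significant_ids, r2: float = 0.2,
                         window: int = 50, step: int = 5,
                         region_gap: int = 1_000_000):
    """Sliding-window pairwise-r^2 pruning of significant SNPs.

    Within each window of ``window`` SNPs (advanced by ``step``), the later
    member of any pair with squared correlation above ``r2`` is removed.
    Returns ``(retained_ids, n_regions)`` where regions merge retained SNPs
    on the same chromosome within ``region_gap`` bp.
    """
    ids = list(g.snp_info["id"])
    pos_of = {s: i for i, s in enumerate(ids)}
    sig_idx = sorted(pos_of[s] for s in significant_ids)
    keep = set(sig_idx)
    dos = g.dosages
    for start in range(0, max(len(sig_idx) - 1, 1), step):
        block = [i for i in sig_idx[start:start + window] if i in keep]
        for ai in range(len(block)):
            if block[ai] not in keep:
                continue
            x = dos[:, block[ai]]
            if np.var(x) == 0:
                continue
            for bi in range(ai + 1, len(block)):
                if block[bi] not in keep:
                    continue
                yv = dos[:, block[bi]]
                if np.var(yv) == 0:
                    keep.discard(block[bi])
                    continue
                r = np.corrcoef(x, yv)[0, 1]
                if r * r > r2:
                    keep.discard(block[bi])
    retained = [ids[i] for i in sorted(keep)]
    info = g.snp_info.set_index("id").loc[retained]
    n_regions = 0
    last = {}
    for row in info.itertuples():
        c, p = row.chrom, row.pos
        if c not in last or p - last[c] > region_gap:
            n_regions += 1
        last[c] = p
    return retained, n_regions
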