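"""Observed and predicted heterosis in the diallel cross.

Observed heterosis compares crossbred performance to the mid-parent mean:
H = 100 * (mean(WY, YW) - mean(WW, YY)) / mean(WW, YY), with group means
taken as least-squares means adjusted for rack imbalance.

Predicted heterosis follows the classical dominance result: the expected
F1 deviation from the mid-parent equals sum_i d_i * y_i^2 where d_i is the
dominance effect and y_i the parental-line allele-frequency difference at
SNP i; dividing by the phenotypic SD puts traits on a common scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gio import CROSSES, GROUPS, PURE_LINES
from .simcross import LineFrequencies


def group_means(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Least-squares genetic-group means adjusted for rack effects.

    Fits y ~ group + rack by OLS and averages predictions over the observed
    rack levels, so rack imbalance between groups does not leak into the
    group contrast.  With balanced racks this equals the raw group means.
    """
    import statsmodels.formula.api as smf

    df = pheno[["group", "rack", trait]].dropna().copy()
    for grp in GROUPS:
        if (df["group"] == grp).sum() == 0:
            raise ValueError(f"no individuals in group {grp}")
    model = smf.ols(f"Q('{trait}') ~ C(group) + C(rack)", data=df).fit()
    racks = sorted(df["rack"].unique())
    means = {}
    for grp in GROUPS:
        pred = model.predict(pd.DataFrame({"group": grp, "rack": racks}))
        means[grp] = float(pred.mean())
    return pd.Series(means)


def observed_heterosis(means) -> float:
    """Crossbred advantage over the mid-parent, in percent.

    H = 100 * (mean(WY, YW) - mean(WW, YY)) / mean(WW, YY).  Undefined
    (ValueError) when the mid-parent mean is zero.
    """
    mp = (means["WW"] + means["YY"]) / 2.0
    if mp == 0:
        raise ValueError("mid-parent mean is zero; heterosis undefined")
    f1 = (means["WY"] + means["YW"]) / 2.0
    return 100.0 * (f1 - mp) / mp


def predicted_dy2(d_effects, freqs: LineFrequencies, pheno_sd: float,
                  mask=None) -> float:
    """Sum of d * y^2 over SNPs, standardized by the phenotypic SD.

    ``d_effects`` are per-SNP dominance effects in trait units (typically
    beta_hat from the AD scan); ``mask`` restricts the sum (e.g. to
    FDR-significant dominance SNPs).  Invariant to allele-label swaps: d is
    unchanged and the frequency difference only flips sign.
    """
    if pheno_sd <= 0:
        raise ValueError("pheno_sd must be positive")
    d = np.asarray(d_effects, float)
    y = freqs.freq_diff
    if d.shape != y.shape:
        raise ValueError("d_effects and frequencies differ in length")
    if mask is not None:
        mask = np.asarray(mask, bool)
        d, y = d[mask], y[mask]
    return float(np.sum(d * y**2) / pheno_sd)


def parental_frequencies(genotypes) -> LineFrequencies:
    """Alt-allele frequencies computed from the purebred groups only."""
    pw = genotypes.dosages[genotypes.group_mask("WW")]
    py = genotypes.dosages[genotypes.group_mask("YY")]
    return LineFrequencies(np.nanmean(pw, axis=0) / 2.0,
                           np.nanmean(py, axis=0) / 2.0)


def heterosis_table(pheno: pd.DataFrame, traits, scans: dict | None = None,
                    genotypes=None, fdr: float = 0.01) -> pd.DataFrame:
    """Per-trait group means, observed H, and dy^2 statistics.

    ``scans`` maps trait name to an AD scan table (with ``beta_hat``,
    ``t_add``, ``t_dom``, ``q_dom`` columns); when provided together with
    ``genotypes``, the dy^2 sums (all SNPs and FDR-significant dominance
    SNPs) and the mean significant SNP ratio are added.
    """
    rows = []
    freqs = parental_frequencies(genotypes) if genotypes is not None else None
    for trait in traits:
        means = group_means(pheno, trait)
        row = {"trait": trait, **means.to_dict(),
               "heterosis_pct": observed_heterosis(means)}
        if scans is not None and trait in scans and freqs is not None:
            tab = scans[trait]
            sd = float(pheno[trait].std())
            d = np.nan_to_num(tab["beta_hat"].to_numpy(), nan=0.0)
            row["sum_dy2_all"] = predicted_dy2(d, freqs, sd)
            sig = (tab["q_dom"] < fdr).to_numpy() | (tab["q_add"] < fdr).to_numpy()
            row["sum_dy2_significant"] = predicted_dy2(d, freqs, sd, mask=sig)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.abs(tab["t_dom"].to_numpy()
                                / tab["t_add"].to_numpy())
            vals = ratios[sig]
            vals = vals[np.isfinite(vals)]
            row["mean_snp_ratio_significant"] = (
                float(vals.mean()) if vals.size else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def ratio_heterosis_correlation(table: pd.DataFrame,
                                statistic: str = "sum_dy2_all"):
    """Pearson correlation across traits between observed H and a dy^2 statistic.

    Returns ``(r, p)`` with the usual t-based two-sided p-value.  Cumulative
    traits share underlying records, so the trait observations are not
    independent; a warning notes this.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 traits for a correlation")
    warnings.warn("traits share individuals and partial sums; the correlation "
                  "p-value treats them as independent observations",
                  stacklevel=2)
    r, p = stats.pearsonr(table["heterosis_pct"], table[statistic])
    return float(r), float(p)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform.

    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))
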