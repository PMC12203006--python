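"""Basic Manhattan, Q-Q and heterosis scatter plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def manhattan(table: pd.DataFrame, path, p_col: str = "p_add",
              fdr_col: str | None = "q_add", fdr: float = 0.01) -> None:
    """Manhattan plot of a scan table (chrom, pos, p-values)."""
    tab = table.dropna(subset=[p_col]).copy()
    chroms = list(dict.fromkeys(tab["chrom"]))
    offset, xpos, ticks = 0, [], []
    for c in chroms:
        sub = tab[tab["chrom"] == c]
        xpos.append(sub["pos"].to_numpy() + offset)
        ticks.append(offset + sub["pos"].max() / 2)
        offset += sub["pos"].max()
    x = np.concatenate(xpos)
    logp = -np.log10(np.clip(tab[p_col].to_numpy(), 1e-300, 1.0))
    colors = np.concatenate([
        np.full(len(xp), i % 2) for i, xp in enumerate(xpos)])
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.scatter(x, logp, s=4, c=np.where(colors == 0, "#4477aa", "#aaaaaa"))
    if fdr_col is not None and fdr_col in tab.columns:
        sig = tab[fdr_col].to_numpy() < fdr
        ax.scatter(x[sig], logp[sig], s=8, c="#cc3311")
    ax.set_xticks(ticks)
    ax.set_xticklabels(chroms, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq(pvalues, path) -> None:
    """Q-Q plot of observed vs expected -log10 p under the uniform null."""
    p = np.sort(np.asarray(pvalues, float))
    p = p[~np.isnan(p)]
    n = len(p)
    expected = -np.log10((np.arange(n) + 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.plot(expected, observed, ".", ms=3)
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], "k-", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heterosis_scatter(table: pd.DataFrame, path,
                      statistic: str = "sum_dy2_all") -> None:
    """Observed heterosis vs a dy^2 statistic across traits."""
    fig, ax = plt.subplots(figsize=(3.6, 3.2))
    ax.scatter(table[statistic], table["heterosis_pct"])
    for row in table.itertuples():
        ax.annotate(row.trait, (getattr(row, statistic), row.heterosis_pct),
                    fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(statistic)
    ax.set_ylabel("observed heterosis (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
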