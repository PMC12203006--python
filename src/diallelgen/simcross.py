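"""Seeded synthetic diallel-cross generator with known genetic architecture.

Emulates the layer-cross design the analysis pipeline assumes: two divergent
purebred lines (WW, YY) kept under Hardy-Weinberg proportions within line,
plus their reciprocal F1 crosses (WY, YW), which on autosomes are
identically distributed (reciprocal differences in real data are
sex-linked/parent-of-origin phenomena and are deliberately not modelled).

Line divergence follows the Balding-Nichols model: per SNP an ancestral
frequency ``p`` is drawn, then each line frequency is Beta-distributed with
mean ``p`` and variance ``F * p * (1 - p)``.  Phenotypes combine sparse QTL
(additive effect ``a`` = half the homozygote difference; dominance ``d`` =
heterozygote deviation from the homozygote midpoint), a polygenic
background of many small effects over the non-QTL SNPs, rack fixed effects,
and Gaussian noise.  Expression data carry planted cis and trans eQTLs.

Every draw flows from ``config.seed``; identical configs give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix, GROUPS, PURE_LINES, STAGE_TRAITS, derive_traits

# salts keeping the per-operation random streams independent
_SALT_FREQ, _SALT_GENO, _SALT_EFFECT, _SALT_PHENO, _SALT_EXPR = range(5)


@dataclass
class SimConfig:
    """Configuration of the synthetic diallel cross.

    Group sizes default to the real design (210 WW, 268 YY, 240 WY, 286 YW
    hens); the line-divergence parameter ``divergence`` is the
    Balding-Nichols F, defaulting to 0.25 for strongly differentiated
    purebred lines.  ``target_sigma_a2``/``target_sigma_d2``, when set,
    rescale the drawn effect vectors so the realized genic additive and
    dominance variances hit those values exactly.
    """

    n_snps: int = 5000
    n_qtl: int = 50
    group_sizes: dict = field(default_factory=lambda: {
        "WW": 210, "YY": 268, "WY": 240, "YW": 286})
    divergence: float = 0.25
    ancestral_freq_range: tuple = (0.05, 0.95)
    additive_effect_sd: float = 1.0
    dominance_effect_sd: float = 1.0
    dominance_mode: str = "mixed"  # none | partial | complete | over | mixed
    polygenic_var: float = 10.0
    polygenic_dominance_var: float = 0.0
    residual_var: float = 60.0
    target_sigma_a2: float | None = None
    target_sigma_d2: float | None = None
    family_structure: bool = True
    n_sires_per_line: int = 30
    n_dams_per_line: int = 120
    n_racks: int = 8
    rack_effect_sd: float = 2.0
    n_genes: int = 200
    cis_fraction: float = 0.15
    trans_fraction: float = 0.10
    expression_noise_sd: float = 1.0
    n_expression_samples: int = 120
    n_chromosomes: int = 28
    chromosome_length: int = 20_000_000
    stage_baselines: dict = field(default_factory=lambda: {
        "CEN200": 35.0, "EN300": 80.0, "EN400": 65.0, "EN500": 60.0,
        "EN600": 45.0, "EN700": 40.0})
    stage_scales: dict = field(default_factory=lambda: {
        "CEN200": 0.4, "EN300": 0.7, "EN400": 1.0, "EN500": 1.3,
        "EN600": 1.1, "EN700": 0.8})
    round_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.n_qtl <= 0 or self.n_racks <= 0:
            raise ValueError("counts must be positive")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if not 0.0 < self.divergence < 1.0:
            raise ValueError(f"divergence must lie in (0, 1), got {self.divergence}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        for name in ("polygenic_var", "polygenic_dominance_var", "residual_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cis_fraction", "trans_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cis_fraction + self.trans_fraction > 1.0:
            raise ValueError("cis_fraction + trans_fraction must not exceed 1")
        if self.dominance_mode not in ("none", "partial", "complete", "over", "mixed"):
            raise ValueError(f"unknown dominance_mode {self.dominance_mode!r}")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in group_sizes: {sorted(unknown)}")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), salt])


@dataclass
class LineFrequencies:
    """Per-SNP alternative-allele frequencies in the two purebred lines."""

    p_W: np.ndarray
    p_Y: np.ndarray

    def __post_init__(self) -> None:
        self.p_W = np.asarray(self.p_W, float)
        self.p_Y = np.asarray(self.p_Y, float)
        if self.p_W.shape != self.p_Y.shape:
            raise ValueError("p_W and p_Y differ in length")
        for arr in (self.p_W, self.p_Y):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def freq_diff(self) -> np.ndarray:
        """Parental-line frequency difference y = p_W - p_Y per SNP."""
        return self.p_W - self.p_Y


@dataclass
class QtlEffects:
    """Sparse QTL architecture: SNP indices with additive/dominance effects."""

    qtl_index: np.ndarray
    a: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.qtl_index = np.asarray(self.qtl_index, int)
        self.a = np.asarray(self.a, float)
        self.d = np.asarray(self.d, float)
        if len(set(self.qtl_index.tolist())) != len(self.qtl_index):
            raise ValueError("duplicate QTL indices")
        if not (len(self.qtl_index) == len(self.a) == len(self.d)):
            raise ValueError("qtl_index, a, d must have equal length")


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype set, the downstream oracle.

    ``sigma_a2``/``sigma_d2`` are realized genic variances of the unit-scale
    genetic value (additive: sum of 2pq a_i^2-type terms via the centered
    dosage coding; dominance likewise via the heterozygosity coding);
    ``analytic_heterosis`` maps trait name to the expected F1 deviation from
    the mid-parent mean, in trait units.
    """

    line_freqs: LineFrequencies
    effects: QtlEffects
    snp_effects_a: np.ndarray
    snp_effects_d: np.ndarray
    sigma_a2: float
    sigma_d2: float
    sigma_e2: float
    analytic_heterosis: dict

    def __post_init__(self) -> None:
        for name in ("sigma_a2", "sigma_d2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def draw_line_frequencies(config: SimConfig) -> LineFrequencies:
    """Draw per-line allele frequencies under the Balding-Nichols model.

    Each SNP gets an ancestral frequency uniform on
    ``config.ancestral_freq_range``; each line frequency is then
    Beta(p(1-F)/F, (1-p)(1-F)/F), so E[p_line] = p and
    Var[p_line] = F p (1-p).
    """
    rng = config.rng(_SALT_FREQ)
    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    F = config.divergence
    alpha = p * (1 - F) / F
    beta = (1 - p) * (1 - F) / F
    p_w = rng.beta(alpha, beta)
    p_y = rng.beta(alpha, beta)
    return LineFrequencies(p_w, p_y)


def _snp_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place SNPs on autosomes 1..n_chromosomes with sorted unique positions."""
    chroms = np.sort(rng.integers(1, config.n_chromosomes + 1, size=config.n_snps))
    pos = np.empty(config.n_snps, dtype=int)
    for c in np.unique(chroms):
        m = chroms == c
        k = int(m.sum())
        pos[m] = np.sort(rng.choice(
            np.arange(1, config.chromosome_length + 1), size=k, replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=config.n_snps)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return pd.DataFrame({
        "id": [f"snp{i}" for i in range(config.n_snps)],
        "chrom": chroms.astype(str), "pos": pos, "ref": ref, "alt": alt})


def simulate_genotypes(freqs: LineFrequencies, config: SimConfig,
                       return_pedigree: bool = False):
    """Draw diallel-cross genotypes from the line frequencies.

    With ``family_structure`` (the default, mirroring the real mating
    design) each line has a finite set of sires and dams drawn HWE from the
    line frequencies; every offspring receives one Mendelian allele from a
    random sire of the sire line and one from a random dam of the dam line.
    The same sires produce the purebred and the crossbred progeny of their
    line, creating the half/full-sib families the relationship matrices
    rely on.  Without it, every individual draws alleles directly from the
    line frequencies (unrelated panel; exact HWE within line).

    WY has White Leghorn-type (W) sires, YW has local-breed (Y) sires;
    on autosomes the two reciprocal crosses are identically distributed.
    With ``return_pedigree`` a ``(GenotypeMatrix, Pedigree)`` pair is
    returned (founders listed with unknown parents but no genotypes).
    """
    if len(freqs.p_W) != config.n_snps:
        raise ValueError("frequencies inconsistent with config.n_snps")
    rng = config.rng(_SALT_GENO)
    snp_info = _snp_map(config, rng)
    blocks, ids, groups = [], [], []
    # (sire line, dam line) per group
    mating = {"WW": ("W", "W"), "YY": ("Y", "Y"),
              "WY": ("W", "Y"), "YW": ("Y", "W")}
    line_freq = {"W": freqs.p_W, "Y": freqs.p_Y}

    if config.family_structure:
        parents = {}
        for line in ("W", "Y"):
            p = line_freq[line]
            for role, count in (("sire", config.n_sires_per_line),
                                ("dam", config.n_dams_per_line)):
                dos = (rng.random((count, config.n_snps)) < p).astype(float)
                dos += rng.random((count, config.n_snps)) < p
                parents[line, role] = dos
        ped_rows = []
        for line in ("W", "Y"):
            for role in ("sire", "dam"):
                for i in range(parents[line, role].shape[0]):
                    ped_rows.append((f"{line}{role}{i:03d}", None, None))
        for grp in GROUPS:
            n = int(config.group_sizes.get(grp, 0))
            if n == 0:
                continue
            sline, dline = mating[grp]
            sires = parents[sline, "sire"]
            dams = parents[dline, "dam"]
            s_idx = rng.integers(0, sires.shape[0], size=n)
            d_idx = rng.integers(0, dams.shape[0], size=n)
            dos = (rng.random((n, config.n_snps)) < sires[s_idx] / 2.0).astype(float)
            dos += rng.random((n, config.n_snps)) < dams[d_idx] / 2.0
            blocks.append(dos)
            for i in range(n):
                iid = f"{grp}_{i:04d}"
                ids.append(iid)
                ped_rows.append((iid, f"{sline}sire{s_idx[i]:03d}",
                                 f"{dline}dam{d_idx[i]:03d}"))
            groups.extend([grp] * n)
    else:
        ped_rows = None
        for grp in GROUPS:
            n = int(config.group_sizes.get(grp, 0))
            if n == 0:
                continue
            sline, dline = mating[grp]
            dos = (rng.random((n, config.n_snps)) < line_freq[sline]).astype(float)
            dos += rng.random((n, config.n_snps)) < line_freq[dline]
            blocks.append(dos)
            ids.extend(f"{grp}_{i:04d}" for i in range(n))
            groups.extend([grp] * n)

    dosages = np.vstack(blocks)
    sample_info = pd.DataFrame({"id": ids, "group": groups})
    g = GenotypeMatrix(dosages, snp_info, sample_info)
    if return_pedigree:
        from .gio import Pedigree

        if ped_rows is None:
            ped_rows = [(i, None, None) for i in ids]
        ped = Pedigree(pd.DataFrame(ped_rows, columns=["id", "sire", "dam"]))
        return g, ped
    return g


# ---------------------------------------------------------------------------
# Effects and phenotypes
# ---------------------------------------------------------------------------

def draw_qtl_effects(config: SimConfig) -> QtlEffects:
    """Draw QTL positions and (a, d) effects per ``config.dominance_mode``.

    Modes map the classical gene-action degrees: ``none`` d=0; ``partial``
    d = 0.5|a|; ``complete`` d = |a|; ``over`` d = 1.5|a| (sign from
    ``dominance_effect_sd`` draws); ``mixed`` draws d independently
    N(0, dominance_effect_sd^2).
    """
    rng = config.rng(_SALT_EFFECT)
    idx = np.sort(rng.choice(config.n_snps, size=config.n_qtl, replace=False))
    a = rng.normal(0.0, config.additive_effect_sd, size=config.n_qtl)
    mode = config.dominance_mode
    if mode == "none":
        d = np.zeros(config.n_qtl)
    elif mode == "mixed":
        d = rng.normal(0.0, config.dominance_effect_sd, size=config.n_qtl)
    else:
        degree = {"partial": 0.5, "complete": 1.0, "over": 1.5}[mode]
        sign = np.where(rng.random(config.n_qtl) < 0.5, -1.0, 1.0)
        d = degree * np.abs(a) * sign
    return QtlEffects(idx, a, d)


def _genic_variances(dosages: np.ndarray, a_all: np.ndarray,
                     d_all: np.ndarray) -> tuple[float, float]:
    """Genic variances in the statistical (orthogonal) parameterization.

    The genotypic effects (a, d) map to an average allele-substitution
    effect alpha = a + (q - p) d and a dominance deviation d, so the
    additive variance is sum 2pq alpha^2 and the dominance variance
    sum (2pq)^2 d^2 — exactly the scalings under which the VanRaden G and
    Vitezica D matrices make REML consistent with the planted effects.
    """
    p = dosages.mean(axis=0) / 2.0
    two_pq = 2.0 * p * (1.0 - p)
    alpha = a_all + (1.0 - 2.0 * p) * d_all
    sigma_a2 = float(np.sum(two_pq * alpha**2))
    sigma_d2 = float(np.sum(two_pq**2 * d_all**2))
    return sigma_a2, sigma_d2


def simulate_phenotypes(genotypes: GenotypeMatrix, effects: QtlEffects,
                        config: SimConfig):
    """Generate per-stage egg-count phenotypes and the matching truth.

    The unit-scale genetic value is ``sum_i (j_i a_i + h_i d_i)`` over QTL
    plus a polygenic sum of small additive effects over the non-QTL SNPs;
    each stage trait scales this value by ``stage_scales`` and adds its own
    rack effect and Gaussian residual.  Cumulative traits are exact partial
    sums of the stage counts (via :func:`~diallelgen.gio.derive_traits`).

    Returns ``(phenotypes, truth)`` where phenotypes is a DataFrame with
    id, group, rack and all trait columns.
    """
    if np.any(effects.qtl_index >= genotypes.n_snps) or np.any(effects.qtl_index < 0):
        raise IndexError("QTL index out of range")
    rng = config.rng(_SALT_PHENO)
    n = genotypes.n_individuals
    dos = genotypes.dosages
    if np.isnan(dos).any():
        raise ValueError("phenotype simulation needs complete genotypes")

    a_all = np.zeros(genotypes.n_snps)
    d_all = np.zeros(genotypes.n_snps)
    a_all[effects.qtl_index] = effects.a
    d_all[effects.qtl_index] = effects.d
    # polygenic background: small additive effects on every non-QTL SNP,
    # scaled so the genic polygenic variance matches config.polygenic_var
    non_qtl = np.setdiff1d(np.arange(genotypes.n_snps), effects.qtl_index)
    p = dos.mean(axis=0) / 2.0
    two_pq = 2.0 * p * (1.0 - p)
    if config.polygenic_var > 0 and len(non_qtl) > 0:
        w = rng.normal(0.0, 1.0, size=len(non_qtl))
        scale = np.sum(two_pq[non_qtl] * w**2)
        if scale > 0:
            a_all[non_qtl] = w * np.sqrt(config.polygenic_var / scale)
    if config.polygenic_dominance_var > 0 and len(non_qtl) > 0:
        wd = rng.normal(0.0, 1.0, size=len(non_qtl))
        scale = np.sum(two_pq[non_qtl] ** 2 * wd**2)
        if scale > 0:
            d_all[non_qtl] = wd * np.sqrt(config.polygenic_dominance_var / scale)

    # exact calibration to requested genic variances (statistical scale):
    # dominance first (it only involves d), then the additive target is hit
    # by scaling a in sum 2pq (c a + (q - p) d)^2 = target, a quadratic in c
    if config.target_sigma_d2 is not None:
        sd2_raw = float(np.sum(two_pq**2 * d_all**2))
        if sd2_raw > 0:
            d_all *= np.sqrt(config.target_sigma_d2 / sd2_raw)
    if config.target_sigma_a2 is not None:
        qp = 1.0 - 2.0 * p
        A = float(np.sum(two_pq * a_all**2))
        B = float(np.sum(two_pq * a_all * qp * d_all))
        C = float(np.sum(two_pq * (qp * d_all) ** 2))
        T = config.target_sigma_a2
        if A > 0:
            disc = B * B - A * (C - T)
            if disc < 0:
                raise ValueError(
                    "target_sigma_a2 unreachable: dominance effects alone "
                    f"contribute {C:.3f} to the additive variance")
            a_all *= (-B + np.sqrt(disc)) / A

    het = (dos == 1).astype(float)
    u = dos @ a_all          # additive genetic value (uncentered; the
    v = het @ d_all          # constant shift is absorbed by the intercept)
    sigma_a2, sigma_d2 = _genic_variances(dos, a_all, d_all)

    racks = rng.integers(0, config.n_racks, size=n)
    base_traits = list(config.stage_baselines)
    pheno = genotypes.sample_info[["id", "group"]].copy()
    pheno["rack"] = [f"rack{r}" for r in racks]
    rack_levels = rng.normal(0.0, config.rack_effect_sd,
                             size=(len(base_traits), config.n_racks))
    for t_i, trait in enumerate(base_traits):
        c = float(config.stage_scales[trait])
        e = rng.normal(0.0, np.sqrt(config.residual_var), size=n)
        y = (config.stage_baselines[trait] + c * (u + v)
             + rack_levels[t_i, racks] + e)
        if config.round_counts:
            y = np.round(y)
        pheno[trait] = np.maximum(y, 0.0)  # egg counts are non-negative
    if {"CEN200", *STAGE_TRAITS} <= set(pheno.columns):
        pheno = derive_traits(pheno)

    analytic = _analytic_by_trait(d_all, genotypes, config)
    truth = SimTruth(
        line_freqs=_empirical_line_freqs(genotypes),
        effects=effects, snp_effects_a=a_all, snp_effects_d=d_all,
        sigma_a2=sigma_a2, sigma_d2=sigma_d2,
        sigma_e2=float(config.residual_var),
        analytic_heterosis=analytic)
    return pheno, truth


def _empirical_line_freqs(genotypes: GenotypeMatrix) -> LineFrequencies:
    """Realized purebred allele frequencies (the quantity y in dy^2 uses)."""
    pw = genotypes.dosages[genotypes.group_mask("WW")].mean(axis=0) / 2.0
    py = genotypes.dosages[genotypes.group_mask("YY")].mean(axis=0) / 2.0
    return LineFrequencies(pw, py)


def analytic_heterosis(freqs: LineFrequencies, effects: QtlEffects) -> float:
    """Expected F1 deviation from the mid-parent mean: sum_i d_i (p_W - p_Y)^2.

    Under random mating within lines, the F1 heterozygosity excess over the
    parental average at a locus is exactly (p_W - p_Y)^2, so the dominance
    effects alone drive the expected heterosis.
    """
    y = freqs.freq_diff[effects.qtl_index]
    return float(np.sum(effects.d * y**2))


def _analytic_by_trait(d_all: np.ndarray, genotypes: GenotypeMatrix,
                       config: SimConfig) -> dict:
    lf = _empirical_line_freqs(genotypes)
    base = float(np.sum(d_all * lf.freq_diff**2))
    out = {t: base * float(config.stage_scales[t]) for t in config.stage_baselines}
    if {"CEN200", *STAGE_TRAITS} <= set(out):
        for x in (300, 400, 500, 600, 700):
            out[f"CEN{x}"] = out[f"CEN{x-100}"] + out[f"EN{x}"]
        out["EN300_500"] = out["EN400"] + out["EN500"]
        out["EN500_700"] = out["EN600"] + out["EN700"]
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(genotypes: GenotypeMatrix, config: SimConfig):
    """Simulate a gene x sample TPM-like matrix with planted eQTLs.

    A ``cis_fraction`` of genes get a causal SNP within 1 Mb of their TSS,
    a ``trans_fraction`` a causal SNP on another chromosome; the rest are
    null.  Expression = baseline + group effect + age effect + genotype
    effect + noise, clipped at zero (TPM is non-negative).  Samples are
    drawn evenly from the four genetic groups.

    Returns ``(expression, gene_info, covariates, truth)`` where truth is a
    DataFrame of planted (gene, snp, beta, locality) rows.
    """
    rng = config.rng(_SALT_EXPR)
    n_total = genotypes.n_individuals
    n_samp = min(config.n_expression_samples, n_total)
    # stratified sample across groups
    idx = []
    per = n_samp // len(GROUPS)
    for grp in GROUPS:
        cand = np.flatnonzero(genotypes.group_mask(grp))
        take = min(per, len(cand))
        idx.extend(rng.choice(cand, size=take, replace=False))
    idx = np.sort(np.asarray(idx, int))
    sub = genotypes.subset(individuals=idx)

    n_genes = config.n_genes
    n_cis = int(round(config.cis_fraction * n_genes))
    n_trans = int(round(config.trans_fraction * n_genes))
    kinds = np.array(["cis"] * n_cis + ["trans"] * n_trans
                     + ["null"] * (n_genes - n_cis - n_trans))
    rng.shuffle(kinds)

    snp_chrom = sub.snp_info["chrom"].to_numpy()
    snp_pos = sub.snp_info["pos"].to_numpy()
    chrom_set = np.unique(snp_chrom)
    # a planted eQTL must segregate in the sampled individuals to be a
    # real signal, so causal SNPs are drawn among those with MAF >= 0.1
    sub_freq = sub.dosages.mean(axis=0) / 2.0
    eligible = np.flatnonzero(np.minimum(sub_freq, 1 - sub_freq) >= 0.1)
    if eligible.size == 0:
        eligible = np.arange(sub.n_snps)

    gene_rows, truth_rows = [], []
    effect = np.zeros((n_genes, sub.n_individuals))
    beta_sd = 2.0 * config.expression_noise_sd
    for gi in range(n_genes):
        kind = kinds[gi]
        gene_id = f"gene{gi}"
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "cis":
            s = int(rng.choice(eligible))
            chrom = snp_chrom[s]
            tss = int(snp_pos[s] + rng.integers(-900_000, 900_001))
            tss = max(1, tss)
        elif kind == "trans":
            s = int(rng.choice(eligible))
            others = chrom_set[chrom_set != snp_chrom[s]]
            chrom = str(rng.choice(others))
            tss = int(rng.integers(1, config.chromosome_length))
        else:
            s = -1
            chrom = str(rng.choice(chrom_set))
            tss = int(rng.integers(1, config.chromosome_length))
        gene_rows.append((gene_id, chrom, tss, strand))
        if s >= 0:
            beta = float(rng.normal(0, beta_sd))
            # keep planted effects away from zero so they are real signals
            beta = float(np.sign(beta) * max(abs(beta), beta_sd))
            effect[gi] = beta * sub.dosages[:, s]
            truth_rows.append((gene_id, sub.snp_info["id"].iloc[s], beta, kind))

    gene_info = pd.DataFrame(gene_rows, columns=["id", "chrom", "tss", "strand"])
    ages = np.tile([150, 250, 320, 500, 700],
                   int(np.ceil(sub.n_individuals / 5)))[: sub.n_individuals]
    group_eff = {g: rng.normal(0, 1.0) for g in GROUPS}
    grp_vec = np.array([group_eff[g] for g in sub.groups])
    age_slope = rng.normal(0, 0.002, size=n_genes)

    base = 50.0
    noise = rng.normal(0, config.expression_noise_sd,
                       size=(n_genes, sub.n_individuals))
    values = (base + effect + grp_vec[None, :]
              + age_slope[:, None] * (ages - 320)[None, :] + noise)
    values = np.maximum(values, 0.0)

    covariates = pd.DataFrame({"id": sub.sample_info["id"],
                               "group": sub.sample_info["group"],
                               "age": ages})
    expression = pd.DataFrame(values, index=gene_info["id"],
                              columns=sub.sample_info["id"])
    truth = pd.DataFrame(truth_rows, columns=["gene", "snp", "beta", "locality"])
    return expression, gene_info, covariates, truth


# ---------------------------------------------------------------------------
# Convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class SimData:
    config: SimConfig
    freqs: LineFrequencies
    genotypes: GenotypeMatrix
    effects: QtlEffects
    phenotypes: pd.DataFrame
    truth: SimTruth


def simulate_diallel(config: SimConfig) -> SimData:
    """Run the full generator: frequencies -> genotypes -> phenotypes."""
    freqs = draw_line_frequencies(config)
    genotypes = simulate_genotypes(freqs, config)
    effects = draw_qtl_effects(config)
    pheno, truth = simulate_phenotypes(genotypes, effects, config)
    return SimData(config, freqs, genotypes, effects, pheno, truth)


def config_to_yaml(config: SimConfig, path) -> None:
    import yaml

    d = asdict(config)
    d["ancestral_freq_range"] = list(d["ancestral_freq_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "ancestral_freq_range" in d:
        d["ancestral_freq_range"] = tuple(d["ancestral_freq_range"])
    return SimConfig(**d)
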