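"""Seeded synthetic cohorts with planted co-methylation structure.

The generator works on the M-value scale (log2 methylation odds), where
array noise is approximately homoscedastic, and maps to beta values through
the logistic transform ``beta = 2**M / (2**M + 1)``.  Each planted module is
a one-factor model: member CpGs load on a shared per-sample eigengene, whose
mean differs between trait groups for trait-associated modules.  Confounders
(age, sex, Braak stage, neuronal proportion, plate) add per-CpG linear
effects so the residualization stage has real work to do.

Genotypes are latent-Gaussian AR(1) blocks thresholded to Hardy-Weinberg
dosages, giving tunable LD decay; GWAS summary statistics come from an
explicit independent panel drawn from the same LD process so LD is
consistent between the mQTL and GWAS panels by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from comethnet.types import (
    AssocStats,
    BetaMatrix,
    ConfigurationError,
    GenotypeSet,
    GroundTruth,
    GwasSpec,
    SimulationConfig,
)

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "simulate_cohort",
    "simulate_genotypes",
    "plant_mqtl_effects",
    "simulate_gwas_summary",
    "simulate_specificity",
]


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Logistic map from M-values to beta values, beta = 2^M / (2^M + 1)."""
    # equivalent to expit(m * log 2); numerically stable for large |m|
    from scipy.special import expit

    return expit(np.asarray(m, dtype=float) * np.log(2.0))


def beta_to_m(beta: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Inverse logistic map, M = log2(beta / (1 - beta)), clipped away from {0,1}."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def _cpg_positions(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic CpG coordinates: fixed spacing on synthetic chromosomes."""
    n = config.n_cpgs
    per_chrom = config.chrom_size
    chrom = np.array([f"chr{1 + i // per_chrom}" for i in range(n)])
    offset = np.arange(n) % per_chrom
    pos = (offset + 1) * config.cpg_spacing
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "genes": [[] for _ in range(n)]},
        index=pd.Index([f"cg{i:07d}" for i in range(n)], name="cpg"),
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a methylation cohort with planted modules and confounders.

    Returns the beta matrix, a sample table (trait + covariates) and the
    planted ground truth.  Module CpG M-values follow
    ``loading * ME + covariate effects + N(0, noise_sd^2)`` plus a per-CpG
    baseline; background CpGs omit the factor term.  Trait-associated
    modules shift the eigengene mean by ``trait_effect_d`` standard
    deviations between trait groups.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_cpgs

    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    trait = (rng.random(n) < config.trait_prevalence).astype(int)
    age = rng.normal(80.0, 9.0, n)
    sex = rng.integers(0, 2, n)
    braak = np.clip(np.rint(rng.normal(5.4, 0.9, n)), 0, 6).astype(int)
    prop_neuron = np.clip(rng.normal(0.35, 0.08, n), 0.05, 0.8)
    plate = rng.integers(1, 5, n)
    samples = pd.DataFrame(
        {
            "trait": trait,
            "age": age,
            "sex": sex,
            "braak": braak,
            "prop_neuron": prop_neuron,
            "plate": [f"P{j}" for j in plate],
        },
        index=sample_ids,
    )

    eff = config.covariate_effects
    plate_offsets = rng.normal(0.0, 1.0, 4)
    # per-CpG covariate coefficient signs/scales vary across the array
    coef = rng.normal(0.0, 1.0, (p, 4))
    cov_design = np.column_stack(
        [
            (age - age.mean()) * eff.get("age", 0.0),
            (sex - sex.mean()) * eff.get("sex", 0.0),
            (braak - braak.mean()) * eff.get("braak", 0.0),
            (prop_neuron - prop_neuron.mean()) * eff.get("prop_neuron", 0.0),
        ]
    )
    m_values = coef @ cov_design.T
    m_values += eff.get("plate", 0.0) * plate_offsets[plate - 1][None, :]
    m_values += rng.normal(0.0, 2.0, p)[:, None]  # per-CpG baseline level
    m_values += rng.normal(0.0, config.noise_sd, (p, n))

    labels = np.zeros(p, dtype=int)
    trait_modules: list[int] = []
    start = 0
    tc = trait - trait.mean()
    tc_unit = tc / tc.std() if tc.std() > 0 else tc
    for k, mod in enumerate(config.module_spec, start=1):
        idx = np.arange(start, start + mod.size)
        start += mod.size
        labels[idx] = k
        me = rng.normal(0.0, 1.0, n)
        if mod.trait_effect_d != 0.0:
            me = me + mod.trait_effect_d * trait
            trait_modules.append(k)
        me = (me - me.mean()) / me.std()
        # graded hubness: per-CpG |loading| spread around the module mean so
        # intramodular connectivity has a genuine hub-to-periphery gradient;
        # random signs because unsigned networks cluster hyper- and
        # hypomethylated members together
        sign = rng.choice([-1.0, 1.0], size=mod.size)
        lo = max(mod.loading_mean - 0.2, 0.05)
        hi = min(mod.loading_mean + 0.2, 0.98)
        loading = rng.uniform(lo, hi, mod.size) * sign
        # per-CpG baseline methylation level, as in the background
        base = rng.normal(0.0, 2.0, mod.size)[:, None]
        noise = rng.normal(0.0, config.noise_sd, (mod.size, n))
        cov_part = coef[idx] @ cov_design.T
        cov_part += eff.get("plate", 0.0) * plate_offsets[plate - 1][None, :]
        m_values[idx] = base + loading[:, None] * me[None, :] + cov_part + noise

    cpg_map = _cpg_positions(config)
    beta = m_to_beta(m_values)
    beta_mat = BetaMatrix(beta, cpg_map.index, sample_ids, cpg_map)
    truth = GroundTruth(
        true_module_labels=pd.Series(labels, index=cpg_map.index, name="module"),
        true_trait_module_ids=trait_modules,
        true_mqtl_pairs=[],
        true_shared_causal_snps=[],
    )
    return beta_mat, samples, truth


def _draw_latent_blocks(
    rng: np.random.Generator, n_snps: int, n_samples: int, block: int, rho: float
) -> np.ndarray:
    """Latent Gaussians with AR(1) correlation rho within consecutive blocks."""
    z = np.empty((n_snps, n_samples))
    innov_sd = np.sqrt(1.0 - rho**2)
    for s in range(0, n_snps, block):
        e = rng.normal(0.0, 1.0, (min(block, n_snps - s), n_samples))
        z[s] = e[0]
        for j in range(1, e.shape[0]):
            z[s + j] = rho * z[s + j - 1] + innov_sd * e[j]
    return z


def _threshold_to_dosage(z: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Threshold latent normals at Hardy-Weinberg genotype frequencies."""
    q_hom_ref = stats.norm.ppf((1.0 - maf) ** 2)[:, None]
    q_het = stats.norm.ppf((1.0 - maf) ** 2 + 2.0 * maf * (1.0 - maf))[:, None]
    return (z > q_hom_ref).astype(float) + (z > q_het)


def simulate_genotypes(
    config: SimulationConfig, n_samples: int | None = None, seed: int | None = None
) -> GenotypeSet:
    """Simulate LD-blocked genotype dosages at Hardy-Weinberg frequencies.

    Each block of ``ld_block_size`` consecutive SNPs shares an AR(1) latent
    Gaussian with autocorrelation ``ld_rho``; per-SNP MAFs are drawn
    uniformly from ``maf_range``.  Positions sit at fixed ``snp_spacing`` on
    the same synthetic chromosomes as the CpGs.
    """
    config.validate()
    n = config.n_samples if n_samples is None else n_samples
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    # allele frequencies are similar within an LD block (as in real haplotype
    # blocks); a shared block MAF with small jitter keeps strong dosage r2
    # attainable between neighbours
    lo, hi = config.maf_range
    n_blocks = -(-config.n_snps // config.ld_block_size)
    block_maf = rng.uniform(lo, hi, n_blocks)
    maf = np.repeat(block_maf, config.ld_block_size)[: config.n_snps]
    maf = np.clip(maf + rng.normal(0.0, 0.01, config.n_snps), lo, hi)
    z = _draw_latent_blocks(rng, config.n_snps, n, config.ld_block_size, config.ld_rho)
    dos = _threshold_to_dosage(z, maf)
    if config.missing_rate > 0:
        dos[rng.random(dos.shape) < config.missing_rate] = np.nan

    per_chrom = config.chrom_size
    chrom = [f"chr{1 + i // per_chrom}" for i in range(config.n_snps)]
    pos = (np.arange(config.n_snps) % per_chrom + 1) * config.snp_spacing + 37
    snp_map = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"},
        index=pd.Index([f"rs{i:07d}" for i in range(config.n_snps)], name="snp"),
    )
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    sim_params = {"maf": maf, "block": config.ld_block_size, "rho": config.ld_rho}
    return GenotypeSet(dos, snp_map, sample_ids, sim_params)


def plant_mqtl_effects(
    beta: BetaMatrix, geno: GenotypeSet, spec
) -> tuple[BetaMatrix, list[tuple[str, str]]]:
    """Add additive dosage effects to CpG M-values at requested variance explained.

    For each ``(snp_index, cpg_index, r2_target)`` the effect size b solves
    ``cor(beta(M + b*d), d)^2 = r2_target`` in the realized sample: because
    the logistic map compresses M-value shifts near the boundaries of
    [0, 1], b is calibrated on the beta scale the matrix is returned on
    (and that downstream regression consumes), accounting for the chance
    covariance between the dosage and the pre-existing values.  Samples
    with missing dosage are left untouched.
    """
    m = beta_to_m(beta.values).copy()
    pairs: list[tuple[str, str]] = []
    for s in spec:
        if s.r2_target >= 1:
            raise ConfigurationError("r2_target must be < 1")
        if s.r2_target == 0:
            pairs.append((geno.snp_ids[s.snp_index], beta.cpg_ids[s.cpg_index]))
            continue
        d = geno.dosages[s.snp_index]
        ok = ~np.isnan(d)
        v = d[ok].var()
        if v == 0:
            raise ConfigurationError("cannot plant mQTL on monomorphic SNP")
        y = m[s.cpg_index, ok]
        s2 = y.var()
        c = np.cov(y, d[ok], ddof=0)[0, 1]
        r2 = s.r2_target
        # M-scale solution of cor(y + b*d, d)^2 = r2 as the starting point
        b0 = (-c * (1 - r2) + np.sqrt((1 - r2) * r2 * (v * s2 - c**2))) / (v * (1 - r2))
        dc = d[ok] - d[ok].mean()

        def realized(b: float) -> float:
            return np.corrcoef(m_to_beta(y + b * dc), d[ok])[0, 1] ** 2 - r2

        from scipy.optimize import brentq

        if realized(0.0) >= 0:
            b = 0.0  # chance correlation already reaches the target
        else:
            hi = max(4.0 * b0, 1e-6)
            while realized(hi) < 0 and hi < 1e3:
                hi *= 2.0
            b = brentq(realized, 0.0, hi) if realized(hi) >= 0 else hi
        m[s.cpg_index, ok] += b * dc
        pairs.append((geno.snp_ids[s.snp_index], beta.cpg_ids[s.cpg_index]))
    out = BetaMatrix(m_to_beta(m), beta.cpg_ids, beta.sample_ids, beta.cpg_map)
    return out, pairs


def _marginal_ols(y: np.ndarray, dos: np.ndarray) -> pd.DataFrame:
    """Per-SNP marginal OLS of y on dosage: beta, se, p (complete rows)."""
    n_snps = dos.shape[0]
    beta = np.full(n_snps, np.nan)
    se = np.full(n_snps, np.nan)
    yc = y - y.mean()
    dc = dos - np.nanmean(dos, axis=1, keepdims=True)
    # no-missing fast path
    sxx = np.nansum(dc * dc, axis=1)
    sxy = np.nansum(dc * np.where(np.isnan(dc), np.nan, yc[None, :]), axis=1)
    nn = (~np.isnan(dos)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        # residual SS computed pairwise-complete
        syy = np.nansum(np.where(np.isnan(dc), np.nan, yc[None, :] ** 2), axis=1)
        rss = syy - beta * sxy
        df = nn - 2
        se = np.sqrt(np.maximum(rss, 0.0) / np.maximum(df, 1) / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "n": nn})


def simulate_gwas_summary(
    geno_panel: GenotypeSet, spec: GwasSpec, seed: int = 0, trait_name: str = "trait"
) -> tuple[AssocStats, GenotypeSet]:
    """Simulate GWAS summary statistics from an independent panel.

    A fresh panel of ``n_gwas`` individuals is drawn from the same LD
    process as ``geno_panel`` (same MAFs, block size and autocorrelation);
    a quantitative phenotype with ``h2_per_causal`` variance per causal SNP
    is regressed marginally on every SNP.  Returns the summary statistics
    and the panel itself (useful as an LD reference).
    """
    if geno_panel.sim_params is None:
        raise ValueError("geno_panel lacks simulation parameters")
    params = geno_panel.sim_params
    rng = np.random.default_rng(seed)
    n_snps = geno_panel.dosages.shape[0]
    z = _draw_latent_blocks(rng, n_snps, spec.n_gwas, params["block"], params["rho"])
    dos = _threshold_to_dosage(z, params["maf"])
    panel = GenotypeSet(dos, geno_panel.snp_map,
                        pd.Index([f"G{i:05d}" for i in range(spec.n_gwas)]),
                        geno_panel.sim_params)

    y = rng.normal(0.0, 1.0, spec.n_gwas)
    for c in spec.causal_indices:
        d = dos[c]
        sd = d.std()
        if sd > 0 and spec.h2_per_causal > 0:
            y = y + np.sqrt(spec.h2_per_causal) * (d - d.mean()) / sd
    table = _marginal_ols(y, dos)
    table.index = geno_panel.snp_ids
    table["chrom"] = geno_panel.snp_map["chrom"].to_numpy()
    table["pos"] = geno_panel.snp_map["pos"].to_numpy()
    table["maf"] = params["maf"]
    stats_out = AssocStats(
        table[["chrom", "pos", "beta", "se", "p", "maf", "n"]],
        trait_type="quantitative",
        trait_name=trait_name,
    )
    return stats_out, panel


def simulate_specificity(
    n_genes: int,
    n_celltypes: int,
    planted: dict[str, list[str]] | None = None,
    seed: int = 0,
    planted_concentration: float = 20.0,
) -> pd.DataFrame:
    """Simulate a gene x cell-type specificity matrix (rows sum to 1).

    Unplanted genes draw specificity rows from a flat Dirichlet; genes in
    ``planted[celltype]`` use a Dirichlet concentrated on that cell type so
    their specificity peaks there.  Planted gene sets must be disjoint.
    """
    rng = np.random.default_rng(seed)
    celltypes = [f"celltype{j}" for j in range(n_celltypes)]
    planted = planted or {}
    seen: set[str] = set()
    for ct, genes in planted.items():
        if ct not in celltypes:
            raise ValueError(f"unknown cell type {ct!r}")
        overlap = seen & set(genes)
        if overlap:
            raise ValueError(f"planted sets overlap: {sorted(overlap)[:5]}")
        seen |= set(genes)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    extra = seen - set(gene_ids)
    if extra:
        raise ValueError(f"planted genes outside universe: {sorted(extra)[:5]}")

    mat = rng.dirichlet(np.ones(n_celltypes), size=n_genes)
    for ct, genes in planted.items():
        j = celltypes.index(ct)
        alpha = np.ones(n_celltypes)
        alpha[j] = planted_concentration
        idx = [gene_ids.index(g) for g in genes]
        mat[idx] = rng.dirichlet(alpha, size=len(idx))
    return pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene"), columns=celltypes)
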