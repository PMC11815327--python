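"""Bayesian colocalization of mQTL and GWAS signals with a permutation p-value.

Each trait's per-SNP evidence is a Wakefield asymptotic Bayes factor; under
the single-causal-variant assumption the posterior mass of the five
hypotheses (H0 no causal variant, H1/H2 one trait only, H3 two distinct
variants, H4 one shared variant) is a prior-weighted sum over causal
configurations, evaluated in log space.  Candidate regions are built by LD
expansion around GWAS lead SNPs (furthest SNP with r^2 > 0.6 within 250 kb).
Candidates with PP3+PP4 > 0.9 receive a permutation p-value: the fraction
of random same-length regions (random lead SNPs, same LD rule) whose
colocalization also reaches PP3+PP4 > 0.9; a candidate is called
colocalized when that fraction is below 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from comethnet.types import AssocStats, ColocResult, GenotypeSet, Region

__all__ = [
    "define_region",
    "wakefield_log_abf",
    "log_abf_table",
    "coloc_posteriors",
    "coloc_scan",
    "coloc_permutation_p",
]

logger = logging.getLogger(__name__)

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12 (coloc defaults)


def define_region(
    lead_snp: str,
    geno_ref: GenotypeSet,
    r2_min: float = 0.6,
    max_dist: int = 250_000,
    source: str = "ld_expanded",
) -> Region:
    """LD-expand a lead SNP: span the furthest SNPs with r^2 > r2_min
    within +/- max_dist bp (lead-only region when none qualify)."""
    if lead_snp not in geno_ref.snp_map.index:
        raise KeyError(f"lead SNP {lead_snp!r} not in reference panel")
    lead = geno_ref.snp_map.loc[lead_snp]
    chrom, pos = lead["chrom"], int(lead["pos"])
    near = geno_ref.snp_map[
        (geno_ref.snp_map["chrom"] == chrom)
        & (geno_ref.snp_map["pos"] >= pos - max_dist)
        & (geno_ref.snp_map["pos"] <= pos + max_dist)
    ]
    d_lead = geno_ref.dosages[geno_ref.snp_map.index.get_loc(lead_snp)]
    start = end = pos
    for sid, row in near.iterrows():
        if sid == lead_snp:
            continue
        d = geno_ref.dosages[geno_ref.snp_map.index.get_loc(sid)]
        ok = ~(np.isnan(d) | np.isnan(d_lead))
        if ok.sum() < 3 or d[ok].std() == 0 or d_lead[ok].std() == 0:
            continue
        r2 = np.corrcoef(d[ok], d_lead[ok])[0, 1] ** 2
        if r2 > r2_min:
            start = min(start, int(row["pos"]))
            end = max(end, int(row["pos"]))
    return Region(chrom, start, end, lead_snp_id=lead_snp, source=source)


def wakefield_log_abf(
    beta: np.ndarray, se: np.ndarray, prior_sd: float
) -> np.ndarray:
    """Log asymptotic Bayes factor for association at one SNP.

    log ABF = 0.5 log(se^2/(se^2+W^2)) + 0.5 z^2 W^2/(se^2+W^2) with
    z = beta/se and W the prior effect SD (0.15*sdY for quantitative
    traits, 0.2 for case-control log odds ratios).  W = 0 gives log ABF 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    if prior_sd == 0:
        return np.zeros_like(beta)
    z2 = (beta / se) ** 2
    shrink = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * np.log(1.0 - shrink) + 0.5 * z2 * shrink


def _prior_sd(stats_: AssocStats, sd_y: float = 1.0) -> float:
    return 0.2 if stats_.trait_type == "case_control" else 0.15 * sd_y


def _fill_beta_se(table: pd.DataFrame) -> pd.DataFrame:
    """Recover beta/se from p + MAF + n when absent (standardized scale):
    var(beta) ~ 1/(2 n maf (1-maf))."""
    from scipy import stats as sps

    t = table.copy()
    need = t["beta"].isna() | t["se"].isna() if {"beta", "se"} <= set(t.columns) else (
        pd.Series(True, index=t.index)
    )
    if need.any():
        if not {"p", "maf", "n"} <= set(t.columns):
            raise ValueError("need either beta+se or p+maf+n per SNP")
        sub = t[need]
        se = 1.0 / np.sqrt(2.0 * sub["n"] * sub["maf"] * (1.0 - sub["maf"]))
        z = sps.norm.isf(sub["p"].to_numpy() / 2.0)
        t.loc[need, "se"] = se
        t.loc[need, "beta"] = z * se  # sign unknown; ABF depends on z^2 only
    return t


def log_abf_table(stats_: AssocStats, sd_y: float = 1.0) -> pd.Series:
    """Per-SNP log ABF, indexed like the stats table."""
    cols = set(stats_.table.columns)
    if {"beta", "se"} <= cols and not stats_.table[["beta", "se"]].isna().any().any():
        table = stats_.table
    else:
        table = _fill_beta_se(stats_.table)
    w = _prior_sd(stats_, sd_y)
    labf = wakefield_log_abf(table["beta"].to_numpy(), table["se"].to_numpy(), w)
    return pd.Series(labf, index=stats_.table.index, name="log_abf")


def _match_by_position(s1: AssocStats, s2: AssocStats) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match the two stats tables on the Chromosome:Position identifier."""
    k1 = s1.table["chrom"].astype(str) + ":" + s1.table["pos"].astype(int).astype(str)
    k2 = s2.table["chrom"].astype(str) + ":" + s2.table["pos"].astype(int).astype(str)
    t1 = s1.table.loc[~k1.duplicated()].set_index(k1[~k1.duplicated()])
    t2 = s2.table.loc[~k2.duplicated()].set_index(k2[~k2.duplicated()])
    shared = t1.index.intersection(t2.index)
    return t1.loc[shared], t2.loc[shared]


def coloc_posteriors(
    stats1: AssocStats,
    stats2: AssocStats,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
) -> tuple[np.ndarray, int]:
    """PP0..PP4 for two traits over their shared SNPs.

    SNPs are matched by chromosome:position.  With per-SNP log ABFs l1, l2:
    S1 = sum exp(l1), S2 = sum exp(l2), S4 = sum exp(l1+l2),
    S3 = S1*S2 - S4; posteriors are the normalized vector
    (1, p1 S1, p2 S2, p1 p2 S3, p12 S4).  Returns (pp, n_shared_snps).
    """
    t1, t2 = _match_by_position(stats1, stats2)
    m = len(t1)
    if m == 0:
        raise ValueError("no shared SNPs between the two traits")
    p1, p2, p12 = priors
    l1 = log_abf_table(AssocStats(t1, stats1.trait_type, stats1.trait_name)).to_numpy()
    l2 = log_abf_table(AssocStats(t2, stats2.trait_type, stats2.trait_name)).to_numpy()

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls4 = logsumexp(l1 + l2)
    # S3 = S1*S2 - S4 in log space; exact cancellation (m == 1) gives -inf
    big, small = ls1 + ls2, ls4
    if big <= small + np.log1p(1e-15):
        ls3 = -np.inf
    else:
        ls3 = big + np.log1p(-np.exp(small - big))

    logs = np.array(
        [
            0.0,
            np.log(p1) + ls1,
            np.log(p2) + ls2,
            np.log(p1) + np.log(p2) + ls3,
            np.log(p12) + ls4,
        ]
    )
    pp = np.exp(logs - logsumexp(logs))
    return pp / pp.sum(), m


def _region_stats(stats_: AssocStats, region: Region) -> AssocStats:
    t = stats_.table
    inside = (t["chrom"].astype(str) == region.chrom) & (
        t["pos"].between(region.start, region.end)
    )
    return AssocStats(t[inside], stats_.trait_type, stats_.trait_name)


def coloc_scan(
    mqtl_stats_by_cpg: dict[str, AssocStats],
    gwas_list: list[AssocStats],
    regions: list[Region],
    h34_threshold: float = 0.9,
    min_snps: int = 10,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
) -> list[ColocResult]:
    """Colocalize every (CpG, GWAS trait, region) triple with enough shared
    SNPs; results with PP3+PP4 above threshold are the candidates for the
    permutation p-value."""
    results = []
    for region in regions:
        for gwas in gwas_list:
            g_reg = _region_stats(gwas, region)
            if len(g_reg.table) == 0:
                continue
            for cpg_id, m_stats in mqtl_stats_by_cpg.items():
                m_reg = _region_stats(m_stats, region)
                if len(m_reg.table) == 0:
                    continue
                try:
                    pp, m = coloc_posteriors(m_reg, g_reg, priors)
                except ValueError:
                    continue
                if m < min_snps:
                    continue
                results.append(
                    ColocResult(cpg_id, gwas.trait_name, region, m, pp)
                )
    return results


def _random_region_like(
    candidate_region: Region,
    lead_snp: str,
    geno_ref: GenotypeSet,
    r2_min: float,
    max_dist: int,
) -> Region:
    """LD region around a random lead, trimmed/extended symmetrically to the
    candidate's exact bp length."""
    raw = define_region(lead_snp, geno_ref, r2_min, max_dist, source="random")
    target = candidate_region.length
    center = (raw.start + raw.end) // 2
    half = (target - 1) // 2
    start = max(1, center - half)
    return Region(raw.chrom, start, start + target - 1, lead_snp, "random")


def coloc_permutation_p(
    candidate: ColocResult,
    geno_ref: GenotypeSet,
    gwas: AssocStats,
    mqtl_stats_by_cpg: dict[str, AssocStats],
    n_random: int = 1000,
    seed: int = 0,
    r2_min: float = 0.6,
    max_dist: int = 250_000,
    min_snps: int = 10,
    h34_threshold: float = 0.9,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    record_p_threshold: float = 1e-5,
) -> float:
    """Permutation p-value: fraction of random same-length regions whose
    colocalization reaches PP3+PP4 > threshold.

    Random lead SNPs are drawn uniformly from the reference panel; each
    region is the lead's LD expansion resized to the candidate's length.
    Within a random region, the GWAS statistics are paired with the module
    CpG holding the most significant mQTL records (p < record threshold)
    among SNPs inside the region — or with the candidate's own CpG when no
    CpG has a record there; draws with fewer than ``min_snps`` shared SNPs
    are redrawn.
    """
    rng = np.random.default_rng(seed)
    snp_ids = geno_ref.snp_map.index.to_numpy()
    hits = 0
    done = 0
    attempts = 0
    max_attempts = 10 * n_random
    while done < n_random:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {n_random} valid random regions in {max_attempts} attempts"
            )
        attempts += 1
        lead = str(rng.choice(snp_ids))
        region = _random_region_like(candidate.region, lead, geno_ref, r2_min, max_dist)
        g_reg = _region_stats(gwas, region)
        if len(g_reg.table) < min_snps:
            continue
        # pair with the module CpG carrying the most significant mQTL
        # records inside the region (candidate's CpG when none does)
        best_cpg, best_count = candidate.cpg_id, 0
        for cpg_id, m_stats in mqtl_stats_by_cpg.items():
            reg_tab = _region_stats(m_stats, region).table
            cnt = int((reg_tab["p"] < record_p_threshold).sum()) if "p" in reg_tab else 0
            if cnt > best_count:
                best_cpg, best_count = cpg_id, cnt
        m_reg = _region_stats(mqtl_stats_by_cpg[best_cpg], region)
        try:
            pp, m = coloc_posteriors(m_reg, g_reg, priors)
        except ValueError:
            continue
        if m < min_snps:
            continue
        done += 1
        if pp[3] + pp[4] > h34_threshold:
            hits += 1
    return hits / n_random
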