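"""Genotype QC and additive-model methylation QTL mapping.

QC mirrors standard array practice: drop samples with > 5% missing calls,
then SNPs with > 1% missingness, minor allele frequency < 0.05, or
Hardy-Weinberg exact-test p < 1e-5; relatedness is screened with a
GRM-based kinship estimate (pairs above 0.25 lose one member).  mQTLs are
mapped with per-pair OLS of residualized methylation on alt-allele dosage
plus the first three genotype principal components, restricted to
same-chromosome SNP-CpG pairs: cis within +/- 1 Mb of the CpG, trans
beyond 1 Mb (different chromosomes are not tested).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from comethnet.types import GenotypeSet, ResidualMatrix

__all__ = [
    "hwe_exact_test",
    "snp_qc",
    "kinship_filter",
    "genotype_pcs",
    "map_mqtls",
    "mqtl_stats_for_cpg",
]

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000


def hwe_exact_test(n_aa_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact Hardy-Weinberg test: two-sided tail by point-probability ordering.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed the
    observed one (the PLINK convention).
    """
    if min(n_aa_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_alt_hom
    if n < 1:
        raise ValueError("total count must be >= 1")
    rare = 2 * min(n_aa_hom, n_alt_hom) + n_het  # rare-allele count
    probs = _hwe_het_probabilities(n, rare)
    obs = probs[n_het] if n_het < len(probs) else 0.0
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_het_probabilities(n: int, rare: int) -> np.ndarray:
    """P(het count | allele counts) for every feasible heterozygote count.

    Feasible counts share the parity of the rare-allele count; infeasible
    entries are 0.  Computed by enumeration with log-gamma factorials.
    """
    from scipy.special import gammaln

    common = 2 * n - rare
    hets = np.arange(rare % 2, min(rare, common) + 1, 2)
    rare_hom = (rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(common + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp)
    out = np.zeros(min(rare, common) + 1)
    out[hets] = p / p.sum()
    return out


def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ok = ~np.isnan(dosages)
    n0 = ((dosages == 0) & ok).sum(axis=1)
    n1 = ((dosages == 1) & ok).sum(axis=1)
    n2 = ((dosages == 2) & ok).sum(axis=1)
    return n0, n1, n2


def snp_qc(
    geno: GenotypeSet,
    max_sample_missing: float = 0.05,
    max_snp_missing: float = 0.01,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-5,
) -> GenotypeSet:
    """Sequential QC: sample missingness, SNP missingness, MAF, HWE.

    Boundaries follow the stated rules strictly: a SNP at MAF exactly 0.05
    is kept (exclusion requires MAF < 0.05); missingness filters are
    strict '>' comparisons.
    """
    miss = np.isnan(geno.dosages)
    keep_samples = miss.mean(axis=0) <= max_sample_missing
    if not keep_samples.any():
        raise ValueError("all samples removed by missingness filter")
    g = geno.subset_samples(np.flatnonzero(keep_samples))

    miss = np.isnan(g.dosages)
    keep = miss.mean(axis=1) <= max_snp_missing
    g = g.subset_snps(keep)

    n0, n1, n2 = _genotype_counts(g.dosages)
    total = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (n1 + 2 * n2) / (2 * total)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    g = g.subset_snps(np.nan_to_num(maf, nan=0.0) >= min_maf - 1e-12)

    n0, n1, n2 = _genotype_counts(g.dosages)
    hwe_p = np.array([hwe_exact_test(a, b, c) for a, b, c in zip(n0, n1, n2)])
    return g.subset_snps(hwe_p >= hwe_alpha)


def _standardized_dosages(geno: GenotypeSet) -> np.ndarray:
    """Mean-imputed, per-SNP standardized dosage matrix."""
    d = geno.dosages.astype(float).copy()
    means = np.nanmean(d, axis=1)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.take(means, np.where(nan_mask)[0])
    d -= means[:, None]
    sd = d.std(axis=1)
    sd[sd == 0] = 1.0
    return d / sd[:, None]


def kinship_filter(geno: GenotypeSet, threshold: float = 0.25) -> GenotypeSet:
    """Remove one member of every sample pair with kinship above threshold.

    Kinship is estimated as GRM/2 from standardized dosages.  Of each
    offending pair the sample with the higher mean kinship to everyone
    else is removed (ties by larger sample id), iterating until no pair
    exceeds the threshold.
    """
    z = _standardized_dosages(geno)
    m, n = z.shape
    grm = z.T @ z / m
    phi = grm / 2.0
    np.fill_diagonal(phi, 0.0)
    keep = np.ones(n, dtype=bool)
    while True:
        masked = phi * np.outer(keep, keep)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        mean_i = phi[i, keep].mean()
        mean_j = phi[j, keep].mean()
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j, key=lambda k: str(geno.sample_ids[k]))
        keep[drop] = False
    return geno.subset_samples(np.flatnonzero(keep))


def genotype_pcs(geno: GenotypeSet, k: int = 3) -> pd.DataFrame:
    """Principal-component scores of the standardized dosage matrix.

    Missing dosages are mean-imputed per SNP.  Sign convention: the
    largest-|loading| SNP of each component is made positive, so scores
    are deterministic.
    """
    z = _standardized_dosages(geno)
    m, n = z.shape
    if k >= min(m, n):
        raise ValueError(f"k={k} must be < min(n_snps, n_samples)={min(m, n)}")
    zc = z - z.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    scores = vt[:k].T * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(u[:, j]))
        if u[lead, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=geno.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    )


def _pair_relations(
    snp_map: pd.DataFrame, cpg_map: pd.DataFrame, cis_window: int = CIS_WINDOW
) -> pd.DataFrame:
    """Long table of testable same-chromosome SNP-CpG pairs with relation."""
    pairs = []
    cpg_by_chrom = {c: sub for c, sub in cpg_map.groupby("chrom", sort=False)}
    for chrom, snps in snp_map.groupby("chrom", sort=False):
        cpgs = cpg_by_chrom.get(chrom)
        if cpgs is None:
            continue
        spos = snps["pos"].to_numpy()[:, None]
        cpos = cpgs["pos"].to_numpy()[None, :]
        dist = np.abs(spos - cpos)
        pairs.append(
            pd.DataFrame(
                {
                    "snp": np.repeat(snps.index.to_numpy(), len(cpgs)),
                    "cpg": np.tile(cpgs.index.to_numpy(), len(snps)),
                    "distance": dist.ravel(),
                }
            )
        )
    if not pairs:
        return pd.DataFrame(columns=["snp", "cpg", "distance", "relation"])
    table = pd.concat(pairs, ignore_index=True)
    table["relation"] = np.where(table["distance"] <= cis_window, "cis", "trans")
    return table


def _residualize_on(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of the rows of x on the columns of design (with intercept)."""
    q, _ = np.linalg.qr(design)
    return x - (x @ q) @ q.T


def map_mqtls(
    resid: ResidualMatrix,
    geno: GenotypeSet,
    pcs: pd.DataFrame,
    p_threshold: float = 1e-5,
    cis_window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Mass additive-model mQTL scan over same-chromosome SNP-CpG pairs.

    Per pair, OLS of residual methylation on [intercept, dosage, PC1..k];
    the dosage t-statistic is computed through the partialled-out
    correlation, which is algebraically identical to the full OLS fit.
    SNPs with missing dosages fall back to complete-case per-SNP fits.
    Returns records with p < ``p_threshold`` sorted by p, with columns
    snp, cpg, chrom, snp_pos, cpg_pos, relation, beta, se, t, p.
    """
    if resid.cpg_map is None:
        raise ValueError("residual matrix lacks CpG annotation (cpg_map)")
    samples = resid.sample_ids.intersection(geno.sample_ids).intersection(pcs.index)
    n = len(samples)
    n_cov = pcs.shape[1] + 2  # intercept + dosage + PCs
    if n <= n_cov:
        raise ValueError(f"need more than {n_cov} samples, got {n}")
    df = n - n_cov

    y = resid.values[:, resid.sample_ids.get_indexer(samples)]
    d = geno.dosages[:, geno.sample_ids.get_indexer(samples)]
    x_pcs = pcs.loc[samples].to_numpy()
    design = np.column_stack([np.ones(n), x_pcs])

    pairs = _pair_relations(geno.snp_map, resid.cpg_map.loc[resid.cpg_ids], cis_window)
    if pairs.empty:
        return pd.DataFrame(
            columns=["snp", "cpg", "chrom", "snp_pos", "cpg_pos", "relation",
                     "beta", "se", "t", "p"]
        )

    y_res = _residualize_on(y, design)
    y_norm = np.sqrt((y_res**2).sum(1))

    snp_idx = geno.snp_map.index.get_indexer(pairs["snp"])
    cpg_idx = resid.cpg_ids.get_indexer(pairs["cpg"])

    complete = ~np.isnan(d).any(axis=1)
    records: list[dict] = []

    # fast path: SNPs without missing calls, vectorized over all their pairs
    d_res = np.full_like(d, np.nan)
    d_res[complete] = _residualize_on(d[complete], design)
    d_norm = np.sqrt(np.nansum(d_res**2, axis=1))

    fast = complete[snp_idx]
    si, ci = snp_idx[fast], cpg_idx[fast]
    with np.errstate(invalid="ignore", divide="ignore"):
        sxy = np.einsum("ij,ij->i", d_res[si], y_res[ci])
        denom = d_norm[si] * y_norm[ci]
        r = sxy / denom
    degenerate = (d_norm[si] < 1e-10) | (y_norm[ci] < 1e-10)
    if degenerate.any():
        logger.info("%d pairs skipped (collinear or constant)", int(degenerate.sum()))
    r = np.clip(np.where(degenerate, np.nan, r), -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
        beta = sxy / d_norm[si] ** 2
        se = beta / t
    p = 2.0 * stats.t.sf(np.abs(t), df)

    fast_tab = pairs[fast].copy()
    fast_tab["beta"], fast_tab["se"], fast_tab["t"], fast_tab["p"] = beta, se, t, p

    # slow path: per-SNP complete-case fits for SNPs with missing dosages
    slow_rows = []
    for s in np.flatnonzero(~complete):
        ok = ~np.isnan(d[s])
        n_ok = int(ok.sum())
        if n_ok <= n_cov:
            continue
        dsg = np.column_stack([np.ones(n_ok), x_pcs[ok]])
        d_r = _residualize_on(d[s][ok][None, :], dsg)[0]
        dn = np.sqrt((d_r**2).sum())
        if dn < 1e-10:
            logger.info("SNP %s collinear with covariates; skipped", geno.snp_ids[s])
            continue
        y_sub = _residualize_on(y[:, ok], dsg)
        yn = np.sqrt((y_sub**2).sum(1))
        mask = snp_idx == s
        for row_i in np.flatnonzero(mask):
            c = cpg_idx[row_i]
            if yn[c] < 1e-10:
                continue
            sxy_ = float(d_r @ y_sub[c])
            r_ = np.clip(sxy_ / (dn * yn[c]), -1.0, 1.0)
            df_ = n_ok - n_cov
            t_ = r_ * np.sqrt(df_ / max(1.0 - r_**2, 1e-300))
            b_ = sxy_ / dn**2
            slow_rows.append(
                {**pairs.iloc[row_i].to_dict(), "beta": b_, "se": b_ / t_ if t_ else np.nan,
                 "t": t_, "p": 2.0 * stats.t.sf(abs(t_), df_)}
            )
    slow_tab = pd.DataFrame(slow_rows)

    table = pd.concat([fast_tab, slow_tab], ignore_index=True)
    table = table[table["p"] < p_threshold].copy()
    table["chrom"] = geno.snp_map.loc[table["snp"], "chrom"].to_numpy()
    table["snp_pos"] = geno.snp_map.loc[table["snp"], "pos"].to_numpy()
    cmap = resid.cpg_map
    table["cpg_pos"] = cmap.loc[table["cpg"], "pos"].to_numpy()
    table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return table[
        ["snp", "cpg", "chrom", "snp_pos", "cpg_pos", "relation", "beta", "se", "t", "p"]
    ]


def mqtl_stats_for_cpg(
    resid: ResidualMatrix,
    geno: GenotypeSet,
    pcs: pd.DataFrame,
    cpg_id: str,
    snp_ids: pd.Index | list[str],
) -> pd.DataFrame:
    """Full (unthresholded) association statistics of one CpG against a SNP set.

    Used by colocalization, which needs every SNP in a region regardless of
    significance.  Same model as :func:`map_mqtls`.
    """
    samples = resid.sample_ids.intersection(geno.sample_ids).intersection(pcs.index)
    n = len(samples)
    n_cov = pcs.shape[1] + 2
    df = n - n_cov
    yrow = resid.values[resid.cpg_ids.get_loc(cpg_id), resid.sample_ids.get_indexer(samples)]
    design = np.column_stack([np.ones(n), pcs.loc[samples].to_numpy()])
    y_res = _residualize_on(yrow[None, :], design)[0]
    yn = np.sqrt((y_res**2).sum())

    sidx = geno.snp_map.index.get_indexer(snp_ids)
    d = geno.dosages[np.ix_(sidx, geno.sample_ids.get_indexer(samples))]
    rows = []
    for i, sid in enumerate(snp_ids):
        ok = ~np.isnan(d[i])
        if ok.all():
            d_r = _residualize_on(d[i][None, :], design)[0]
            y_r, df_ = y_res, df
        else:
            n_ok = int(ok.sum())
            if n_ok <= n_cov:
                continue
            dsg = np.column_stack([np.ones(n_ok), pcs.loc[samples].to_numpy()[ok]])
            d_r = _residualize_on(d[i][ok][None, :], dsg)[0]
            y_r = _residualize_on(yrow[ok][None, :], dsg)[0]
            df_ = n_ok - n_cov
        dn = np.sqrt((d_r**2).sum())
        yn_ = np.sqrt((y_r**2).sum())
        if dn < 1e-10 or yn_ < 1e-10:
            continue
        sxy = float(d_r @ y_r)
        r = np.clip(sxy / (dn * yn_), -1.0, 1.0)
        t = r * np.sqrt(df_ / max(1.0 - r**2, 1e-300))
        beta = sxy / dn**2
        se = abs(beta / t) if t != 0 else np.sqrt(yn_**2 / df_) / dn
        rows.append(
            {
                "snp": sid,
                "chrom": geno.snp_map.loc[sid, "chrom"],
                "pos": int(geno.snp_map.loc[sid, "pos"]),
                "beta": beta,
                "se": se,
                "p": 2.0 * stats.t.sf(abs(t), df_),
            }
        )
    return pd.DataFrame(rows).set_index("snp") if rows else pd.DataFrame(
        columns=["chrom", "pos", "beta", "se", "p"]
    )
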