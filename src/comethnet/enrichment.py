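"""Fisher-exact set / GWAS-region enrichment and bootstrap cell-type enrichment.

Module CpG sets are tested against external CpG lists (one-sided Fisher
exact test on the shared-array background) and against GWAS regions
(per-region 2x2 tables on the network background, Bonferroni across
regions, run for all module CpGs and for hub CpGs separately).  Cell-type
enrichment follows the expression-weighted bootstrap scheme: the mean
specificity of the module's annotated genes in each cell type is compared
with same-size random gene samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from comethnet.types import EnrichmentResult, Region

__all__ = [
    "cpgs_to_genes",
    "fisher_set_enrichment",
    "merge_regions",
    "gwas_region_enrichment",
    "ewce_bootstrap",
]

logger = logging.getLogger(__name__)


def cpgs_to_genes(
    cpg_ids, cpg_map: pd.DataFrame, max_dist: int = 1000
) -> set[str]:
    """Union of genes within ``max_dist`` bp of any listed CpG.

    ``cpg_map['genes']`` holds per-CpG lists of (gene, distance_bp) tuples;
    unannotated CpGs contribute nothing.
    """
    genes: set[str] = set()
    for cpg in cpg_ids:
        if cpg not in cpg_map.index:
            continue
        for gene, dist in cpg_map.at[cpg, "genes"]:
            if dist <= max_dist:
                genes.add(gene)
    return genes


def fisher_set_enrichment(
    module_cpgs,
    target_cpgs,
    background_cpgs,
    target_name: str = "",
    subset_tag: str = "all_cpgs",
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher exact test of module vs target overlap on a background.

    The 2x2 table is (module & target, module - target, target - module,
    neither), all restricted to the background.  The odds ratio is the
    sample (a d)/(b c) with Haldane 0.5 correction when any cell is zero.
    """
    bg = set(background_cpgs)
    if not bg:
        raise ValueError("background is empty")
    mod = set(module_cpgs) & bg
    if set(module_cpgs) - bg:
        raise ValueError("module CpGs must be a subset of the background")
    tgt = set(target_cpgs) & bg
    a = len(mod & tgt)
    b = len(mod - tgt)
    c = len(tgt - mod)
    d = len(bg) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return EnrichmentResult(target_name, a, b, c, d, float(odds), float(p),
                            subset=subset_tag)


def merge_regions(regions: list[Region]) -> list[Region]:
    """Merge overlapping regions per chromosome (log notice on merges)."""
    out: list[Region] = []
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged_any = False
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur = rs[0]
        for nxt in rs[1:]:
            if nxt.start <= cur.end:
                merged_any = True
                cur = Region(chrom, cur.start, max(cur.end, nxt.end),
                             cur.lead_snp_id, cur.source)
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    if merged_any:
        logger.info("overlapping regions were merged")
    return out


def gwas_region_enrichment(
    module_cpgs,
    hub_cpgs,
    regions: list[Region],
    all_network_cpgs,
    cpg_map: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Per-region Fisher enrichment of module and hub CpGs in GWAS regions.

    Background = all network CpGs; membership = CpG position inside the
    region (1-based inclusive).  Bonferroni correction across regions,
    separately within the all-CpG and hub-CpG test families.  Regions with
    no background CpGs yield a degenerate p = 1 result.
    """
    regions = merge_regions(list(regions))
    background = list(all_network_cpgs)
    pos = cpg_map.loc[background, ["chrom", "pos"]]
    results: list[EnrichmentResult] = []
    for subset_tag, cpgs in (("all_cpgs", module_cpgs), ("hub_cpgs", hub_cpgs)):
        subset_results = []
        for i, region in enumerate(regions):
            inside = pos.index[
                (pos["chrom"] == region.chrom)
                & pos["pos"].between(region.start, region.end)
            ]
            name = f"{region.chrom}:{region.start}-{region.end}"
            if len(inside) == 0:
                subset_results.append(
                    EnrichmentResult(name, 0, len(set(cpgs) & set(background)),
                                     0, len(background) - len(set(cpgs) & set(background)),
                                     1.0, 1.0, subset=subset_tag, degenerate=True)
                )
                continue
            res = fisher_set_enrichment(cpgs, inside, background, name, subset_tag)
            subset_results.append(res)
        n_regions = len(regions)
        for res in subset_results:
            res.p_bonferroni = min(1.0, res.p * n_regions)
        results.extend(subset_results)
    return results


def ewce_bootstrap(
    gene_list,
    specificity: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap cell-type enrichment of a gene list against a specificity matrix.

    Statistic per cell type: mean specificity of the gene list.  The null
    resamples ``n_boot`` same-size gene sets uniformly from the matrix's
    gene universe; p = (1 + #{null >= observed}) / (1 + n_boot); fold =
    observed / null mean; Benjamini-Hochberg adjustment across cell types.
    """
    genes = sorted(set(gene_list))
    missing = [g for g in genes if g not in specificity.index]
    if missing:
        raise ValueError(f"genes absent from specificity matrix: {missing[:10]}")
    if len(genes) < 4:
        raise ValueError("need at least 4 genes in the specificity universe")
    rng = np.random.default_rng(seed)
    spec = specificity.to_numpy()
    obs = specificity.loc[genes].mean(axis=0).to_numpy()
    draws = rng.integers(0, spec.shape[0], size=(n_boot, len(genes)))
    null_means = spec[draws].mean(axis=1)  # n_boot x n_celltypes
    p = (1.0 + (null_means >= obs[None, :]).sum(axis=0)) / (1.0 + n_boot)
    fold = obs / null_means.mean(axis=0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"fold": fold, "p": p, "p_adj": p_adj},
        index=pd.Index(specificity.columns, name="celltype"),
    )
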