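"""Permutation Z-summary module preservation between two cohorts.

Preservation of a reference-cohort module in a test cohort is scored with
three density statistics (mean within-module adjacency, proportion of
variance explained by the test eigengene, mean |kME|) and three
connectivity statistics (cross-cohort correlations of intramodular
connectivity, of kME, and of the vectorized within-module correlation
matrices).  A permutation null replaces the module with random same-size
CpG sets (label permutation applied jointly in both cohorts); each
statistic is Z-scored against its null, Z-density and Z-connectivity are
the medians of their three components, and Z-summary is their mean.
Bands: > 10 highly preserved, 5-10 moderately preserved, < 5 not preserved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from comethnet.network import NetworkParams, _row_correlation
from comethnet.types import ModuleStats, PreservationResult, ResidualMatrix

__all__ = [
    "preservation_observed",
    "preservation_null",
    "z_summary",
    "module_preservation",
    "replication_decision",
]

logger = logging.getLogger(__name__)

STAT_NAMES = ["mean_adj", "prop_var_explained", "mean_kme", "cor_kim", "cor_kme", "cor_cor"]
DENSITY_STATS = ["mean_adj", "prop_var_explained", "mean_kme"]
CONNECTIVITY_STATS = ["cor_kim", "cor_kme", "cor_cor"]


def _first_pc(values: np.ndarray) -> np.ndarray:
    z = values - values.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    if (z @ me).mean() < 0:
        me = -me
    return me


def _cor_with_vector(values: np.ndarray, v: np.ndarray) -> np.ndarray:
    xc = values - values.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((xc**2).sum(1) * (vc**2).sum())
    denom[denom == 0] = np.inf
    return xc @ vc / denom

def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _module_stats_pair(
    ref_vals: np.ndarray, test_vals: np.ndarray, power: float
) -> dict[str, float]:
    """All six preservation statistics for one CpG set present in both cohorts."""
    r_ref = _row_correlation(ref_vals)
    r_test = _row_correlation(test_vals)
    a_ref = np.abs(r_ref) ** power
    a_test = np.abs(r_test) ** power
    m = ref_vals.shape[0]
    off = ~np.eye(m, dtype=bool)

    me_test = _first_pc(test_vals)
    kme_test = _cor_with_vector(test_vals, me_test)
    me_ref = _first_pc(ref_vals)
    kme_ref = _cor_with_vector(ref_vals, me_ref)

    kim_ref = a_ref.sum(1) - 1.0
    kim_test = a_test.sum(1) - 1.0
    iu = np.triu_indices(m, k=1)
    return {
        "mean_adj": float(a_test[off].mean()),
        "prop_var_explained": float((kme_test**2).mean()),
        "mean_kme": float(np.abs(kme_test).mean()),
        "cor_kim": _safe_cor(kim_ref, kim_test),
        "cor_kme": _safe_cor(kme_ref, kme_test),
        "cor_cor": _safe_cor(r_ref[iu], r_test[iu]),
    }


def _align(ref: ResidualMatrix, test: ResidualMatrix) -> tuple[ResidualMatrix, ResidualMatrix]:
    shared = ref.cpg_ids.intersection(test.cpg_ids)
    if len(shared) == 0:
        raise ValueError("no shared CpGs between cohorts")
    return ref.subset_cpgs(shared), test.subset_cpgs(shared)


def preservation_observed(
    ref: ResidualMatrix,
    labels: pd.Series,
    test: ResidualMatrix,
    params: NetworkParams | None = None,
) -> pd.DataFrame:
    """Observed preservation statistics per reference module in the test cohort.

    CpGs are intersected by id; modules with fewer than 3 surviving CpGs
    are skipped.
    """
    params = params or NetworkParams()
    ref_a, test_a = _align(ref, test)
    out = {}
    for m in sorted(set(labels.unique()) - {0}):
        members = labels.index[labels == m].intersection(ref_a.cpg_ids)
        if len(members) < 3:
            logger.warning("module %s has <3 CpGs after intersection; skipped", m)
            continue
        ridx = ref_a.cpg_ids.get_indexer(members)
        tidx = test_a.cpg_ids.get_indexer(members)
        out[int(m)] = _module_stats_pair(
            ref_a.values[ridx], test_a.values[tidx], params.power
        )
    table = pd.DataFrame(out).T
    table.index.name = "module"
    return table


def preservation_null(
    ref: ResidualMatrix,
    test: ResidualMatrix,
    module_size: int,
    n_perm: int = 1000,
    seed: int = 0,
    params: NetworkParams | None = None,
) -> pd.DataFrame:
    """Null distribution of the preservation statistics for one module size.

    Each permutation draws a uniform random CpG set of ``module_size`` from
    the shared CpGs and treats it as the module in BOTH cohorts, so
    cross-cohort statistics stay well defined.  Returns an n_perm x 6
    DataFrame of statistic draws.
    """
    if n_perm < 50:
        logger.warning("n_perm=%d < 50 gives unstable Z statistics", n_perm)
    params = params or NetworkParams()
    ref_a, test_a = _align(ref, test)
    n = len(ref_a.cpg_ids)
    if n <= module_size:
        raise ValueError("test network has too few CpGs for the module size")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_perm):
        idx = rng.choice(n, size=module_size, replace=False)
        rows.append(_module_stats_pair(ref_a.values[idx], test_a.values[idx], params.power))
    return pd.DataFrame(rows)


def z_summary(
    observed: pd.DataFrame, null_draws: dict[int, pd.DataFrame]
) -> PreservationResult:
    """Z-score observed statistics against their permutation nulls.

    Z(stat) = (observed - null mean) / null SD; Z-density and
    Z-connectivity are medians of their component Zs (zero-SD statistics
    are excluded with a log notice); Z-summary is their mean.  median_rank
    is the median across statistics of the module's rank (1 = highest
    observed value) among all modules.
    """
    rows = {}
    for m in observed.index:
        null = null_draws[int(m)]
        zs = {}
        for s in STAT_NAMES:
            sd = null[s].std(ddof=1)
            if sd == 0 or np.isnan(sd):
                logger.warning("null SD of %s is zero for module %s; excluded", s, m)
                zs[s] = np.nan
            else:
                zs[s] = (observed.loc[m, s] - null[s].mean()) / sd
        z_density = np.nanmedian([zs[s] for s in DENSITY_STATS])
        z_connectivity = np.nanmedian([zs[s] for s in CONNECTIVITY_STATS])
        rows[int(m)] = {
            **{f"z_{s}": zs[s] for s in STAT_NAMES},
            "z_density": z_density,
            "z_connectivity": z_connectivity,
            "z_summary": (z_density + z_connectivity) / 2.0,
        }
    table = pd.DataFrame(rows).T
    table = observed.join(table)
    ranks = observed[STAT_NAMES].rank(ascending=False, method="average")
    table["median_rank"] = ranks.median(axis=1)
    # bands: > 10 high, 5..10 moderate (boundaries inclusive), < 5 none
    tol = 1e-9
    table["band"] = np.where(
        table["z_summary"] > 10.0 + tol,
        "high",
        np.where(table["z_summary"] >= 5.0 - tol, "moderate", "none"),
    )
    table.index.name = "module"
    n_perm = len(next(iter(null_draws.values()))) if null_draws else 0
    return PreservationResult(table, n_perm)


def module_preservation(
    ref: ResidualMatrix,
    labels: pd.Series,
    test: ResidualMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    params: NetworkParams | None = None,
) -> PreservationResult:
    """Observed statistics + per-module-size permutation null + Z-summary."""
    params = params or NetworkParams()
    observed = preservation_observed(ref, labels, test, params)
    ref_a, test_a = _align(ref, test)
    nulls: dict[int, pd.DataFrame] = {}
    size_cache: dict[int, pd.DataFrame] = {}
    for m in observed.index:
        size = int((labels == m).sum())
        size = min(size, len(ref_a.cpg_ids) - 1)
        if size not in size_cache:
            size_cache[size] = preservation_null(
                ref_a, test_a, size, n_perm=n_perm, seed=seed + size, params=params
            )
        nulls[int(m)] = size_cache[size]
    return z_summary(observed, nulls)


def replication_decision(
    pres_row: pd.Series, test_stats: ModuleStats, module: int, alpha: float = 0.05
) -> bool:
    """Replicated iff highly preserved (Z-summary > 10) AND the test cohort
    shows a significant MM-PS correlation AND module-trait test (p < alpha),
    computed with the reference module labels."""
    return bool(
        pres_row["z_summary"] > 10.0
        and test_stats.mmps.loc[module, "p"] < alpha
        and test_stats.trait_test.loc[module, "p"] < alpha
    )
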