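"""Unsigned weighted co-methylation network and module statistics.

The network follows the WGCNA recipe: adjacency ``a_ij = |cor(x_i,x_j)|^power``
(unsigned), topological overlap similarity, average-linkage clustering of
the TOM dissimilarity, module extraction with a minimum size, eigengene
merging, and the module-level statistics used for trait association —
module eigengenes (ME, first principal component of the module), module
membership (kME), probe significance (point-biserial correlation with the
binary trait), the module–trait Welch t-test, the MM–PS correlation, and
hub CpG selection (top quartile of both |MM| and |PS|).

Large networks are handled blockwise: CpGs are pre-clustered into balanced
blocks (k-means on principal-component loadings), modules are cut per
block, and eigengene merging across blocks reconciles split modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from comethnet.types import ModuleAssignment, ModuleStats, ResidualMatrix

__all__ = [
    "NetworkParams",
    "pick_soft_threshold",
    "build_adjacency",
    "tom_similarity",
    "partition_blocks",
    "cut_modules",
    "module_eigengenes",
    "merge_modules",
    "detect_modules",
    "module_membership",
    "probe_significance",
    "module_trait_test",
    "mm_ps_correlation",
    "compute_module_stats",
    "select_candidate_modules",
    "hub_probes",
]

GREY = 0  # unassigned label


@dataclass
class NetworkParams:
    """Network construction parameters (defaults: unsigned, power 3,
    max block 30,000 CpGs, minimum module size 100, merge height 0.15)."""

    power: float = 3.0
    max_block_size: int = 30_000
    min_module_size: int = 100
    merge_cut_height: float = 0.15
    signed: bool = False
    cut_height_fraction: float = 0.99  # static-cut fraction of the tree height
    reassign_p: float = 1e-3  # kME significance for the final membership sweep

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    x = values - values.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        bad = np.flatnonzero(sd.ravel() == 0)
        raise ValueError(f"zero-variance rows at indices {bad[:10].tolist()}")
    return x / sd


def _row_correlation(values: np.ndarray) -> np.ndarray:
    z = _standardize_rows(values)
    r = (z @ z.T) / z.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def build_adjacency(mat: ResidualMatrix | np.ndarray, params: NetworkParams) -> np.ndarray:
    """Unsigned adjacency ``|cor|^power`` (signed option: ((1+cor)/2)^power)."""
    values = mat.values if isinstance(mat, ResidualMatrix) else np.asarray(mat, float)
    try:
        r = _row_correlation(values)
    except ValueError as exc:
        if isinstance(mat, ResidualMatrix) and "zero-variance" in str(exc):
            sd = values.std(axis=1)
            ids = mat.cpg_ids[sd == 0][:10].tolist()
            raise ValueError(f"zero-variance CpGs: {ids}") from exc
        raise
    base = (1.0 + r) / 2.0 if params.signed else np.abs(r)
    adj = base**params.power
    np.fill_diagonal(adj, 1.0)
    return adj


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity (row sum minus
    the diagonal).  TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    l = a @ a - 2.0 * a  # removes u=i and u=j terms given unit diagonal
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def pick_soft_threshold(
    mat: ResidualMatrix,
    powers: list[float] | None = None,
    max_cpgs: int = 2000,
    n_bins: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Scale-free topology fit index and mean connectivity per candidate power.

    For each power the unsigned adjacency is built on a random subsample of
    at most ``max_cpgs`` CpGs; connectivities are binned on log10 scale and
    the signed R^2 of the log-frequency vs log-mean-connectivity regression
    is reported (the standard scale-free criterion).
    """
    powers = powers or [1, 2, 3, 4, 5, 6, 8, 10]
    n = len(mat.cpg_ids)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=min(max_cpgs, n), replace=False))
    values = mat.values[idx]
    r = np.abs(_row_correlation(values))
    rows = []
    for power in powers:
        adj = r**power
        np.fill_diagonal(adj, 1.0)
        k = adj.sum(axis=1) - 1.0
        degenerate = bool(k.std() < 1e-6 * max(k.mean(), 1.0) or (k <= 0).all())
        if degenerate:
            rows.append((power, 0.0, float(k.mean()), True))
            continue
        logk = np.log10(np.maximum(k, 1e-300))
        edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            members = which == b
            if members.sum() == 0:
                continue
            xs.append(logk[members].mean())
            ys.append(np.log10(members.mean()))
        if len(xs) < 3:
            rows.append((power, 0.0, float(k.mean()), True))
            continue
        slope, _, rval, _, _ = stats.linregress(xs, ys)
        rows.append((power, float(np.sign(slope) * rval**2), float(k.mean()), False))
    return pd.DataFrame(
        rows, columns=["power", "scale_free_r2", "mean_connectivity", "degenerate"]
    )


def partition_blocks(
    mat: ResidualMatrix, max_block_size: int, seed: int = 0
) -> list[np.ndarray]:
    """Split CpGs into balanced blocks of at most ``max_block_size``.

    CpGs are embedded by their loadings on the top-8 sample-space principal
    components and clustered with k-means into ceil(n/max) groups; clusters
    over capacity shed their farthest members to the nearest cluster with
    room.  Returns a list of index arrays partitioning range(n).
    """
    n = len(mat.cpg_ids)
    if n <= max_block_size:
        return [np.arange(n)]
    n_blocks = math.ceil(n / max_block_size)
    z = _standardize_rows(mat.values)
    n_comp = min(8, z.shape[1] - 1, n - 1)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    emb = u[:, :n_comp] * s[:n_comp]

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_blocks, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    centers = km.cluster_centers_
    capacity = max_block_size

    dist = ((emb[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    sizes = np.bincount(labels, minlength=n_blocks)
    # move farthest members out of over-full clusters into the nearest
    # cluster with spare capacity (deterministic order)
    for b in np.argsort(-sizes):
        while sizes[b] > capacity:
            members = np.flatnonzero(labels == b)
            worst = members[np.argmax(dist[members, b])]
            order = np.argsort(dist[worst])
            for target in order:
                if target != b and sizes[target] < capacity:
                    labels[worst] = target
                    sizes[b] -= 1
                    sizes[target] += 1
                    break
            else:  # pragma: no cover - cannot happen with ceil(n/max) blocks
                raise RuntimeError("no block with spare capacity")
    return [np.flatnonzero(labels == b) for b in range(n_blocks)]


def _leaf_join_heights(z: np.ndarray, n: int) -> np.ndarray:
    """Height at which each original leaf first merges into the tree."""
    h = np.zeros(n)
    for a, b, height, _ in z:
        for side in (int(a), int(b)):
            if side < n:
                h[side] = height
    return h


def _tight_enough(
    d_sub: np.ndarray,
    corr_sub: np.ndarray | None,
    n_samples: int | None,
    background_dissim: float,
    tight_mult: float = 2.5,
) -> bool:
    """Is a cluster's internal similarity clearly above the chance level?

    With the |correlation| matrix and sample count available, the reference
    is the median |r| of an uncorrelated pair (~0.6745/sqrt(n-1)); a
    genuine co-methylation module must beat ``tight_mult`` times that.
    Otherwise, fall back to requiring the mean internal TOM dissimilarity
    to sit well below the matrix-wide background.
    """
    m = d_sub.shape[0]
    off = ~np.eye(m, dtype=bool)
    if corr_sub is not None and n_samples is not None:
        null_abs_r = 0.6745 / np.sqrt(max(n_samples - 1, 1))
        return float(corr_sub[off].mean()) > tight_mult * null_abs_r
    return float(d_sub[off].mean()) < 0.9 * background_dissim


def _recursive_cut(
    d: np.ndarray,
    idx: np.ndarray,
    params: NetworkParams,
    corr_abs: np.ndarray | None,
    n_samples: int | None,
    out: list[np.ndarray],
    background_dissim: float,
    depth: int = 0,
    shave_gap_fraction: float = 0.10,
) -> None:
    n = len(idx)
    if n < params.min_module_size or depth > 30:
        return
    d_sub = d[np.ix_(idx, idx)]
    if n == 1:
        return
    z = hierarchy.linkage(squareform(d_sub, checks=False), method="average")
    root = z[-1, 2]
    if root <= 1e-12:  # fully degenerate: one perfectly tight cluster
        out.append(idx)
        return

    # 1. straggler shaving: a clear gap in the leaf join heights, in the
    #    tail beyond a minimum-size core, separates chained-on leaves
    #    (for example noise CpGs glued onto a module) from the branch core
    join = _leaf_join_heights(z, n)
    order = np.argsort(join, kind="stable")
    sorted_join = join[order]
    gaps = np.diff(sorted_join)
    span = sorted_join[-1] - sorted_join[0]
    lo = params.min_module_size - 1
    if span > 0 and lo < len(gaps):
        tail = gaps[lo:]
        g = lo + int(np.argmax(tail))
        core_size = g + 1
        if tail.max() > shave_gap_fraction * span and core_size < n:
            _recursive_cut(d, idx[order[:core_size]], params, corr_abs, n_samples,
                           out, background_dissim, depth + 1)
            return

    # 2. split at a static cut near the top of this branch's tree
    cut = params.cut_height_fraction * root
    flat = hierarchy.fcluster(z, t=cut, criterion="distance")
    branches = [np.flatnonzero(flat == c) for c in np.unique(flat)]
    big = [b for b in branches if len(b) >= params.min_module_size]
    if len(big) >= 2:
        # descend into every minimum-size branch; oversplitting a genuine
        # module is repaired downstream by eigengene merging and the kME
        # membership sweep, whereas under-splitting cannot be repaired
        for members in big:
            _recursive_cut(d, idx[members], params, corr_abs, n_samples,
                           out, background_dissim, depth + 1)
        return
    elif len(big) == 1 and (n - len(big[0])) > 0.25 * n:
        # one dense branch in a sea of unclustered leaves: descend into it
        _recursive_cut(d, idx[big[0]], params, corr_abs, n_samples,
                       out, background_dissim, depth + 1)
        return

    # 3. atomic branch: keep as a module only if genuinely tight
    corr_sub = corr_abs[np.ix_(idx, idx)] if corr_abs is not None else None
    if _tight_enough(d_sub, corr_sub, n_samples, background_dissim):
        out.append(idx)


def cut_modules(
    tom_dissim: np.ndarray,
    params: NetworkParams,
    corr_abs: np.ndarray | None = None,
    n_samples: int | None = None,
) -> np.ndarray:
    """Extract preliminary module labels from a TOM dissimilarity matrix.

    A dynamic branch cut in the spirit of the hybrid dynamic tree cut:
    average-linkage clustering, recursive descent that (a) shaves straggler
    leaves chained onto a branch (largest gap in leaf join heights),
    (b) splits branches whose top merge is clearly higher than their
    internal structure, and (c) accepts an atomic branch as a module only
    when its internal similarity clearly exceeds the chance level (see
    ``_tight_enough``; pass ``corr_abs`` and ``n_samples`` to calibrate it).  Clusters
    smaller than ``min_module_size`` are unassigned (label 0).  Labels are
    1..K in decreasing module size (ties by smallest member index), so
    they are stable under CpG reordering.
    """
    d = np.asarray(tom_dissim, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity must be square and symmetric")
    n = d.shape[0]
    labels = np.zeros(n, dtype=int)
    if n < 2:
        return labels
    found: list[np.ndarray] = []
    background = float(np.median(d[np.triu_indices(n, k=1)]))
    _recursive_cut(d, np.arange(n), params, corr_abs, n_samples, found, background)
    found.sort(key=lambda m: (-len(m), m[0]))
    for new_label, members in enumerate(found, start=1):
        labels[members] = new_label
    return labels


def module_eigengenes(
    mat: ResidualMatrix, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    Rows of the returned module x sample DataFrame are unit-length right
    singular vectors, sign-aligned so the mean correlation with member
    CpGs is non-negative.
    """
    lab = np.asarray(labels if not isinstance(labels, pd.Series) else labels.to_numpy())
    mes = {}
    for m in sorted(set(lab) - {GREY}):
        members = np.flatnonzero(lab == m)
        if len(members) < 1:
            continue
        sub = mat.values[members]
        if (sub.std(axis=1) == 0).any():
            bad = mat.cpg_ids[members][sub.std(axis=1) == 0][:5].tolist()
            raise ValueError(f"zero-variance CpGs in module {m}: {bad}")
        z = _standardize_rows(sub)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        if (z @ me).mean() < 0:  # mean cor with members, up to positive scale
            me = -me
        mes[int(m)] = me
    out = pd.DataFrame(mes).T
    out.columns = mat.sample_ids
    out.index.name = "module"
    return out


def merge_modules(
    mat: ResidualMatrix,
    labels: np.ndarray | pd.Series,
    merge_cut_height: float = 0.15,
    use_abs: bool = True,
) -> ModuleAssignment:
    """Merge modules whose eigengenes are closer than ``merge_cut_height``.

    Iteratively merges the closest qualifying pair (1 - |cor(ME)| < height),
    recomputing eigengenes after every merge, until no pair qualifies.
    Absolute eigengene correlation is the default because in an unsigned
    network a module mixes anti-correlated CpGs, which leaves the ME sign
    convention arbitrary — two halves of one split module can anticorrelate
    perfectly; ``use_abs=False`` restores signed merging for signed
    networks.  Closest-pair-first processing makes the result independent
    of input ordering.  Final labels are renumbered 1..K by decreasing size.
    """
    lab = np.array(labels if not isinstance(labels, pd.Series) else labels.to_numpy())
    while True:
        modules = sorted(set(lab) - {GREY})
        if len(modules) < 2:
            break
        mes = module_eigengenes(mat, lab)
        me_arr = mes.to_numpy()
        r = np.corrcoef(me_arr)
        if use_abs:
            r = np.abs(r)
        np.fill_diagonal(r, -np.inf)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if 1.0 - r[i, j] >= merge_cut_height:
            break
        a, b = mes.index[i], mes.index[j]
        lab[lab == max(a, b)] = min(a, b)

    # renumber by decreasing size, ties by smallest member index
    sizes = [(-(lab == m).sum(), np.flatnonzero(lab == m)[0], m)
             for m in sorted(set(lab) - {GREY})]
    sizes.sort()
    relabel = {old: new for new, (_, _, old) in enumerate(sizes, start=1)}
    new_lab = np.array([relabel.get(v, GREY) for v in lab])
    mes = module_eigengenes(mat, new_lab) if relabel else pd.DataFrame(
        np.empty((0, len(mat.sample_ids))), columns=mat.sample_ids
    )
    label_series = pd.Series(new_lab, index=mat.cpg_ids, name="module")
    size_series = label_series[label_series != GREY].value_counts().sort_index()
    return ModuleAssignment(label_series, mes, size_series)


def _kme_sweep(
    mat: ResidualMatrix, assignment: ModuleAssignment, params: NetworkParams
) -> ModuleAssignment:
    """Final membership pass: each CpG joins its argmax-|kME| module when
    that correlation is significant (Bonferroni-style cut), else grey.

    Reconciles peripheral members across blocks: a CpG whose module core
    landed in another block still joins it, and weakly attached CpGs drop
    out symmetrically in single- and multi-block runs.
    """
    if assignment.eigengenes.empty:
        return assignment
    mm, mm_p = module_membership(mat, assignment.eigengenes)
    best = mm.abs().to_numpy().argmax(axis=1)
    modules = np.asarray(assignment.eigengenes.index)
    best_p = mm_p.to_numpy()[np.arange(len(best)), best]
    labels = np.where(best_p < params.reassign_p, modules[best], GREY)
    # drop modules that fell below the minimum size
    sizes = pd.Series(labels).value_counts()
    for m in modules:
        if sizes.get(m, 0) < params.min_module_size:
            labels[labels == m] = GREY
    return merge_modules(mat, labels, merge_cut_height=0.0)


def detect_modules(
    mat: ResidualMatrix, params: NetworkParams | None = None, seed: int = 0
) -> ModuleAssignment:
    """Blockwise module detection: partition, per-block TOM + tree cut,
    eigengene merging across blocks, and a final kME membership sweep."""
    params = params or NetworkParams()
    blocks = partition_blocks(mat, params.max_block_size, seed=seed)
    labels = np.zeros(len(mat.cpg_ids), dtype=int)
    offset = 0
    for block in blocks:
        sub = mat.values[block]
        adj = build_adjacency(ResidualMatrix(sub, mat.cpg_ids[block], mat.sample_ids), params)
        tom = tom_similarity(adj)
        block_labels = cut_modules(
            1.0 - tom, params,
            corr_abs=adj ** (1.0 / params.power),
            n_samples=len(mat.sample_ids),
        )
        nonzero = block_labels > 0
        labels[block[nonzero]] = block_labels[nonzero] + offset
        if block_labels.max(initial=0) > 0:
            offset += block_labels.max()
    merged = merge_modules(mat, labels, params.merge_cut_height)
    return _kme_sweep(mat, merged, params)


# ---------------------------------------------------------------------------
# module statistics


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of x (rows) against y (vector) with t-based p."""
    n = x.shape[-1]
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(-1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return r, np.clip(p, 0.0, 1.0)


def module_membership(
    mat: ResidualMatrix, me: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME: Pearson r (and p) of every CpG against every module eigengene."""
    rs, ps = {}, {}
    for m in me.index:
        r, p = _pearson_with_p(mat.values, me.loc[m].to_numpy())
        rs[m], ps[m] = r, p
    mm = pd.DataFrame(rs, index=mat.cpg_ids)
    mm_p = pd.DataFrame(ps, index=mat.cpg_ids)
    return mm, mm_p


def probe_significance(
    mat: ResidualMatrix, trait: np.ndarray | pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Point-biserial correlation of each CpG with the 0/1 trait."""
    t = np.asarray(trait, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("trait must have both classes")
    r, p = _pearson_with_p(mat.values, t)
    return (
        pd.Series(r, index=mat.cpg_ids, name="ps"),
        pd.Series(p, index=mat.cpg_ids, name="ps_p"),
    )


def module_trait_test(me: pd.DataFrame, trait: np.ndarray | pd.Series) -> pd.DataFrame:
    """Welch two-sample t-test of each module eigengene between trait groups."""
    t = np.asarray(trait, dtype=float)
    g1, g0 = t == 1, t == 0
    if g1.sum() < 2 or g0.sum() < 2:
        raise ValueError("need at least 2 samples per trait group")
    rows = {}
    for m in me.index:
        v = me.loc[m].to_numpy()
        tt = stats.ttest_ind(v[g1], v[g0], equal_var=False)
        rows[m] = (tt.statistic, tt.pvalue)
    return pd.DataFrame(rows, index=["t", "p"]).T


def mm_ps_correlation(
    mm: pd.DataFrame, ps: pd.Series, labels: pd.Series, module: int
) -> tuple[float, float, bool]:
    """Pearson correlation between |MM| and |PS| over a module's CpGs.

    Returns (r, p, degenerate); degenerate when either vector has zero
    variance, in which case r = 0 and p = 1.
    """
    members = labels.index[labels == module]
    if len(members) < 3:
        raise ValueError("module must have at least 3 CpGs")
    x = mm.loc[members, module].abs().to_numpy()
    y = ps.loc[members].abs().to_numpy()
    if x.std() == 0 or y.std() == 0:
        return 0.0, 1.0, True
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), False


def compute_module_stats(
    mat: ResidualMatrix, assignment: ModuleAssignment, trait: np.ndarray | pd.Series
) -> ModuleStats:
    """All module statistics for a given assignment and binary trait."""
    mm, mm_p = module_membership(mat, assignment.eigengenes)
    ps, ps_p = probe_significance(mat, trait)
    trait_test = module_trait_test(assignment.eigengenes, trait)
    rows = {}
    for m in assignment.module_ids:
        r, p, degen = mm_ps_correlation(mm, ps, assignment.labels, m)
        rows[m] = (r, p, degen)
    mmps = pd.DataFrame(rows, index=["r", "p", "degenerate"]).T
    return ModuleStats(mm, mm_p, ps, ps_p, trait_test, mmps)


def select_candidate_modules(stats_: ModuleStats, alpha: float = 0.05) -> list[int]:
    """Modules with trait-test p < alpha and a significant positive MM-PS
    correlation (p < alpha, r > 0)."""
    out = []
    for m in stats_.trait_test.index:
        if (
            stats_.trait_test.loc[m, "p"] < alpha
            and stats_.mmps.loc[m, "p"] < alpha
            and stats_.mmps.loc[m, "r"] > 0
        ):
            out.append(int(m))
    return out


def hub_probes(
    stats_: ModuleStats,
    labels: pd.Series,
    module: int,
    top_fraction: float = 0.25,
) -> list[str]:
    """Hub CpGs: intersection of the top-|MM| and top-|PS| quartiles
    within a module (ties broken by CpG id)."""
    members = labels.index[labels == module]
    if len(members) < 4:
        raise ValueError("module must have at least 4 CpGs")
    n_top = math.ceil(top_fraction * len(members))
    mm_rank = sorted(members, key=lambda c: (-abs(stats_.mm.loc[c, module]), c))
    ps_rank = sorted(members, key=lambda c: (-abs(stats_.ps.loc[c]), c))
    top_mm = set(mm_rank[:n_top])
    top_ps = set(ps_rank[:n_top])
    return sorted(top_mm & top_ps)
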