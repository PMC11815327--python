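"""Confounder residualization, sample-outlier screening and the MAD filter.

Confounders (age, sex, Braak stage, cell proportions, plate) are regressed
out of every CpG's beta values with an ordinary-least-squares fit on the
beta scale; downstream network construction uses the residuals.  CpGs are
then ranked by (unscaled) median absolute deviation and the most variable
fraction retained.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from comethnet.types import BetaMatrix, ResidualMatrix

__all__ = [
    "build_design_matrix",
    "residualize",
    "mad_filter",
    "sample_outlier_check",
]

_CATEGORICAL = ("sex", "plate")


def build_design_matrix(
    covariates: pd.DataFrame, categorical: tuple[str, ...] = _CATEGORICAL
) -> pd.DataFrame:
    """Intercept + covariates, one-hot encoding categoricals (drop first).

    Compositional cell-proportion columns should already exclude one
    reference component (the caller passes all-but-one proportion columns).
    """
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        if col in categorical or covariates[col].dtype == object:
            dummies = pd.get_dummies(
                covariates[col], prefix=col, drop_first=True, dtype=float
            )
            parts.append(dummies)
        else:
            parts.append(covariates[col].astype(float))
    design = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return design


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Name columns whose removal restores full rank (greedy QR-based scan)."""
    x = design.to_numpy()
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [c for c, d in zip(design.columns, diag) if d < tol]


def residualize(beta: BetaMatrix | ResidualMatrix, covariates: pd.DataFrame) -> ResidualMatrix:
    """OLS residuals of every CpG on [intercept + covariates].

    Rows of the result have mean ~0 (the intercept is always included) and
    are orthogonal to every covariate column.
    """
    if not covariates.index.equals(pd.Index(beta.sample_ids)):
        covariates = covariates.loc[beta.sample_ids]
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {bad}")
    design = build_design_matrix(covariates)
    q, _ = np.linalg.qr(design.to_numpy())
    vals = np.asarray(beta.values, dtype=float)
    resid = vals - (vals @ q) @ q.T
    return ResidualMatrix(
        resid,
        beta.cpg_ids,
        beta.sample_ids,
        covariates_removed=list(design.columns[1:]),
        cpg_map=beta.cpg_map,
    )


def mad_filter(mat: ResidualMatrix, keep_fraction: float = 0.5) -> ResidualMatrix:
    """Keep the ceil(keep_fraction * n) CpGs with highest MAD.

    MAD is the unscaled median of |x - median(x)| per CpG; ranking is
    invariant to the 1.4826 consistency constant so it is omitted.  Ties
    break by CpG id (lexicographic) for determinism.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    med = np.median(mat.values, axis=1, keepdims=True)
    mad = np.median(np.abs(mat.values - med), axis=1)
    n_keep = math.ceil(keep_fraction * len(mad))
    order = sorted(range(len(mad)), key=lambda i: (-mad[i], mat.cpg_ids[i]))
    keep = sorted(order[:n_keep])  # preserve original row order
    return ResidualMatrix(
        mat.values[keep],
        mat.cpg_ids[keep],
        mat.sample_ids,
        list(mat.covariates_removed),
        mat.cpg_map.loc[mat.cpg_ids[keep]] if mat.cpg_map is not None else None,
    )


def _singleton_outliers(dist_condensed: np.ndarray, n: int) -> set[int]:
    """Samples merging into an average-linkage tree as late singleton branches."""
    z = hierarchy.linkage(dist_condensed, method="average")
    heights = z[:, 2]
    q1, q3 = np.percentile(heights, [25, 75])
    threshold = np.median(heights) + 3.0 * (q3 - q1)
    flagged: set[int] = set()
    for a, b, h, _ in z:
        if h <= threshold:
            continue
        for side in (int(a), int(b)):
            if side < n:  # original observation, still a singleton at this merge
                flagged.add(side)
    return flagged


def sample_outlier_check(mat: ResidualMatrix) -> list[str]:
    """Flag samples that are extreme singleton branches under BOTH Euclidean
    and correlation distance (average-linkage trees).

    A sample is flagged only when its merge height exceeds
    median + 3*IQR of all merge heights in both trees.  Nothing is dropped
    automatically; the caller decides.
    """
    x = mat.values.T  # sample x CpG
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    d_euc = squareform(_euclidean(x), checks=False)
    corr = np.corrcoef(x)
    d_cor = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    flagged = _singleton_outliers(d_euc, n) & _singleton_outliers(d_cor, n)
    return sorted(mat.sample_ids[i] for i in flagged)


def _euclidean(x: np.ndarray) -> np.ndarray:
    sq = (x**2).sum(1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))
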