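"""Within-diagnosis phenotype clustering.

Preprocessing (on the whole cohort): mean imputation of missing feature
cells, removal of near-zero-variance features, z-standardization.  A PCA
feature space keeps the smallest number of leading components reaching 90%
cumulative explained variance.  Within each diagnosis group, k-means is run
for k = 2..10 (k-means++ initialization, 50 restarts) and k is chosen by
the Calinski-Harabasz criterion; clusters with fewer than 10 members are
flagged and excluded from the between-cluster comparisons.  Comparisons are
Welch t-tests on the ORIGINAL feature scales (plus demographics), with
Benjamini-Hochberg adjustment applied within each diagnosis group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .evaluate import bh_adjust

MIN_CLUSTER_SIZE = 10
NEAR_ZERO_VARIANCE = 1e-8


@dataclass
class PreprocessedMatrix:
    values: np.ndarray  # participants x retained features, standardized
    feature_names: list[str]
    dropped: list[str]
    impute_means: np.ndarray
    center: np.ndarray
    scale: np.ndarray


@dataclass
class ClusterResult:
    group: str
    k: int
    assignments: np.ndarray
    ch_by_k: dict[int, float]
    excluded_clusters: list[int] = field(default_factory=list)

    @property
    def retained_clusters(self) -> list[int]:
        return [
            c for c in np.unique(self.assignments) if c not in self.excluded_clusters
        ]


def preprocess(
    table: pd.DataFrame,
    feature_names: list[str],
    max_missing: float = 0.05,
    on_excess_missing: str = "error",
) -> PreprocessedMatrix:
    """Impute (column mean), drop near-zero-variance features, standardize.

    Features missing in more than ``max_missing`` of participants either
    raise (default) or are dropped (``on_excess_missing='drop'``, used by the
    end-to-end pipeline, where stage-conditional features such as wake-band
    power in a quarter with no wake can be structurally missing).  Features
    with no observed value at all are always dropped, with a warning.
    """
    X = table[list(feature_names)].to_numpy(dtype=float)
    frac_missing = np.mean(~np.isfinite(X), axis=0)
    all_missing = frac_missing >= 1.0
    excess = (frac_missing > max_missing) & ~all_missing
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} all-missing features",
            stacklevel=2,
        )
    if excess.any():
        bad = [f for f, m in zip(feature_names, excess) if m]
        if on_excess_missing == "error":
            raise ValueError(
                f"features exceed {max_missing:.0%} missingness: {bad[:5]}..."
            )
        warnings.warn(
            f"dropping {len(bad)} features above {max_missing:.0%} missingness",
            stacklevel=2,
        )
    elif np.any(frac_missing > 0.02):
        warnings.warn("some features exceed 2% missingness", stacklevel=2)

    finite = np.isfinite(X)
    counts = finite.sum(axis=0)
    sums = np.where(finite, X, 0.0).sum(axis=0)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    X = np.where(np.isfinite(X), X, means)

    variances = X.var(axis=0)
    n_distinct = np.array([np.unique(col).size for col in X.T])
    keep = (variances >= NEAR_ZERO_VARIANCE) & (n_distinct >= 2) & ~all_missing
    if on_excess_missing == "drop":
        keep &= ~excess
    dropped = [f for f, k in zip(feature_names, keep) if not k]

    center = X[:, keep].mean(axis=0)
    scale = X[:, keep].std(axis=0)
    values = (X[:, keep] - center) / scale
    return PreprocessedMatrix(
        values=values,
        feature_names=[f for f, k in zip(feature_names, keep) if k],
        dropped=dropped,
        impute_means=means,
        center=center,
        scale=scale,
    )


def pca_space(matrix: np.ndarray, variance_threshold: float = 0.90) -> np.ndarray:
    """Project onto the smallest number of leading principal components with
    cumulative explained variance >= the threshold."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 participants")
    pca = PCA()
    coords = pca.fit_transform(matrix)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    if not np.isfinite(cumvar[-1]) or cumvar[-1] <= 0:
        raise ValueError("degenerate matrix: no variance to decompose")
    m = int(np.searchsorted(cumvar, variance_threshold - 1e-12) + 1)
    return coords[:, :m]


def calinski_harabasz(points: np.ndarray, assignments: np.ndarray) -> float:
    """Between/within dispersion ratio: (B/(k-1)) / (W/(n-k)).

    Returns +inf when within-cluster dispersion is exactly zero.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    n, k = points.shape[0], labels.size
    if k < 2 or n <= k:
        raise ValueError("need 2 <= k < n")
    grand = points.mean(axis=0)
    between = within = 0.0
    for lab in labels:
        cluster = points[assignments == lab]
        if cluster.size == 0:
            raise ValueError("empty cluster")
        centroid = cluster.mean(axis=0)
        between += cluster.shape[0] * np.sum((centroid - grand) ** 2)
        within += np.sum((cluster - centroid) ** 2)
    if within == 0.0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def cluster_group(
    points: np.ndarray,
    group: str = "",
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_restarts: int = 50,
    criterion: str = "maximize",
) -> ClusterResult:
    """k-means over a k range with Calinski-Harabasz model selection.

    ``criterion`` selects the direction applied to the CH index; the
    standard reading (higher = better separated) is the default.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n <= MIN_CLUSTER_SIZE:
        raise ValueError("group too small to cluster")
    if criterion not in ("maximize", "minimize"):
        raise ValueError("criterion must be 'maximize' or 'minimize'")
    k_lo, k_hi = k_range
    if n <= k_hi:
        k_hi = n - 1  # shrink the range for small groups

    ch_by_k: dict[int, float] = {}
    assignments_by_k: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            tol=1e-6,
            random_state=seed,
        ).fit(points)
        ch_by_k[k] = calinski_harabasz(points, km.labels_)
        assignments_by_k[k] = km.labels_
    pick = max if criterion == "maximize" else min
    best_k = pick(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    assignments = assignments_by_k[best_k]
    sizes = np.bincount(assignments, minlength=best_k)
    excluded = [c for c in range(best_k) if sizes[c] < MIN_CLUSTER_SIZE]
    return ClusterResult(
        group=group,
        k=best_k,
        assignments=assignments,
        ch_by_k=ch_by_k,
        excluded_clusters=excluded,
    )


def compare_clusters(
    table: pd.DataFrame,
    result: ClusterResult,
    columns: list[str],
) -> pd.DataFrame:
    """Welch t-tests between the group's two retained clusters on original
    feature scales; BH adjustment within this group's family of tests.

    ``table`` must contain only the group's participants, in the order used
    for clustering.  Columns may include demographics (never used in the
    clustering itself).  If more than two clusters survive the size filter,
    the two largest are compared.
    """
    if len(table) != result.assignments.size:
        raise ValueError("table and assignments length mismatch")
    retained = result.retained_clusters
    if len(retained) < 2:
        raise ValueError("fewer than two retained clusters to compare")
    if len(retained) > 2:
        sizes = {c: np.sum(result.assignments == c) for c in retained}
        retained = sorted(sizes, key=sizes.get, reverse=True)[:2]
    c1, c2 = retained
    a = table[result.assignments == c1]
    b = table[result.assignments == c2]

    rows = []
    for col in columns:
        x = a[col].dropna().to_numpy(dtype=float)
        y = b[col].dropna().to_numpy(dtype=float)
        m1 = x.mean() if x.size else np.nan
        m2 = y.mean() if y.size else np.nan
        pct = 100.0 * (m1 - m2) / m2 if np.isfinite(m2) and m2 != 0 else np.nan
        if x.size > 1 and y.size > 1 and (x.std() > 0 or y.std() > 0):
            t, p = stats.ttest_ind(x, y, equal_var=False)
        else:
            t, p = np.nan, np.nan  # constant in both clusters, or too small
        rows.append(
            {
                "feature": col,
                f"mean_c{c1}": m1,
                f"mean_c{c2}": m2,
                "pct_diff": pct,
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["sig"] = out["p"] < 0.05
    out["sig_adj"] = out["p_adj"] < 0.05
    return out
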