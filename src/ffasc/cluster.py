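"""Cluster-based validation of the criteria matrix.

The screen's ranking is cross-checked by unsupervised structure: k-means
partitions of the species × criteria matrix, silhouette and
Calinski–Harabasz (CH) quality indices, and a "natural k" heuristic that
uses known outgroup species (eukaryotic diatoms among cyanobacteria) to
bracket the plausible cluster counts — the scan looks for the k at which
the outgroup first occupies a cluster of its own and stops once it starts
splitting across clusters.  A heatmap layout (noise-stabilised matrix,
double z-standardisation, Spearman-distance average-linkage leaf orders)
supports the visual comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import cdist, squareform
from scipy import stats
from scipy.stats import spearmanr

from .errors import ClusteringError

OutlierStatus = Literal["mixed", "exclusive_together", "split"]

#: Sentinel returned by :func:`calinski_harabasz` when the within-cluster
#: scatter is exactly zero (clusters of coincident points).
INFINITE_SEPARATION = float("inf")


@dataclass
class ClusterAssignment:
    species_ids: list[str]
    labels: np.ndarray  # integer cluster ids in 1..k
    k: int
    inertia: float

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in zip(self.species_ids, self.labels) if c == cluster]


@dataclass
class KScanRecord:
    k: int
    labels: np.ndarray
    avg_silhouette: float
    ch_index: float
    outlier_status: OutlierStatus


@dataclass
class ClusterValidationReport:
    records: list[KScanRecord]
    candidate_ks: list[int]
    selected_k: int | None
    warnings: list[str] = field(default_factory=list)


@dataclass
class HeatmapLayout:
    row_order: np.ndarray
    column_order: np.ndarray
    transformed_matrix: np.ndarray


def _as_array(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(i) for i in matrix.index]
    arr = np.asarray(matrix, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    """Lloyd's algorithm; returns labels, centers and the inertia trace.

    The within-cluster sum of squares is non-increasing across iterations.
    Empty clusters are refilled with the point farthest from its center.
    """
    k = centers.shape[0]
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = d2.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                # refill with the farthest point that is not the sole
                # member of its current cluster
                counts = np.bincount(new_labels, minlength=k)
                costs = d2[np.arange(len(X)), new_labels]
                costs = np.where(counts[new_labels] > 1, costs, -np.inf)
                worst = costs.argmax()
                new_labels[worst] = c
                d2[worst, :] = -np.inf  # exclude from further refills
        inertia = float(
            ((X - centers[new_labels]) ** 2).sum()
        )
        trace.append(inertia)
        if np.array_equal(new_labels, labels) and len(trace) > 1:
            break
        labels = new_labels
        centers = np.vstack(
            [X[labels == c].mean(axis=0) for c in range(k)]
        )
    inertia = float(((X - centers[labels]) ** 2).sum())
    trace.append(inertia)
    return labels, centers, trace


def kmeans_cluster(
    matrix: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterAssignment:
    """Best-of-restarts k-means under squared Euclidean distance.

    Each restart initialises the centers with ``k`` distinct rows drawn
    uniformly at random; the restart with the lowest within-cluster sum of
    squares wins.  Deterministic for a fixed seed.
    """
    X, species_ids = _as_array(matrix)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ClusteringError(f"k={k} outside 1..{n}")
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        labels, _, trace = _lloyd(X, X[idx].copy())
        if trace[-1] < best_inertia:
            best_inertia, best_labels = trace[-1], labels
    assert best_labels is not None
    return ClusterAssignment(species_ids, best_labels + 1, k, best_inertia)


def _check_labels(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ClusteringError("label length does not match matrix rows")
    return labels


def average_silhouette(
    matrix: pd.DataFrame | np.ndarray,
    assignment: ClusterAssignment | np.ndarray,
) -> float:
    """Mean silhouette width of a partition, in [-1, 1].

    Per point: ``(b - a) / max(a, b)`` with ``a`` the mean distance to the
    other members of its own cluster and ``b`` the smallest mean distance
    to another cluster (Euclidean).  Points in singleton clusters, and the
    0/0 case of coincident points, contribute 0.
    """
    X, _ = _as_array(matrix)
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    labels = _check_labels(X, labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ClusteringError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    sil = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            sil[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def calinski_harabasz(
    matrix: pd.DataFrame | np.ndarray,
    assignment: ClusterAssignment | np.ndarray,
) -> float:
    """Calinski–Harabasz index [B/(k-1)] / [W/(n-k)].

    ``B`` is the between-cluster and ``W`` the within-cluster sum of
    squares about the centroids.  Returns the ``INFINITE_SEPARATION``
    sentinel when ``W`` is exactly 0.
    """
    X, _ = _as_array(matrix)
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    labels = _check_labels(X, labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], len(uniq)
    if k < 2 or k >= n:
        raise ClusteringError(f"CH index requires 2 <= k < n (k={k}, n={n})")
    grand = X.mean(axis=0)
    W = 0.0
    B = 0.0
    for c in uniq:
        block = X[labels == c]
        centroid = block.mean(axis=0)
        W += float(((block - centroid) ** 2).sum())
        B += block.shape[0] * float(((centroid - grand) ** 2).sum())
    if W == 0.0:
        return INFINITE_SEPARATION
    return (B / (k - 1)) / (W / (n - k))


def outlier_status(labels: np.ndarray, outlier_mask: np.ndarray) -> OutlierStatus:
    """Classify where the outgroup sits in a partition.

    ``exclusive_together``: all outliers share one cluster containing no
    in-group species; ``split``: the outliers span more than one cluster;
    ``mixed``: they share one cluster but alongside in-group species.
    """
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    out_clusters = np.unique(labels[outlier_mask])
    if len(out_clusters) > 1:
        return "split"
    cluster = out_clusters[0]
    if np.any((labels == cluster) & ~outlier_mask):
        return "mixed"
    return "exclusive_together"


def select_natural_k(
    matrix: pd.DataFrame,
    outlier_ids: Sequence[str],
    k_min: int = 2,
    k_max: int = 12,
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterValidationReport:
    """Scan k and pick the "natural" cluster count using the outgroup.

    Candidate k's run from the smallest k at which the outgroup occupies a
    cluster of its own (``exclusive_together``) through the first k at
    which it splits (inclusive).  Among candidates, the k with the highest
    average silhouette is selected; the CH index is reported alongside.
    """
    if not outlier_ids:
        raise ClusteringError("outlier_ids must be nonempty")
    species = [str(s) for s in matrix.index]
    missing = set(outlier_ids) - set(species)
    if missing:
        raise ClusteringError(f"outlier ids not in matrix: {sorted(missing)}")
    mask = np.array([s in set(outlier_ids) for s in species])

    records: list[KScanRecord] = []
    for k in range(k_min, k_max + 1):
        assignment = kmeans_cluster(matrix, k, seed=seed + k, n_restarts=n_restarts)
        status = outlier_status(assignment.labels, mask)
        sil = average_silhouette(matrix, assignment) if k >= 2 else 0.0
        ch = (
            calinski_harabasz(matrix, assignment)
            if 2 <= k < len(species)
            else float("nan")
        )
        records.append(KScanRecord(k, assignment.labels, sil, ch, status))

    notes: list[str] = []
    together = [r.k for r in records if r.outlier_status == "exclusive_together"]
    if not together:
        notes.append("no k places the outgroup in an exclusive cluster")
        return ClusterValidationReport(records, [], None, notes)
    start = together[0]
    split_after = [
        r.k for r in records if r.k > start and r.outlier_status == "split"
    ]
    end = split_after[0] if split_after else records[-1].k
    candidates = [r.k for r in records if start <= r.k <= end]
    by_k = {r.k: r for r in records}
    selected = max(candidates, key=lambda k: by_k[k].avg_silhouette)
    return ClusterValidationReport(records, candidates, selected, notes)


def heatmap_transform(
    matrix: pd.DataFrame | np.ndarray, seed: int = 0
) -> np.ndarray:
    """Add uniform(-0.5, 0.5)·1e-10 noise elementwise.

    Breaks exact ties and singular structure before correlation-based
    clustering while perturbing no entry by more than 0.5e-10.
    """
    X, _ = _as_array(matrix)
    rng = np.random.default_rng(seed)
    return X + (rng.random(X.shape) - 0.5) * 1e-10


def _zscore(X: np.ndarray, axis: int) -> np.ndarray:
    mean = X.mean(axis=axis, keepdims=True)
    std = X.std(axis=axis, ddof=0, keepdims=True)
    std = np.where(std == 0, 1.0, std)
    return (X - mean) / std


def _spearman_linkage_order(X: np.ndarray) -> np.ndarray:
    """Leaf order of average-linkage clustering under 1 - Spearman rho."""
    if X.shape[0] == 1:
        return np.array([0])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant rows are reported once below, not per scipy call
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = spearmanr(X, axis=1).statistic
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if np.isnan(rho).any():
        warnings.warn(
            "constant row/column: Spearman correlation undefined, "
            "using maximal distance 2",
            stacklevel=3,
        )
        rho = np.where(np.isnan(rho), -1.0, rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2, checks=False)
    return leaves_list(average(condensed))


def heatmap_order(matrix: pd.DataFrame | np.ndarray) -> HeatmapLayout:
    """Row/column leaf orders for a clustered heatmap of the criteria.

    Rows then columns are z-standardised; distances are 1 - Spearman rank
    correlation; average-linkage agglomerative clustering provides the leaf
    order for both axes.  The matrix itself is returned untransformed here;
    use :func:`make_heatmap_layout` for the noise-stabilised variant.
    """
    X, _ = _as_array(matrix)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ClusteringError("heatmap ordering needs at least a 2x2 matrix")
    Z = _zscore(_zscore(X, axis=1), axis=0)
    row_order = _spearman_linkage_order(Z)
    col_order = _spearman_linkage_order(Z.T)
    return HeatmapLayout(row_order, col_order, X)


def make_heatmap_layout(
    matrix: pd.DataFrame | np.ndarray, seed: int = 0
) -> HeatmapLayout:
    """Noise-stabilise the matrix, then compute the heatmap leaf orders."""
    transformed = heatmap_transform(matrix, seed)
    layout = heatmap_order(transformed)
    return HeatmapLayout(layout.row_order, layout.column_order, transformed)
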