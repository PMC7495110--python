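"""Brain-state estimation.

Exemplar windows (per-subject local maxima of across-feature variance) feed a
cluster-number search scored by the Davies-Bouldin and Ray-Turi validity
indices; the full cohort is then clustered by k-means under correlation
distance (1 - Pearson r across features) and every window is assigned a state.
States are renumbered in descending overall occupancy, so state 1 is always
the modal state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import CohortFeatures, DfcFeatureSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation geometry

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale it to unit norm.

    Correlation distance between raw rows equals half the squared Euclidean
    distance between standardized rows, so k-means under correlation distance
    operates on this representation.
    """
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if (norms == 0).any():
        bad = np.flatnonzero(norms.ravel() == 0)
        raise ValueError(f"constant row(s) {bad.tolist()} have no correlation direction")
    return centered / norms


def correlation_distances(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - Pearson r between every row of ``x`` and every centroid."""
    return 1.0 - _standardize_rows(x) @ _standardize_rows(centroids).T


def _pairwise_distance(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        return correlation_distances(a, b)
    if metric == "euclidean":
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# exemplar selection

@dataclass
class ExemplarSet:
    """Pooled high-variance windows used for cheap cluster-number estimation."""

    indices: dict[str, np.ndarray]
    matrix: np.ndarray


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Interior local maxima; plateaus yield their leftmost index.

    Endpoints are excluded.  If no interior peak exists the (leftmost) global
    maximum is returned as a fallback.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    # compress runs of equal values
    starts = [0]
    for t in range(1, n):
        if values[t] != values[starts[-1]]:
            starts.append(t)
    peaks = []
    for r in range(1, len(starts) - 1):
        s = starts[r]
        if values[s] > values[starts[r - 1]] and values[s] > values[starts[r + 1]]:
            peaks.append(s)
    if not peaks:
        return np.array([int(np.argmax(values))])
    return np.array(peaks)


def select_exemplars(feature_sets: list[DfcFeatureSet]) -> ExemplarSet:
    """Windows at local maxima of per-window across-feature variance."""
    indices: dict[str, np.ndarray] = {}
    blocks = []
    for fs in feature_sets:
        if fs.n_windows < 3:
            raise ValueError(f"subject {fs.subject_id}: need >= 3 windows for exemplars")
        variance = fs.features.var(axis=1)
        idx = _local_maxima(variance)
        indices[fs.subject_id] = idx
        blocks.append(fs.features[idx])
    return ExemplarSet(indices=indices, matrix=np.vstack(blocks))


# ---------------------------------------------------------------------------
# cluster validity

def _check_clustering(labels: np.ndarray, centroids: np.ndarray) -> None:
    k = centroids.shape[0]
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise ValueError(f"empty cluster(s): {np.flatnonzero(counts == 0).tolist()}")


def davies_bouldin(
    data: np.ndarray, labels: np.ndarray, centroids: np.ndarray, metric: str = "correlation"
) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (spread_i + spread_j) / centroid-distance ratio.  Lower is better."""
    labels = np.asarray(labels)
    _check_clustering(labels, centroids)
    k = centroids.shape[0]
    d_point = _pairwise_distance(data, centroids, metric)
    spread = np.array([d_point[labels == i, i].mean() for i in range(k)])
    d_cent = _pairwise_distance(centroids, centroids, metric)
    if np.any((d_cent + np.eye(k)) == 0):
        raise ValueError("coincident centroids: between-cluster distance is zero")
    ratios = (spread[:, None] + spread[None, :]) / np.where(np.eye(k, dtype=bool), np.inf, d_cent)
    return float(ratios.max(axis=1).mean())


def ray_turi(
    data: np.ndarray, labels: np.ndarray, centroids: np.ndarray, metric: str = "correlation"
) -> float:
    """Ray-Turi index: mean squared within-cluster distance over the minimal
    squared centroid separation.  Lower is better."""
    labels = np.asarray(labels)
    _check_clustering(labels, centroids)
    k = centroids.shape[0]
    d_point = _pairwise_distance(data, centroids, metric)
    within = float((d_point[np.arange(len(labels)), labels] ** 2).mean())
    d_cent = _pairwise_distance(centroids, centroids, metric)
    off = d_cent[~np.eye(k, dtype=bool)]
    if (off == 0).any():
        raise ValueError("coincident centroids: between-cluster distance is zero")
    return within / float((off**2).min())


# ---------------------------------------------------------------------------
# k-means under correlation distance

@dataclass
class StateModel:
    """A fitted k-state model: centroids (row-standardized) plus the
    clustering configuration that produced them."""

    k: int
    centroids: np.ndarray
    distance: str = "correlation"
    replicates: int = 33
    max_iter: int = 4000
    seed: int = 0
    inertia: float = float("nan")
    occupancy_order: np.ndarray | None = None


@dataclass
class StateSequence:
    """Per-subject series of 1-based state labels, one per feature window."""

    subject_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size and self.states.min() < 1:
            raise ValueError("state labels are 1-based")


def _init_centroids(
    xs: np.ndarray, k: int, rng: np.random.Generator, init: str = "random"
) -> np.ndarray:
    """k distinct (non-coincident) rows, seeded.

    ``init="spread"`` picks a seeded first row then greedily adds the row
    farthest (in correlation distance) from the chosen set.
    """
    n = xs.shape[0]
    if init == "spread":
        idx = [int(rng.integers(n))]
        dist = 1.0 - xs @ xs[idx[-1]]
        while len(idx) < k:
            idx.append(int(dist.argmax()))
            dist = np.minimum(dist, 1.0 - xs @ xs[idx[-1]])
        cand = xs[idx]
        if np.all((cand @ cand.T)[~np.eye(k, dtype=bool)] < 1 - 1e-12):
            return cand.copy()
        raise ValueError(f"could not find {k} distinct rows to initialize centroids")
    for _ in range(100):
        idx = rng.choice(n, size=k, replace=False)
        cand = xs[idx]
        gram = cand @ cand.T
        if np.all(gram[~np.eye(k, dtype=bool)] < 1 - 1e-12):
            return cand.copy()
    raise ValueError(f"could not find {k} distinct rows to initialize centroids")


def _kmeans_once(
    xs: np.ndarray, k: int, max_iter: int, rng: np.random.Generator, init: str = "random"
) -> tuple[np.ndarray, np.ndarray, float]:
    n = xs.shape[0]
    centroids = _init_centroids(xs, k, rng, init=init)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        dist = 1.0 - xs @ centroids.T
        new_labels = dist.argmin(axis=1)
        for j in range(k):  # re-seed empty clusters from the worst-fit row
            if not (new_labels == j).any():
                far = dist[np.arange(n), new_labels].argmax()
                centroids[j] = xs[far]
                new_labels[far] = j
                logger.debug("re-seeded empty cluster %d from row %d", j, far)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            mean = xs[labels == j].mean(axis=0)
            mean -= mean.mean()
            norm = np.linalg.norm(mean)
            if norm > 0:
                centroids[j] = mean / norm
    dist = 1.0 - xs @ centroids.T
    labels = dist.argmin(axis=1)
    cost = float(dist[np.arange(n), labels].sum())
    return labels, centroids, cost


def kmeans_correlation(
    data: np.ndarray,
    k: int,
    replicates: int = 33,
    max_iter: int = 4000,
    seed: int = 0,
    init: str = "random",
) -> tuple[StateModel, np.ndarray]:
    """Best-of-``replicates`` k-means under correlation distance.

    Rows are standardized (centered, unit norm) so correlation distance is
    monotone in Euclidean distance; centroids are means of member standardized
    rows, re-standardized.  The replicate with minimal total distance wins.
    Labels are 0-based cluster indices in fit order (no occupancy renumbering
    at this level).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {data.shape[0]}")
    xs = _standardize_rows(data)
    root = np.random.SeedSequence(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for child in root.spawn(replicates):
        rng = np.random.default_rng(child)
        labels, centroids, cost = _kmeans_once(xs, k, max_iter, rng, init=init)
        if best is None or cost < best[2]:
            best = (labels, centroids, cost)
    labels, centroids, cost = best
    model = StateModel(
        k=k, centroids=centroids, replicates=replicates, max_iter=max_iter, seed=seed, inertia=cost
    )
    return model, labels


# ---------------------------------------------------------------------------
# cluster-number estimation

@dataclass
class ClusterValidityCurve:
    """Davies-Bouldin and Ray-Turi scores over a range of k.

    ``chosen_k`` minimizes the Ray-Turi index (primary rule);
    ``chosen_k_db`` records the Davies-Bouldin minimizer alongside.
    """

    k_values: list[int]
    db_index: list[float]
    rt_index: list[float]
    chosen_k: int = field(init=False)
    chosen_k_db: int = field(init=False)
    chooser: str = "ray-turi minimum (davies-bouldin reported alongside)"

    def __post_init__(self) -> None:
        self.chosen_k = self.k_values[int(np.argmin(self.rt_index))]
        self.chosen_k_db = self.k_values[int(np.argmin(self.db_index))]


def estimate_k(
    exemplars: ExemplarSet,
    k_range: range | list[int] = range(2, 11),
    replicates: int = 10,
    max_iter: int = 4000,
    seed: int = 0,
) -> ClusterValidityCurve:
    """Score candidate cluster numbers on the pooled exemplar windows."""
    k_values = [int(k) for k in k_range]
    n = exemplars.matrix.shape[0]
    usable = [k for k in k_values if k < n]
    if len(usable) < len(k_values):
        logger.warning("k range truncated to %s (only %d exemplars)", usable, n)
        k_values = usable
    if not k_values:
        raise ValueError("no feasible k: too few exemplar windows")
    db, rt = [], []
    for k in k_values:
        model, labels = kmeans_correlation(
            exemplars.matrix, k, replicates=replicates, max_iter=max_iter, seed=seed + k
        )
        db.append(davies_bouldin(exemplars.matrix, labels, model.centroids))
        rt.append(ray_turi(exemplars.matrix, labels, model.centroids))
    curve = ClusterValidityCurve(k_values=k_values, db_index=db, rt_index=rt)
    if curve.chosen_k != curve.chosen_k_db:
        logger.info(
            "validity indices disagree: ray-turi -> %d, davies-bouldin -> %d (ray-turi primary)",
            curve.chosen_k, curve.chosen_k_db,
        )
    return curve


# ---------------------------------------------------------------------------
# assignment and the full fit

def assign_states(model: StateModel, cohort: CohortFeatures) -> list[StateSequence]:
    """Label every window with its nearest centroid (1-based states).

    Ties break toward the lower state index (argmin convention).
    """
    if cohort.matrix.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"feature dimension {cohort.matrix.shape[1]} != centroid dimension "
            f"{model.centroids.shape[1]}"
        )
    dist = correlation_distances(cohort.matrix, model.centroids)
    labels = dist.argmin(axis=1) + 1
    out = []
    for sid in cohort.index["subject_id"].unique():
        rows = cohort.subject_rows(sid)
        out.append(StateSequence(subject_id=sid, states=labels[rows]))
    return out


def fit_states(
    cohort: CohortFeatures,
    k: int,
    replicates: int = 33,
    max_iter: int = 4000,
    seed: int = 0,
) -> tuple[StateModel, list[StateSequence]]:
    """Cluster the concatenated cohort and renumber states by occupancy.

    After fitting, states are relabeled in descending overall window share, so
    state 1 is the modal state; the fit-order -> final-label mapping is kept
    on the model (``occupancy_order``).
    """
    model, labels = kmeans_correlation(
        cohort.matrix, k, replicates=replicates, max_iter=max_iter, seed=seed
    )
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")  # fit-order indices, most occupied first
    model.centroids = model.centroids[order]
    model.occupancy_order = order
    sequences = assign_states(model, cohort)
    return model, sequences
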