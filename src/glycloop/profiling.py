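"""Two-stage unsupervised glycemic profiling.

For each of the four label-defined subsets of the training data
(hypoglycemia / non-hypoglycemia / hyperglycemia / non-hyperglycemia) a
10x10 self-organizing map is trained on the z-scored continuous features,
then k-means (k = 3) groups the 100 SOM prototype vectors into behavioral
subgroups. Each subgroup's centroid -- the mean of its member prototypes --
is stored, giving 12 centroids in all: 3 per (system, event-class). At
inference a test instance is compared with its system's 6 centroids by
Euclidean distance in the normalized space.

The clustering space uses the 12 continuous features, excluding the
hour-of-day (a cyclic integer on which Euclidean distance is ill-posed);
pass ``include_hour=True`` to restore all 13. Features are z-scored with
one set of statistics per profile index (computed over all training
instances) so that distances to all of a system's centroids are comparable.

The cluster-label input feature carried into classification is the index of
the assigned subgroup within the system, 0-2 for the event-class subgroups
and 3-5 for the non-event ones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._compat import njit
from .errors import ProfilingError
from .features import MealInstance, N_FEATURES, FEATURE_NAMES

logger = logging.getLogger(__name__)

SYSTEMS = ("S1", "S2")
EVENT_CLASSES = ("event", "nonevent")
#: index of the hour-of-day feature, excluded from the clustering space
HOUR_INDEX = FEATURE_NAMES.index("meal_hour")

CentroidKey = tuple[str, str, int]   # (system, event_class, cluster index)


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SOMGrid:
    """A trained rectangular SOM."""

    weights: np.ndarray          # (rows*cols, d), row-major grid order
    rows: int
    cols: int
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def grid_coords(self) -> np.ndarray:
        rr, cc = np.divmod(np.arange(self.n_neurons), self.cols)
        return np.column_stack([rr, cc]).astype(float)


@njit
def _som_train_core(X, weights, coords, order, lr0, lr1, r0, r1):
    n_steps = order.shape[0]
    n_neurons, d = weights.shape
    for s in range(n_steps):
        frac = s / max(n_steps - 1, 1)
        lr = lr0 * (lr1 / lr0) ** frac
        radius = r0 * (r1 / r0) ** frac
        x = X[order[s]]
        # best-matching unit (first minimum = smallest (row, col))
        best, best_d = 0, 1e300
        for j in range(n_neurons):
            dist = 0.0
            for k in range(d):
                diff = weights[j, k] - x[k]
                dist += diff * diff
            if dist < best_d:
                best_d, best = dist, j
        br, bc = coords[best, 0], coords[best, 1]
        denom = 2.0 * radius * radius
        for j in range(n_neurons):
            dr = coords[j, 0] - br
            dc = coords[j, 1] - bc
            h = np.exp(-(dr * dr + dc * dc) / denom)
            step = lr * h
            for k in range(d):
                weights[j, k] += step * (x[k] - weights[j, k])
    return weights


def train_som(
    vectors: np.ndarray,
    rows: int = 10,
    cols: int = 10,
    epochs: int = 500,
    seed: int = 0,
    lr0: float = 0.5,
    lr1: float = 0.01,
    radius0: float = 5.0,
    radius1: float = 1.0,
) -> SOMGrid:
    """Online SOM with Gaussian neighborhood and exponential schedules.

    Weights are initialized by seeded uniform sampling within each
    dimension's data range. One epoch visits every input once in a seeded
    shuffled order; learning rate and radius decay exponentially over the
    total number of updates.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ProfilingError("SOM training requires a non-empty 2-D input")
    n, d = X.shape
    if n < rows * cols:
        logger.warning("SOM trained on %d < %d vectors; prototypes may be sparse",
                       n, rows * cols)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    weights = rng.uniform(lo, hi, size=(rows * cols, d))
    order = np.concatenate([rng.permutation(n) for _ in range(epochs)])
    som = SOMGrid(weights=weights, rows=rows, cols=cols,
                  meta=dict(epochs=epochs, lr0=lr0, lr1=lr1,
                            radius0=radius0, radius1=radius1, seed=seed))
    _som_train_core(X, som.weights, som.grid_coords(), order,
                    lr0, lr1, radius0, radius1)
    return som


def best_matching_unit(som: SOMGrid, v: np.ndarray) -> tuple[int, int]:
    """Grid coordinates of the nearest prototype (lexicographic tie-break)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (som.weights.shape[1],):
        raise ProfilingError(
            f"dimension mismatch: vector has {v.shape}, SOM expects "
            f"({som.weights.shape[1]},)")
    d2 = np.sum((som.weights - v) ** 2, axis=1)
    j = int(np.argmin(d2))  # first minimum = smallest (row, col) in row-major
    return divmod(j, som.cols)


def som_update_step(
    som: SOMGrid, x: np.ndarray, lr: float, radius: float
) -> tuple[int, int]:
    """One online update in place; returns the BMU. Exposed for inspection."""
    bmu = best_matching_unit(som, x)
    coords = som.grid_coords()
    d2 = np.sum((coords - np.array(bmu, dtype=float)) ** 2, axis=1)
    h = np.exp(-d2 / (2.0 * radius * radius))
    som.weights += (lr * h)[:, None] * (np.asarray(x, dtype=float) - som.weights)
    return bmu


# ---------------------------------------------------------------------------
# cluster-count selection
# ---------------------------------------------------------------------------

def choose_k(
    prototypes: np.ndarray,
    k_range: range = range(2, 9),
    seed: int = 0,
) -> tuple[int, dict]:
    """Silhouette-maximizing k over ``k_range``, with an elbow diagnostic.

    Returns (k, diagnostics) where diagnostics holds the within-cluster SSE
    (elbow curve) and silhouette score per candidate k. Degenerate inputs
    (all prototypes identical) fall back to k = 3 with a warning.
    """
    P = np.asarray(prototypes, dtype=float)
    if np.allclose(P, P[0]):
        logger.warning("degenerate prototypes: silhouette undefined, using k=3")
        return 3, {"sse": {}, "silhouette": {}}
    sse, sil = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(P)
        sse[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(P, km.labels_))
    best = max(sil, key=sil.get)
    return best, {"sse": sse, "silhouette": sil}


# ---------------------------------------------------------------------------
# centroid store
# ---------------------------------------------------------------------------

@dataclass
class CentroidStore:
    """The 12 subgroup centroids with their normalization statistics."""

    centroids: dict[CentroidKey, np.ndarray]
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    feature_idx: np.ndarray      # columns of the 13-vector used for clustering
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.centroids) != len(SYSTEMS) * len(EVENT_CLASSES) * self.k:
            raise ProfilingError(
                f"centroid store must hold {2 * 2 * self.k} centroids")

    @property
    def k(self) -> int:
        return int(self.meta.get("k", 3))

    def normalize(self, v: np.ndarray) -> np.ndarray:
        """Project a raw 13-feature vector into the normalized cluster space."""
        v = np.asarray(v, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ProfilingError(
                f"expected a raw {N_FEATURES}-feature vector, got shape {v.shape}; "
                "normalized/clustering-space vectors are not accepted")
        return (v[self.feature_idx] - self.norm_mean) / self.norm_sd

    def system_keys(self, system: str) -> list[CentroidKey]:
        """The 6 keys of one system in canonical order (event first)."""
        return [(system, ec, c) for ec in EVENT_CLASSES for c in range(self.k)]

    def to_dict(self) -> dict:
        return {
            "centroids": {"|".join(map(str, k)): v.tolist()
                          for k, v in self.centroids.items()},
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "feature_idx": self.feature_idx.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidStore":
        cents = {}
        for key, v in d["centroids"].items():
            system, ec, c = key.split("|")
            cents[(system, ec, int(c))] = np.asarray(v, dtype=float)
        return cls(
            centroids=cents,
            norm_mean=np.asarray(d["norm_mean"], dtype=float),
            norm_sd=np.asarray(d["norm_sd"], dtype=float),
            feature_idx=np.asarray(d["feature_idx"], dtype=int),
            meta=d.get("meta", {}),
        )


def _subset_mask(instances: list[MealInstance], system: str, event_class: str) -> np.ndarray:
    labels = np.array([i.label_hypo if system == "S1" else i.label_hyper
                       for i in instances])
    return labels == (1 if event_class == "event" else 0)


def build_profile_index(
    instances: list[MealInstance],
    seed: int = 0,
    k: int = 3,
    som_epochs: int = 500,
    include_hour: bool = False,
    assign_training_clusters: bool = True,
) -> CentroidStore:
    """Train the full two-stage profiling pipeline on a training set.

    Per label subset: SOM on the z-scored clustering features, k-means
    (seeded, 10 restarts) on the 100 prototypes, subgroup centroid = mean of
    the member prototypes. When ``assign_training_clusters`` is set, every
    training instance receives its per-system cluster id in place
    (``cluster_id_s1`` / ``cluster_id_s2``).
    """
    if not instances:
        raise ProfilingError("cannot profile an empty training set")
    feature_idx = np.arange(N_FEATURES) if include_hour else np.array(
        [i for i in range(N_FEATURES) if i != HOUR_INDEX])
    X = np.vstack([inst.features.to_array() for inst in instances])[:, feature_idx]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mean) / sd

    centroids: dict[CentroidKey, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for system, event_class in itertools.product(SYSTEMS, EVENT_CLASSES):
        mask = _subset_mask(instances, system, event_class)
        if not mask.any():
            raise ProfilingError(f"empty subset: {system}/{event_class}")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        som = train_som(Z[mask], epochs=som_epochs, seed=sub_seed)
        km = KMeans(n_clusters=k, n_init=10, random_state=sub_seed).fit(som.weights)
        for c in range(k):
            members = som.weights[km.labels_ == c]
            if members.size == 0:  # keep the slot; fall back to kmeans center
                centroids[(system, event_class, c)] = km.cluster_centers_[c]
            else:
                centroids[(system, event_class, c)] = members.mean(axis=0)

    store = CentroidStore(
        centroids=centroids, norm_mean=mean, norm_sd=sd,
        feature_idx=feature_idx,
        meta=dict(k=k, som_epochs=som_epochs, seed=seed,
                  include_hour=include_hour),
    )
    if assign_training_clusters:
        for inst in instances:
            v = inst.features.to_array()
            inst.cluster_id_s1 = training_cluster_value(store, v, "S1", inst.label_hypo)
            inst.cluster_id_s2 = training_cluster_value(store, v, "S2", inst.label_hyper)
    return store


def assign_clusters(
    store: CentroidStore, v: np.ndarray, system: str
) -> list[tuple[CentroidKey, float]]:
    """All 6 centroids of ``system`` ranked by distance to ``v``.

    Distances are Euclidean in the store's normalized space; ties resolve by
    the canonical key order (event-class subgroups before non-event, then
    cluster index).
    """
    if system not in SYSTEMS:
        raise ProfilingError(f"unknown system {system!r}")
    z = store.normalize(v)
    keys = store.system_keys(system)
    ranked = sorted(
        ((key, float(np.linalg.norm(z - store.centroids[key]))) for key in keys),
        key=lambda kv: (kv[1], keys.index(kv[0])),
    )
    return ranked


def cluster_feature_value(store: CentroidStore, v: np.ndarray, system: str) -> int:
    """Cluster-label input feature: 0..k-1 event subgroup, k..2k-1 non-event.

    For unseen (test) instances: id of the nearest of all 6 centroids.
    """
    key, _ = assign_clusters(store, v, system)[0]
    return key_feature_value(store, key)


def training_cluster_value(
    store: CentroidStore, v: np.ndarray, system: str, label: int
) -> int:
    """Cluster id of a training instance: nearest centroid within its own
    label subset (event centroids for label 1, non-event for label 0)."""
    event_class = "event" if label == 1 else "nonevent"
    z = store.normalize(v)
    dists = [np.linalg.norm(z - store.centroids[(system, event_class, c)])
             for c in range(store.k)]
    c = int(np.argmin(dists))
    return key_feature_value(store, (system, event_class, c))


def key_feature_value(store: CentroidStore, key: CentroidKey) -> int:
    """Map a centroid key to its 0..2k-1 cluster-label feature value."""
    _, event_class, c = key
    return c if event_class == "event" else store.k + c


__all__ = [
    "SOMGrid", "CentroidStore", "CentroidKey", "SYSTEMS", "EVENT_CLASSES",
    "train_som", "best_matching_unit", "som_update_step", "choose_k",
    "build_profile_index", "assign_clusters", "cluster_feature_value",
    "training_cluster_value", "key_feature_value",
]
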