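"""Centroid-routed dual ensemble classification.

Two independent systems predict postprandial events: S1 (hypoglycemia) and
S2 (hyperglycemia). Each holds six random-forest classifiers, one per
profiling subgroup (3 event-class + 3 non-event subgroups). At inference an
instance is routed to the two subgroup models whose centroids lie nearest
in the normalized feature space; their binary votes fuse through a logical
AND gate (event declared only on agreement), and the continuous fused score
is the minimum of the two event probabilities, which is consistent with the
AND decision rule.

A subgroup's training set is its own cluster's instances plus an equal
number of opposite-label instances nearest to the subgroup centroid
(centroid-local class balancing; ``negatives="all"`` instead uses every
opposite-label instance). Model selection uses a seeded randomized
hyperparameter search scored by the Matthews correlation coefficient, and
each model's probability threshold maximizes the MCC of its out-of-fold
predictions. Baselines are single random forests over the 13 features with
Youden-J thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .errors import TrainingError
from .features import MealInstance
from .profiling import (
    CentroidKey, CentroidStore, assign_clusters, build_profile_index,
    key_feature_value,
)
from .report import confusion_metrics, mcc_threshold, mcc_score, \
    roc_auc, youden_threshold

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Randomized hyperparameter search space and budget."""

    n_estimators: tuple[int, int] = (100, 500)
    max_depth: tuple[int, int] = (3, 12)
    min_samples_leaf: tuple[int, int] = (1, 8)
    n_draws: int = 25
    cv: int = 5

    def draw(self, rng: np.random.Generator) -> dict:
        return dict(
            n_estimators=int(rng.integers(self.n_estimators[0], self.n_estimators[1] + 1)),
            max_depth=int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            min_samples_leaf=int(rng.integers(self.min_samples_leaf[0],
                                              self.min_samples_leaf[1] + 1)),
        )


@dataclass
class TrainedSystem:
    """Six routed classifiers (plus thresholds) for one prediction system."""

    system: str
    models: dict[CentroidKey, RandomForestClassifier]
    thresholds: dict[CentroidKey, float]
    search_records: dict[CentroidKey, dict]
    seed: int


@dataclass
class Prediction:
    system: str
    selected: list[CentroidKey]
    probabilities: tuple[float, float]
    votes: tuple[int, int]
    fused_vote: int
    fused_score: float


def _target(inst: MealInstance, system: str) -> int:
    return inst.label_hypo if system == "S1" else inst.label_hyper


def _cluster_id(inst: MealInstance, system: str) -> int:
    return inst.cluster_id_s1 if system == "S1" else inst.cluster_id_s2


def _design_matrix(instances: list[MealInstance], system: str) -> np.ndarray:
    """13 features + the instance's own-system cluster-label feature."""
    X = np.vstack([i.features.to_array() for i in instances])
    cid = np.array([_cluster_id(i, system) for i in instances], dtype=float)
    return np.column_stack([X, cid])


def _sorted_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lexicographic row sort for instance-order invariance."""
    order = np.lexsort(X.T[::-1])
    return X[order], y[order]


def _fit_with_search(
    X: np.ndarray, y: np.ndarray, seed: int, search: SearchConfig,
) -> tuple[RandomForestClassifier, np.ndarray, dict]:
    """Seeded randomized search scored by out-of-fold MCC.

    Returns the refit best model, its out-of-fold event probabilities and
    the search record.
    """
    rng = np.random.default_rng(seed)
    n_splits = min(search.cv, int(np.bincount(y).min()))
    if n_splits < 2:
        raise TrainingError("cannot cross-validate: a class has < 2 members")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best = None
    for i in range(search.n_draws):
        params = search.draw(rng)
        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        oof = cross_val_predict(clf, X, y, cv=cv, method="predict_proba")[:, 1]
        yhat = (oof >= 0.5).astype(int)
        tp = int(np.sum((y == 1) & (yhat == 1)))
        tn = int(np.sum((y == 0) & (yhat == 0)))
        fp = int(np.sum((y == 0) & (yhat == 1)))
        fn = int(np.sum((y == 1) & (yhat == 0)))
        score = mcc_score(tp, tn, fp, fn)
        if best is None or score > best["score"] + 1e-12:
            best = dict(score=score, params=params, oof=oof, draw=i)
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **best["params"])
    model.fit(X, y)
    record = dict(params=best["params"], oof_mcc=best["score"],
                  n_draws=search.n_draws, cv=n_splits, best_draw=best["draw"])
    return model, best["oof"], record


def train_subgroup_model(
    instances: list[MealInstance],
    key: CentroidKey,
    store: CentroidStore,
    seed: int,
    search: SearchConfig | None = None,
    negatives: str = "local",
) -> tuple[RandomForestClassifier, float, dict]:
    """Train one subgroup's event-vs-non-event classifier.

    The training set is every instance of the key's cluster plus, for class
    balance, the equally many opposite-label instances nearest (Euclidean,
    normalized space) to the key's centroid. The decision threshold on the
    event probability maximizes the MCC over the out-of-fold score grid.
    """
    search = search or SearchConfig()
    system, event_class, _ = key
    key_value = key_feature_value(store, key)
    members = [i for i in instances if _cluster_id(i, system) == key_value]
    if len(members) < 10:
        raise TrainingError(f"cluster {key} has {len(members)} (< 10) instances")
    own_label = 1 if event_class == "event" else 0
    opposite = [i for i in instances if _target(i, system) != own_label]
    if not opposite:
        raise TrainingError(f"no opposite-label instances for {key}")
    if negatives == "local":
        centroid = store.centroids[key]
        d = [float(np.linalg.norm(store.normalize(i.features.to_array()) - centroid))
             for i in opposite]
        order = np.argsort(d, kind="stable")
        opposite = [opposite[j] for j in order[: len(members)]]
    elif negatives != "all":
        raise ValueError("negatives must be 'local' or 'all'")

    chosen = members + opposite
    X = _design_matrix(chosen, system)
    y = np.array([_target(i, system) for i in chosen])
    X, y = _sorted_rows(X, y)
    model, oof, record = _fit_with_search(X, y, seed, search)
    threshold = mcc_threshold(oof, y)
    return model, threshold, record


def train_system(
    instances: list[MealInstance],
    system: str,
    store: CentroidStore,
    seed: int,
    search: SearchConfig | None = None,
    negatives: str = "local",
) -> TrainedSystem:
    """Train the six subgroup models of one system."""
    models, thresholds, records = {}, {}, {}
    for j, key in enumerate(store.system_keys(system)):
        model, thr, rec = train_subgroup_model(
            instances, key, store, seed=seed + j, search=search, negatives=negatives)
        models[key], thresholds[key], records[key] = model, thr, rec
    return TrainedSystem(system=system, models=models, thresholds=thresholds,
                         search_records=records, seed=seed)


def predict_instance(
    system: TrainedSystem, store: CentroidStore, v: np.ndarray
) -> Prediction:
    """Route to the two nearest-centroid models and fuse with an AND gate."""
    ranked = assign_clusters(store, v, system.system)
    selected = [ranked[0][0], ranked[1][0]]
    cid = float(key_feature_value(store, selected[0]))
    x = np.concatenate([np.asarray(v, dtype=float), [cid]])[None, :]
    probs, votes = [], []
    for key in selected:
        p = float(system.models[key].predict_proba(x)[0, 1])
        probs.append(p)
        votes.append(int(p >= system.thresholds[key]))
    fused_vote = int(votes[0] and votes[1])
    fused_score = min(probs)
    return Prediction(system=system.system, selected=selected,
                      probabilities=(probs[0], probs[1]),
                      votes=(votes[0], votes[1]),
                      fused_vote=fused_vote, fused_score=fused_score)


def predict_matrix(
    system: TrainedSystem, store: CentroidStore, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched routing + AND fusion over a (n, 13) feature matrix.

    Equivalent to :func:`predict_instance` row by row, but routes all rows
    at once and batches each subgroup model's probability calls.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    n = M.shape[0]
    Z = (M[:, store.feature_idx] - store.norm_mean) / store.norm_sd
    keys = store.system_keys(system.system)
    C = np.vstack([store.centroids[k] for k in keys])
    D = np.linalg.norm(Z[:, None, :] - C[None, :, :], axis=2)
    order = np.argsort(D, axis=1, kind="stable")   # ties -> canonical key order
    sel = order[:, :2]
    cid = np.array([key_feature_value(store, keys[j]) for j in sel[:, 0]],
                   dtype=float)
    X = np.column_stack([M, cid])
    probs = np.empty((n, 2))
    votes = np.empty((n, 2), dtype=int)
    for slot in range(2):
        for j, key in enumerate(keys):
            rows = np.flatnonzero(sel[:, slot] == j)
            if rows.size == 0:
                continue
            p = system.models[key].predict_proba(X[rows])[:, 1]
            probs[rows, slot] = p
            votes[rows, slot] = (p >= system.thresholds[key]).astype(int)
    fused_votes = votes[:, 0] & votes[:, 1]
    fused_scores = probs.min(axis=1)
    return fused_votes, fused_scores


def predict_dataset(
    system: TrainedSystem, store: CentroidStore, instances: list[MealInstance]
) -> tuple[np.ndarray, np.ndarray]:
    """(fused votes, fused scores) over a list of instances."""
    M = np.vstack([inst.features.to_array() for inst in instances])
    return predict_matrix(system, store, M)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def train_baseline(
    instances: list[MealInstance],
    target: str,
    seed: int,
    search: SearchConfig | None = None,
) -> tuple[RandomForestClassifier, float]:
    """Single random forest on the 13 features with a Youden-J threshold."""
    search = search or SearchConfig()
    system = "S1" if target == "hypo" else "S2"
    X = np.vstack([i.features.to_array() for i in instances])
    y = np.array([_target(i, system) for i in instances])
    X, y = _sorted_rows(X, y)
    model, oof, _ = _fit_with_search(X, y, seed, search)
    threshold = youden_threshold(oof, y)
    return model, threshold


def predict_baseline(
    model: RandomForestClassifier, threshold: float, instances: list[MealInstance]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([i.features.to_array() for i in instances])
    scores = model.predict_proba(X)[:, 1]
    return (scores >= threshold).astype(int), scores


# ---------------------------------------------------------------------------
# repeated-split evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    """Per-iteration metrics and their medians for the four models."""

    table: pd.DataFrame   # iteration, model, accuracy, mcc, sens, spec, auc
    n_iter: int

    def medians(self) -> pd.DataFrame:
        return self.table.groupby("model")[
            ["accuracy", "mcc", "sensitivity", "specificity", "auc"]
        ].median()


def _metrics_row(y, votes, scores, model_name, iteration) -> dict:
    cm = confusion_metrics(y, votes)
    try:
        _, auc = roc_auc(scores, y)
    except Exception:
        auc = float("nan")
    return dict(iteration=iteration, model=model_name, accuracy=cm.accuracy,
                mcc=cm.mcc, sensitivity=cm.sensitivity,
                specificity=cm.specificity, auc=auc)


def _stratified_split(instances, test_frac, rng):
    """Index split stratified on the joint (hypo, hyper) label pair."""
    strata = {}
    for idx, inst in enumerate(instances):
        strata.setdefault((inst.label_hypo, inst.label_hyper), []).append(idx)
    test_idx = []
    for idxs in strata.values():
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        n_test = int(round(test_frac * len(idxs)))
        test_idx.extend(idxs[:n_test].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(instances)) if i not in test_set]
    return train_idx, sorted(test_idx)


def run_protocol(
    instances: list[MealInstance],
    n_iter: int = 20,
    test_frac: float = 0.1,
    seed: int = 0,
    search: SearchConfig | None = None,
    som_epochs: int = 500,
    k: int = 3,
    negatives: str = "local",
    max_retries: int = 5,
) -> ProtocolResult:
    """Repeated 90/10 train-test evaluation of both systems and baselines.

    Per iteration: stratified split, profiling and all training on the
    training side only, evaluation of S1, S2 and the two baselines on the
    held-out side. Iterations whose split or training lacks a class are
    resampled (at most ``max_retries`` times). Reported metrics are the
    per-iteration values; medians summarize the 20 iterations.
    """
    search = search or SearchConfig()
    rows = []
    rng = np.random.default_rng(seed)
    it = 0
    while it < n_iter:
        ok = False
        for attempt in range(max_retries):
            train_idx, test_idx = _stratified_split(instances, test_frac, rng)
            assert not set(train_idx) & set(test_idx), "train/test overlap"
            train = [instances[i] for i in train_idx]
            test = [instances[i] for i in test_idx]
            y1 = np.array([i.label_hypo for i in test])
            y2 = np.array([i.label_hyper for i in test])
            if len({i.label_hypo for i in train}) < 2 or \
               len({i.label_hyper for i in train}) < 2 or \
               len(set(y1)) < 2 or len(set(y2)) < 2:
                logger.info("iteration %d attempt %d: a class is absent, resampling",
                            it, attempt)
                continue
            try:
                store = build_profile_index(train, seed=int(rng.integers(2**31 - 1)),
                                            k=k, som_epochs=som_epochs)
                sub_seed = int(rng.integers(2**31 - 1))
                s1 = train_system(train, "S1", store, seed=sub_seed,
                                  search=search, negatives=negatives)
                s2 = train_system(train, "S2", store, seed=sub_seed + 100,
                                  search=search, negatives=negatives)
                b1_model, b1_thr = train_baseline(train, "hypo", seed=sub_seed + 200,
                                                  search=search)
                b2_model, b2_thr = train_baseline(train, "hyper", seed=sub_seed + 300,
                                                  search=search)
            except TrainingError as exc:
                logger.info("iteration %d attempt %d: %s, resampling", it, attempt, exc)
                continue
            v1, s1_scores = predict_dataset(s1, store, test)
            v2, s2_scores = predict_dataset(s2, store, test)
            bv1, bs1 = predict_baseline(b1_model, b1_thr, test)
            bv2, bs2 = predict_baseline(b2_model, b2_thr, test)
            rows.append(_metrics_row(y1, v1, s1_scores, "S1", it))
            rows.append(_metrics_row(y2, v2, s2_scores, "S2", it))
            rows.append(_metrics_row(y1, bv1, bs1, "baseline_hypo", it))
            rows.append(_metrics_row(y2, bv2, bs2, "baseline_hyper", it))
            ok = True
            break
        if not ok:
            raise TrainingError(
                f"iteration {it}: no valid split after {max_retries} retries")
        it += 1
    return ProtocolResult(table=pd.DataFrame(rows), n_iter=n_iter)


__all__ = [
    "SearchConfig", "TrainedSystem", "Prediction", "ProtocolResult",
    "train_subgroup_model", "train_system", "predict_instance",
    "predict_matrix", "predict_dataset", "train_baseline", "predict_baseline",
    "run_protocol",
]
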