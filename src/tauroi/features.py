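"""Data-driven ROI derivation.

Three steps, mirroring the standard recipe for collinear imaging features:

1. :func:`cv_feature_importance` — extremely-randomized-trees (Extra Trees)
   ensembles fit within 10-fold cross-validation; impurity-decrease feature
   importances are averaged over folds (mean and SD per region).
2. :func:`cluster_features` — average-linkage hierarchical clustering of
   regions under a ``1 - Pearson correlation`` distance, summarizing the
   redundancy structure of regional SUVR values as a dendrogram.
3. :func:`select_representatives` — for k = 1..K the dendrogram is cut into
   k clusters and the highest-importance member of each cluster is taken as
   its representative; the unweighted mean SUVR over the selected regions is
   scored by stratified cross-validated AUC, and the final k is the smallest
   one whose score is within one standard error of the best (favouring a
   minimalist ROI).

All outputs are invariant to subject order: rows are canonicalized
internally before any fold assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import StratifiedKFold

from .roc import auc


@dataclass(frozen=True)
class ImportanceResult:
    labels: tuple[str, ...]
    mean_importance: np.ndarray
    sd_importance: np.ndarray
    n_folds: int
    seed: int

    def ranking(self) -> list[str]:
        order = np.argsort(-self.mean_importance, kind="stable")
        return [self.labels[i] for i in order]

    def importance_of(self, label: str) -> float:
        return float(self.mean_importance[self.labels.index(label)])


@dataclass(frozen=True)
class FeatureDendrogram:
    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str = "average"
    metric: str = "1 - pearson"

    def cut(self, k: int) -> np.ndarray:
        """Cluster assignment (1..k) per label when cutting into k clusters."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in [1, {len(self.labels)}], got {k}")
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")


@dataclass(frozen=True)
class FeatureSelectionTrace:
    ks: tuple[int, ...]
    selected: tuple[tuple[str, ...], ...]
    scores: tuple[float, ...]
    fold_scores: tuple[tuple[float, ...], ...]
    chosen_k: int

    @property
    def final_members(self) -> tuple[str, ...]:
        return self.selected[self.ks.index(self.chosen_k)]


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Subject ordering determined only by data content (label, then features)."""
    return np.lexsort(np.vstack([X.T[::-1], y]))


def _validate_xy(X, y, labels=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D subject x region matrix")
    if X.shape[0] != y.size:
        raise ValueError("X and y must have the same number of subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"y must contain exactly two classes, found {classes.size}")
    y = (y == classes[1]).astype(int)
    if labels is not None and len(labels) != X.shape[1]:
        raise ValueError("labels length must match number of columns of X")
    return X, y


def cv_feature_importance(
    X,
    y,
    labels: list[str] | tuple[str, ...],
    n_folds: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceResult:
    """Cross-validated Extra-Trees impurity importances per region.

    One ensemble is fit per fold on the training portion only; the
    per-fold importance vectors (each summing to 1) are averaged.
    """
    X, y = _validate_xy(X, y, labels)
    if np.all(X == X.flat[0]):
        raise ValueError("X is constant; feature importances are undefined")
    if X.shape[0] < n_folds:
        raise ValueError("need at least as many subjects as folds")
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    imps = np.empty((n_folds, X.shape[1]))
    for fold, (train, _test) in enumerate(skf.split(X, y)):
        clf = ExtraTreesClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed + 1000 * (fold + 1),
            n_jobs=1,
        )
        clf.fit(X[train], y[train])
        imps[fold] = clf.feature_importances_
    return ImportanceResult(
        labels=tuple(labels),
        mean_importance=imps.mean(axis=0),
        sd_importance=imps.std(axis=0, ddof=1),
        n_folds=n_folds,
        seed=seed,
    )


def cluster_features(X, labels: list[str] | tuple[str, ...]) -> FeatureDendrogram:
    """Average-linkage dendrogram over regions, distance = 1 - Pearson r."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least two regions")
    if len(labels) != X.shape[1]:
        raise ValueError("labels length must match number of columns of X")
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance region(s): {[labels[i] for i in dead[:5]]}"
        )
    corr = np.corrcoef(X, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    return FeatureDendrogram(labels=tuple(labels), linkage_matrix=z)


def _composite_cv_auc(
    composite: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> tuple[float, np.ndarray]:
    """Stratified k-fold AUC of a fixed composite score (mean, per-fold)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs = np.empty(n_folds)
    for fold, (_train, test) in enumerate(skf.split(composite[:, None], y)):
        ct, yt = composite[test], y[test]
        fold_aucs[fold] = auc(ct[yt == 0], ct[yt == 1])
    return float(fold_aucs.mean()), fold_aucs


def select_representatives(
    dendrogram: FeatureDendrogram,
    importance: ImportanceResult,
    X,
    y,
    K_max: int = 8,
    n_folds: int = 10,
    seed: int = 0,
) -> FeatureSelectionTrace:
    """Iterative cluster-representative selection over dendrogram cuts.

    For each k the tree is cut into k clusters and each cluster contributes
    its highest-importance member (ties broken lexicographically).  The
    unweighted mean SUVR over the selected members is scored by stratified
    CV AUC; ``chosen_k`` is the smallest k scoring within one standard error
    of the maximum.
    """
    labels = dendrogram.labels
    if set(labels) - set(importance.labels):
        raise ValueError("importance does not cover all dendrogram leaves")
    if K_max > len(labels):
        raise ValueError(f"K_max={K_max} exceeds number of regions {len(labels)}")
    X, y = _validate_xy(X, y)
    if X.shape[1] != len(labels):
        raise ValueError("X columns must match dendrogram leaves")
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    imp = {lab: importance.importance_of(lab) for lab in labels}

    ks, chosen_sets, scores, fold_scores = [], [], [], []
    for k in range(1, K_max + 1):
        assign = dendrogram.cut(k)
        members: list[str] = []
        for cluster in np.unique(assign):
            cluster_labels = [lab for lab, c in zip(labels, assign) if c == cluster]
            # highest importance; ties -> lexicographically smallest label
            best = min(cluster_labels, key=lambda lab: (-imp[lab], lab))
            members.append(best)
        members = sorted(members)
        idx = [labels.index(lab) for lab in members]
        composite = X[:, idx].mean(axis=1)
        score, per_fold = _composite_cv_auc(composite, y, n_folds, seed)
        ks.append(k)
        chosen_sets.append(tuple(members))
        scores.append(score)
        fold_scores.append(tuple(per_fold))

    scores_arr = np.asarray(scores)
    best_idx = int(np.argmax(scores_arr))
    se_best = float(
        np.std(fold_scores[best_idx], ddof=1) / np.sqrt(len(fold_scores[best_idx]))
    )
    eligible = np.flatnonzero(scores_arr >= scores_arr[best_idx] - se_best)
    chosen_k = ks[int(eligible[0])]
    return FeatureSelectionTrace(
        ks=tuple(ks),
        selected=tuple(chosen_sets),
        scores=tuple(float(s) for s in scores),
        fold_scores=tuple(fold_scores),
        chosen_k=chosen_k,
    )
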