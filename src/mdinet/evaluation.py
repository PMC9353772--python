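"""Clustering and classification harness with bespoke performance statistics.

Unsupervised side: UPGMA hierarchical clustering (Euclidean distance) and
best-of-restarts K-means, scored by

* correct clustering % — classes whose samples form a pure node of the
  dendrogram (HCA) or an exactly matching cluster (K-means);
* discrimination distance — for each correctly clustered class, the height
  gap between the formation of its pure node and the merge that absorbs it,
  normalized by the maximum merge height (HCA; the absorption-height variant
  is available), or the nearest-other-centroid distance over the maximum
  pairwise centroid distance (K-means); 0 for incorrect classes, averaged
  over classes;
* correct first cluster % — samples whose first merge joins only own-class
  samples (HCA);
* adjusted Rand index (K-means).

Supervised side: random-forest and PLS-DA classifiers under repeated
stratified k-fold cross-validation with a master-seed hierarchy (one seed
derives per-iteration and per-fold sub-seeds, so every accuracy is
reproducible bit for bit), label-permutation significance tests with the
+1-corrected p-value, and pooled cross-validated ROC/AUC for two-class
problems. PLS-DA uses the NIPALS PLS2 algorithm with one-hot responses,
argmax decision (0.5 threshold for two classes), in-fold auto-scaling and
Q2-maximizing component selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

__all__ = [
    "LinkageTree",
    "ClusterEvalResult",
    "CVResult",
    "hca",
    "hca_correct_clustering",
    "hca_discrimination_distance",
    "hca_correct_first_cluster",
    "kmeans_cluster",
    "kmeans_eval",
    "rf_classify_cv",
    "plsda_classify_cv",
    "select_components_q2",
    "recommended_plsda_components",
    "permutation_test",
    "roc_auc_cv",
]


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class LinkageTree:
    """UPGMA merge history: scipy linkage matrix + leaf sample ids."""

    merges: np.ndarray  # (n-1, 4): ids merged, height, new cluster size
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_leafsets(self) -> list[frozenset[int]]:
        """Leaf-index sets for every node (leaves then internal, in order)."""
        n = self.n_leaves
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for a, b, _, _ in self.merges:
            sets.append(sets[int(a)] | sets[int(b)])
        return sets

    def formation_height(self, node_id: int) -> float:
        return 0.0 if node_id < self.n_leaves else float(self.merges[node_id - self.n_leaves, 2])

    def absorption_height(self, node_id: int) -> float | None:
        """Height of the merge that absorbs ``node_id`` (None for the root)."""
        rows = np.nonzero(
            (self.merges[:, 0] == node_id) | (self.merges[:, 1] == node_id)
        )[0]
        return float(self.merges[rows[0], 2]) if len(rows) else None

    @property
    def max_height(self) -> float:
        return float(self.merges[:, 2].max()) if len(self.merges) else 0.0


def hca(profile: pd.DataFrame) -> LinkageTree:
    """UPGMA (average-linkage) agglomeration on Euclidean distances."""
    if profile.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    z = linkage(profile.to_numpy(dtype=float), method="average", metric="euclidean")
    return LinkageTree(z, list(profile.index))


def _class_sets(tree: LinkageTree, labels: Mapping[str, str]) -> dict[str, frozenset[int]]:
    missing = [s for s in tree.leaves if s not in labels]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    classes: dict[str, set[int]] = {}
    for i, s in enumerate(tree.leaves):
        classes.setdefault(labels[s], set()).add(i)
    return {c: frozenset(v) for c, v in classes.items()}


def _pure_nodes(tree: LinkageTree, labels: Mapping[str, str]) -> dict[str, int | None]:
    """Per class, the node whose leaf set equals the class (None if absent)."""
    leafsets = tree.node_leafsets()
    out: dict[str, int | None] = {}
    for cls, members in _class_sets(tree, labels).items():
        out[cls] = next((i for i, ls in enumerate(leafsets) if ls == members), None)
    return out


def hca_correct_clustering(tree: LinkageTree, labels: Mapping[str, str]) -> float:
    """% of classes whose samples all cluster together before anything else."""
    nodes = _pure_nodes(tree, labels)
    return 100.0 * sum(n is not None for n in nodes.values()) / len(nodes)


def hca_discrimination_distance(
    tree: LinkageTree, labels: Mapping[str, str], variant: str = "gap"
) -> float:
    """Mean normalized separation of correctly clustered classes.

    ``gap`` (default): (absorption height - formation height) / max height.
    ``absorption``: absorption height / max height.
    Classes that do not cluster correctly contribute 0.
    """
    if variant not in {"gap", "absorption"}:
        raise ValueError(f"unknown variant {variant!r}")
    nodes = _pure_nodes(tree, labels)
    hmax = tree.max_height
    if hmax == 0:
        return 0.0
    vals = []
    for node in nodes.values():
        if node is None:
            vals.append(0.0)
            continue
        absorb = tree.absorption_height(node)
        if absorb is None:  # class == all samples; nothing to separate from
            vals.append(0.0)
            continue
        top = absorb - tree.formation_height(node) if variant == "gap" else absorb
        vals.append(top / hmax)
    return float(np.mean(vals))


def hca_correct_first_cluster(tree: LinkageTree, labels: Mapping[str, str]) -> float:
    """% of samples whose first merge joins only own-class samples."""
    _class_sets(tree, labels)  # label validation
    leafsets = tree.node_leafsets()
    n = tree.n_leaves
    correct = 0
    for i, s in enumerate(tree.leaves):
        # the smallest internal node containing leaf i = its first merge
        node = next(j for j in range(n, len(leafsets)) if i in leafsets[j])
        correct += all(labels[tree.leaves[k]] == labels[s] for k in leafsets[node])
    return 100.0 * correct / n


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterEvalResult:
    correct_clustering_pct: float
    discrimination_distance: float
    adjusted_rand: float
    correct_first_cluster_pct: float | None = None


def kmeans_cluster(
    profile: pd.DataFrame, k: int, restarts: int = 20, seed: int | None = 0
) -> tuple[pd.Series, np.ndarray, float]:
    """Best-of-``restarts`` K-means (Euclidean); returns labels, centroids, inertia."""
    from sklearn.cluster import KMeans

    if k > profile.shape[0]:
        raise ValueError("more clusters than samples")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    part = km.fit_predict(profile.to_numpy(dtype=float))
    return pd.Series(part, index=profile.index), km.cluster_centers_, float(km.inertia_)


def kmeans_eval(
    partition: pd.Series, centroids: np.ndarray, labels: Mapping[str, str]
) -> ClusterEvalResult:
    """Score a K-means partition against ground-truth classes.

    A class is correct iff some cluster contains all and only its samples
    (homogeneity and completeness); its discrimination distance is the
    distance from its centroid to the nearest other centroid, normalized by
    the maximum pairwise centroid distance.
    """
    from sklearn.metrics import adjusted_rand_score

    y = np.asarray([labels[s] for s in partition.index])
    ari = float(adjusted_rand_score(y, partition.to_numpy()))
    cluster_sets = {c: set(partition.index[partition == c]) for c in np.unique(partition)}
    class_sets = {c: set(partition.index[y == c]) for c in np.unique(y)}
    if len(centroids) > 1:
        cd = pdist(centroids)
        dmax = float(cd.max())
        from scipy.spatial.distance import squareform

        dmat = squareform(cd)
        np.fill_diagonal(dmat, np.inf)
    else:
        dmax = 0.0
    per_class = []
    n_correct = 0
    for cls, members in class_sets.items():
        match = next((cid for cid, cs in cluster_sets.items() if cs == members), None)
        if match is None or dmax == 0:
            per_class.append(0.0)
            continue
        n_correct += 1
        per_class.append(float(dmat[match].min()) / dmax)
    return ClusterEvalResult(
        correct_clustering_pct=100.0 * n_correct / len(class_sets),
        discrimination_distance=float(np.mean(per_class)),
        adjusted_rand=ari,
    )


# ---------------------------------------------------------------------------
# cross-validated classifiers
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    accuracy_mean: float
    accuracy_sd: float
    accuracies: list[float]
    importances: pd.Series | None = None
    fold_assignments: list[np.ndarray] = field(default_factory=list)
    permutation_p: float | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)
    auc: float | None = None


def _iteration_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _check_folds(y: np.ndarray, n_folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {n_folds} folds"
        )


Transformer = Callable[[pd.DataFrame, np.ndarray, pd.DataFrame], tuple[pd.DataFrame, pd.DataFrame]]


def rf_classify_cv(
    profile: pd.DataFrame,
    labels: Sequence[str],
    n_folds: int = 3,
    n_iterations: int = 20,
    n_trees: int = 100,
    seed: int | None = 0,
    transformer: Transformer | None = None,
) -> CVResult:
    """Random forest accuracy under repeated stratified k-fold CV.

    ``transformer(train_X, train_y, test_X)`` hooks in profile types that
    need fitted state (IDT pretreatment, WMDBI importances): it is called
    per fold with training data only, returning transformed train/test
    matrices. Mean gini importances are averaged over all folds (on the
    final transformed feature space; requires a stable column set).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels)
    _check_folds(y, n_folds)
    accs: list[float] = []
    importances: list[pd.Series] = []
    assignments: list[np.ndarray] = []
    for it_seed in _iteration_seeds(seed, n_iterations):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=it_seed)
        fold_idx = np.empty(len(y), dtype=int)
        hits = 0
        for f, (tr, te) in enumerate(skf.split(profile, y)):
            fold_idx[te] = f
            xtr, xte = profile.iloc[tr], profile.iloc[te]
            if transformer is not None:
                xtr, xte = transformer(xtr, y[tr], xte)
            rf = RandomForestClassifier(n_estimators=n_trees, random_state=it_seed + f)
            rf.fit(xtr.to_numpy(), y[tr])
            hits += int((rf.predict(xte.to_numpy()) == y[te]).sum())
            importances.append(pd.Series(rf.feature_importances_, index=xtr.columns))
        accs.append(hits / len(y))
        assignments.append(fold_idx)
    imp = pd.concat(importances, axis=1).mean(axis=1) if importances else None
    return CVResult(
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        accuracies=accs,
        importances=imp,
        fold_assignments=assignments,
    )


def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class order (sorted) and response matrix: one-hot, or 0/1 column."""
    classes = np.unique(y)
    if len(classes) == 2:
        resp = (y == classes[1]).astype(float)[:, None]
    else:
        resp = np.stack([(y == c).astype(float) for c in classes], axis=1)
    return classes, resp


def _plsda_predict(model, classes: np.ndarray, x: np.ndarray) -> np.ndarray:
    yhat = model.predict(x)
    if len(classes) == 2:
        return np.where(yhat[:, 0] > 0.5, classes[1], classes[0])
    return classes[np.argmax(yhat, axis=1)]  # argmax ties -> lowest index


def select_components_q2(
    profile: pd.DataFrame,
    labels: Sequence[str],
    max_components: int = 10,
    n_folds: int = 3,
    seed: int | None = 0,
) -> int:
    """Pick the PLS component count maximizing Q2 under stratified CV.

    Q2 = 1 - PRESS/TSS on the (one-hot) response, pooled over folds.
    """
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.model_selection import StratifiedKFold
    from sklearn.preprocessing import StandardScaler

    y = np.asarray(labels)
    _check_folds(y, n_folds)
    classes, resp = _encode_labels(y)
    x = profile.to_numpy(dtype=float)
    limit = min(max_components, x.shape[1], x.shape[0] - 2)
    best_a, best_q2 = 1, -np.inf
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    tss = float(((resp - resp.mean(axis=0)) ** 2).sum())
    for a in range(1, max(limit, 1) + 1):
        press = 0.0
        for tr, te in splits:
            scaler = StandardScaler().fit(x[tr])
            pls = PLSRegression(n_components=a, scale=False)
            pls.fit(scaler.transform(x[tr]), resp[tr])
            press += float(((resp[te] - pls.predict(scaler.transform(x[te]))) ** 2).sum())
        q2 = 1.0 - press / tss
        if q2 > best_q2:
            best_a, best_q2 = a, q2
    return best_a


#: component counts used by default for the MDB-impact profile families
RECOMMENDED_PLSDA_COMPONENTS = {"mdbi": 4, "wmdbi": 6}


def recommended_plsda_components(profile_kind: str) -> int | str:
    """Default component count per profile kind ('auto' when unconstrained)."""
    return RECOMMENDED_PLSDA_COMPONENTS.get(profile_kind.lower(), "auto")


def plsda_classify_cv(
    profile: pd.DataFrame,
    labels: Sequence[str],
    n_components: int | str = "auto",
    n_folds: int = 3,
    n_iterations: int = 20,
    seed: int | None = 0,
    autoscale: bool = True,
) -> CVResult:
    """PLS-DA accuracy under repeated stratified k-fold CV.

    PLS2 (NIPALS) regression on the encoded response; profiles are
    auto-scaled inside each fold (fit on train) unless the input is already
    scaled. ``n_components='auto'`` selects the count by maximizing Q2.
    """
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.model_selection import StratifiedKFold
    from sklearn.preprocessing import StandardScaler

    y = np.asarray(labels)
    _check_folds(y, n_folds)
    classes, resp = _encode_labels(y)
    if n_components == "auto":
        n_components = select_components_q2(profile, labels, n_folds=n_folds, seed=seed)
    n_components = int(n_components)
    max_rank = min(profile.shape[1], profile.shape[0] - 1)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {max_rank}")
    x = profile.to_numpy(dtype=float)
    accs: list[float] = []
    assignments: list[np.ndarray] = []
    loadings: list[np.ndarray] = []
    for it_seed in _iteration_seeds(seed, n_iterations):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=it_seed)
        fold_idx = np.empty(len(y), dtype=int)
        hits = 0
        for f, (tr, te) in enumerate(skf.split(x, y)):
            fold_idx[te] = f
            xtr, xte = x[tr], x[te]
            if autoscale:
                scaler = StandardScaler().fit(xtr)
                xtr, xte = scaler.transform(xtr), scaler.transform(xte)
            a = min(n_components, len(tr) - 1)
            pls = PLSRegression(n_components=a, scale=False)
            pls.fit(xtr, resp[tr])
            hits += int((_plsda_predict(pls, classes, xte) == y[te]).sum())
            loadings.append(np.abs(pls.x_loadings_).sum(axis=1))
        accs.append(hits / len(y))
        assignments.append(fold_idx)
    imp = pd.Series(np.mean(loadings, axis=0), index=profile.columns)
    return CVResult(
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        accuracies=accs,
        importances=imp,
        fold_assignments=assignments,
    )


# ---------------------------------------------------------------------------
# significance and ROC
# ---------------------------------------------------------------------------

def permutation_test(
    classifier_cv: Callable[..., CVResult],
    profile: pd.DataFrame,
    labels: Sequence[str],
    n_perm: int = 500,
    seed: int | None = 0,
    **cv_kwargs,
) -> float:
    """Label-permutation p-value for a cross-validated classifier.

    p = (1 + #{permuted accuracy >= observed}) / (1 + n_perm); the +1
    correction keeps p strictly positive (minimum 1/(n_perm+1)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels)
    observed = classifier_cv(profile, y, seed=seed, **cv_kwargs).accuracy_mean
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        acc = classifier_cv(profile, perm, seed=seed, **cv_kwargs).accuracy_mean
        hits += acc >= observed
    return (1 + hits) / (1 + n_perm)


def roc_auc_cv(
    profile: pd.DataFrame,
    labels: Sequence[str],
    classifier: str = "rf",
    n_folds: int = 5,
    n_trees: int = 100,
    n_components: int = 2,
    seed: int | None = 0,
) -> CVResult:
    """Pooled cross-validated ROC curve and trapezoidal AUC (two classes).

    Scores are the positive-class probability (RF) or the raw PLS response;
    the positive class is the lexicographically larger label.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.metrics import auc, roc_curve
    from sklearn.model_selection import StratifiedKFold
    from sklearn.preprocessing import StandardScaler

    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("ROC analysis requires exactly two classes")
    _check_folds(y, n_folds)
    x = profile.to_numpy(dtype=float)
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=object)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(x, y):
        if classifier == "rf":
            rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
            rf.fit(x[tr], y[tr])
            pos = list(rf.classes_).index(classes[1])
            scores[te] = rf.predict_proba(x[te])[:, pos]
            preds[te] = rf.predict(x[te])
        elif classifier == "plsda":
            scaler = StandardScaler().fit(x[tr])
            pls = PLSRegression(n_components=n_components, scale=False)
            pls.fit(scaler.transform(x[tr]), (y[tr] == classes[1]).astype(float))
            s = pls.predict(scaler.transform(x[te]))[:, 0]
            scores[te] = s
            preds[te] = np.where(s > 0.5, classes[1], classes[0])
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
    fpr, tpr, _ = roc_curve(y == classes[1], scores)
    acc = float((preds == y).mean())
    return CVResult(
        accuracy_mean=acc, accuracy_sd=0.0, accuracies=[acc],
        roc=(fpr, tpr), auc=float(auc(fpr, tpr)),
    )
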