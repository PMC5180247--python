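"""Exploratory layer: z-scored element profiles, hierarchical clustering of
elements by correlation distance, and group classification.

Element profiles are the per-element vectors of concentrations across all
samples, z-scored row-wise so elements with very different absolute levels
(Ca at hundreds of units vs Bi at hundredths) become comparable. Clustering
uses 1 - rho as the distance between profiles, with Spearman rho by default
for consistency with the network statistics (Pearson available via flag).

Classification separates two groups from the per-sample element vectors
pooled across time points; feature importances identify marker elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .dataset import IonomeDataset


@dataclass
class ElementProfileMatrix:
    """Row-standardised element x sample matrix.

    Each row has mean 0 and sample sd 1 except rows that were constant in
    the raw data, which are all-zero and listed in ``constant_rows``.
    """

    values: pd.DataFrame            # rows: elements, columns: samples
    constant_rows: list[str] = field(default_factory=list)


def profile_matrix(dataset: IonomeDataset) -> pd.DataFrame:
    """Raw element x sample concentration matrix in canonical element order."""
    wide = dataset.records.pivot(index="element", columns="sample_id",
                                 values="concentration")
    order = [e for e in dataset.element_order if e in wide.index]
    return wide.loc[order]


def zscore_rows(matrix: pd.DataFrame) -> ElementProfileMatrix:
    """Standardise each row to mean 0, sample sd 1 (ddof=1).

    Constant rows cannot be standardised; they become all-zero and are
    flagged rather than propagating NaNs into the clustering distances.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to z-score")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd[sd == 0].index.tolist()
    sd = sd.replace(0, 1.0)
    z = matrix.sub(mu, axis=0).div(sd, axis=0)
    return ElementProfileMatrix(values=z, constant_rows=constant)


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    labels: list[str]
    memberships: dict[str, int] | None   # element -> flat cluster id, if k given

    def clusters(self) -> list[set[str]]:
        """Flat clusters as sets of element symbols (requires k)."""
        if self.memberships is None:
            raise ValueError("no flat clustering was requested (k is None)")
        out: dict[int, set[str]] = {}
        for e, c in self.memberships.items():
            out.setdefault(c, set()).add(e)
        return list(out.values())


def correlation_distance_matrix(profiles: ElementProfileMatrix,
                                metric: str = "spearman") -> pd.DataFrame:
    """Pairwise 1 - rho distances between element profiles (range [0, 2])."""
    z = profiles.values
    if metric == "spearman":
        rho = stats.spearmanr(z.to_numpy().T).statistic
        rho = np.atleast_2d(rho)
    elif metric == "pearson":
        rho = np.corrcoef(z.to_numpy())
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # constant rows were zero-filled: their correlation is undefined -> treat
    # as uncorrelated (distance 1) rather than NaN
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    d = 1.0 - rho
    return pd.DataFrame(d, index=z.index, columns=z.index)


def cluster_elements(profiles: ElementProfileMatrix, linkage: str = "average",
                     k: int | None = None,
                     metric: str = "spearman") -> ClusteringResult:
    """Agglomerative clustering of elements with correlation distance.

    Deterministic given the input; rows are processed in their canonical
    order so the dendrogram does not depend on incidental input ordering.
    """
    if linkage not in {"average", "complete", "ward"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    if profiles.values.shape[0] < 3:
        raise ValueError("need at least 3 elements to cluster")
    dist = correlation_distance_matrix(profiles, metric=metric)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    labels = list(dist.index)
    memberships = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        memberships = dict(zip(labels, (int(c) for c in flat)))
    return ClusteringResult(linkage_matrix=Z, labels=labels,
                            memberships=memberships)


def linkage_to_newick(result: ClusteringResult) -> str:
    """Serialise the dendrogram as a Newick string with merge-height branch
    lengths (loadable by any tree viewer)."""
    tree = hierarchy.to_tree(result.linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


_CLASSIFIERS = {
    # shallow tree: ~60 samples and 15 features leave no room for deep fits
    "decision_tree": lambda seed: DecisionTreeClassifier(
        max_depth=3, min_samples_leaf=3, random_state=seed),
    "naive_bayes": lambda seed: GaussianNB(),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=200, max_depth=3, random_state=seed),
}


@dataclass
class ClassificationResult:
    algorithm: str
    cv_accuracy: float
    fold_accuracies: np.ndarray
    importances: pd.Series      # per element, sorted descending


def classify_groups(dataset: IonomeDataset, labels: tuple[str, str],
                    algorithm: str = "decision_tree", cv_folds: int = 5,
                    seed: int = 0) -> ClassificationResult:
    """Cross-validated separation of two groups from element concentrations.

    Samples are pooled across time points (time is not a feature). Accuracy
    is the mean over stratified folds; importances come from the model fit
    on all data (impurity importances for trees/forests, permutation
    importances for naive Bayes). Deterministic under a fixed seed.
    """
    if algorithm not in _CLASSIFIERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"choose from {sorted(_CLASSIFIERS)}")
    g1, g2 = labels
    df = dataset.records
    sub = df[df["group"].isin(labels)]
    if sub["group"].nunique() < 2:
        raise ValueError("need samples from both classes")
    X = sub.pivot(index="sample_id", columns="element", values="concentration")
    X = X[[e for e in dataset.element_order if e in X.columns]]
    y = sub.groupby("sample_id")["group"].first().loc[X.index]
    if y.value_counts().min() < cv_folds:
        raise ValueError("fewer samples in a class than CV folds")

    clf = _CLASSIFIERS[algorithm](seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, X.to_numpy(), y.to_numpy(), cv=cv,
                             scoring="accuracy")
    fitted = _CLASSIFIERS[algorithm](seed).fit(X.to_numpy(), y.to_numpy())
    if hasattr(fitted, "feature_importances_"):
        imp = pd.Series(fitted.feature_importances_, index=X.columns)
    else:
        pi = permutation_importance(fitted, X.to_numpy(), y.to_numpy(),
                                    n_repeats=20, random_state=seed)
        imp = pd.Series(pi.importances_mean, index=X.columns)
    imp = imp.sort_values(ascending=False)
    return ClassificationResult(algorithm=algorithm,
                                cv_accuracy=float(scores.mean()),
                                fold_accuracies=scores, importances=imp)
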