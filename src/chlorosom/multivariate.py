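"""Ordination, clustering and group comparison for mixed-unit feature tables.

Leaf element contents (g/kg and mg/kg), soil properties and JIP parameters
live on very different scales, so all multivariate analysis here operates
on standardised (z-scored) features: PCA is correlation-matrix PCA, and
distances are Euclidean in standardised space.

Provided tools:

* :class:`CorrelationPCA` — PCA on the correlation matrix, with loadings
  reported as feature-component correlations (biplot arrows) and a fixed
  sign convention.
* :func:`ward_dendrogram` / :func:`dendrogram_to_newick` — Ward
  minimum-variance agglomeration and a Newick export.
* :class:`HKMeans` — hierarchical k-means: Lloyd iterations started from
  the centroids of a Ward-tree cut, with Calinski-Harabasz selection of k.
* :func:`anova_tukey` — one-way ANOVA with Tukey HSD and a compact letter
  display.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.metrics import calinski_harabasz_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "standardise",
    "CorrelationPCA",
    "pca",
    "ward_dendrogram",
    "dendrogram_to_newick",
    "cut_dendrogram",
    "HKMeans",
    "hkmeans",
    "GroupComparison",
    "anova_tukey",
    "compact_letter_display",
]


def standardise(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (sample SD, ddof=1).

    Raises ``ValueError`` naming the first zero-variance feature.
    """
    values = table.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        bad = table.columns[np.where(~np.isfinite(values))[1][0]]
        raise ValueError(f"feature {bad!r} contains missing or non-finite values")
    sd = values.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(f"feature {table.columns[zero[0]]!r} has zero variance")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=table.index, columns=table.columns)


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """PCA on the correlation matrix of a samples-by-features table.

    Input features are z-scored internally (``scale=True``, the default) so
    that mixed-unit tables are handled correctly; eigenvalues then sum to
    the number of features.  Loadings are reported as feature-component
    correlations, suitable as biplot arrows.  The sign of each component is
    fixed so that its largest-magnitude loading is positive.

    Attributes (after :meth:`fit`)
    ------------------------------
    eigenvalues_ : (p,) variances of the scores, non-increasing
    components_ : (p, p) orthonormal eigenvectors (rows)
    loadings_ : (p, p) feature-component correlations (columns = components)
    proportion_variance_ : (p,) fractions of total variance, summing to 1
    """

    def __init__(self, scale: bool = True):
        self.scale = scale

    def fit(self, X, y=None):
        X = self._validate(X)
        n, p = X.shape
        # SVD of the standardised matrix: eigenvalues of the correlation
        # matrix are s^2/(n-1).
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        eig = s**2 / (n - 1)
        # sign convention: largest-|loading| feature of each component positive
        for j in range(Vt.shape[0]):
            i = int(np.argmax(np.abs(Vt[j])))
            if Vt[j, i] < 0:
                Vt[j] *= -1.0
                U[:, j] *= -1.0
        self.n_samples_ = n
        self.feature_names_ = list(self._columns)
        self.eigenvalues_ = eig
        self.components_ = Vt
        self.loadings_ = (Vt * np.sqrt(eig)[:, None]).T
        self.proportion_variance_ = eig / eig.sum()
        self._mean = self._fit_mean
        self._sd = self._fit_sd
        self.scores_ = X @ Vt.T
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        X = (X - self._mean) / self._sd
        return X @ self.components_.T

    def inverse_transform(self, scores):
        return np.asarray(scores) @ self.components_ * self._sd + self._mean

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            self._columns = list(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            self._columns = [f"f{j}" for j in range(values.shape[1])]
        if values.ndim != 2 or values.shape[0] < 2:
            raise ValueError("PCA requires a 2-D table with at least 2 samples")
        if np.any(~np.isfinite(values)):
            raise ValueError("PCA input contains missing or non-finite values")
        self._fit_mean = values.mean(axis=0)
        if self.scale:
            sd = values.std(axis=0, ddof=1)
            if np.any(sd == 0):
                j = int(np.where(sd == 0)[0][0])
                raise ValueError(f"feature {self._columns[j]!r} has zero variance")
            self._fit_sd = sd
        else:
            self._fit_sd = np.ones(values.shape[1])
        return (values - self._fit_mean) / self._fit_sd


def pca(table: pd.DataFrame) -> CorrelationPCA:
    """Fit a :class:`CorrelationPCA` on a feature table."""
    return CorrelationPCA().fit(table)


def ward_dendrogram(X) -> np.ndarray:
    """Ward minimum-variance linkage matrix (scipy format, Euclidean)."""
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return sch.linkage(values, method="ward")


def cut_dendrogram(Z: np.ndarray, height: float | None = None,
                   k: int | None = None) -> np.ndarray:
    """Flat 1..k cluster labels from a height threshold or a requested k."""
    if (height is None) == (k is None):
        raise ValueError("give exactly one of height or k")
    if height is not None:
        return sch.fcluster(Z, t=height, criterion="distance")
    return sch.fcluster(Z, t=k, criterion="maxclust")


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick export; branch lengths are merge-height differences."""
    tree = sch.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


class HKMeans(BaseEstimator, ClusterMixin):
    """Hierarchical k-means: Lloyd refinement of a Ward-tree cut.

    The initial centroids are the group centroids of a Ward dendrogram cut
    at ``k`` clusters; Lloyd iterations then minimise the within-group sum
    of squares until the relative WSS change falls below ``tol`` or
    ``max_iter`` is reached.  With ``k="auto"`` the k in ``k_range``
    maximising the Calinski-Harabasz index is chosen.

    Ties (a point equidistant from several centroids) go to the lowest
    centroid index; an emptied cluster is re-seeded with the point farthest
    from its current centroid.  ``labels_`` are 1..k.
    """

    def __init__(self, k="auto", k_range=(2, 8), max_iter=300, tol=1e-10, seed=1):
        self.k = k
        self.k_range = k_range
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _wss(X, labels, centers) -> float:
        return float(((X - centers[labels]) ** 2).sum())

    def _lloyd(self, X: np.ndarray, centers: np.ndarray):
        n, k = X.shape[0], centers.shape[0]
        prev_wss = np.inf
        labels = np.zeros(n, dtype=int)
        for _ in range(self.max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
            for j in range(k):
                if not np.any(labels == j):
                    far = int(d2[np.arange(n), labels].argmax())
                    centers[j] = X[far]
                    labels[far] = j
            centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
            wss = self._wss(X, labels, centers)
            if not wss <= prev_wss + 1e-9 * max(prev_wss, 1.0):  # pragma: no cover
                raise AssertionError("WSS increased during a Lloyd iteration")
            if prev_wss - wss < self.tol * max(prev_wss, 1.0):
                break
            prev_wss = wss
        return labels, centers, self._wss(X, labels, centers)

    def _fit_single(self, X: np.ndarray, Z: np.ndarray, k: int):
        init_labels = sch.fcluster(Z, t=k, criterion="maxclust")
        centers = np.vstack([X[init_labels == j].mean(axis=0)
                             for j in range(1, k + 1)])
        return self._lloyd(X, centers)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if np.any(~np.isfinite(values)):
            raise ValueError("non-finite values in clustering input")
        n = values.shape[0]
        Z = ward_dendrogram(values)
        if self.k == "auto":
            lo, hi = self.k_range
            hi = min(hi, n - 1)
            best = None
            self.ch_scores_ = {}
            for k in range(lo, hi + 1):
                labels, centers, wss = self._fit_single(values, Z, k)
                if len(np.unique(labels)) < 2:
                    continue
                ch = calinski_harabasz_score(values, labels)
                self.ch_scores_[k] = ch
                if best is None or ch > best[0]:
                    best = (ch, k, labels, centers, wss)
            if best is None:
                raise ValueError("auto-k failed: no k produced >=2 clusters")
            _, k, labels, centers, wss = best
        else:
            k = int(self.k)
            if k < 1 or k > n:
                raise ValueError(f"k={k} out of range for {n} samples")
            labels, centers, wss = self._fit_single(values, Z, k)
            self.ch_scores_ = {}
        self.k_ = k
        self.labels_ = labels + 1  # 1..k
        self.cluster_centers_ = centers
        self.inertia_ = wss
        self.linkage_ = Z
        return self

    def predict(self, X):
        values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        d2 = ((values[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1) + 1


def hkmeans(scores, k="auto", seed: int = 1) -> HKMeans:
    """Fit :class:`HKMeans` on a score matrix and return the fitted model."""
    return HKMeans(k=k, seed=seed).fit(scores)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD + compact letter display


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc for one feature."""

    feature: str
    F: float
    p: float
    group_order: list[str]          # descending group mean
    means: dict[str, float]
    se: dict[str, float]
    n: dict[str, int]
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05


def compact_letter_display(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` must be ordered (here: descending mean); ``significant``
    holds unordered significant pairs.  Groups sharing no letter differ
    significantly; groups sharing a letter do not.
    """
    sig = {frozenset(p) for p in significant}
    cols: list[set[str]] = [set(groups)]
    for a, b in (tuple(sorted(p)) for p in sorted(sig, key=sorted)):
        new_cols: list[set[str]] = []
        for col in cols:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        cols = [c for c in new_cols if c and not any(
            c < other for other in new_cols if other is not c)]
        # deduplicate
        seen: list[set[str]] = []
        for c in cols:
            if c not in seen:
                seen.append(c)
        cols = seen
    # order columns by the first (highest-mean) group they contain
    rank = {g: i for i, g in enumerate(groups)}
    cols.sort(key=lambda c: min(rank[g] for g in c))
    letters: dict[str, str] = {g: "" for g in groups}
    alphabet = string.ascii_lowercase
    for j, col in enumerate(cols):
        letter = alphabet[j % 26] * (1 + j // 26)
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def anova_tukey(values, labels, alpha: float = 0.05,
                feature: str = "") -> GroupComparison:
    """One-way ANOVA F-test plus Tukey honest-significant-difference test.

    Every group needs at least 2 samples.  Letters are assigned in
    descending group-mean order with the insert-and-absorb algorithm.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    group_names = list(pd.unique(labels))
    samples = {g: values[labels == g] for g in group_names}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups")
    F, p = stats.f_oneway(*samples.values())
    order = sorted(group_names, key=lambda g: -float(samples[g].mean()))
    means = {g: float(samples[g].mean()) for g in group_names}
    se = {g: float(samples[g].std(ddof=1) / np.sqrt(samples[g].size))
          for g in group_names}
    n = {g: int(samples[g].size) for g in group_names}

    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_p: dict[tuple[str, str], float] = {}
    significant: set[tuple[str, str]] = set()
    table = res.summary().data[1:]
    for row in table:
        a, b, padj, reject = str(row[0]), str(row[1]), float(row[3]), bool(row[6])
        tukey_p[(a, b)] = padj
        tukey_p[(b, a)] = padj
        if reject:
            significant.add((a, b))
    letters = compact_letter_display([str(g) for g in order],
                                     {(str(a), str(b)) for a, b in significant})
    return GroupComparison(
        feature=feature, F=float(F), p=float(p),
        group_order=[str(g) for g in order],
        means={str(g): means[g] for g in group_names},
        se={str(g): se[g] for g in group_names},
        n={str(g): n[g] for g in group_names},
        tukey_p={(str(a), str(b)): v for (a, b), v in tukey_p.items()},
        letters=letters, alpha=alpha,
    )
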