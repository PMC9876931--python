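"""Per-cluster stability metrics: reassign, TF-IDF exclusivity, SCCAF.

Each annotation set is scored independently.  Three complementary views of
cluster coherence are used:

* **reassign** — the fraction of a cluster's cells whose nearest centroid,
  in a PCA space built from the union of top discriminative markers, is
  their own cluster's centroid.
* **tfidf(n)** — the exclusivity (term frequency x inverse document
  frequency on binarized expression) of the cluster's nth-ranked exclusive
  feature; a cluster with many private markers scores high.
* **sccaf** — per-cluster recall of a cross-validated multinomial logistic
  regression trained on all features (Single Cell Clustering Assessment
  Framework style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .config import RunConfig
from .io import AnnotationTable, FeatureMatrix

logger = logging.getLogger("sctri")

EPSILON = 1e-5  # pseudo value guarding log(0) in the TF-IDF terms


@dataclass
class MarkerTable:
    """Ranked marker lists per cluster plus their union ``L``.

    Each per-cluster frame holds feature id, log-fold-change, p-value and
    the three ranks (p-value rank, lfc rank, combined = their mean; best
    rank is 0), sorted ascending by combined rank and truncated to the
    requested list length.
    """

    per_cluster: dict[str, pd.DataFrame] = field(default_factory=dict)
    union: list[str] = field(default_factory=list)


def rank_markers(
    X: FeatureMatrix, labels: np.ndarray, top_markers: int = 30
) -> MarkerTable:
    """Rank features per cluster by combined t-test / fold-change rank.

    For every cluster a Welch two-sided t-test (cluster vs all other cells)
    is run per feature; features are ranked by p-value (rank 0 = most
    significant) and by log-fold-change (rank 0 = largest positive), and the
    two ranks are averaged.  Singleton clusters have no defined t-test: all
    their p-value ranks are set to the worst rank and ordering falls back to
    fold change alone.
    """
    labels = np.asarray(labels, dtype=str)
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("rank_markers requires at least 2 clusters")
    values = X.values
    n_cells, n_features = values.shape
    worst = float(n_features - 1)
    k = min(int(top_markers), n_features)
    per_cluster: dict[str, pd.DataFrame] = {}
    union: set[str] = set()
    feature_index = pd.Index(X.feature_ids)
    for cluster in clusters:
        mask = labels == cluster
        in_c = values[mask]
        out_c = values[~mask]
        lfc = in_c.mean(axis=0) - out_c.mean(axis=0)
        if mask.sum() < 2:
            logger.warning(
                "cluster %r has a single cell; p-value ranks set to worst", cluster
            )
            r_pval = np.full(n_features, worst)
            pvals = np.full(n_features, np.nan)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                _, pvals = stats.ttest_ind(in_c, out_c, equal_var=False, axis=0)
            pvals = np.where(np.isfinite(pvals), pvals, 1.0)
            r_pval = stats.rankdata(pvals, method="min") - 1.0
        r_lfc = stats.rankdata(-lfc, method="min") - 1.0
        r_combined = (r_pval + r_lfc) / 2.0
        frame = pd.DataFrame(
            {
                "feature": feature_index,
                "lfc": lfc,
                "pval": pvals,
                "r_pval": r_pval,
                "r_lfc": r_lfc,
                "r_combined": r_combined,
            }
        )
        frame = frame.sort_values(["r_combined", "feature"], kind="mergesort")
        frame = frame.head(k).reset_index(drop=True)
        per_cluster[cluster] = frame
        union.update(frame["feature"])
    return MarkerTable(per_cluster=per_cluster, union=sorted(union))


def _marker_pca(
    X: FeatureMatrix, marker_union: list[str], n_pcs: int
) -> np.ndarray:
    """Mean-centered PCA of the marker-restricted matrix (no rescaling)."""
    idx = [X.feature_ids.index(f) for f in marker_union]
    sub = X.values[:, idx]
    n_cells = sub.shape[0]
    p = min(n_pcs, len(idx) - 1, n_cells - 1)
    if p < 1:
        raise ValueError("fewer than 2 markers/cells: PCA space is empty")
    pca = PCA(n_components=p, svd_solver="full" if p < 30 else "auto", random_state=0)
    return pca.fit_transform(sub)


def nearest_centroid_labels(
    embedding: np.ndarray, centroids: np.ndarray, centroid_labels: list[str]
) -> np.ndarray:
    """Label of the Euclidean-nearest centroid for every row of ``embedding``."""
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; the ||x||^2 term is constant per row
    cross = embedding @ centroids.T
    d2 = (centroids**2).sum(axis=1)[None, :] - 2.0 * cross
    nearest = np.argmin(d2, axis=1)
    return np.asarray(centroid_labels, dtype=object)[nearest]


def reassign_score(
    X: FeatureMatrix,
    labels: np.ndarray,
    markers: MarkerTable,
    n_pcs: int = 30,
) -> dict[str, float]:
    """Fraction of each cluster's cells reclassified to their own centroid.

    Cluster centroids are taken in the marker-PCA space; every cell is
    assigned to the nearest centroid and the score of a cluster is the
    fraction of its members that come back to it.
    """
    labels = np.asarray(labels, dtype=str)
    embedding = _marker_pca(X, markers.union, n_pcs)
    clusters = sorted(pd.unique(labels))
    centroids = np.vstack([embedding[labels == c].mean(axis=0) for c in clusters])
    assigned = nearest_centroid_labels(embedding, centroids, clusters)
    scores = {}
    for c in clusters:
        mask = labels == c
        scores[c] = float((assigned[mask] == c).mean())
    return scores


def tfidf_exclusivity(
    X: FeatureMatrix, labels: np.ndarray, cluster: str, epsilon: float = EPSILON
) -> np.ndarray:
    """Per-feature exclusivity TF x IDF for one cluster.

    TF is the in-cluster detection fraction (+epsilon), IDF the negative log
    of the global detection fraction (+epsilon); binarization is strictly
    ``value > 0`` on the normalized matrix.
    """
    labels = np.asarray(labels, dtype=str)
    mask = labels == str(cluster)
    if not mask.any():
        raise ValueError(f"cluster {cluster!r} has no cells")
    detected = X.values > 0
    tf = detected[mask].mean(axis=0) + epsilon
    idf = -np.log(detected.mean(axis=0) + epsilon)
    return tf * idf


def tfidf_n_score(exclusivity: np.ndarray, n: int) -> float:
    """The nth largest exclusivity (1-based); the last value when F < n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    exclusivity = np.asarray(exclusivity, dtype=float)
    if exclusivity.size == 0:
        raise ValueError("empty feature set")
    ordered = np.sort(exclusivity)[::-1]
    return float(ordered[min(n, ordered.size) - 1])


def sccaf_score(
    X: FeatureMatrix,
    labels: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    variant: str = "row_recall",
) -> dict[str, float]:
    """Cross-validated logistic-regression confusion scores per cluster.

    A multinomial L2-regularized logistic regression is fit on all features
    under stratified k-fold cross-validation; out-of-fold predictions build
    a confusion matrix Psi.  ``row_recall`` scores a cluster as
    Psi_cc / row-sum (its recall); ``trace`` divides by the trace instead.
    Folds are reduced to the smallest cluster size when needed; singleton
    clusters cannot be stratified and score 0.  Cells are put in a canonical
    (cell-id) order before fold assignment so the scores do not depend on
    the storage order of the matrix.
    """
    labels = np.asarray(labels, dtype=str)
    order = np.argsort(np.asarray(X.cell_ids))
    X_values = X.values[order]
    labels = labels[order]
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("sccaf_score requires at least 2 clusters")
    counts = pd.Series(labels).value_counts()
    singletons = [c for c in clusters if counts[c] < 2]
    if singletons:
        logger.warning("singleton cluster(s) %s score 0 under SCCAF", singletons)
    usable = [c for c in clusters if counts[c] >= 2]
    scores = {c: 0.0 for c in clusters}
    if len(usable) < 2:
        return scores
    keep = np.isin(labels, usable)
    folds = int(min(n_folds, counts[usable].min()))
    folds = max(folds, 2)
    model = LogisticRegression(max_iter=200)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    predicted = cross_val_predict(model, X_values[keep], labels[keep], cv=cv)
    psi = confusion_matrix(labels[keep], predicted, labels=usable)
    diag = np.diag(psi).astype(float)
    if variant == "row_recall":
        denom = psi.sum(axis=1).astype(float)
    elif variant == "trace":
        denom = np.full(len(usable), max(diag.sum(), 1.0))
    else:
        raise ValueError(f"unknown SCCAF variant: {variant!r}")
    for c, d, s in zip(usable, diag, denom):
        scores[c] = float(d / s) if s > 0 else 0.0
    return scores


@dataclass
class ClusterStabilityTable:
    """Stability score for every (annotation, cluster, metric) triple."""

    scores: dict[tuple[str, str, str], float]
    metrics: tuple[str, ...]
    annotations: tuple[str, ...]

    def score(self, annotation: str, cluster: str, metric: str) -> float:
        return self.scores[(annotation, str(cluster), metric)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"annotation": a, "cluster": c, "metric": m, "score": s}
            for (a, c, m), s in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows)


def compute_stability(
    X: FeatureMatrix, annotations: AnnotationTable, config: RunConfig
) -> ClusterStabilityTable:
    """Score every cluster of every annotation set with every metric."""
    scores: dict[tuple[str, str, str], float] = {}
    for name in annotations.annotation_names:
        labels = annotations.labels[name].to_numpy(dtype=str)
        clusters = sorted(pd.unique(labels))
        markers = rank_markers(X, labels, config.top_markers)
        reassign = reassign_score(X, labels, markers, config.n_pcs_reassign)
        sccaf = sccaf_score(
            X,
            labels,
            seed=config.random_seed,
            n_folds=config.sccaf_folds,
            variant=config.sccaf_variant,
        )
        for c in clusters:
            exclusivity = tfidf_exclusivity(X, labels, c)
            scores[(name, c, "reassign")] = reassign[c]
            for n in config.tfidf_orders:
                scores[(name, c, f"tfidf{n}")] = tfidf_n_score(exclusivity, n)
            scores[(name, c, "sccaf")] = sccaf[c]
        logger.info("stability scored for annotation %r (%d clusters)", name, len(clusters))
    return ClusterStabilityTable(
        scores=scores,
        metrics=config.metrics,
        annotations=tuple(annotations.annotation_names),
    )
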