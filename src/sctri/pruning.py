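"""Pruning of unstable winner clusters and nearest-centroid reclassification.

A raw winner cluster that keeps only a small fraction of its originating
cluster's cells, or too few cells in absolute terms, likely won by chance;
its cells are reassigned to the nearest surviving cluster centroid in a
marker-PCA space rebuilt from the stable clusters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import AnnotationTable, FeatureMatrix
from .stability import _marker_pca, nearest_centroid_labels, rank_markers

logger = logging.getLogger("sctri")


def split_raw_label(raw_label: str) -> tuple[str, str]:
    annotation, _, label = raw_label.partition("@")
    return annotation, label


def winning_fraction(
    raw_labels: np.ndarray, annotations: AnnotationTable
) -> dict[str, float]:
    """wf_c = |cells finally assigned to c| / |originating cluster of c|.

    The originating cluster is the (annotation, label) pair encoded in the
    raw label, so identical label strings in different annotation sets stay
    distinct.
    """
    raw_labels = np.asarray(raw_labels, dtype=object)
    won = pd.Series(raw_labels).value_counts()
    wf = {}
    for cluster, n_won in won.items():
        annotation, label = split_raw_label(cluster)
        original = int((annotations.labels[annotation].astype(str) == label).sum())
        wf[cluster] = float(n_won) / original
    return wf


def prune_clusters(
    raw_labels: np.ndarray, wf: dict[str, float], config: RunConfig
) -> tuple[set[str], np.ndarray]:
    """Mark clusters unstable when wf < cutoff or size < abs_thresh.

    Returns the stable cluster set and a boolean mask of cells needing
    reclassification.  All clusters unstable is an error: the cutoffs are
    too strict for the data.
    """
    raw_labels = np.asarray(raw_labels, dtype=object)
    sizes = pd.Series(raw_labels).value_counts()
    stable = {
        c
        for c in sizes.index
        if wf[c] >= config.win_fraction_cutoff and sizes[c] >= config.abs_thresh
    }
    if not stable:
        raise ValueError(
            "every raw cluster is unstable; lower win_fraction_cutoff/abs_thresh"
        )
    unstable_cells = ~np.isin(raw_labels, list(stable))
    n_pruned = len(sizes) - len(stable)
    if n_pruned:
        logger.info(
            "pruned %d unstable cluster(s) covering %d cells",
            n_pruned,
            int(unstable_cells.sum()),
        )
    return stable, unstable_cells


def reclassify_cells(
    X: FeatureMatrix,
    raw_labels: np.ndarray,
    stable: set[str],
    unstable_cells: np.ndarray,
    config: RunConfig,
) -> np.ndarray:
    """Send unstable cells to the nearest stable-cluster centroid.

    The marker-PCA space is recomputed from the stable clusters only (same
    procedure as the reassign score); stable cells keep their raw labels.
    """
    raw_labels = np.asarray(raw_labels, dtype=object)
    final = raw_labels.copy()
    if not unstable_cells.any():
        return final
    stable_list = sorted(stable)
    stable_mask = ~unstable_cells
    if len(stable_list) == 1:
        final[unstable_cells] = stable_list[0]
        return final
    stable_labels = raw_labels[stable_mask].astype(str)
    sub = FeatureMatrix(
        values=X.values[stable_mask],
        cell_ids=[X.cell_ids[i] for i in np.flatnonzero(stable_mask)],
        feature_ids=list(X.feature_ids),
        feature_modality=list(X.feature_modality),
        is_raw_counts=False,
    )
    markers = rank_markers(sub, stable_labels, config.top_markers)
    # fit PCA on all cells restricted to the stable-cluster marker union so
    # unstable cells can be projected into the same space
    embedding = _marker_pca(X, markers.union, config.n_pcs_reassign)
    centroids = np.vstack(
        [
            embedding[stable_mask][stable_labels == c].mean(axis=0)
            for c in stable_list
        ]
    )
    assigned = nearest_centroid_labels(
        embedding[unstable_cells], centroids, stable_list
    )
    final[unstable_cells] = assigned
    return final
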