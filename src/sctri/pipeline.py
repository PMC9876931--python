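"""End-to-end triangulation: stability -> importance -> winners -> pruning.

The per-cell score matrix D (annotations x metrics) only depends on the
cell's label vector across annotation sets, so importances are computed
once per unique label combination and broadcast back to cells — the number
of realized combinations is tiny compared to the number of cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .contribution import modality_contribution
from .io import AnnotationTable, FeatureMatrix
from .pruning import prune_clusters, reclassify_cells, winning_fraction
from .shapley import (
    assign_winners,
    cluster_quality,
    rank_importance,
    shapley_values,
)
from .stability import ClusterStabilityTable, compute_stability

logger = logging.getLogger("sctri")


@dataclass
class TriangulationResult:
    """Everything a triangulation run produces."""

    cell_ids: list[str]
    annotation_names: list[str]
    metrics: tuple[str, ...]
    phi: np.ndarray  # cells x annotations importance
    winner_annotation: np.ndarray
    raw_label: np.ndarray
    final_label: np.ndarray
    wf: dict[str, float]
    quality: dict[str, float]
    stable_clusters: set[str]
    stability: ClusterStabilityTable
    config: RunConfig
    contributions: pd.DataFrame | None = None
    importance_method: str = "shapley"

    @property
    def n_final_clusters(self) -> int:
        return int(pd.Series(self.final_label).nunique())


def cell_score_tensor(
    stability: ClusterStabilityTable, annotations: AnnotationTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique label combinations and their D matrices.

    Returns (combos, inverse, D) where ``combos`` is the unique label-vector
    array (n_combos x A), ``inverse`` maps each cell to its combo row and
    ``D`` is n_combos x A x M.
    """
    label_matrix = annotations.labels.to_numpy(dtype=str)
    combos, inverse = np.unique(label_matrix, axis=0, return_inverse=True)
    names = annotations.annotation_names
    metrics = stability.metrics
    D = np.empty((combos.shape[0], len(names), len(metrics)))
    for r, row in enumerate(combos):
        for a, name in enumerate(names):
            for m, metric in enumerate(metrics):
                D[r, a, m] = stability.score(name, row[a], metric)
    return combos, inverse, D


def triangulate(
    X: FeatureMatrix,
    annotations: AnnotationTable,
    config: RunConfig | None = None,
) -> TriangulationResult:
    """Run the full decision-level integration on a normalized matrix."""
    config = config or RunConfig()
    if X.is_raw_counts:
        raise ValueError("normalize the matrix before triangulation")
    if X.cell_ids != list(annotations.labels.index):
        raise ValueError("cell order of matrix and annotation table differ")

    stability = compute_stability(X, annotations, config)
    combos, inverse, D = cell_score_tensor(stability, annotations)
    n_annotations = annotations.n_annotations

    method = config.importance_method
    if method == "auto":
        method = (
            "shapley" if n_annotations <= config.shapley_max_annotations else "rank"
        )
        if method == "rank":
            logger.info(
                "falling back to rank importance for %d annotation sets",
                n_annotations,
            )
    if method == "shapley":
        phi_combo = np.vstack(
            [
                shapley_values(
                    D[r],
                    offset=config.offset,
                    adjustment=config.rank_adjustment,
                    hard_cap=config.shapley_hard_cap,
                )
                for r in range(combos.shape[0])
            ]
        )
    else:
        phi_combo = np.vstack(
            [
                rank_importance(
                    D[r], adjustment=config.rank_adjustment, offset=config.offset
                )
                for r in range(combos.shape[0])
            ]
        )
    phi = phi_combo[inverse]

    label_matrix = annotations.labels.to_numpy(dtype=str)
    sizes = annotations.cluster_sizes()
    winners, raw = assign_winners(
        phi, label_matrix, annotations.annotation_names, sizes
    )
    winner_index = np.array(
        [annotations.annotation_names.index(w) for w in winners]
    )
    wf = winning_fraction(raw, annotations)
    quality = cluster_quality(phi, winner_index, raw, n_annotations)
    stable, unstable_cells = prune_clusters(raw, wf, config)
    final = reclassify_cells(X, raw, stable, unstable_cells, config)

    contributions = None
    final_counts = pd.Series(final).value_counts()
    if len(final_counts) >= 2 and final_counts.min() >= 2:
        contributions = modality_contribution(X, final)

    logger.info(
        "triangulation finished: %d raw clusters -> %d final clusters",
        len(wf),
        int(final_counts.size),
    )
    return TriangulationResult(
        cell_ids=list(X.cell_ids),
        annotation_names=list(annotations.annotation_names),
        metrics=stability.metrics,
        phi=phi,
        winner_annotation=winners,
        raw_label=raw,
        final_label=final,
        wf=wf,
        quality=quality,
        stable_clusters=stable,
        stability=stability,
        config=config,
        contributions=contributions,
        importance_method=method,
    )
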