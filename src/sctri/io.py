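"""Readers and writers for feature matrices, label tables and result reports.

The on-disk formats are deliberately plain: Matrix Market (MTX) triplets with
feature/barcode TSV sidecars, dense CSV/TSV matrices, TSV label tables and
TSV/JSON result reports.  All loaders normalize orientation and row order so
that downstream code can assume a cells x features matrix whose rows line up
with the annotation table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("sctri")


@dataclass
class FeatureMatrix:
    """A cells x features matrix with per-feature modality tags.

    ``values`` is dense float64, oriented cells (rows) x features (columns).
    Feature ids are globally unique because each loader prefixes them with
    the modality tag (``RNA:GeneA``), which keeps concatenated multimodal
    matrices unambiguous.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    feature_modality: list[str]
    is_raw_counts: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.feature_modality = [str(m) for m in self.feature_modality]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_cells, n_feats = self.values.shape
        if n_cells < 1 or n_feats < 1:
            raise ValueError("matrix must have at least one cell and one feature")
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != number of rows {n_cells}"
            )
        if len(self.feature_ids) != n_feats:
            raise ValueError(
                f"feature_ids length {len(self.feature_ids)} != number of columns {n_feats}"
            )
        if len(self.feature_modality) != n_feats:
            raise ValueError("feature_modality must have one tag per feature")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        if len(set(self.feature_ids)) != n_feats:
            raise ValueError("feature_ids are not unique (after modality prefixing)")
        if self.is_raw_counts and (self.values < 0).any():
            raise ValueError("raw count matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def modality_of(self, feature_id: str) -> str:
        return self.feature_modality[self.feature_ids.index(feature_id)]


@dataclass
class AnnotationTable:
    """Per-cell categorical labels for each of several annotation sets.

    Rows follow the cell order of the paired :class:`FeatureMatrix`; every
    cell must carry a non-missing label in every annotation set.
    """

    labels: pd.DataFrame  # index = cell ids, one column per annotation set
    annotation_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.annotation_names:
            self.annotation_names = [str(c) for c in self.labels.columns]
        self.labels = self.labels.astype(str)
        self.labels.columns = self.annotation_names
        if self.labels.isna().any().any():
            raise ValueError("annotation table contains missing labels")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def n_annotations(self) -> int:
        return len(self.annotation_names)

    def cluster_sizes(self) -> dict[tuple[str, str], int]:
        """Original size of every (annotation, cluster label) pair."""
        sizes: dict[tuple[str, str], int] = {}
        for name in self.annotation_names:
            for label, count in self.labels[name].value_counts().items():
                sizes[(name, str(label))] = int(count)
        return sizes


def _prefix_features(feature_ids: Sequence[str], modality: str) -> list[str]:
    prefixed = [f"{modality}:{f}" for f in feature_ids]
    if len(set(prefixed)) != len(prefixed):
        dupes = pd.Index(prefixed)
        dupes = sorted(dupes[dupes.duplicated()].unique()[:5])
        raise ValueError(f"duplicate feature ids after modality prefixing: {dupes}")
    return prefixed


def _read_id_file(path: Path) -> list[str]:
    table = pd.read_csv(path, sep="\t", header=None)
    return [str(v) for v in table.iloc[:, 0]]


def load_feature_matrix(
    path: str | Path,
    format: str = "mtx",
    modality: str = "RNA",
    is_raw_counts: bool = True,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> FeatureMatrix:
    """Load a cell x feature matrix from MTX triplet or dense CSV/TSV.

    MTX matrices are accepted in either orientation (cells x features or
    features x cells); the orientation is detected from the lengths of the
    feature/barcode sidecar files.  Dense CSV/TSV files are read as cells in
    rows (header row = feature ids, first column = cell ids).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        folder = path.parent
        if features_path is None:
            candidates = [folder / n for n in ("features.tsv", "genes.tsv")]
            features_path = next((c for c in candidates if c.exists()), None)
            if features_path is None:
                raise FileNotFoundError(f"no features.tsv/genes.tsv next to {path}")
        if barcodes_path is None:
            barcodes_path = folder / "barcodes.tsv"
            if not Path(barcodes_path).exists():
                raise FileNotFoundError(f"no barcodes.tsv next to {path}")
        feats = _read_id_file(Path(features_path))
        cells = _read_id_file(Path(barcodes_path))
        if mat.shape == (len(feats), len(cells)) and mat.shape != (len(cells), len(feats)):
            mat = mat.T  # stored features x cells
        if mat.shape != (len(cells), len(feats)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither (cells={len(cells)}, "
                f"features={len(feats)}) orientation"
            )
    elif format in ("csv", "tsv"):
        sep = "\t" if format == "tsv" or path.suffix.lower() in (".tsv", ".txt") else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        mat = frame.to_numpy(dtype=float)
        cells = [str(i) for i in frame.index]
        feats = [str(c) for c in frame.columns]
    else:
        raise ValueError(f"unknown matrix format: {format!r}")
    return FeatureMatrix(
        values=mat,
        cell_ids=cells,
        feature_ids=_prefix_features(feats, modality),
        feature_modality=[modality] * len(feats),
        is_raw_counts=is_raw_counts,
    )


def load_annotations(path: str | Path, cell_ids: Sequence[str]) -> AnnotationTable:
    """Load a cell x annotation label table and align it to ``cell_ids``.

    The file must contain a cell-id column (first column, or one named
    ``cell``/``cell_id``/``barcode``); remaining columns each become one
    annotation set.  Rows may appear in any order on disk.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    id_col = next(
        (c for c in table.columns if c.lower() in ("cell", "cell_id", "barcode")),
        table.columns[0],
    )
    table = table.set_index(id_col)
    if table.shape[1] == 0:
        raise ValueError("annotation table has no annotation columns")
    missing = [c for c in cell_ids if c not in table.index]
    if missing:
        raise ValueError(f"cells absent from annotation file: {missing[:5]}")
    table = table.loc[list(cell_ids)]
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing labels in annotation column(s): {bad}")
    for col in table.columns:
        if table[col].nunique() == 0:
            raise ValueError(f"empty annotation column: {col}")
    return AnnotationTable(labels=table)


def write_results(result, outdir: str | Path) -> dict[str, Path]:
    """Write per-cell and per-cluster reports plus a JSON run manifest.

    Emits ``cell_results.tsv`` (winner annotation, raw and final labels, one
    Shapley/importance column per annotation), ``cluster_results.tsv``
    (winning fraction, size, quality per raw winner cluster) and
    ``manifest.json`` (configuration, seed, package version).
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cell = pd.DataFrame(
        {
            "cell_id": result.cell_ids,
            "winner_annotation": result.winner_annotation,
            "raw_label": result.raw_label,
            "final_label": result.final_label,
        }
    )
    phi = pd.DataFrame(
        result.phi, columns=[f"importance_{a}" for a in result.annotation_names]
    )
    cell = pd.concat([cell, phi], axis=1)
    cell_path = outdir / "cell_results.tsv"
    cell.to_csv(cell_path, sep="\t", index=False, float_format="%.17g")

    raw = pd.Series(result.raw_label)
    rows = []
    for cluster, size in raw.value_counts().items():
        rows.append(
            {
                "raw_cluster": cluster,
                "size": int(size),
                "winning_fraction": result.wf[cluster],
                "quality": result.quality[cluster],
                "stable": cluster in result.stable_clusters,
            }
        )
    cluster_path = outdir / "cluster_results.tsv"
    pd.DataFrame(rows).to_csv(cluster_path, sep="\t", index=False, float_format="%.17g")

    manifest = {
        "package": "sctri",
        "version": __version__,
        "config": result.config.to_dict(),
        "seed": result.config.random_seed,
        "n_cells": len(result.cell_ids),
        "annotations": list(result.annotation_names),
        "metrics": list(result.metrics),
        "n_final_clusters": int(pd.Series(result.final_label).nunique()),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    if result.contributions is not None:
        contrib_path = outdir / "modality_contributions.tsv"
        result.contributions.to_csv(contrib_path, sep="\t", index=False)

    logger.info("results written to %s", outdir)
    return {"cells": cell_path, "clusters": cluster_path, "manifest": manifest_path}
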