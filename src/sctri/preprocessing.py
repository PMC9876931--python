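"""Normalization and multimodal concatenation.

Count-based modalities (RNA, ATAC peaks) are put on a log counts-per-ten-
thousand scale; antibody-derived tags (ADT) use the centered log-ratio (CLR)
across features within each cell.  Once each block is normalized, blocks are
concatenated feature-wise into a single matrix so every stability metric can
see all modalities jointly.
"""

from __future__ import annotations

import numpy as np

from .io import FeatureMatrix


def normalize_cptt(counts: FeatureMatrix, scale: float = 10_000.0) -> FeatureMatrix:
    """Log counts-per-ten-thousand: ``ln(1 + scale * c_if / sum_f c_if)``.

    Depth-invariant within each cell; an all-zero feature stays exactly 0.
    """
    if not counts.is_raw_counts:
        raise ValueError("normalize_cptt expects a raw count matrix")
    totals = counts.values.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = [counts.cell_ids[i] for i in np.flatnonzero(zero)[:10]]
        raise ValueError(f"cells with zero total count: {bad}")
    values = np.log1p(scale * counts.values / totals[:, None])
    return FeatureMatrix(
        values=values,
        cell_ids=list(counts.cell_ids),
        feature_ids=list(counts.feature_ids),
        feature_modality=list(counts.feature_modality),
        is_raw_counts=False,
    )


def normalize_clr(adt: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """Centered log-ratio per cell: ``y_f = ln(x_f + 1) - mean_f ln(x_f + 1)``.

    Rows are exactly centered, so a constant multiplicative shift of a cell's
    log counts changes nothing.
    """
    if (adt.values < 0).any():
        raise ValueError("CLR normalization requires non-negative values")
    if adt.n_features < 1:
        raise ValueError("cell with zero features")
    logged = np.log(adt.values + pseudocount)
    values = logged - logged.mean(axis=1, keepdims=True)
    return FeatureMatrix(
        values=values,
        cell_ids=list(adt.cell_ids),
        feature_ids=list(adt.feature_ids),
        feature_modality=list(adt.feature_modality),
        is_raw_counts=False,
    )


def concat_modalities(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack normalized modality blocks feature-wise into one matrix.

    All blocks must cover the same cells; blocks whose rows are ordered
    differently are reordered to the first block's cell order.
    """
    if not blocks:
        raise ValueError("no blocks to concatenate")
    first = blocks[0]
    aligned = [first.values]
    for block in blocks[1:]:
        if set(block.cell_ids) != set(first.cell_ids):
            raise ValueError("cell sets differ between modality blocks")
        if block.cell_ids == first.cell_ids:
            aligned.append(block.values)
        else:
            order = [block.cell_ids.index(c) for c in first.cell_ids]
            aligned.append(block.values[order])
    if any(b.is_raw_counts for b in blocks):
        raise ValueError("normalize blocks before concatenation")
    return FeatureMatrix(
        values=np.concatenate(aligned, axis=1),
        cell_ids=list(first.cell_ids),
        feature_ids=[f for b in blocks for f in b.feature_ids],
        feature_modality=[m for b in blocks for m in b.feature_modality],
        is_raw_counts=False,
    )
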