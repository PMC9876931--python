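"""Modality contribution: which modality's features drive each final cluster.

Each final cluster's top-20 markers (combined t-test / fold-change rank)
are weighted by list position — the top-1 marker counts 20, position k
counts 21-k — and the weights are summed per modality.  With at least 20
features the per-cluster contributions always partition 210.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FeatureMatrix
from .stability import rank_markers

TOP_N = 20


def modality_contribution(
    X: FeatureMatrix, final_labels: np.ndarray, top_n: int = TOP_N
) -> pd.DataFrame:
    """Rank-weighted modality membership of each cluster's top markers.

    Returns a long-format frame (cluster, modality, contribution) covering
    every modality present in the matrix, plus the positional marker lists
    in the ``marker``/``position``/``weight`` columns of the companion
    frame attached as ``.attrs['markers']``.
    """
    final_labels = np.asarray(final_labels, dtype=str)
    markers = rank_markers(X, final_labels, top_markers=top_n)
    modality_by_feature = dict(zip(X.feature_ids, X.feature_modality))
    modalities = sorted(set(X.feature_modality))
    rows = []
    marker_rows = []
    for cluster, frame in markers.per_cluster.items():
        contrib = {m: 0 for m in modalities}
        for pos, feature in enumerate(frame["feature"], start=1):
            weight = top_n + 1 - pos
            contrib[modality_by_feature[feature]] += weight
            marker_rows.append(
                {
                    "cluster": cluster,
                    "position": pos,
                    "marker": feature,
                    "modality": modality_by_feature[feature],
                    "weight": weight,
                }
            )
        for m in modalities:
            rows.append(
                {"cluster": cluster, "modality": m, "contribution": contrib[m]}
            )
    result = pd.DataFrame(rows)
    result.attrs["markers"] = pd.DataFrame(marker_rows)
    return result
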