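"""Entropy-based agreement between a predicted and a reference labeling.

Homogeneity (each predicted cluster contains one reference class),
completeness (each reference class lands in one predicted cluster) and
their harmonic mean (V-measure) are computed from the class x cluster
contingency table with natural-log entropies.  All three are invariant to
label renaming and lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Contingency:
    """Class x cluster contingency table with its marginals."""

    n: int
    n_c: np.ndarray  # per reference class
    n_k: np.ndarray  # per predicted cluster
    n_ck: np.ndarray  # class x cluster counts

    @classmethod
    def from_labels(cls, reference, prediction) -> "Contingency":
        reference = np.asarray(reference)
        prediction = np.asarray(prediction)
        if reference.shape != prediction.shape:
            raise ValueError("reference and prediction must have equal length")
        table = pd.crosstab(pd.Series(reference), pd.Series(prediction)).to_numpy()
        return cls(
            n=int(table.sum()),
            n_c=table.sum(axis=1),
            n_k=table.sum(axis=0),
            n_ck=table,
        )


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _conditional_entropy(n_ck: np.ndarray, n_given: np.ndarray, n: int) -> float:
    """H(rows | columns): -sum_ck n_ck/n * log(n_ck / n_k)."""
    total = 0.0
    for k in range(n_ck.shape[1]):
        col = n_ck[:, k]
        nz = col[col > 0]
        total -= float((nz / n * np.log(nz / n_given[k])).sum())
    return total


def homogeneity(reference, prediction) -> float:
    """1 - H(C|K)/H(C); 1 when the reference has zero entropy."""
    t = Contingency.from_labels(reference, prediction)
    h_c = _entropy(t.n_c, t.n)
    if h_c == 0.0:
        return 1.0
    h_c_given_k = _conditional_entropy(t.n_ck, t.n_k, t.n)
    return 1.0 - h_c_given_k / h_c


def completeness(reference, prediction) -> float:
    """1 - H(K|C)/H(K); 1 when the prediction has zero entropy."""
    t = Contingency.from_labels(reference, prediction)
    h_k = _entropy(t.n_k, t.n)
    if h_k == 0.0:
        return 1.0
    h_k_given_c = _conditional_entropy(t.n_ck.T, t.n_c, t.n)
    return 1.0 - h_k_given_c / h_k


def v_measure(reference, prediction) -> float:
    """Harmonic mean of homogeneity and completeness (0 when both are 0)."""
    h = homogeneity(reference, prediction)
    c = completeness(reference, prediction)
    if h + c == 0.0:
        return 0.0
    return 2.0 * h * c / (h + c)


def evaluate(reference, prediction) -> dict:
    """All three agreement metrics plus cluster counts, as a plain dict."""
    return {
        "homogeneity": homogeneity(reference, prediction),
        "completeness": completeness(reference, prediction),
        "v_measure": v_measure(reference, prediction),
        "n_clusters_pred": int(pd.Series(np.asarray(prediction)).nunique()),
        "n_clusters_truth": int(pd.Series(np.asarray(reference)).nunique()),
    }
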