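"""Group-structured count simulation and conflicting-annotation construction.

The count generator follows the Splat model family: gene base means drawn
from a Gamma distribution, per-group differential-expression factors drawn
log-normally (half inverted, i.e. down-regulated), log-normal library
sizes, and Gamma-Poisson (negative binomial) sampling around the expected
counts with a mean-trended biological coefficient of variation.  On top of the
ground-truth grouping, merge/split recipes build deliberately under- and
over-clustered annotation sets (Broad / Median / Fine / Excessive) so that
no single input matches the truth — the integration task the triangulation
engine is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotationTable, FeatureMatrix


@dataclass
class SimParams:
    """Generator parameters (Splat-style defaults).

    ``mean_shape``/``mean_rate`` parameterize the Gamma of gene base means;
    ``de_prob[g]`` is the fraction of genes differentially expressed in
    group ``g`` with log-normal factors LogN(``de_fac_loc``,
    ``de_fac_scale``); library sizes are LogN(``lib_loc``, ``lib_scale``)
    reads per cell; ``bcv_common``/``bcv_df`` set the asymptote and the
    per-gene inflation of the biological coefficient of variation.
    """

    batch_cells: int = 3000
    n_genes: int = 2000
    group_prob: tuple[float, ...] = (0.23, 0.15, 0.15, 0.23, 0.24)
    de_prob: tuple[float, ...] = (0.15, 0.15, 0.15, 0.2, 0.4)
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.4
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    bcv_common: float = 0.1
    bcv_df: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.group_prob, dtype=float)
        if probs.ndim != 1 or probs.size < 1 or (probs < 0).any():
            raise ValueError("group_prob must be a non-negative vector")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("group_prob must sum to 1")
        de = np.asarray(self.de_prob, dtype=float)
        if de.shape != probs.shape:
            raise ValueError("de_prob must have one entry per group")
        if ((de < 0) | (de > 1)).any():
            raise ValueError("de_prob entries must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, for parameter-recovery tests."""

    group_labels: np.ndarray  # per cell, 'c1'..'cG'
    de_genes: pd.DataFrame  # genes x groups boolean indicator
    de_factors: pd.DataFrame  # genes x groups multiplicative factor
    params: SimParams = field(repr=False, default=None)


def simulate_counts(params: SimParams) -> tuple[FeatureMatrix, SimulationTruth]:
    """Draw a raw count matrix with group structure.

    Per group, each gene is differentially expressed with probability
    ``de_prob[g]``; its base mean is multiplied by a log-normal factor
    (inverted with probability 0.5).  A cell's expected counts are its
    library size times the normalized mean profile of its group; observed
    counts are Gamma-Poisson around that expectation with a biological CV
    of ``bcv_common + 1/sqrt(mean)``, inflated per gene by an
    inverse-chi-square factor at ``bcv_df`` degrees of freedom.
    """
    rng = np.random.default_rng(params.seed)
    n_cells, n_genes = params.batch_cells, params.n_genes
    n_groups = len(params.group_prob)
    group_names = [f"c{g + 1}" for g in range(n_groups)]

    base_means = rng.gamma(shape=params.mean_shape, scale=1.0 / params.mean_rate,
                           size=n_genes)
    de_indicator = np.zeros((n_genes, n_groups), dtype=bool)
    de_factors = np.ones((n_genes, n_groups))
    for g in range(n_groups):
        is_de = rng.random(n_genes) < params.de_prob[g]
        factors = rng.lognormal(params.de_fac_loc, params.de_fac_scale, size=n_genes)
        invert = rng.random(n_genes) < 0.5
        factors = np.where(invert, 1.0 / factors, factors)
        de_indicator[:, g] = is_de
        de_factors[:, g] = np.where(is_de, factors, 1.0)

    group_means = base_means[:, None] * de_factors  # genes x groups
    group_props = group_means / group_means.sum(axis=0, keepdims=True)

    labels_idx = rng.choice(n_groups, size=n_cells, p=params.group_prob)
    lib_sizes = rng.lognormal(params.lib_loc, params.lib_scale, size=n_cells)

    expected = lib_sizes[:, None] * group_props[:, labels_idx].T  # cells x genes
    if params.bcv_common > 0:
        # biological CV trends upward for weakly expressed genes
        # (bcv_common + 1/sqrt(mean)), with a per-gene inverse-chi-square
        # inflation at bcv_df degrees of freedom
        with np.errstate(divide="ignore"):
            bcv = params.bcv_common + 1.0 / np.sqrt(expected)
        if np.isfinite(params.bcv_df) and params.bcv_df > 0:
            chi2 = rng.chisquare(params.bcv_df, size=n_genes)
            bcv = bcv * np.sqrt(params.bcv_df / chi2)[None, :]
        disp = bcv**2
        positive = expected > 0
        noisy = np.zeros_like(expected)
        noisy[positive] = rng.gamma(
            shape=1.0 / disp[positive], scale=expected[positive] * disp[positive]
        )
    else:
        noisy = expected
    counts = rng.poisson(noisy).astype(float)

    matrix = FeatureMatrix(
        values=counts,
        cell_ids=[f"cell_{i + 1}" for i in range(n_cells)],
        feature_ids=[f"RNA:gene_{j + 1}" for j in range(n_genes)],
        feature_modality=["RNA"] * n_genes,
        is_raw_counts=True,
    )
    truth = SimulationTruth(
        group_labels=np.asarray([group_names[g] for g in labels_idx], dtype=object),
        de_genes=pd.DataFrame(
            de_indicator, index=matrix.feature_ids, columns=group_names
        ),
        de_factors=pd.DataFrame(
            de_factors, index=matrix.feature_ids, columns=group_names
        ),
        params=params,
    )
    return matrix, truth


def _apply_recipe(
    labels: np.ndarray, recipe: list[tuple], rng: np.random.Generator
) -> np.ndarray:
    """Apply ordered merge/split operations to a copy of the labels.

    Operations: ``("merge", [groups...])`` relabels the listed groups to one
    joint label; ``("split", group)`` partitions the group's cells uniformly
    at random into two sub-labels of (near-)equal size.
    """
    out = np.asarray(labels, dtype=object).copy()
    known = set(out)
    for op in recipe:
        kind = op[0]
        if kind == "merge":
            groups = list(op[1])
            missing = [g for g in groups if g not in known]
            if missing:
                raise ValueError(f"recipe references unknown group(s): {missing}")
            joint = "+".join(groups)
            out[np.isin(out, groups)] = joint
            known = set(out)
        elif kind == "split":
            group = op[1]
            if group not in known:
                raise ValueError(f"recipe references unknown group: {group}")
            members = np.flatnonzero(out == group)
            perm = rng.permutation(members)
            half = len(perm) // 2
            out[perm[:half]] = f"{group}_s1"
            out[perm[half:]] = f"{group}_s2"
            known = set(out)
        else:
            raise ValueError(f"unknown recipe operation: {kind!r}")
    return out


def perturb_annotations(
    truth_labels: np.ndarray,
    recipes: dict[str, list[tuple]],
    cell_ids: list[str],
    seed: int = 0,
) -> AnnotationTable:
    """Build one annotation set per recipe from the ground-truth labels."""
    rng = np.random.default_rng(seed)
    columns = {}
    for name, recipe in recipes.items():
        columns[name] = _apply_recipe(truth_labels, recipe, rng)
    frame = pd.DataFrame(columns, index=list(cell_ids))
    return AnnotationTable(labels=frame)


EXPERIMENT1 = SimParams(
    batch_cells=3000,
    group_prob=(0.23, 0.15, 0.15, 0.23, 0.24),
    de_prob=(0.15, 0.15, 0.15, 0.2, 0.4),
)
# Six groups where c3-c6 differ only subtly (0.5% of genes differentially
# expressed): the regime where a second, more permissive TF-IDF order is
# needed to keep the subtle groups apart.
EXPERIMENT2 = SimParams(
    batch_cells=3000,
    group_prob=(0.2, 0.2, 0.15, 0.15, 0.15, 0.15),
    de_prob=(0.2, 0.2, 0.005, 0.005, 0.005, 0.005),
)

RECIPES = {
    "experiment1": {
        "Broad": [("merge", ["c1", "c2", "c3"])],
        "Median": [("merge", ["c2", "c3"])],
        "Fine": [("split", "c5")],
        "Excessive": [("split", "c2"), ("split", "c3")],
    },
    "experiment2": {
        "Broad": [("merge", ["c3", "c4", "c5", "c6"])],
        "Median": [("merge", ["c3", "c4"]), ("merge", ["c5", "c6"])],
        "Fine": [],
    },
}


def make_fixture(
    name: str, seed: int = 0, n_genes: int = 2000
) -> tuple[FeatureMatrix, AnnotationTable, SimulationTruth]:
    """Simulate one of the two benchmark scenarios with its annotations.

    ``experiment1``: 3000 cells, 5 groups, four conflicting annotations
    (Broad/Median/Fine/Excessive), none matching the truth.
    ``experiment2``: 3000 cells, 6 groups with four subtly distinct ones,
    three annotations (Broad/Median/Fine), Fine matching the truth.
    """
    if name not in RECIPES:
        raise ValueError(f"unknown fixture: {name!r} (use experiment1/experiment2)")
    params = replace(
        EXPERIMENT1 if name == "experiment1" else EXPERIMENT2,
        seed=seed,
        n_genes=n_genes,
    )
    matrix, truth = simulate_counts(params)
    annotations = perturb_annotations(
        truth.group_labels, RECIPES[name], matrix.cell_ids, seed=seed + 1
    )
    return matrix, annotations, truth
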