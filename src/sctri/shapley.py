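"""Coalition-game importance of annotation sets and winner assignment.

Every annotation set is a player; a cell's score row across stability
metrics is that player's performance.  A coalition's value rewards players
that top-rank the coalition per metric (with an additive tolerance, so
near-ties share the top rank).  The Shapley value averages each player's
marginal surplus over all coalitions, giving a principled per-cell
importance; a pure full-coalition rank is available as a cheap fallback
when the player count makes exact enumeration intractable.
"""

from __future__ import annotations

import logging
from math import factorial

import numpy as np

logger = logging.getLogger("sctri")


def _rank_with_offset(x: float, others: np.ndarray) -> int:
    """Ascending rank of ``x`` among ``others`` plus itself, ties sharing the
    maximal rank: 1 + number of other scores <= x."""
    return 1 + int(np.count_nonzero(others <= x))


def coalition_surplus(
    D_i: np.ndarray,
    a: int,
    T: tuple[int, ...],
    offset: float = 0.01,
    adjustment: str = "all_or_none",
) -> float:
    """Marginal value of adding player ``a`` to coalition ``T``.

    Per metric, players in ``T | {a}`` are ranked ascending by score with
    ties sharing the maximal rank; the focal player's score is lifted by
    ``offset`` before ranking, so a player within ``offset`` of the leader
    still attains the top rank.  Under ``all_or_none`` the coalition size is
    credited only when the focal player is top; under ``classic`` the focal
    player's rank is credited for every metric.
    """
    D_i = np.asarray(D_i, dtype=float)
    if a in T:
        raise ValueError("focal player must not be in the coalition")
    size = len(T) + 1
    others = D_i[list(T), :] if T else np.empty((0, D_i.shape[1]))
    v = 0.0
    for m in range(D_i.shape[1]):
        rank = _rank_with_offset(D_i[a, m] + offset, others[:, m])
        if adjustment == "all_or_none":
            if rank == size:
                v += size
        elif adjustment == "classic":
            v += rank
        else:
            raise ValueError(f"unknown rank adjustment: {adjustment!r}")
    return v


def shapley_values(
    D_i: np.ndarray,
    offset: float = 0.01,
    adjustment: str = "all_or_none",
    hard_cap: int = 20,
) -> np.ndarray:
    """Exact Shapley value of every player by subset enumeration.

    Phi_a = sum over coalitions T not containing a of
    |T|! (A-|T|-1)! / A!  times the marginal surplus of a joining T.
    Enumeration is exponential in the player count; beyond ``hard_cap``
    players callers should use :func:`rank_importance` instead.
    """
    D_i = np.asarray(D_i, dtype=float)
    n_players = D_i.shape[0]
    if n_players > hard_cap:
        raise ValueError(
            f"{n_players} players exceed the exact-enumeration cap ({hard_cap}); "
            "use rank_importance"
        )
    fact = [factorial(k) for k in range(n_players + 1)]
    weights = [
        fact[t] * fact[n_players - t - 1] / fact[n_players]
        for t in range(n_players)
    ]
    phi = np.zeros(n_players)
    players = range(n_players)
    for a in players:
        rest = [p for p in players if p != a]
        for mask in range(1 << len(rest)):
            T = tuple(rest[j] for j in range(len(rest)) if mask >> j & 1)
            phi[a] += weights[len(T)] * coalition_surplus(
                D_i, a, T, offset=offset, adjustment=adjustment
            )
    return phi


def rank_importance(
    D_i: np.ndarray,
    adjustment: str = "all_or_none",
    offset: float = 0.01,
) -> np.ndarray:
    """Full-coalition rank importance (no coalitional iteration).

    Per metric each player is ranked among all players with offset-tolerant
    ties; ``classic`` sums the ranks, ``all_or_none`` zeroes non-top ranks
    first.
    """
    D_i = np.asarray(D_i, dtype=float)
    n_players, n_metrics = D_i.shape
    importance = np.zeros(n_players)
    for m in range(n_metrics):
        col = D_i[:, m]
        for a in range(n_players):
            others = np.delete(col, a)
            rank = _rank_with_offset(col[a] + offset, others)
            if adjustment == "all_or_none":
                if rank == n_players:
                    importance[a] += rank
            elif adjustment == "classic":
                importance[a] += rank
            else:
                raise ValueError(f"unknown rank adjustment: {adjustment!r}")
    return importance


def assign_winners(
    phi: np.ndarray,
    label_matrix: np.ndarray,
    annotation_names: list[str],
    cluster_sizes: dict[tuple[str, str], int],
    tie_tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell argmax of importance, with deterministic tie-breaking.

    Ties (importances within ``tie_tol`` of the maximum) are resolved in
    favor of the annotation whose originating cluster is smallest — the more
    specific population — then lexicographically by annotation name.
    Returns (winner annotation, raw label ``annotation@cluster``) per cell.
    """
    phi = np.asarray(phi, dtype=float)
    n_cells, n_players = phi.shape
    winners = np.empty(n_cells, dtype=object)
    raw = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        row = phi[i]
        top = row.max()
        tied = np.flatnonzero(row >= top - tie_tol)
        if tied.size == 1:
            a = int(tied[0])
        else:
            keyed = sorted(
                (
                    cluster_sizes[(annotation_names[a], str(label_matrix[i, a]))],
                    annotation_names[a],
                    a,
                )
                for a in tied
            )
            a = keyed[0][2]
        winners[i] = annotation_names[a]
        raw[i] = f"{annotation_names[a]}@{label_matrix[i, a]}"
    return winners, raw


def cluster_quality(
    phi: np.ndarray,
    winner_index: np.ndarray,
    raw_labels: np.ndarray,
    n_players: int,
) -> dict[str, float]:
    """Elo-like quality: mean winner importance per cluster, normalized by
    the number of players and the number of clusters."""
    raw_labels = np.asarray(raw_labels, dtype=object)
    clusters = sorted(set(raw_labels))
    n_clusters = len(clusters)
    winner_phi = phi[np.arange(len(raw_labels)), winner_index]
    quality = {}
    for c in clusters:
        mask = raw_labels == c
        quality[c] = float(winner_phi[mask].mean() / n_players / n_clusters)
    return quality
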