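"""Run configuration, logging and random-seed plumbing."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("sctri")


@dataclass
class RunConfig:
    """All tunables of a triangulation run.

    offset
        Additive tolerance when ranking stability scores inside a coalition;
        scores within ``offset`` of the leader share the top rank.  Stability
        scores live on a 0-2 scale, so the default of 0.01 treats differences
        below one percent of that scale as noise.
    win_fraction_cutoff, abs_thresh
        Pruning thresholds: a raw winner cluster is unstable when it retains
        less than ``win_fraction_cutoff`` of its originating cluster's cells
        or fewer than ``abs_thresh`` cells in total.
    tfidf_orders
        Which nth-ranked exclusivity scores to compute (10 by default; add 5
        to promote clusters with few exclusive markers).
    rank_adjustment
        ``all_or_none`` zeroes every non-top rank per metric (winner takes
        all); ``classic`` keeps the full rank vector.
    importance_method
        ``shapley`` enumerates all coalitions exactly; ``rank`` scores the
        full coalition only.  ``auto`` uses Shapley up to
        ``shapley_max_annotations`` players and falls back to rank beyond.
    """

    offset: float = 0.01
    win_fraction_cutoff: float = 0.25
    abs_thresh: int = 10
    top_markers: int = 30
    tfidf_orders: tuple[int, ...] = (10,)
    n_pcs_reassign: int = 30
    rank_adjustment: str = "all_or_none"
    importance_method: str = "auto"
    shapley_max_annotations: int = 15
    shapley_hard_cap: int = 20
    sccaf_variant: str = "row_recall"
    sccaf_folds: int = 5
    clr_pseudocount: float = 1.0
    random_seed: int = 0
    metrics: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if not 0 <= self.win_fraction_cutoff <= 1:
            raise ValueError("win_fraction_cutoff must be in [0, 1]")
        if self.abs_thresh < 0:
            raise ValueError("abs_thresh must be >= 0")
        if self.rank_adjustment not in ("classic", "all_or_none"):
            raise ValueError("rank_adjustment must be 'classic' or 'all_or_none'")
        if self.importance_method not in ("shapley", "rank", "auto"):
            raise ValueError("importance_method must be 'shapley', 'rank' or 'auto'")
        if self.sccaf_variant not in ("row_recall", "trace"):
            raise ValueError("sccaf_variant must be 'row_recall' or 'trace'")
        orders = tuple(sorted(set(int(n) for n in self.tfidf_orders), reverse=True))
        if any(n < 1 for n in orders):
            raise ValueError("tfidf orders must be >= 1")
        object.__setattr__(self, "tfidf_orders", orders)
        metrics = ["reassign"] + [f"tfidf{n}" for n in orders] + ["sccaf"]
        object.__setattr__(self, "metrics", tuple(metrics))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.random_seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tfidf_orders"] = list(self.tfidf_orders)
        d["metrics"] = list(self.metrics)
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        mapping = dict(mapping)
        mapping.pop("metrics", None)
        if "tfidf_orders" in mapping:
            mapping["tfidf_orders"] = tuple(mapping["tfidf_orders"])
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def setup_logging(level: int = logging.INFO) -> logging.Logger:
    """Attach a stream handler to the package logger (idempotent)."""
    log = logging.getLogger("sctri")
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s [%(name)s] %(levelname)s: %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level)
    return log
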