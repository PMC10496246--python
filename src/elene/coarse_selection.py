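"""Coarse feature selection: rank the 26 catalog subsets by CV accuracy on
three classification tasks and pool the top five of each."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._svm import cv_accuracy, make_folds
from .errors import FoldError
from .feature_catalog import catalog
from .io_preprocess import LABELS

#: The three evaluation tasks: label mapping applied to the 3-class truth.
TASKS = {
    # metastatic-or-not; ENE nodes are pathologically metastatic
    "met-vs-normal": {"normal": 0, "metastatic": 1, "ENE": 1},
    "ene-vs-rest": {"normal": 0, "metastatic": 0, "ENE": 1},
    "three-class": {"normal": 0, "metastatic": 1, "ENE": 2},
}

#: Small C x gamma grid for the coarse step (best of 9 per subset/task).
COARSE_C = (1.0, 32.0, 1024.0)
COARSE_GAMMA = (2.0 ** -7, 2.0 ** -3, 2.0)


@dataclass
class SubsetRanking:
    """Per-task ordered (subset, accuracy) lists and the pooled union."""

    rankings: dict[str, list[tuple[str, float]]]
    top_subsets: dict[str, list[str]]
    pool_subsets: list[str]
    pool_features: list[str]
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "rankings": self.rankings,
            "top_subsets": self.top_subsets,
            "pool_subsets": self.pool_subsets,
            "pool_features": self.pool_features,
            "seed": self.seed,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubsetRanking":
        d = json.loads(text)
        rankings = {t: [(n, a) for n, a in v] for t, v in d["rankings"].items()}
        return cls(rankings, d["top_subsets"], d["pool_subsets"],
                   d["pool_features"], d["seed"])


def evaluate_subsets(table: pd.DataFrame, n_folds: int = 10, seed: int = 0,
                     top_k: int = 5) -> SubsetRanking:
    """Rank every catalog subset on every task by stratified CV accuracy.

    Each subset is scored with an RBF SVM (best of a small fixed C x gamma
    grid, z-scored per training fold); the pool is the union of the top
    ``top_k`` subsets across the three tasks, in catalog order.
    """
    cat = catalog()
    labels = table["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise FoldError("need at least 2 classes to rank subsets")

    rankings: dict[str, list[tuple[str, float]]] = {}
    tops: dict[str, list[str]] = {}
    for task, mapping in TASKS.items():
        y = np.array([mapping[l] for l in labels])
        folds = make_folds(y, n_folds, seed)
        scored = []
        for sub in cat.subsets:
            cols = [c for c in sub.features if c in table.columns]
            if not cols:
                continue
            X = table[cols].to_numpy(dtype=np.float64)
            acc = max(cv_accuracy(X, y, folds, C, g)
                      for C in COARSE_C for g in COARSE_GAMMA)
            scored.append((sub.name, float(acc)))
        # stable order: accuracy descending, catalog order on ties
        order = {s.name: i for i, s in enumerate(cat.subsets)}
        scored.sort(key=lambda t: (-t[1], order[t[0]]))
        rankings[task] = scored
        tops[task] = [name for name, _ in scored[:top_k]]

    pool_names = {n for names in tops.values() for n in names}
    pool_subsets = [s.name for s in cat.subsets if s.name in pool_names]
    pool_features = list(cat.subset_union(pool_subsets))
    return SubsetRanking(rankings, tops, pool_subsets, pool_features, seed)
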