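"""Voting ensemble of independently optimized SVM members.

Each of the 31 members is one optimizer run (consecutive seeds) retrained
on the full training table with its selected features and (C, gamma).
Prediction is by plurality vote; ties fall back to summed per-class SVM
confidence, then to severity order ENE > metastatic > normal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import SchemaError
from .ibcga_optimizer import IBCGAConfig, run

log = logging.getLogger(__name__)

N_MEMBERS = 31
SEVERITY = ("ENE", "metastatic", "normal")  # tie-break order, worst first

SCHEMA_VERSION = 1


@dataclass
class Member:
    """One trained SVM with its feature subset and training data.

    The raw (unscaled) training matrix is stored so the member can be
    refit deterministically after JSON round-trips.
    """

    features: tuple[str, ...]
    C: float
    gamma: float
    fitness: float
    seed: int
    X_train: np.ndarray
    y_train: np.ndarray  # string labels
    _clf: Optional[SVC] = field(default=None, repr=False, compare=False)
    _mu: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _sd: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def _fit(self) -> None:
        X = np.asarray(self.X_train, dtype=np.float64)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        self._clf = SVC(C=self.C, gamma=self.gamma, kernel="rbf",
                        decision_function_shape="ovr")
        self._clf.fit((X - self._mu) / sd, self.y_train)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._clf is None:
            self._fit()
        return self._clf.predict((X - self._mu) / self._sd)

    def class_scores(self, X: np.ndarray) -> pd.DataFrame:
        """Per-class one-vs-rest decision values, columns = class labels."""
        if self._clf is None:
            self._fit()
        df = self._clf.decision_function((X - self._mu) / self._sd)
        if df.ndim == 1:  # binary: signed distance to the second class
            df = np.column_stack([-df, df])
        return pd.DataFrame(df, columns=self._clf.classes_)


@dataclass
class EnsembleModel:
    members: list[Member]
    pool: tuple[str, ...]
    classes: tuple[str, ...]
    metadata: dict

    def __post_init__(self) -> None:
        for m in self.members:
            if not set(m.features) <= set(self.pool):
                raise SchemaError("member features must lie in the candidate pool")

    def selection_frequency(self) -> pd.Series:
        """How many members selected each pool feature (Table-3 analogue)."""
        counts = {f: 0 for f in self.pool}
        for m in self.members:
            for f in m.features:
                counts[f] += 1
        return pd.Series(counts).sort_values(ascending=False)

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": SCHEMA_VERSION,
            "pool": list(self.pool),
            "classes": list(self.classes),
            "metadata": self.metadata,
            "members": [{
                "features": list(m.features), "C": m.C, "gamma": m.gamma,
                "fitness": m.fitness, "seed": m.seed,
                "X_train": np.asarray(m.X_train).tolist(),
                "y_train": np.asarray(m.y_train).tolist(),
            } for m in self.members],
        })

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        d = json.loads(text)
        members = [Member(tuple(m["features"]), m["C"], m["gamma"],
                          m["fitness"], m["seed"],
                          np.asarray(m["X_train"], dtype=np.float64),
                          np.asarray(m["y_train"]))
                   for m in d["members"]]
        return cls(members, tuple(d["pool"]), tuple(d["classes"]),
                   d["metadata"])


@dataclass
class Prediction:
    node_id: str
    votes: dict[str, int]
    final: str
    tie_broken: bool
    ene_score: float
    met_score: float


def train_ensemble(table: pd.DataFrame, pool: list[str], cfg: IBCGAConfig,
                   n_members: int = N_MEMBERS) -> EnsembleModel:
    """Train ``n_members`` optimizer runs with seeds cfg.seed + 0..n-1."""
    classes = tuple(sorted(table["label"].unique()))
    members = []
    for k in range(n_members):
        res = run(IBCGAConfig(**{**cfg.__dict__, "seed": cfg.seed + k}),
                  table, pool)
        members.append(Member(
            features=res.feature_names, C=res.C, gamma=res.gamma,
            fitness=res.fitness, seed=cfg.seed + k,
            X_train=table[list(res.feature_names)].to_numpy(dtype=np.float64),
            y_train=table["label"].to_numpy()))
        log.info("member %d/%d: m=%d fitness=%.3f", k + 1, n_members,
                 res.m, res.fitness)
    meta = {"master_seed": cfg.seed, "n_members": n_members,
            "cv_folds": cfg.cv_folds, "g_max": cfg.g_max,
            "r_start": cfg.r_start, "r_end": cfg.r_end}
    return EnsembleModel(members, tuple(pool), classes, meta)


def predict(model: EnsembleModel, table: pd.DataFrame) -> list[Prediction]:
    """Plurality vote of all members over a feature table."""
    needed = {f for m in model.members for f in m.features}
    missing = sorted(needed - set(table.columns))
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")

    n = len(table)
    votes = np.zeros((n, len(model.classes)), dtype=int)
    cls_index = {c: i for i, c in enumerate(model.classes)}
    conf = np.zeros((n, len(model.classes)))
    for m in model.members:
        X = table[list(m.features)].to_numpy(dtype=np.float64)
        for i, lab in enumerate(m.predict(X)):
            votes[i, cls_index[lab]] += 1
        scores = m.class_scores(X)
        for c in scores.columns:
            conf[:, cls_index[c]] += scores[c].to_numpy()

    node_ids = (table["node_id"].astype(str).to_numpy()
                if "node_id" in table.columns
                else np.array([str(i) for i in range(n)]))
    sev_rank = {c: SEVERITY.index(c) if c in SEVERITY else len(SEVERITY)
                for c in model.classes}
    preds = []
    for i in range(n):
        v = votes[i]
        top = int(v.max())
        tied = [j for j in range(len(model.classes)) if v[j] == top]
        tie_broken = len(tied) > 1
        if tie_broken:
            # highest summed confidence among tied classes, then severity
            tied.sort(key=lambda j: (-conf[i, j], sev_rank[model.classes[j]]))
        final = model.classes[tied[0]]
        vd = {c: int(v[cls_index[c]]) for c in model.classes}
        total = int(v.sum())
        ene = vd.get("ENE", 0) / total
        met = (vd.get("ENE", 0) + vd.get("metastatic", 0)) / total
        preds.append(Prediction(node_ids[i], vd, final, tie_broken, ene, met))
    return preds


def predictions_frame(preds: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame([{
        "node_id": p.node_id, "final": p.final, "tie_broken": p.tie_broken,
        "ene_score": p.ene_score, "met_score": p.met_score,
        **{f"votes_{c}": v for c, v in p.votes.items()},
    } for p in preds])


def binary_views(preds: list[Prediction],
                 truth: dict[str, str] | pd.Series) -> dict[str, pd.DataFrame]:
    """Derive the ENE and metastasis binary task frames with scores.

    ENE task: positive iff (predicted / true) class is ENE.  Metastasis
    task: positive iff the class is metastatic or ENE.
    """
    if isinstance(truth, pd.Series):
        truth = dict(truth)
    rows_ene, rows_met = [], []
    for p in preds:
        t = truth[p.node_id]
        rows_ene.append({"node_id": p.node_id,
                         "pred": int(p.final == "ENE"),
                         "truth": int(t == "ENE"),
                         "score": p.ene_score})
        rows_met.append({"node_id": p.node_id,
                         "pred": int(p.final in ("metastatic", "ENE")),
                         "truth": int(t in ("metastatic", "ENE")),
                         "score": p.met_score})
    return {"ene": pd.DataFrame(rows_ene), "metastasis": pd.DataFrame(rows_met)}
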