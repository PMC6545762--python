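"""Shared containers for variable-importance learners.

Each learner produces nonnegative raw importances, which are rescaled so the
top variable scores 100 and the rest are expressed relative to it; variables
with a relative score of at least 20 (cutoff 0.2) count as selected. Ranks
use the average-rank convention on ties, so all zero-importance variables
share one rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_CUTOFF = 0.2  # fraction of the top score required for selection


def relative_importance(
    raw: Sequence[float], cutoff: float = DEFAULT_CUTOFF
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale raw importances to [0, 100] and flag selections.

    scores = 100 * raw / max(raw) when max(raw) > 0, else all zero;
    selected iff score >= 100 * cutoff (boundary inclusive).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw importances must be finite")
    if np.any(raw < 0):
        raise ValueError("raw importances must be nonnegative; floor negatives first")
    top = raw.max() if raw.size else 0.0
    scores = 100.0 * raw / top if top > 0 else np.zeros_like(raw)
    selected = scores >= 100.0 * cutoff if top > 0 else np.zeros(raw.shape, dtype=bool)
    return scores, selected


def tied_ranks(raw: Sequence[float]) -> np.ndarray:
    """Descending average ranks: largest importance gets rank 1."""
    return rankdata(-np.asarray(raw, dtype=float), method="average")


@dataclass
class ImportanceRanking:
    """One learner's ranking of every candidate variable."""

    variables: list[str]
    raw_importance: np.ndarray
    relative_score: np.ndarray
    rank: np.ndarray
    selected: np.ndarray

    @classmethod
    def from_raw(
        cls, variables: Sequence[str], raw: Sequence[float], cutoff: float = DEFAULT_CUTOFF
    ) -> "ImportanceRanking":
        raw = np.asarray(raw, dtype=float)
        if len(variables) != raw.size:
            raise ValueError("variables and importances differ in length")
        scores, selected = relative_importance(raw, cutoff)
        return cls(list(variables), raw, scores, tied_ranks(raw), selected)

    @property
    def selected_set(self) -> set[str]:
        return {v for v, s in zip(self.variables, self.selected) if s}

    def rank_of(self) -> dict[str, float]:
        return dict(zip(self.variables, self.rank))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "raw_importance": self.raw_importance,
                "relative_score": self.relative_score,
                "rank": self.rank,
                "selected": self.selected.astype(bool),
            }
        ).sort_values("rank", kind="stable", ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class LearnerResult:
    """A fitted learner: its ranking, cross-validated AUC, and provenance."""

    learner: str  # one of {"lasso", "mars", "rf", "bt"}
    ranking: ImportanceRanking
    auc: float
    cv_folds: int | str  # 10, or "oob" for the random forest
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.auc):
            raise ValueError(f"{self.learner}: AUC is not finite")

    @property
    def selected_set(self) -> set[str]:
        return self.ranking.selected_set

    def to_json(self, path) -> None:
        payload = {
            "learner": self.learner,
            "auc": self.auc,
            "cv_folds": self.cv_folds,
            "hyperparameters": {k: _jsonable(v) for k, v in dict(self.hyperparameters).items()},
            "seed": self.seed,
            "entries": self.ranking.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; a classifier cannot be fit")
    return X, y.astype(int)


def mean_fold_auc(aucs: Sequence[float]) -> float:
    aucs = [a for a in aucs if np.isfinite(a)]
    return float(np.mean(aucs)) if aucs else float("nan")
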