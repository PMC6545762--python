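"""Random forest ranking with out-of-bag permutation importance.

The forest itself is a standard bagged ensemble of CART trees with per-node
random feature subsetting. Importance follows the classic OOB permutation
definition: for every tree, the misclassification rate on that tree's
out-of-bag subjects is recorded before and after permuting one variable
within the OOB set, and the importance is the mean of the per-tree
differences. The model AUC is computed from OOB predicted class fractions,
so no separate cross-validation loop is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .base import ImportanceRanking, LearnerResult, validate_xy


@dataclass
class Forest:
    """A fitted ensemble with the per-tree bookkeeping the importance and
    proximity computations need.

    ``estimators`` expose ``predict`` and (for proximity) ``apply``;
    ``inbag_indices[t]`` lists the training rows drawn into tree ``t``'s
    bootstrap sample (with repetitions). ``inbag_indices=None`` means the
    forest carries no OOB bookkeeping and permutation importance refuses
    to run.
    """

    estimators: Sequence
    inbag_indices: Sequence[np.ndarray] | None
    n_samples: int
    sk_model: RandomForestClassifier | None = None

    @property
    def n_trees(self) -> int:
        return len(self.estimators)

    def oob_mask(self, t: int) -> np.ndarray:
        if self.inbag_indices is None:
            raise ValueError("forest was built without out-of-bag bookkeeping")
        mask = np.ones(self.n_samples, dtype=bool)
        mask[np.asarray(self.inbag_indices[t])] = False
        return mask

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index of every subject in every tree, shape (n, n_trees)."""
        if self.sk_model is not None:
            return self.sk_model.apply(np.asarray(X, dtype=float))
        return np.column_stack([est.apply(np.asarray(X, dtype=float)) for est in self.estimators])


def oob_permutation_importance(
    forest: Forest, X, y, seed: int = 0, return_per_tree: bool = False
):
    """Mean per-tree OOB error increase under within-OOB permutation.

    A variable used in no split of any tree gets importance exactly 0: the
    permutation cannot change any prediction. Negative values (permutation
    accidentally helping) are possible and are left unfloored here; the
    ranking layer floors them.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != forest.n_samples:
        raise ValueError("X does not match the forest's training sample count")
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    diffs = np.full((forest.n_trees, p), np.nan)
    for t, est in enumerate(forest.estimators):
        oob = np.flatnonzero(forest.oob_mask(t))
        if oob.size == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base_err = np.mean(est.predict(X_oob) != y_oob)
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xp = X_oob.copy()
            Xp[:, j] = X_oob[perm, j]
            diffs[t, j] = np.mean(est.predict(Xp) != y_oob) - base_err
    importance = np.nanmean(diffs, axis=0)
    if return_per_tree:
        return importance, diffs
    return importance


def fit_random_forest(
    X,
    y,
    variables=None,
    n_trees: int = 500,
    mtry: int | None = None,
    cutoff: float = 0.2,
    seed: int = 0,
) -> tuple[LearnerResult, Forest]:
    """Fit the forest; rank variables by OOB permutation importance.

    Returns the ranking result and the :class:`Forest` handle, which the
    proximity/MDS clustering stage reuses.
    """
    X, y = validate_xy(X, y)
    n, p = X.shape
    variables = list(variables) if variables is not None else [f"x{j}" for j in range(p)]
    if n_trees < 50:
        warnings.warn(f"n_trees={n_trees} < 50: permutation importances will be unstable")
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    forest = Forest(
        estimators=rf.estimators_,
        inbag_indices=[np.asarray(s) for s in rf.estimators_samples_],
        n_samples=n,
        sk_model=rf,
    )

    # OOB predicted class-1 fractions -> OOB AUC
    votes = np.zeros(n)
    counts = np.zeros(n)
    for t, est in enumerate(forest.estimators):
        oob = forest.oob_mask(t)
        if not oob.any():
            continue
        votes[oob] += est.predict(X[oob])
        counts[oob] += 1
    covered = counts > 0
    oob_frac = np.zeros(n)
    oob_frac[covered] = votes[covered] / counts[covered]
    auc = roc_auc_score(y[covered], oob_frac[covered])

    raw = oob_permutation_importance(forest, X, y, seed=seed)
    raw = np.maximum(raw, 0.0)  # relative scores live in [0, 100]
    result = LearnerResult(
        learner="rf",
        ranking=ImportanceRanking.from_raw(variables, raw, cutoff),
        auc=float(auc),
        cv_folds="oob",
        hyperparameters={"n_trees": n_trees, "mtry": mtry},
        seed=seed,
    )
    return result, forest
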