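"""Multivariate adaptive regression splines with GCV-based importance.

The model is a sum of products of reflected hinge pairs
``max(0, x - t)`` / ``max(0, t - x)`` placed at observed knots. The forward
pass greedily adds the hinge pair (parent term, variable, knot) that most
reduces the residual sum of squares; the backward pass prunes terms to the
submodel minimizing the generalized cross-validation (GCV) criterion

    GCV = (RSS / n) / (1 - C/n)^2,      C = n_terms + penalty * n_knots.

A binary outcome is fitted by least squares on its 0/1 coding (the classic
MARS approach to classification); the model score is thresholded only when
an ROC is required. Variable importance is the GCV reduction accrued at each
forward step, credited to the variables of the added basis functions and
restricted to steps with at least one term surviving the backward pass.

Candidate-knot evaluation is vectorized: existing basis columns are held as
an orthonormal matrix Q, and each hinge pair is scored by projecting it off
Q, which gives the exact RSS drop without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .base import ImportanceRanking, LearnerResult, mean_fold_auc, validate_xy

_EPS = 1e-10


def gcv(rss: float, n: int, n_terms: int, n_knots: int, penalty: float) -> float:
    """Generalized cross-validation score of a fitted spline model.

    ``n_terms`` counts basis functions including the intercept; each knot
    contributes ``penalty`` extra effective parameters. Undefined (raises)
    when the effective complexity ``C = n_terms + penalty * n_knots``
    reaches ``n``.
    """
    if rss < 0 or n <= 0:
        raise ValueError("rss must be nonnegative and n positive")
    c = n_terms + penalty * n_knots
    if c >= n:
        raise ValueError(f"effective complexity C={c} must be < n={n}")
    return (rss / n) / (1.0 - c / n) ** 2


@dataclass(frozen=True)
class HingeFactor:
    var: int
    knot: float
    sign: int  # +1: max(0, x-t); -1: max(0, t-x)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.sign * (X[:, self.var] - self.knot))


@dataclass(frozen=True)
class BasisTerm:
    """Product of hinge factors; the empty product is the intercept."""

    factors: tuple[HingeFactor, ...] = ()

    def design_column(self, X: np.ndarray) -> np.ndarray:
        col = np.ones(X.shape[0])
        for f in self.factors:
            col = col * f(X)
        return col

    @property
    def variables(self) -> frozenset[int]:
        return frozenset(f.var for f in self.factors)

    @property
    def degree(self) -> int:
        return len(self.factors)


@dataclass
class MarsModel:
    """A pruned spline model: surviving terms, their coefficients, and the
    per-forward-step GCV bookkeeping needed for variable importance."""

    terms: list[BasisTerm]
    coef: np.ndarray
    n_features: int
    penalty: float
    gcv_: float
    # one record per forward step: (variables credited, gcv drop, term ids added)
    forward_steps: list[tuple[frozenset, float, tuple[int, ...]]] = field(default_factory=list)
    surviving_ids: frozenset = frozenset()

    def design(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([t.design_column(X) for t in self.terms])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.design(X) @ self.coef

    def variable_importance(self) -> np.ndarray:
        """GCV-reduction importance over the ``n_features`` input variables.

        A forward step's GCV drop is credited to the variables of the added
        hinge pair, but only variables still present in the pruned model
        collect credit — the restriction is per variable, not per term,
        because the backward pass may replace an early hinge pair with a
        numerically equivalent later copy on the same variable.
        """
        surviving_vars = set()
        for t in self.terms:
            surviving_vars |= t.variables
        imp = np.zeros(self.n_features)
        for variables, drop, _term_ids in self.forward_steps:
            if drop <= 0:
                continue
            for v in variables:
                if v in surviving_vars:
                    imp[v] += drop
        return imp

    def knots_on(self, var: int) -> list[float]:
        return [
            f.knot
            for t in self.terms
            for f in t.factors
            if f.var == var
        ]


def _candidate_knots(x: np.ndarray, active: np.ndarray, max_knots: int) -> np.ndarray:
    """Quantile-spaced knots among rows where the parent term is active."""
    vals = x[active]
    uniq = np.unique(vals)
    if uniq.size < 3:  # constant / near-constant: no usable knot
        return np.empty(0)
    levels = np.linspace(0.0, 1.0, min(max_knots, uniq.size - 1) + 2)[1:-1]
    return np.unique(np.quantile(vals, levels))


def fit_mars_regression(
    X,
    y,
    max_terms: int | None = None,
    max_degree: int = 1,
    penalty: float | None = None,
    max_knots: int = 30,
) -> MarsModel:
    """Forward/backward MARS fit of a numeric response by least squares."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if max_terms is None:
        max_terms = min(2 * p + 1, 21)
    if max_terms < 3:
        raise ValueError(f"max_terms must be >= 3, got {max_terms}")
    if penalty is None:
        penalty = 2.0 if max_degree == 1 else 3.0

    terms: list[BasisTerm] = [BasisTerm()]
    B = np.ones((n, 1))
    Q = B / np.sqrt(n)
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    n_knots = 0
    forward_steps: list[tuple[frozenset, float, tuple[int, ...]]] = []
    gcv_prev = gcv(rss, n, 1, 0, penalty)

    while len(terms) + 2 <= max_terms:
        if len(terms) + 2 + penalty * (n_knots + 1) >= n:
            break
        best = None  # (reduction, parent_id, var, knot)
        for parent_id, parent in enumerate(terms):
            if parent.degree >= max_degree:
                continue
            parent_col = B[:, parent_id]
            active = parent_col > 0
            if active.sum() < 3:
                continue
            for var in range(p):
                if var in parent.variables:
                    continue
                knots = _candidate_knots(X[:, var], active, max_knots)
                if knots.size == 0:
                    continue
                x = X[:, var]
                # hinge pairs for all knots at once, n x K
                H1 = parent_col[:, None] * np.maximum(0.0, x[:, None] - knots[None, :])
                H2 = parent_col[:, None] * np.maximum(0.0, knots[None, :] - x[:, None])
                A1 = H1 - Q @ (Q.T @ H1)
                n1 = np.einsum("ij,ij->j", A1, A1)
                A2 = H2 - Q @ (Q.T @ H2)
                dot12 = np.einsum("ij,ij->j", A1, A2)
                scale = np.where(n1 > _EPS * n, dot12 / np.where(n1 > 0, n1, 1.0), 0.0)
                A2 = A2 - A1 * scale[None, :]
                n2 = np.einsum("ij,ij->j", A2, A2)
                r1 = A1.T @ resid
                r2 = A2.T @ resid
                red = np.where(n1 > _EPS * n, r1**2 / np.where(n1 > 0, n1, 1.0), 0.0)
                red = red + np.where(n2 > _EPS * n, r2**2 / np.where(n2 > 0, n2, 1.0), 0.0)
                k_best = int(np.argmax(red))
                if best is None or red[k_best] > best[0]:
                    best = (float(red[k_best]), parent_id, var, float(knots[k_best]))
        if best is None or best[0] <= _EPS * max(rss, 1.0):
            break
        reduction, parent_id, var, knot = best
        parent = terms[parent_id]
        new_ids = []
        for sign in (+1, -1):
            factor = HingeFactor(var, knot, sign)
            term = BasisTerm(parent.factors + (factor,))
            col = term.design_column(X)
            if col.max() <= 0:
                continue
            new_ids.append(len(terms))
            terms.append(term)
            B = np.column_stack([B, col])
        if not new_ids:
            break
        n_knots += 1
        Q, _ = np.linalg.qr(B)
        resid = y - Q @ (Q.T @ y)
        rss = float(resid @ resid)
        gcv_now = gcv(rss, n, len(terms), n_knots, penalty)
        credited = frozenset().union(*(terms[i].variables for i in new_ids))
        forward_steps.append((credited, max(0.0, gcv_prev - gcv_now), tuple(new_ids)))
        gcv_prev = gcv_now

    surviving = _backward_pass(B, y, terms, penalty)
    keep = sorted(surviving)
    B_keep = B[:, keep]
    coef, *_ = np.linalg.lstsq(B_keep, y, rcond=None)
    rss_keep = float(np.sum((y - B_keep @ coef) ** 2))
    kept_terms = [terms[i] for i in keep]
    model = MarsModel(
        terms=kept_terms,
        coef=coef,
        n_features=p,
        penalty=penalty,
        gcv_=gcv(rss_keep, n, len(keep), _count_knots(kept_terms), penalty),
        forward_steps=forward_steps,
        surviving_ids=frozenset(surviving),
    )
    return model


def _count_knots(terms: list[BasisTerm]) -> int:
    return len({(f.var, f.knot) for t in terms for f in t.factors})


def _backward_pass(B: np.ndarray, y: np.ndarray, terms: list[BasisTerm], penalty: float) -> set[int]:
    """Prune greedily to the minimum-GCV subset (intercept always kept)."""
    n = B.shape[0]

    def score(ids: list[int]) -> float:
        coef, *_ = np.linalg.lstsq(B[:, ids], y, rcond=None)
        rss = float(np.sum((y - B[:, ids] @ coef) ** 2))
        return gcv(rss, n, len(ids), _count_knots([terms[i] for i in ids]), penalty)

    current = list(range(len(terms)))
    best_ids, best_gcv = list(current), score(current)
    while len(current) > 1:
        trial_scores = [
            (score([i for i in current if i != drop]), drop)
            for drop in current
            if drop != 0
        ]
        if not trial_scores:
            break
        g, drop = min(trial_scores)
        current = [i for i in current if i != drop]
        if g <= best_gcv:
            best_gcv, best_ids = g, list(current)
    return set(best_ids)


def fit_mars(
    X,
    y,
    variables=None,
    max_terms: int | None = None,
    max_degree: int = 1,
    penalty: float | None = None,
    max_knots: int = 30,
    folds: int = 10,
    cutoff: float = 0.2,
    seed: int = 0,
) -> tuple[LearnerResult, MarsModel]:
    """Fit MARS to a binary outcome and rank variables by GCV reduction.

    Returns the :class:`LearnerResult` (importances, selections, 10-fold CV
    AUC of the model scores) together with the full-data :class:`MarsModel`.
    """
    X, y = validate_xy(X, y)
    n, p = X.shape
    variables = list(variables) if variables is not None else [f"x{j}" for j in range(p)]

    model = fit_mars_regression(X, y.astype(float), max_terms, max_degree, penalty, max_knots)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        fold_model = fit_mars_regression(
            X[tr], y[tr].astype(float), max_terms, max_degree, penalty, max_knots
        )
        scores = fold_model.predict(X[te])
        if len(np.unique(y[te])) == 2 and np.ptp(scores) > 0:
            aucs.append(roc_auc_score(y[te], scores))
        elif len(np.unique(y[te])) == 2:
            aucs.append(0.5)

    result = LearnerResult(
        learner="mars",
        ranking=ImportanceRanking.from_raw(variables, model.variable_importance(), cutoff),
        auc=mean_fold_auc(aucs),
        cv_folds=folds,
        hyperparameters={
            "max_terms": max_terms if max_terms is not None else min(2 * p + 1, 21),
            "max_degree": max_degree,
            "penalty": model.penalty,
            "max_knots": max_knots,
        },
        seed=seed,
    )
    return result, model
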