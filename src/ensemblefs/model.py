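"""Model/Results facade over the ensemble feature-selection pipeline.

:class:`EnsembleSelector` is constructed from a preprocessed cohort table
(or any feature DataFrame plus binary outcome); ``fit`` runs the four
importance-ranking learners, aggregates their rankings with AUC weights,
and takes the majority vote. The returned :class:`EnsembleResults` carries
the per-learner results, the aggregated ranking, the consensus subset, and
methods to evaluate the subset (bootstrap SVM ROC), cluster subjects
(random-forest proximity + MDS), and print a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ensemble as _ensemble
from .clustering import MdsEmbedding, ProximityMatrix, label_separation, mds_embed, proximity_matrix
from .cohort import CANDIDATES
from .evaluation import RocResult, evaluate_subset
from .learners import (
    Forest,
    LearnerResult,
    fit_boosted_trees,
    fit_lasso,
    fit_mars,
    fit_random_forest,
)
from ._utils import spawn_seeds

LEARNERS = ("lasso", "mars", "rf", "bt")


class EnsembleSelector:
    """Consensus variable selection over a binary obesity outcome.

    Parameters
    ----------
    X : DataFrame
        Standardized candidate features, one column per variable.
    y : array-like of {0, 1}
        Binary outcome (e.g. waist- or BMI-defined obesity).
    cutoff : float
        Relative-importance selection threshold as a fraction of the top
        score (default 0.2, i.e. a relative score of 20).
    min_votes : int
        Learners that must select a variable for it to win the majority
        vote (default 3 of 4).
    learner_config : mapping
        Optional per-learner keyword overrides, keyed by learner name.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        cutoff: float = 0.2,
        min_votes: int = _ensemble.DEFAULT_MIN_VOTES,
        learner_config: Mapping[str, Mapping] | None = None,
    ) -> None:
        if not 0.0 < cutoff <= 1.0:
            raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
        if not 1 <= min_votes <= len(LEARNERS):
            raise ValueError(f"min_votes must lie in 1..{len(LEARNERS)}, got {min_votes}")
        self.X = pd.DataFrame(X)
        self.y = np.asarray(y).astype(int)
        if self.y.shape[0] != len(self.X):
            raise ValueError("X and y differ in length")
        self.variables = list(self.X.columns)
        self.cutoff = cutoff
        self.min_votes = min_votes
        self.learner_config = {k: dict(v) for k, v in (learner_config or {}).items()}

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        outcome: str = "obw",
        features: Sequence[str] | None = None,
        **kwargs,
    ) -> "EnsembleSelector":
        """Build a selector from a preprocessed cohort table."""
        if outcome not in table.columns:
            raise ValueError(f"outcome column {outcome!r} not in table")
        feats = list(features) if features is not None else [
            c for c in CANDIDATES if c in table.columns
        ]
        missing = [c for c in feats if c not in table.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        return cls(table[feats], table[outcome].to_numpy(), **kwargs)

    def fit(self, seed: int = 0) -> "EnsembleResults":
        """Run all four learners and combine their rankings."""
        seeds = spawn_seeds(seed, len(LEARNERS))
        Xv = self.X.to_numpy(dtype=float)
        common = dict(variables=self.variables, cutoff=self.cutoff)

        lasso = fit_lasso(Xv, self.y, seed=seeds[0], **common, **self.learner_config.get("lasso", {}))
        mars, mars_model = fit_mars(
            Xv, self.y, seed=seeds[1], **common, **self.learner_config.get("mars", {})
        )
        rf, forest = fit_random_forest(
            Xv, self.y, seed=seeds[2], **common, **self.learner_config.get("rf", {})
        )
        bt = fit_boosted_trees(
            Xv, self.y, seed=seeds[3], **common, **self.learner_config.get("bt", {})
        )

        results = [lasso, mars, rf, bt]
        agg = _ensemble.aggregate_ranks(results, min_votes=self.min_votes)
        return EnsembleResults(
            model=self,
            learner_results={r.learner: r for r in results},
            aggregated=agg,
            forest=forest,
            mars_model=mars_model,
            seed=seed,
        )


@dataclass
class EnsembleResults:
    """Fitted ensemble: rankings, consensus, and downstream analyses."""

    model: EnsembleSelector
    learner_results: dict[str, LearnerResult]
    aggregated: _ensemble.AggregatedRanking
    forest: Forest
    mars_model: object
    seed: int
    _proximity: ProximityMatrix | None = field(default=None, repr=False)

    @property
    def consensus(self) -> list[str]:
        """Majority-vote winners ordered by aggregated rank."""
        return self.aggregated.consensus_subset()

    @property
    def vote_counts(self) -> dict[str, int]:
        t = self.aggregated.table
        return dict(zip(t["variable"], t["vote_count"]))

    def evaluate(self, B: int = 100, seed: int | None = None, subset=None) -> RocResult:
        """Bootstrap SVM ROC of the consensus subset (or an explicit one)."""
        subset = list(subset) if subset is not None else self.consensus
        if not subset:
            raise ValueError("consensus subset is empty; nothing to evaluate")
        return evaluate_subset(
            self.model.X[subset].to_numpy(dtype=float),
            self.model.y,
            B=B,
            seed=self.seed if seed is None else seed,
        )

    def proximity(self) -> ProximityMatrix:
        if self._proximity is None:
            self._proximity = proximity_matrix(self.forest, self.model.X.to_numpy(dtype=float))
        return self._proximity

    def mds(self, dims: int = 2) -> MdsEmbedding:
        return mds_embed(self.proximity(), dims=dims)

    def separation(self, labels=None, embedding: MdsEmbedding | None = None) -> float:
        """Silhouette of the MDS embedding under the outcome labels."""
        emb = embedding if embedding is not None else self.mds()
        return label_separation(emb, self.model.y if labels is None else labels)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a regression printout."""
        lines = []
        lines.append("Consensus variable selection (4 learners)")
        lines.append("=" * 66)
        lines.append("Model AUC weights:")
        for name, w in self.aggregated.model_weights.items():
            lines.append(
                f"  {name:<6} AUC={self.learner_results[name].auc:.3f}  weight={w:.3f}"
            )
        lines.append("-" * 66)
        lines.append(f"{'variable':<14}{'agg. rank':>10}{'votes':>7}{'consensus':>11}")
        for _, row in self.aggregated.table.iterrows():
            lines.append(
                f"{row['variable']:<14}{row['aggregated_rank']:>10.2f}"
                f"{int(row['vote_count']):>7}{('yes' if row['consensus'] else ''):>11}"
            )
        lines.append("-" * 66)
        cons = self.consensus
        lines.append(f"Consensus subset ({len(cons)}): {', '.join(cons) if cons else '(empty)'}")
        return "\n".join(lines)

    def plot_ranking(self, path=None):
        """Horizontal bar chart of aggregated ranks, consensus in color."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.aggregated.table.sort_values("aggregated_rank", ascending=False)
        colors = ["#c23b22" if c else "#7f7f7f" for c in t["consensus"]]
        fig, ax = plt.subplots(figsize=(6, 0.3 * len(t) + 1))
        ax.barh(t["variable"], t["aggregated_rank"], color=colors)
        ax.set_xlabel("aggregated rank (lower = more important)")
        fig.tight_layout()
        if path:
            fig.savefig(path)
            plt.close(fig)
        return fig

    def plot_roc(self, roc: RocResult, path=None):
        """Bootstrap-averaged ROC curve with its percentile TPR band."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(roc.fpr_grid, roc.mean_tpr, color="#1f4e79")
        if roc.tpr_lo is not None:
            ax.fill_between(roc.fpr_grid, roc.tpr_lo, roc.tpr_hi, alpha=0.25, color="#1f4e79")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC {roc.auc_point:.3f} (95% CI {roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f})")
        fig.tight_layout()
        if path:
            fig.savefig(path)
            plt.close(fig)
        return fig

    def plot_mds(self, path=None, labels=None):
        """Scatter of the 2-D proximity embedding, obese subjects in blue."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        emb = self.mds()
        lab = np.asarray(self.model.y if labels is None else labels)
        fig, ax = plt.subplots(figsize=(5, 5))
        for value, color, name in ((0, "#c23b22", "non-obese"), (1, "#1f4e79", "obese")):
            m = lab == value
            ax.scatter(emb.coordinates[m, 0], emb.coordinates[m, 1], s=8, c=color, label=name)
        ax.set_xlabel("dimension 1")
        ax.set_ylabel("dimension 2")
        ax.legend(frameon=False)
        fig.tight_layout()
        if path:
            fig.savefig(path)
            plt.close(fig)
        return fig
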