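"""AUC-weighted rank aggregation and majority voting across learners.

Each learner contributes a full (tied-average) rank list over the same
candidate variables. The aggregated rank of variable j is the weighted mean

    R_j = sum_i w_i * R_ij,     w_i = AUC_i / sum_i AUC_i,

so better-performing models pull the consensus ordering harder. A variable
selected (relative importance >= the cutoff) by at least ``min_votes`` of
the learners wins the majority vote; the consensus subset is the majority
winners ordered by ascending aggregated rank.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .learners.base import LearnerResult

logger = logging.getLogger(__name__)

DEFAULT_MIN_VOTES = 3


@dataclass
class AggregatedRanking:
    """Weighted-mean ranks, vote counts, and consensus flags per variable."""

    table: pd.DataFrame  # variable, aggregated_rank, vote_count, consensus
    model_weights: dict[str, float]
    source: list[LearnerResult]

    @property
    def variables(self) -> list[str]:
        return self.table["variable"].tolist()

    def consensus_subset(self) -> list[str]:
        """Majority-vote winners ordered by ascending aggregated rank."""
        sel = self.table[self.table["consensus"]]
        out = sel.sort_values("aggregated_rank", kind="stable")["variable"].tolist()
        if not out:
            logger.warning("empty consensus: no variable reached the vote threshold")
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "model_weights": self.model_weights,
            "entries": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _check_variable_sets(results: Sequence[LearnerResult]) -> list[str]:
    ref = results[0].ranking.variables
    ref_set = set(ref)
    for r in results[1:]:
        other = set(r.ranking.variables)
        if other != ref_set:
            diff = sorted(ref_set.symmetric_difference(other))
            raise ValueError(f"learners rank different variable sets; difference: {diff}")
    return list(ref)


def aggregate_ranks(
    results: Sequence[LearnerResult], min_votes: int = DEFAULT_MIN_VOTES
) -> AggregatedRanking:
    """Combine per-learner rankings into the weighted consensus ordering."""
    if not results:
        raise ValueError("no learner results to aggregate")
    variables = _check_variable_sets(results)
    aucs = np.array([r.auc for r in results], dtype=float)
    if np.any(aucs <= 0):
        bad = [r.learner for r, a in zip(results, aucs) if a <= 0]
        raise ValueError(f"nonpositive AUC weight for learner(s): {bad}")
    weights = aucs / aucs.sum()

    rank_mat = np.array(
        [[r.ranking.rank_of()[v] for v in variables] for r in results]
    )  # (n_learners, p)
    agg = weights @ rank_mat
    votes = np.sum(
        [[v in r.selected_set for v in variables] for r in results], axis=0
    )
    consensus = votes >= min_votes

    table = (
        pd.DataFrame(
            {
                "variable": variables,
                "aggregated_rank": agg,
                "vote_count": votes.astype(int),
                "consensus": consensus,
            }
        )
        .sort_values("aggregated_rank", kind="stable", ignore_index=True)
    )
    return AggregatedRanking(
        table=table,
        model_weights={r.learner: float(w) for r, w in zip(results, weights)},
        source=list(results),
    )


def majority_vote(
    results: Sequence[LearnerResult], min_votes: int = DEFAULT_MIN_VOTES
) -> tuple[dict[str, int], set[str]]:
    """Per-variable vote counts and the consensus set."""
    if min_votes > len(results):
        raise ValueError(
            f"min_votes={min_votes} exceeds the number of learners ({len(results)})"
        )
    variables = _check_variable_sets(results)
    return vote_from_selections(
        {r.learner: r.selected_set for r in results}, variables, min_votes
    )


def vote_from_selections(
    selections: Mapping[str, Iterable[str]],
    variables: Sequence[str],
    min_votes: int = DEFAULT_MIN_VOTES,
) -> tuple[dict[str, int], set[str]]:
    """Majority vote over plain selected-variable lists.

    Useful for reanalysing published per-learner selections where only the
    selected lists (not full rankings) are available.
    """
    if min_votes > len(selections):
        raise ValueError(
            f"min_votes={min_votes} exceeds the number of learners ({len(selections)})"
        )
    sets = {k: set(v) for k, v in selections.items()}
    counts = {v: sum(v in s for s in sets.values()) for v in variables}
    winners = {v for v, c in counts.items() if c >= min_votes}
    return counts, winners


def consensus_subset(agg: AggregatedRanking) -> list[str]:
    return agg.consensus_subset()
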