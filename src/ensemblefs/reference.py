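"""Published per-learner results from the original salivary-biomarker cohort.

The original childhood-obesity cohort (saliva multiplex panel, n ~ 726 after
exclusions) is not publicly deposited, but the study's per-learner selected
variable lists (ordered by relative importance) and model AUCs were
published. They are recorded here so the aggregation and majority-vote
machinery can be exercised on the real reported selections, e.g.::

    >>> from ensemblefs import reference, ensemble
    >>> counts, winners = ensemble.vote_from_selections(
    ...     reference.SELECTED_OBW, reference.variable_universe())
    >>> sorted(winners)
    ['adiponectin', 'crp', 'fitness', 'insulin', 'leptin']
"""

from __future__ import annotations

from .cohort import CANDIDATES

#: Ordered selected-variable lists (relative importance >= 20%), waist outcome.
SELECTED_OBW: dict[str, list[str]] = {
    "lasso": ["insulin", "crp", "fitness", "adiponectin", "leptin"],
    "mars": ["crp", "insulin", "adiponectin", "fitness", "vegf_a", "leptin"],
    "rf": ["crp", "insulin", "leptin"],
    "bt": ["crp", "insulin", "adiponectin", "leptin", "fitness"],
}

#: Ordered selected-variable lists, BMI outcome.
SELECTED_OBWHO: dict[str, list[str]] = {
    "lasso": ["insulin", "crp", "adiponectin", "fitness"],
    "mars": ["crp", "insulin", "adiponectin", "sex", "vegf_a", "fitness"],
    "rf": ["crp", "insulin", "adiponectin"],
    "bt": ["crp", "insulin", "adiponectin"],
}

#: Reported AUCs of the models that generated the rankings.
MODEL_AUC_OBW: dict[str, float] = {"lasso": 0.787, "mars": 0.837, "rf": 0.826, "bt": 0.816}
MODEL_AUC_OBWHO: dict[str, float] = {"lasso": 0.816, "mars": 0.853, "rf": 0.833, "bt": 0.822}


def variable_universe() -> list[str]:
    """The candidate variable set of the original analysis."""
    return list(CANDIDATES)
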