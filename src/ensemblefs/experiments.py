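"""Seed-replicated simulation experiments.

These harnesses wrap the full analysis in multi-seed loops to measure the
properties the package is designed around: recovery of planted informative
biomarkers, the waist/BMI leptin asymmetry, and null calibration of the
learners and of the bootstrap ROC. Both the test suite and the acceptance
script drive them; problem sizes are arguments so callers can scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import spawn_seeds
from .cohort import BIOMARKERS, GeneratorSpec, derive_outcomes, exclude_influential, generate_cohort, preprocess
from .evaluation import evaluate_subset
from .model import EnsembleSelector

#: Planted informative biomarkers of the default generator.
INFORMATIVE: tuple[str, ...] = ("crp", "insulin", "adiponectin", "leptin")

#: Scaled-down learner settings used for replicated experiments (the
#: defaults are heavier than multi-seed loops need; see docs/methods.md).
EXPERIMENT_LEARNER_CONFIG: dict = {
    "rf": {"n_trees": 500},
    "bt": {"max_trees": 200},
    "mars": {"max_knots": 20},
}


@dataclass
class RecoveryOutcome:
    """Per-seed consensus sets and summary rates of the recovery study."""

    per_seed: list[dict] = field(default_factory=list)

    @property
    def n_seeds(self) -> int:
        return len(self.per_seed)

    def _rate(self, key: str) -> float:
        return float(np.mean([rec[key] for rec in self.per_seed]))

    @property
    def waist_recovery_rate(self) -> float:
        """Seeds where the waist consensus holds all informative markers
        with at most one null biomarker."""
        return self._rate("waist_recovered")

    @property
    def union_recovery_rate(self) -> float:
        """Same, over the union of the waist and BMI consensus sets."""
        return self._rate("union_recovered")

    @property
    def leptin_discrimination_rate(self) -> float:
        """Seeds where leptin reaches the waist consensus but not the BMI
        consensus — the marker's visceral specificity."""
        return self._rate("leptin_discriminates")


def planted_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    spec_kwargs: dict | None = None,
    learner_config: dict | None = None,
) -> RecoveryOutcome:
    """Run the full two-outcome analysis on ``n_seeds`` fresh cohorts."""
    nulls = set(BIOMARKERS) - set(INFORMATIVE)
    cfg = EXPERIMENT_LEARNER_CONFIG if learner_config is None else learner_config
    cohort_seeds = spawn_seeds(base_seed, n_seeds)
    fit_seeds = spawn_seeds(base_seed + 1, n_seeds)
    out = RecoveryOutcome()
    for cs, fs in zip(cohort_seeds, fit_seeds):
        spec = GeneratorSpec(seed=cs, **(spec_kwargs or {}))
        table = derive_outcomes(preprocess(generate_cohort(spec)))
        consensus: dict[str, set] = {}
        for oc in ("obw", "obwho"):
            sub, _ = exclude_influential(table, oc)
            res = EnsembleSelector.from_dataframe(sub, outcome=oc, learner_config=cfg).fit(seed=fs)
            consensus[oc] = set(res.consensus)
        union = consensus["obw"] | consensus["obwho"]
        out.per_seed.append(
            {
                "cohort_seed": cs,
                "obw": sorted(consensus["obw"]),
                "obwho": sorted(consensus["obwho"]),
                "waist_recovered": all(m in consensus["obw"] for m in INFORMATIVE)
                and len(consensus["obw"] & nulls) <= 1,
                "union_recovered": all(m in union for m in INFORMATIVE)
                and len(union & nulls) <= 1,
                "leptin_discriminates": "leptin" in consensus["obw"]
                and "leptin" not in consensus["obwho"],
            }
        )
    return out


@dataclass
class NullCalibrationOutcome:
    learner_auc: dict[str, list[float]] = field(default_factory=dict)
    ci_covers_half: list[bool] = field(default_factory=list)

    @property
    def mean_auc(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.learner_auc.items()}

    @property
    def coverage(self) -> float:
        return float(np.mean(self.ci_covers_half))


def null_calibration(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_subjects: int = 400,
    bootstrap: int = 100,
    learner_config: dict | None = None,
) -> NullCalibrationOutcome:
    """Outcome-permuted cohorts: learner CV AUCs must hover near 0.5 and
    the bootstrap 95% CI of the subset AUC must usually cover 0.5."""
    cfg = EXPERIMENT_LEARNER_CONFIG if learner_config is None else learner_config
    cohort_seeds = spawn_seeds(base_seed, n_seeds)
    fit_seeds = spawn_seeds(base_seed + 1, n_seeds)
    out = NullCalibrationOutcome(learner_auc={k: [] for k in ("lasso", "mars", "rf", "bt")})
    for cs, fs in zip(cohort_seeds, fit_seeds):
        table = derive_outcomes(
            preprocess(generate_cohort(GeneratorSpec(n_subjects=n_subjects, seed=cs)))
        )
        rng = np.random.default_rng(fs)
        table = table.assign(obw=rng.permutation(table["obw"].to_numpy()))
        res = EnsembleSelector.from_dataframe(table, outcome="obw", learner_config=cfg).fit(seed=fs)
        for k, lr in res.learner_results.items():
            out.learner_auc[k].append(float(lr.auc))
        roc = evaluate_subset(
            table[list(INFORMATIVE)].to_numpy(float),
            table["obw"].to_numpy(),
            B=bootstrap,
            seed=fs,
        )
        out.ci_covers_half.append(roc.auc_ci[0] <= 0.5 <= roc.auc_ci[1])
    return out
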