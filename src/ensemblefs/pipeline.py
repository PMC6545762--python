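"""End-to-end orchestration: simulate -> preprocess -> rank -> aggregate ->
evaluate -> cluster, with artifact writing and seeded reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from ._utils import spawn_seeds
from .cohort import (
    GeneratorSpec,
    derive_outcomes,
    exclude_influential,
    generate_cohort,
    preprocess,
    read_cohort,
    write_cohort,
)
from .model import EnsembleSelector

logger = logging.getLogger(__name__)

OUTCOMES = ("obw", "obwho")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    input: str | None = None  # cohort CSV; None -> simulate
    generator: GeneratorSpec | None = None
    outcome: str = "both"  # obw | obwho | both
    cutoff: float = 0.2
    min_votes: int = 3
    bootstrap: int = 100
    percentile: float = 95.0
    influence_threshold: float | None = None
    influence_statistic: str = "leverage"
    exclude: bool = True
    learner_config: Mapping[str, Mapping] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "out"

    def __post_init__(self) -> None:
        if self.outcome not in ("obw", "obwho", "both"):
            raise ValueError(f"outcome must be obw, obwho or both, got {self.outcome!r}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ValueError(f"cutoff must lie in (0, 1], got {self.cutoff}")
        if not 1 <= self.min_votes <= 4:
            raise ValueError(f"min_votes must lie in 1..4, got {self.min_votes}")
        if self.bootstrap < 1:
            raise ValueError("bootstrap count must be positive")
        if self.input is None and self.generator is None:
            self.generator = GeneratorSpec(seed=self.seed)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return OUTCOMES if self.outcome == "both" else (self.outcome,)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorSpec(**gen)
        return cfg

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Index of everything a run produced, with provenance."""

    config_digest: str
    seed: int
    version: str
    per_outcome: dict
    artifacts: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def load_or_simulate(config: RunConfig) -> pd.DataFrame:
    if config.input is not None:
        path = Path(config.input)
        if not path.exists():
            raise FileNotFoundError(f"cohort input not readable: {path}")
        return read_cohort(path)
    return generate_cohort(config.generator)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage for each requested outcome and write artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts.append(str(path))

    table = load_or_simulate(config)
    table = preprocess(table)
    table = derive_outcomes(table, percentile=config.percentile)
    save("cohort.csv", lambda p: write_cohort(table, p, config.generator))
    if config.generator is not None:
        artifacts.append(str(outdir / "cohort.csv.spec.json"))

    fit_seed, eval_seed = spawn_seeds(config.seed, 2)
    per_outcome: dict[str, dict] = {}
    for outcome in config.outcomes:
        logger.info("stage: %s analysis", outcome)
        sub = table
        excluded: list = []
        if config.exclude:
            sub, excluded = exclude_influential(
                table,
                outcome=outcome,
                threshold=config.influence_threshold,
                statistic=config.influence_statistic,
            )
        selector = EnsembleSelector.from_dataframe(
            sub,
            outcome=outcome,
            cutoff=config.cutoff,
            min_votes=config.min_votes,
            learner_config=config.learner_config,
        )
        res = selector.fit(seed=fit_seed)

        for name, lr in res.learner_results.items():
            save(f"{outcome}_{name}.json", lr.to_json)
            save(f"{outcome}_{name}.tsv", lr.ranking.to_tsv)
        save(f"{outcome}_aggregated.tsv", res.aggregated.to_tsv)
        save(f"{outcome}_aggregated.json", res.aggregated.to_json)

        consensus = res.consensus
        entry: dict = {
            "n_subjects": int(len(sub)),
            "excluded": excluded,
            "consensus": consensus,
            "vote_counts": res.vote_counts,
            "learner_auc": {k: float(v.auc) for k, v in res.learner_results.items()},
        }
        if consensus:
            roc = res.evaluate(B=config.bootstrap, seed=eval_seed)
            save(f"{outcome}_roc.json", roc.to_json)
            save(f"{outcome}_roc_curve.tsv", roc.curve_tsv)
            entry["roc"] = {"auc": roc.auc_point, "ci": list(roc.auc_ci)}
        else:
            logger.warning("%s: empty consensus; ROC evaluation skipped", outcome)

        emb = res.mds()
        save(
            f"{outcome}_mds.tsv",
            lambda p, e=emb, s=sub, o=outcome: e.to_tsv(
                p, subject_ids=s["subject_id"], labels=s[o]
            ),
        )
        entry["silhouette"] = float(res.separation())
        per_outcome[outcome] = entry

    report = RunReport(
        config_digest=config.digest(),
        seed=config.seed,
        version=__version__,
        per_outcome=per_outcome,
        artifacts=artifacts,
    )
    report.to_json(outdir / "report.json")
    missing = [a for a in artifacts if not Path(a).exists()]
    if missing:
        raise RuntimeError(f"run finished but artifacts missing: {missing}")
    return report
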