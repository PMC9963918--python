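"""Pipeline driver: configuration, stage sequencing, manifesting.

The configuration is a nested YAML document with blocks mirroring the
analysis stages (``task``, ``agent``, ``cohort``, ``sequenceness``,
``linking``).  Defaults reproduce the study's settings: 6 blocks x 24
trials, 24 participants, a 10-600-ms lag grid, analysis lags of 70 ms
(forward, planning and feedback) and 40 ms (backward, feedback).  Every
output is stamped with the config hash and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behavior import AgentParams, fit_cohort
from .cohort import CohortSpec, simulate_replay_cohort, trialwise_scores
from .io import write_json, write_tsv
from .linking import dissociation_test, link_glm
from .stats import rt_glm, stay_glm
from .task import TaskConfig
from .tdlm import SequencenessAnalysis

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

REQUIRED_BLOCKS = ("task", "agent", "cohort", "sequenceness", "linking")


@dataclass
class PipelineConfig:
    seed: int = 0
    task: dict = field(default_factory=dict)
    agent: dict = field(default_factory=lambda: {
        "alpha": 0.5, "beta": 2.0, "w": 1.0, "model": "hybrid"})
    cohort: dict = field(default_factory=lambda: {"n_participants": 24})
    sequenceness: dict = field(default_factory=lambda: {
        "lag_min_ms": 10, "lag_max_ms": 600, "lag_step_ms": 10,
        "planning_lag_ms": 70, "feedback_lag_ms": 40, "n_perms": 500})
    linking: dict = field(default_factory=lambda: {
        "regressors": ["different_start"], "tost_bound": 0.5})
    fit_behavior: dict = field(default_factory=lambda: {
        "model": "hybrid", "n_starts": 10})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        missing = [b for b in REQUIRED_BLOCKS if b not in d]
        if missing:
            raise ValueError(f"config missing required blocks: {missing}")
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            default = getattr(base, f.name)
            val = d.get(f.name, default)
            if isinstance(default, dict) and isinstance(val, dict):
                val = {**default, **val}
            merged[f.name] = val
        return cls(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: PipelineConfig, out_dir=None, seed=None) -> dict:
    """simulate -> fit behavior -> sequenceness -> link; returns the bundle."""
    seed = config.seed if seed is None else int(seed)
    agent_kw = dict(config.agent)
    model = agent_kw.pop("model", "hybrid")
    spec = CohortSpec(
        n_participants=int(config.cohort.get("n_participants", 24)),
        task=TaskConfig(**config.task),
        agent=AgentParams(**agent_kw),
        agent_model=model,
    )
    logger.info("stage simulate: %d participants", spec.n_participants)
    cohort = simulate_replay_cohort(spec, seed=seed)
    sq = config.sequenceness

    logger.info("stage fit-behavior")
    fits = fit_cohort(cohort.choices, config.fit_behavior.get("model", "hybrid"),
                      n_starts=int(config.fit_behavior.get("n_starts", 10)),
                      seed=seed)
    import pandas as pd
    fit_table = pd.concat([f.summary() for f in fits])
    fit_table.index.name = "participant"

    logger.info("stage behavior GLMs")
    stay = stay_glm(cohort.choices)
    rt = rt_glm(cohort.choices)

    logger.info("stage sequenceness")
    lags = list(range(int(sq["lag_min_ms"]), int(sq["lag_max_ms"]) + 1,
                      int(sq["lag_step_ms"])))
    curve = SequencenessAnalysis(
        [[r.values for r in trials] for trials in cohort.planning.values()],
        cohort.transition_spec, lags).fit()
    threshold = curve.permutation_threshold(int(sq.get("n_perms", 500)),
                                            seed=seed)
    threshold = {k: v for k, v in threshold.items() if k != "maxima"}

    logger.info("stage link-replay")
    plan_scores = trialwise_scores(cohort.planning, cohort.transition_spec,
                                   cohort.table, sq["planning_lag_ms"],
                                   "current", "forward")
    fb_scores = trialwise_scores(cohort.feedback, cohort.transition_spec,
                                 cohort.table, sq["feedback_lag_ms"],
                                 "other", "backward")
    plan_link = link_glm(plan_scores, cohort.table, ["different_start"])
    fb_link = link_glm(fb_scores, cohort.table, ["rarity_other"])
    a = plan_link[plan_link["term"] == "different_start"].iloc[0]
    b = fb_link[fb_link["term"] == "rarity_other"].iloc[0]
    dissoc = dissociation_test(a["estimate"], a["se"], b["estimate"], b["se"])

    bundle = {
        "choices": cohort.choices,
        "fits": fit_table,
        "stay_glm": stay,
        "rt_glm": rt,
        "sequenceness": curve,
        "threshold": threshold,
        "planning_link": plan_link,
        "feedback_link": fb_link,
        "dissociation": dissoc,
        "manifest": {
            "seqreplay_version": __version__,
            "seed": seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(cohort.choices, out / "choices.tsv")
        write_tsv(fit_table.reset_index(), out / "behavior_fits.tsv")
        write_tsv(stay, out / "stay_glm.tsv")
        write_tsv(rt, out / "rt_glm.tsv")
        write_tsv(curve.to_frame(), out / "sequenceness.tsv")
        write_tsv(plan_link, out / "planning_link.tsv")
        write_tsv(fb_link, out / "feedback_link.tsv")
        write_json({"threshold": threshold, "dissociation": dissoc},
                   out / "thresholds.json")
        write_json(bundle["manifest"], out / "manifest.json")
    return bundle
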