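"""End-to-end driver: simulate -> select -> sample -> featurize -> train ->
predict -> evaluate, with a reproducibility manifest.

One global seed fans out into per-stage seeds (simulation, expert-rating
noise, chart-review sampling, model training, bootstrap), so any stage can
be re-run independently and the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import (
    select_diagnosed_cohort,
    select_potential_cohort,
    select_silver_positives,
    mental_disorder_profile,
)
from .ehr import Gender, StudyConfig
from .evaluation import EvaluationReport, evaluate_scores
from .features import build_feature_spec, featurize, select_prevalent_codes
from .model import LabeledSet, ModelBundle, predict, train_pipeline
from .sampling import assign_stratum, stratified_train_test_pair
from .synthetic import SimConfig, generate_cohort, generate_ratings

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "PipelineResult", "run_end_to_end"]

_STAGE_NAMES = ("simulate", "select", "sample", "featurize", "train", "evaluate")


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    stage_seconds: dict[str, float]
    funnel: dict[str, dict[str, int]]
    counts: dict[str, int]
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    manifest: RunManifest
    report: EvaluationReport
    bundle: ModelBundle
    scores: pd.DataFrame
    extras: dict[str, float]


def _derive_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES) - 1)
    names = ("simulate", "ratings", "sample", "train", "bootstrap")
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(names, children)
    }


def run_end_to_end(
    config: StudyConfig,
    sim: SimConfig,
    seed: int,
    out_dir: str | Path | None = None,
    gold_n: int = 228,
) -> PipelineResult:
    """Execute the full screening-study pipeline on synthetic data.

    Generates a cohort, applies the rule engine, draws paired stratified
    gold-label samples of size ``gold_n``, builds the Boolean feature space,
    trains the three-model semi-supervised pipeline, scores the held-out
    gold test set, and evaluates with bootstrap intervals. When ``out_dir``
    is given, writes ``scores.csv``, ``report.json``, ``manifest.json`` and
    the model bundle there.
    """
    config.validate()
    sim.validate()
    seeds = _derive_seeds(seed)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    records, truth, ccsr, assoc = generate_cohort(
        dataclasses.replace(sim, seed=seeds["simulate"])
    )
    by_id = {r.patient_id: r for r in records}
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    potential = select_potential_cohort(records, ccsr, config)
    diagnosed = select_diagnosed_cohort(records, ccsr, config)
    diagnosed_records = [by_id[i] for i in sorted(diagnosed.included_ids)]
    silver_pos_ids = select_silver_positives(diagnosed_records, ccsr, config)
    for stage, count in potential.counts_per_stage.items():
        logger.info("potential-cohort funnel: %-20s %d", stage, count)
    timings["select"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    potential_records = [by_id[i] for i in sorted(potential.included_ids)]
    strata = {}
    for p in potential_records:
        if p.gender is Gender.UNKNOWN_OTHER:
            continue
        profile = mental_disorder_profile(p, ccsr, config)
        strata[p.patient_id] = assign_stratum(p, profile, config)
    train_ids, test_ids = stratified_train_test_pair(
        strata, gold_n, seeds["sample"]
    )
    gold_ids = sorted(train_ids | test_ids)
    ratings = {
        l.patient_id: l
        for l in generate_ratings(
            [by_id[i] for i in gold_ids], truth, sim, seed=seeds["ratings"]
        )
    }
    timings["sample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    codes = select_prevalent_codes(diagnosed_records, potential_records, config)
    # the target code itself must never be a screening feature
    codes.discard(cohort_mod.BOPD_ICD10)
    spec = build_feature_spec(codes, ccsr, assoc, potential_records, config)
    X_potential = featurize(potential_records, spec, config)
    X_silver_pos = featurize(
        [by_id[i] for i in sorted(silver_pos_ids)], spec, config
    )

    def gold_set(ids: set[str]) -> LabeledSet:
        ordered = sorted(ids)
        return LabeledSet(
            X=X_potential.loc[ordered],
            y=np.array([ratings[i].positive for i in ordered], dtype=int),
            provenance="gold",
            classic=np.array([ratings[i].classic for i in ordered], dtype=bool),
            categories=np.array(
                [ratings[i].category.value for i in ordered], dtype=object
            ),
        )

    gold_train = gold_set(train_ids)
    gold_test = gold_set(test_ids)
    X_pool = X_potential.drop(index=gold_ids)
    timings["featurize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bundle = train_pipeline(
        gold_train, X_pool, X_silver_pos, config, seeds["train"], spec=spec
    )
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scores = predict(bundle, gold_test.X)
    report = evaluate_scores(
        scores["p_final"].to_numpy(),
        gold_test.y,
        gold_test.classic,
        config,
        seeds["bootstrap"],
    )
    extras = {
        "gold_model_test_auroc": _safe_auroc(
            bundle.model1.predict_proba(gold_test.X), gold_test.y
        ),
        "main_model_test_auroc": _safe_auroc(
            scores["p2"].to_numpy(), gold_test.y
        ),
        "n_silver_positives": float(len(X_silver_pos)),
    }
    timings["evaluate"] = time.perf_counter() - t0

    payload = json.dumps(
        {"config": config.to_dict(), "sim_n": sim.n_patients, "gold_n": gold_n},
        sort_keys=True,
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(payload.encode()).hexdigest()[:16],
        seeds=seeds,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        funnel={
            "potential": dict(potential.counts_per_stage),
            "diagnosed": dict(diagnosed.counts_per_stage),
        },
        counts={
            "patients": len(records),
            "potential_cohort": len(potential.included_ids),
            "diagnosed_cohort": len(diagnosed.included_ids),
            "silver_positives": len(silver_pos_ids),
            "gold_train": len(train_ids),
            "gold_test": len(test_ids),
        },
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        scores_out = scores.copy()
        scores_out.insert(0, "patient_id", scores_out.index)
        scores_out.to_csv(out_dir / "scores.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        bundle.save(out_dir / "bundle")
        manifest.outputs = [
            str(out_dir / "scores.csv"),
            str(out_dir / "report.json"),
            str(out_dir / "bundle"),
            str(out_dir / "manifest.json"),
        ]
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=1)

    return PipelineResult(
        manifest=manifest,
        report=report,
        bundle=bundle,
        scores=scores,
        extras=extras,
    )


def _safe_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .evaluation import auroc

    try:
        return auroc(scores, labels)
    except ValueError:
        return float("nan")
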