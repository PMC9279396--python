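"""Classifier evaluation: AUROC, threshold metrics and bootstrap intervals.

AUROC is computed as the Mann-Whitney rank statistic — the probability that
a random positive outscores a random negative, with ties counted 1/2.
Threshold metrics (accuracy, PPV, sensitivity, specificity, and sensitivity
restricted to classic-BoPD cases) derive from the confusion matrix at the
strict decision threshold. Confidence intervals are percentile bootstrap
over patient-level resamples.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .ehr import StudyConfig

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_NAMES",
    "EvaluationReport",
    "auroc",
    "threshold_metrics",
    "bootstrap_ci",
    "evaluate_scores",
]

METRIC_NAMES = (
    "auroc",
    "accuracy",
    "ppv",
    "sensitivity",
    "specificity",
    "classic_sensitivity",
)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC with ties counted 1/2.

    Raises ValueError when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _confusion_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    classic: np.ndarray | None,
    threshold: float,
) -> dict[str, float | None]:
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    n = len(labels)
    out: dict[str, float | None] = {
        "accuracy": (tp + tn) / n if n else None,
        "ppv": tp / (tp + fp) if (tp + fp) else None,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
    }
    if classic is not None and classic.any():
        out["classic_sensitivity"] = float(pred[classic].mean())
    else:
        out["classic_sensitivity"] = None
    return out


def threshold_metrics(
    scores,
    labels,
    classic_flags,
    config: StudyConfig,
) -> dict[str, float | None]:
    """Confusion-matrix metrics at the strict decision threshold.

    ``classic_flags`` marks the classic-BoPD subset of the positives;
    classic sensitivity is the screen-positive fraction among them. PPV is
    ``None`` (with a warning) when nothing is predicted positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classic = (
        None if classic_flags is None else np.asarray(classic_flags, dtype=bool)
    )
    if classic is not None and np.any(classic & (labels == 0)):
        raise ValueError("classic flags must be a subset of the positives")
    out = _confusion_metrics(scores, labels, classic, config.decision_threshold)
    if out["ppv"] is None:
        warnings.warn("no predicted positives; PPV undefined", stacklevel=2)
    return out


def _all_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    classic: np.ndarray | None,
    threshold: float,
) -> dict[str, float | None]:
    out = _confusion_metrics(scores, labels, classic, threshold)
    try:
        out["auroc"] = auroc(scores, labels)
    except ValueError:
        out["auroc"] = None
    return out


@dataclass
class MetricSummary:
    point: float | None
    lower: float | None
    upper: float | None
    n_skipped: int = 0


@dataclass
class EvaluationReport:
    """Point estimates with percentile bootstrap confidence intervals."""

    metrics: dict[str, MetricSummary]
    n: int
    threshold: float
    seed: int
    bootstrap_reps: int
    ci_level: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "threshold": self.threshold,
            "seed": self.seed,
            "bootstrap_reps": self.bootstrap_reps,
            "ci_level": self.ci_level,
            "metrics": {
                k: dataclasses.asdict(v) for k, v in self.metrics.items()
            },
        }


def bootstrap_ci(
    scores,
    labels,
    classic_flags,
    config: StudyConfig,
    seed: int,
) -> dict[str, tuple[float | None, float | None, int]]:
    """Percentile bootstrap (lower, upper, n_skipped) per metric.

    Patients are resampled with replacement ``config.bootstrap_reps``
    times; replicates where a metric is undefined (single class, no
    predicted positives, no classic cases drawn) are skipped for that
    metric. A metric undefined in more than half the replicates gets a
    missing interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classic = (
        None if classic_flags is None else np.asarray(classic_flags, dtype=bool)
    )
    n = len(scores)
    if n < 2:
        raise ValueError("bootstrap requires n >= 2")
    rng = np.random.default_rng(seed)
    reps = int(config.bootstrap_reps)
    values: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        rep = _all_metrics(
            scores[idx],
            labels[idx],
            None if classic is None else classic[idx],
            config.decision_threshold,
        )
        for m in METRIC_NAMES:
            if rep[m] is not None:
                values[m].append(rep[m])
    alpha = 1.0 - config.ci_level
    out: dict[str, tuple[float | None, float | None, int]] = {}
    for m in METRIC_NAMES:
        good = values[m]
        skipped = reps - len(good)
        if skipped > reps / 2:
            logger.warning(
                "metric %s undefined in %d/%d replicates; CI missing",
                m, skipped, reps,
            )
            out[m] = (None, None, skipped)
        else:
            lo, hi = np.quantile(good, [alpha / 2, 1 - alpha / 2])
            out[m] = (float(lo), float(hi), skipped)
    return out


def evaluate_scores(
    scores,
    labels,
    classic_flags,
    config: StudyConfig,
    seed: int,
) -> EvaluationReport:
    """Full evaluation: point estimates plus bootstrap intervals."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classic = (
        None if classic_flags is None else np.asarray(classic_flags, dtype=bool)
    )
    points = _all_metrics(scores, labels, classic, config.decision_threshold)
    cis = bootstrap_ci(scores, labels, classic, config, seed)
    metrics = {
        m: MetricSummary(
            point=points[m],
            lower=cis[m][0],
            upper=cis[m][1],
            n_skipped=cis[m][2],
        )
        for m in METRIC_NAMES
    }
    return EvaluationReport(
        metrics=metrics,
        n=len(scores),
        threshold=config.decision_threshold,
        seed=seed,
        bootstrap_reps=config.bootstrap_reps,
        ci_level=config.ci_level,
    )
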