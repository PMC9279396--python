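"""Semi-supervised screening pipeline.

Three L1-regularized logistic regressions over one Boolean feature space:

* **Model 1** (seed model) — fit on the small expert-rated gold set,
  positive class "most likely BoPD" (category E);
* **Model 2** (main model) — fit on the much larger silver-label set:
  silver positives are rule-selected from the EHR-diagnosed BoPD cohort,
  silver negatives are a random draw from potential-cohort patients that
  Model 1 predicts negative, sized to preserve the gold class ratio;
* **Model 3** (adjustment model) — fit on the gold subset restricted to
  categories E and B (severe psychotic/substance abuse) to push down
  psychotic/substance false positives.

The combined score is ``p_final = p2 if p3 > 0.5 else p2 * p3``, so the
adjustment can only lower a patient's score, never raise it.

Regularization strength is selected from a fixed 13-point log-spaced grid
spanning six orders of magnitude by mean validation AUROC under stratified
k-fold cross-validation; ties prefer the sparser (stronger) penalty. The
penalty applies to the *mean* log-loss, so the fit does not depend on how
many times each distinct row is replicated.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .ehr import StudyConfig
from .evaluation import auroc
from .features import FeatureSpec
from .sampling import RatingCategory

logger = logging.getLogger(__name__)

__all__ = [
    "REGULARIZATION_GRID",
    "LabeledSet",
    "L1LogisticModel",
    "ModelBundle",
    "ScreeningScore",
    "train_l1_logreg",
    "silver_negative_count",
    "build_silver_set",
    "train_pipeline",
    "predict",
    "classify",
]

# 13 log-spaced inverse penalties on the mean log-loss, spanning 6 orders
REGULARIZATION_GRID = tuple(np.logspace(-1.0, 5.0, 13))


@dataclass
class LabeledSet:
    """A feature matrix with binary labels (positive = most likely BoPD)."""

    X: pd.DataFrame
    y: np.ndarray
    provenance: str  # "gold" or "silver"
    classic: np.ndarray | None = None
    categories: np.ndarray | None = None  # A-E strings, gold sets only

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != len(self.X):
            raise ValueError("labels not aligned to feature rows")
        if self.provenance == "silver" and self.classic is not None:
            raise ValueError("silver sets carry no classic flags")


@dataclass
class L1LogisticModel:
    """A fitted sparse logistic model.

    ``C`` is the selected inverse strength of the L1 penalty on the mean
    log-loss; ``cv_auroc`` is the mean validation-fold AUROC at that C.
    """

    coef: pd.Series
    intercept: float
    C: float
    cv_auroc: float
    feature_names: list[str]

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.feature_names].to_numpy(dtype=float)
        return Z @ self.coef.to_numpy() + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class for each row."""
        z = self.decision(X)
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.to_dict(),
            "intercept": self.intercept,
            "C": self.C,
            "cv_auroc": self.cv_auroc,
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "L1LogisticModel":
        names = list(d["feature_names"])
        return cls(
            coef=pd.Series({n: d["coef"][n] for n in names}, index=names),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            cv_auroc=float(d["cv_auroc"]),
            feature_names=names,
        )


def _fit_at(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> LogisticRegression:
    # penalty applies to the mean loss: sklearn's C multiplies the sum
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=C / len(y),
        solver="liblinear",
        random_state=seed,
        max_iter=1000,
        tol=1e-6,
    )
    clf.fit(X, y)
    return clf


def train_l1_logreg(
    labeled: LabeledSet | tuple[pd.DataFrame, np.ndarray],
    config: StudyConfig,
    seed: int,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> L1LogisticModel:
    """Fit an L1 logistic model with CV-selected regularization strength.

    The strength is chosen from :data:`REGULARIZATION_GRID` by mean
    validation-fold AUROC over stratified ``config.cv_folds``-fold CV (ties
    go to the strongest penalty); the final model is refit on all rows.
    ``folds`` overrides the CV split with explicit (train, test) index
    arrays. All-constant feature columns are dropped with a warning.
    """
    if isinstance(labeled, LabeledSet):
        X_df, y = labeled.X, labeled.y
    else:
        X_df, y = labeled
        y = np.asarray(y, dtype=int)

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    constant = [c for c in X_df.columns if X_df[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping {len(constant)} all-constant feature(s): {constant[:5]}...",
            stacklevel=2,
        )
        X_df = X_df.drop(columns=constant)
    X = X_df.to_numpy(dtype=float)

    if folds is None:
        n_splits = int(config.cv_folds)
        if counts.min() < n_splits:
            raise ValueError(
                f"need >= {n_splits} rows per class for {n_splits}-fold CV; "
                f"smallest class has {counts.min()}"
            )
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))

    mean_auroc = np.empty(len(REGULARIZATION_GRID))
    for j, C in enumerate(REGULARIZATION_GRID):
        scores = []
        for tr, te in folds:
            clf = _fit_at(X[tr], y[tr], C, seed)
            p = clf.predict_proba(X[te])[:, 1]
            if len(np.unique(y[te])) < 2:
                continue  # unscorable fold
            scores.append(auroc(p, y[te]))
        mean_auroc[j] = float(np.mean(scores)) if scores else 0.5

    # grid is ascending in C, so argmax ties resolve to the strongest penalty
    best = int(np.argmax(mean_auroc))
    C = float(REGULARIZATION_GRID[best])
    clf = _fit_at(X, y, C, seed)
    return L1LogisticModel(
        coef=pd.Series(clf.coef_[0], index=X_df.columns),
        intercept=float(clf.intercept_[0]),
        C=C,
        cv_auroc=float(mean_auroc[best]),
        feature_names=list(X_df.columns),
    )


def silver_negative_count(n_pos: int, config: StudyConfig) -> int:
    """Silver-negative count preserving the gold positive:negative ratio.

    ``floor(n_pos * gold_ratio_neg / gold_ratio_pos)`` — e.g. 5961 silver
    positives at a 66:162 gold ratio call for 14,631 silver negatives.
    """
    if n_pos <= 0:
        raise ValueError("n_pos must be positive")
    return math.floor(n_pos * config.gold_ratio_neg / config.gold_ratio_pos)


def build_silver_set(
    model1: L1LogisticModel,
    pool_X: pd.DataFrame,
    silver_pos_X: pd.DataFrame,
    config: StudyConfig,
    seed: int | np.random.Generator,
) -> LabeledSet:
    """Assemble the silver-label training set.

    Silver negatives are a seeded simple random sample (without
    replacement) from pool rows with Model-1 probability strictly below the
    decision threshold; the pool must already exclude gold-label patients
    and the silver positives.
    """
    overlap = pool_X.index.intersection(silver_pos_X.index)
    if len(overlap):
        raise ValueError(
            f"{len(overlap)} silver-positive patient(s) present in the "
            "unlabelled pool"
        )
    n_pos = len(silver_pos_X)
    n_neg = silver_negative_count(n_pos, config)
    p1 = model1.predict_proba(pool_X)
    negative_ids = pool_X.index[p1 < config.decision_threshold]
    if len(negative_ids) < n_neg:
        raise ValueError(
            f"need {n_neg} predicted-negative patients but pool has only "
            f"{len(negative_ids)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(negative_ids), size=n_neg, replace=False)
    X = pd.concat([silver_pos_X, pool_X.loc[chosen]], axis=0)
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return LabeledSet(X=X, y=y, provenance="silver")


@dataclass
class ModelBundle:
    """The deployable screening artifact: three models + spec + threshold."""

    model1: L1LogisticModel
    model2: L1LogisticModel
    model3: L1LogisticModel
    spec: FeatureSpec
    decision_threshold: float

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("model1", "model2", "model3"):
            with open(directory / f"{name}.json", "w") as fh:
                json.dump(getattr(self, name).to_dict(), fh, indent=1)
        self.spec.to_json(directory / "feature_spec.json")
        with open(directory / "bundle.json", "w") as fh:
            json.dump({"decision_threshold": self.decision_threshold}, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        models = {}
        for name in ("model1", "model2", "model3"):
            with open(directory / f"{name}.json") as fh:
                models[name] = L1LogisticModel.from_dict(json.load(fh))
        spec = FeatureSpec.from_json(directory / "feature_spec.json")
        with open(directory / "bundle.json") as fh:
            meta = json.load(fh)
        return cls(
            spec=spec,
            decision_threshold=float(meta["decision_threshold"]),
            **models,
        )


def train_pipeline(
    gold_train: LabeledSet,
    potential_X: pd.DataFrame,
    silver_pos_X: pd.DataFrame,
    config: StudyConfig,
    seed: int,
    spec: FeatureSpec | None = None,
) -> ModelBundle:
    """Run the full semi-supervised training pipeline.

    ``potential_X`` must hold the unlabelled potential-cohort patients
    (gold patients removed). Model 3 trains on the gold rows rated E or B
    with E positive; gold sets lacking either category are rejected.
    """
    if gold_train.categories is None:
        raise ValueError("gold training set must carry rating categories")
    ss = np.random.SeedSequence(seed)
    s_m1, s_silver, s_m2, s_m3 = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]

    overlap = potential_X.index.intersection(gold_train.X.index)
    if len(overlap):
        raise ValueError(
            f"{len(overlap)} gold patient(s) present in the unlabelled pool"
        )

    model1 = train_l1_logreg(gold_train, config, s_m1)
    silver = build_silver_set(model1, potential_X, silver_pos_X, config, s_silver)
    model2 = train_l1_logreg(silver, config, s_m2)

    cats = np.asarray(gold_train.categories, dtype=object)
    mask = np.isin(cats, [RatingCategory.E.value, RatingCategory.B.value])
    if not (cats == RatingCategory.E.value).any() or not (
        cats == RatingCategory.B.value
    ).any():
        raise ValueError(
            "adjustment model needs both category E and category B rows"
        )
    sub = LabeledSet(
        X=gold_train.X.loc[mask],
        y=(cats[mask] == RatingCategory.E.value).astype(int),
        provenance="gold",
    )
    model3 = train_l1_logreg(sub, config, s_m3)

    if spec is None:
        spec = FeatureSpec(features=[], freq_cutoffs=(0.0, 0.0))
    return ModelBundle(
        model1=model1,
        model2=model2,
        model3=model3,
        spec=spec,
        decision_threshold=config.decision_threshold,
    )


def combine_probabilities(p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Adjustment rule: ``p_final = p2`` when ``p3 > 0.5``, else ``p2*p3``."""
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    return np.where(p3 > 0.5, p2, p2 * p3)


@dataclass(frozen=True)
class ScreeningScore:
    p2: float
    p3: float

    @property
    def p_final(self) -> float:
        return float(combine_probabilities(self.p2, self.p3))


def predict(bundle: ModelBundle, X: pd.DataFrame) -> pd.DataFrame:
    """Per-patient screening scores (p2, p3, p_final, screen_positive)."""
    missing = set(bundle.model2.feature_names) - set(X.columns)
    if missing:
        raise ValueError(f"feature matrix missing columns: {sorted(missing)[:5]}")
    p2 = bundle.model2.predict_proba(X)
    p3 = bundle.model3.predict_proba(X)
    p_final = combine_probabilities(p2, p3)
    return pd.DataFrame(
        {
            "p2": p2,
            "p3": p3,
            "p_final": p_final,
            "screen_positive": p_final > bundle.decision_threshold,
        },
        index=X.index,
    )


def classify(p_final: float | np.ndarray, config: StudyConfig) -> bool | np.ndarray:
    """Screen positive iff ``p_final`` strictly exceeds the threshold."""
    result = np.asarray(p_final) > config.decision_threshold
    return bool(result) if np.isscalar(p_final) else result
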