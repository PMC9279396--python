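"""Semi-supervised pipeline: trainer, silver-set construction, score
combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bopdscreen.ehr import StudyConfig
from bopdscreen.evaluation import auroc
from bopdscreen.model import (
    L1LogisticModel,
    LabeledSet,
    build_silver_set,
    classify,
    combine_probabilities,
    predict,
    silver_negative_count,
    train_l1_logreg,
    train_pipeline,
)
from bopdscreen.synthetic import planted_logistic_features


def _features(n, k, rng, prob=0.4):
    return pd.DataFrame(
        rng.random((n, k)) < prob,
        columns=[f"x{j}" for j in range(k)],
        index=[f"p{i}" for i in range(n)],
    )


class TestTrainer:
    def test_separable_toy_set_reaches_perfect_training_auroc(self, config):
        rng = np.random.default_rng(0)
        X = _features(60, 2, rng)
        y = X["x0"].to_numpy().astype(int)  # label equals first feature
        model = train_l1_logreg((X, y), config, seed=1)
        assert auroc(model.predict_proba(X), y) == 1.0
        assert model.coef["x0"] > 0

    def test_null_labels_give_chance_level_cv_auroc(self, config):
        rng = np.random.default_rng(1)
        X = _features(500, 8, rng)
        y = (rng.random(500) < 0.5).astype(int)  # independent of features
        model = train_l1_logreg((X, y), config, seed=2)
        assert 0.4 <= model.cv_auroc <= 0.6

    def test_single_class_rejected(self, config):
        rng = np.random.default_rng(2)
        X = _features(40, 3, rng)
        with pytest.raises(ValueError, match="single class"):
            train_l1_logreg((X, np.ones(40, dtype=int)), config, seed=0)

    def test_constant_features_dropped_with_warning(self, config):
        rng = np.random.default_rng(3)
        X = _features(60, 3, rng)
        X["const"] = True
        y = X["x0"].to_numpy().astype(int)
        with pytest.warns(UserWarning, match="constant"):
            model = train_l1_logreg((X, y), config, seed=1)
        assert "const" not in model.feature_names

    def test_duplicated_dataset_invariance_at_matched_folds(self, config):
        """Replicating every row (with matched fold composition) must not
        change the selected strength or the coefficients."""
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(4)
        X, y = planted_logistic_features(
            120, [1.5, -1.0, 0.0, 0.5], 0.0, 0.4, rng
        )
        folds = list(
            StratifiedKFold(n_splits=5, shuffle=True, random_state=0).split(X, y)
        )
        n = len(y)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        folds2 = [
            (np.concatenate([tr, tr + n]), np.concatenate([te, te + n]))
            for tr, te in folds
        ]
        m1 = train_l1_logreg((X, y), config, seed=9, folds=folds)
        m2 = train_l1_logreg((X2, y2), config, seed=9, folds=folds2)
        assert m1.C == m2.C
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-3)
        np.testing.assert_allclose(m1.intercept, m2.intercept, atol=1e-3)


class TestSilverNegativeCount:
    @pytest.mark.parametrize(
        "n_pos,expected",
        [(66, 162), (5961, 14631), (100, 245), (10, 24), (1, 2)],
    )
    def test_gold_ratio_floor(self, config, n_pos, expected):
        assert silver_negative_count(n_pos, config) == expected

    def test_nonpositive_rejected(self, config):
        with pytest.raises(ValueError):
            silver_negative_count(0, config)

    def test_ratio_within_integer_truncation(self, config):
        target = config.gold_ratio_neg / config.gold_ratio_pos
        for n_pos in range(1, 400):
            ratio = silver_negative_count(n_pos, config) / n_pos
            assert target - 1 / n_pos < ratio <= target


def _constant_model(names, intercept):
    return L1LogisticModel(
        coef=pd.Series(0.0, index=names),
        intercept=intercept,
        C=1.0,
        cv_auroc=0.5,
        feature_names=list(names),
    )


class TestBuildSilverSet:
    def test_sizes_and_labels(self, config):
        rng = np.random.default_rng(5)
        pool = _features(100, 2, rng)
        pos = _features(10, 2, rng).set_axis([f"s{i}" for i in range(10)])
        model1 = _constant_model(pool.columns, intercept=-2.0)  # p1 ~ 0.12
        silver = build_silver_set(model1, pool, pos, config, seed=0)
        assert silver.provenance == "silver"
        assert int(silver.y.sum()) == 10
        assert len(silver.y) == 10 + 24  # floor(10*162/66) = 24

    def test_probability_exactly_half_is_not_negative(self, config):
        rng = np.random.default_rng(6)
        pool = _features(30, 2, rng)
        pos = _features(2, 2, rng).set_axis(["s0", "s1"])
        model1 = _constant_model(pool.columns, intercept=0.0)  # p1 = 0.5 exactly
        with pytest.raises(ValueError, match="only 0"):
            build_silver_set(model1, pool, pos, config, seed=0)

    def test_overlap_with_positives_rejected(self, config):
        rng = np.random.default_rng(7)
        pool = _features(30, 2, rng)
        pos = pool.iloc[:3]
        model1 = _constant_model(pool.columns, intercept=-2.0)
        with pytest.raises(ValueError, match="pool"):
            build_silver_set(model1, pool, pos, config, seed=0)

    def test_seeded_reproducibility(self, config):
        rng = np.random.default_rng(8)
        pool = _features(200, 3, rng)
        pos = _features(20, 3, rng).set_axis([f"s{i}" for i in range(20)])
        model1 = _constant_model(pool.columns, intercept=-1.0)
        a = build_silver_set(model1, pool, pos, config, seed=3)
        b = build_silver_set(model1, pool, pos, config, seed=3)
        assert list(a.X.index) == list(b.X.index)


class TestCombineProbabilities:
    @pytest.mark.parametrize(
        "p2,p3,expected",
        [(0.8, 0.6, 0.8), (0.8, 0.4, 0.32), (0.0, 0.9, 0.0), (0.0, 0.1, 0.0)],
    )
    def test_published_branches(self, p2, p3, expected):
        assert combine_probabilities(p2, p3) == pytest.approx(expected)

    @given(
        p2=st.floats(0, 1, allow_nan=False),
        p3=st.floats(0, 1, allow_nan=False),
    )
    def test_adjustment_never_raises_the_score(self, p2, p3):
        p_final = float(combine_probabilities(p2, p3))
        assert 0.0 <= p_final <= p2
        if p3 > 0.5:
            assert p_final == p2
        else:
            assert p_final == pytest.approx(p2 * p3)

    @given(
        p2=st.floats(0.01, 1, allow_nan=False),
        p3a=st.floats(0, 0.5),
        p3b=st.floats(0, 0.5),
    )
    def test_monotone_in_p3_below_half(self, p2, p3a, p3b):
        lo, hi = sorted([p3a, p3b])
        assert combine_probabilities(p2, lo) <= combine_probabilities(p2, hi)

    def test_half_falls_to_multiplicative_branch(self):
        assert combine_probabilities(0.8, 0.5) == pytest.approx(0.4)


class TestClassify:
    @pytest.mark.parametrize(
        "p,expected", [(0.51, True), (0.5, False), (0.49, False)]
    )
    def test_strict_threshold(self, config, p, expected):
        assert classify(p, config) is expected


class TestTrainPipeline:
    def _gold(self, rng, n=228):
        X, y = planted_logistic_features(
            n, [2.0, -1.5, 1.0, 0.0, 0.0, -0.5], -1.0, 0.4, rng
        )
        X.index = [f"g{i}" for i in range(n)]
        cats = np.where(
            y == 1, "E", rng.choice(["A", "B", "C", "D"], size=n)
        ).astype(object)
        return LabeledSet(
            X=X, y=y, provenance="gold",
            classic=(y == 1) & (rng.random(n) < 0.2),
            categories=cats,
        )

    def test_end_to_end_bundle(self, config):
        rng = np.random.default_rng(11)
        gold = self._gold(rng)
        pool, _ = planted_logistic_features(
            800, [2.0, -1.5, 1.0, 0.0, 0.0, -0.5], -1.0, 0.4, rng
        )
        pool.index = [f"u{i}" for i in range(800)]
        pos, _ = planted_logistic_features(
            60, [2.0, -1.5, 1.0, 0.0, 0.0, -0.5], 2.0, 0.5, rng
        )
        pos.index = [f"s{i}" for i in range(60)]
        bundle = train_pipeline(gold, pool, pos, config, seed=3)
        scores = predict(bundle, pool)
        assert set(scores.columns) == {"p2", "p3", "p_final", "screen_positive"}
        assert ((scores["p_final"] <= scores["p2"]) | np.isclose(
            scores["p_final"], scores["p2"])).all()
        # adjustment never creates positives
        assert not (scores["screen_positive"] & (scores["p2"] <= 0.5)).any()

    def test_model3_trains_on_e_and_b_subset(self, config):
        rng = np.random.default_rng(12)
        gold = self._gold(rng)
        n_e = int((np.asarray(gold.categories) == "E").sum())
        n_b = int((np.asarray(gold.categories) == "B").sum())
        pool, _ = planted_logistic_features(
            600, [2.0, -1.5, 1.0, 0.0, 0.0, -0.5], -1.0, 0.4, rng
        )
        pool.index = [f"u{i}" for i in range(600)]
        pos = pool.iloc[:40].copy()
        pos.index = [f"s{i}" for i in range(40)]
        bundle = train_pipeline(gold, pool.iloc[40:], pos, config, seed=3)
        assert n_e >= 10 and n_b >= 10  # subset really contains both classes
        assert bundle.model3 is not None

    def test_missing_category_b_rejected(self, config):
        rng = np.random.default_rng(13)
        gold = self._gold(rng)
        cats = np.asarray(gold.categories, dtype=object)
        cats[cats == "B"] = "C"
        gold.categories = cats
        pool, _ = planted_logistic_features(
            600, [2.0, -1.5, 1.0, 0.0, 0.0, -0.5], -1.0, 0.4, rng
        )
        pool.index = [f"u{i}" for i in range(600)]
        pos = pool.iloc[:40].copy()
        pos.index = [f"s{i}" for i in range(40)]
        with pytest.raises(ValueError, match="category"):
            train_pipeline(gold, pool.iloc[40:], pos, config, seed=3)

    def test_gold_patients_in_pool_rejected(self, config):
        rng = np.random.default_rng(14)
        gold = self._gold(rng, n=120)
        pool = gold.X.iloc[:50]
        with pytest.raises(ValueError, match="gold"):
            train_pipeline(gold, pool, gold.X.iloc[50:60], config, seed=0)


def test_bundle_roundtrip(tmp_path, config):
    rng = np.random.default_rng(15)
    X, y = planted_logistic_features(200, [1.5, -1.0, 0.5], -0.5, 0.4, rng)
    model = train_l1_logreg((X, y), config, seed=1)
    from bopdscreen.features import FeatureSpec
    from bopdscreen.model import ModelBundle

    bundle = ModelBundle(
        model1=model, model2=model, model3=model,
        spec=FeatureSpec(features=[], freq_cutoffs=(1.0, 2.0)),
        decision_threshold=0.5,
    )
    bundle.save(tmp_path / "b")
    back = ModelBundle.load(tmp_path / "b")
    np.testing.assert_array_equal(
        predict(bundle, X)["p_final"], predict(back, X)["p_final"]
    )
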