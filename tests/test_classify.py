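import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regiodist import (
    BoostedEnsemble,
    DataError,
    DecisionStump,
    ensemble_score,
    feature_importance,
    fit_stump,
    loocv_evaluate,
    roc_from_scores,
    train_rusboost,
)


def stump_error(stump, X, y, w):
    votes = stump.votes(X)
    return float(np.sum(w * (1.0 - y * votes) / 2.0))


def brute_force_best_error(X, y, w):
    """Exhaustive search over every (region, midpoint, polarity)."""
    best = np.inf
    for region in range(X.shape[1]):
        v = np.unique(X[:, region])
        thresholds = (v[:-1] + v[1:]) / 2.0 if v.size > 1 else v[:1]
        for thr in thresholds:
            for pol in (1, -1):
                err = stump_error(DecisionStump(region, thr, pol), X, y, w)
                best = min(best, err)
    return best


class TestFitStump:
    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 21))
            r = int(rng.integers(1, 6))
            X = rng.normal(size=(n, r)).round(2)  # ties likely
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            if np.all(y == y[0]):
                y[0] = -y[0]
            w = rng.random(n) + 0.05
            w = w / w.sum()
            stump = fit_stump(X, y, w)
            assert stump_error(stump, X, y, w) == pytest.approx(
                brute_force_best_error(X, y, w), abs=1e-12
            )

    def test_separable_data_gets_zero_error_in_the_gap(self):
        X = np.array([[0.1], [0.2], [0.3], [1.1], [1.2], [1.3]])
        y = np.array([-1, -1, -1, 1, 1, 1], float)
        w = np.full(6, 1 / 6)
        stump = fit_stump(X, y, w)
        assert stump_error(stump, X, y, w) == 0.0
        assert 0.3 < stump.threshold < 1.1
        assert stump.polarity == 1

    def test_all_identical_values_is_degenerate(self):
        X = np.ones((5, 1))
        y = np.array([1, 1, -1, -1, -1], float)
        w = np.array([0.1, 0.1, 0.3, 0.3, 0.2])
        stump = fit_stump(X, y, w)
        assert stump.degenerate
        assert stump_error(stump, X, y, w) == pytest.approx(0.2)  # min class weight

    def test_tie_breaks_prefer_lowest_region_then_threshold(self):
        # both regions separate perfectly; region 0 must win
        X = np.array([[0.0, 10.0], [1.0, 11.0], [2.0, 12.0], [3.0, 13.0]])
        y = np.array([-1, -1, 1, 1], float)
        w = np.full(4, 0.25)
        stump = fit_stump(X, y, w)
        assert stump.region_index == 0
        assert stump.threshold == pytest.approx(1.5)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            fit_stump(np.zeros((3, 1)), np.ones(3), np.full(3, 1 / 3))

    def test_nan_features_abstain_at_half_weight(self):
        X = np.array([[0.0], [1.0], [np.nan]])
        y = np.array([-1, 1, 1], float)
        w = np.full(3, 1 / 3)
        stump = fit_stump(X, y, w)
        assert stump_error(stump, X, y, w) == pytest.approx(1 / 6)


class TestRUSBoost:
    def test_separable_single_region_zero_training_error_after_round_one(self, rng):
        X = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 8)])[:, None]
        labels = np.array(["CN"] * 20 + ["AD"] * 8)
        model = train_rusboost(X, labels, rounds=1, seed=0)
        scores = ensemble_score(model, X)
        assert np.all((scores > 0) == (labels == "AD"))

    def test_same_seed_is_bit_identical(self, rng):
        X = rng.normal(size=(30, 5))
        labels = np.array(["CN"] * 20 + ["AD"] * 10)
        m1 = train_rusboost(X, labels, rounds=25, seed=42)
        m2 = train_rusboost(X, labels, rounds=25, seed=42)
        assert m1.to_dict() == m2.to_dict()

    def test_beats_majority_base_rate_with_planted_regions(self, rng):
        n_cn, n_ad, regions = 30, 10, 20
        X = rng.normal(size=(n_cn + n_ad, regions))
        X[n_cn:, :3] += 1.5  # three informative regions
        labels = np.array(["CN"] * n_cn + ["AD"] * n_ad)
        model = train_rusboost(X, labels, rounds=40, seed=3)
        scores = ensemble_score(model, X)
        errors = np.mean((scores > 0) != (labels == "AD"))
        assert errors < n_ad / (n_cn + n_ad)  # majority-class base rate

    def test_single_class_and_bad_rounds_rejected(self):
        X = np.zeros((4, 1))
        with pytest.raises(DataError):
            train_rusboost(X, np.array(["CN"] * 4), rounds=5)
        from regiodist import ConfigError

        with pytest.raises(ConfigError):
            train_rusboost(
                X, np.array(["CN", "CN", "AD", "AD"]), rounds=0
            )


class TestEnsembleScore:
    def test_empty_ensemble_scores_zero(self):
        model = BoostedEnsemble(n_features=2)
        assert ensemble_score(model, np.array([1.0, 2.0])) == 0.0

    def test_single_stump_gives_plus_alpha_on_patient_side(self):
        model = BoostedEnsemble(
            stumps=[DecisionStump(0, 0.5, 1, alpha=0.7)], n_features=1
        )
        assert ensemble_score(model, np.array([0.9])) == pytest.approx(0.7)
        assert ensemble_score(model, np.array([0.1])) == pytest.approx(-0.7)

    def test_three_stump_hand_computed_sum(self):
        model = BoostedEnsemble(
            stumps=[
                DecisionStump(0, 1.0, 1, alpha=0.5),
                DecisionStump(1, 2.0, -1, alpha=0.25),
                DecisionStump(0, 5.0, 1, alpha=1.0),
            ],
            n_features=2,
        )
        # row (3, 1): votes +1, +1, -1 -> 0.5 + 0.25 - 1.0
        assert ensemble_score(model, np.array([3.0, 1.0])) == pytest.approx(-0.25)

    def test_missing_feature_abstains(self):
        model = BoostedEnsemble(
            stumps=[
                DecisionStump(0, 0.0, 1, alpha=0.5),
                DecisionStump(1, 0.0, 1, alpha=0.3),
            ],
            n_features=2,
        )
        assert ensemble_score(model, np.array([1.0, np.nan])) == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        model = BoostedEnsemble(n_features=3)
        with pytest.raises(DataError):
            ensemble_score(model, np.array([1.0]))


class TestImportance:
    def test_single_region_takes_everything(self):
        model = BoostedEnsemble(
            stumps=[DecisionStump(2, 0.0, 1, alpha=1.3)], n_features=4
        )
        imp = feature_importance([model])
        assert imp.iloc[2] == pytest.approx(100.0)
        assert imp.drop(imp.index[2]).sum() == 0.0

    def test_two_ensembles_average_to_fifty_fifty(self):
        m1 = BoostedEnsemble(stumps=[DecisionStump(0, 0, 1, alpha=2.0)], n_features=2)
        m2 = BoostedEnsemble(stumps=[DecisionStump(1, 0, 1, alpha=0.5)], n_features=2)
        imp = feature_importance([m1, m2])
        np.testing.assert_allclose(imp.to_numpy(), [50.0, 50.0])

    def test_sums_to_100(self, rng):
        X = rng.normal(size=(24, 6))
        X[16:, 1] += 1.0
        labels = np.array(["CN"] * 16 + ["AD"] * 8)
        models = [
            train_rusboost(X, labels, rounds=15, seed=s) for s in range(3)
        ]
        imp = feature_importance(models)
        assert imp.sum() == pytest.approx(100.0, abs=1e-9)
        assert (imp >= 0).all()

    def test_duplicated_informative_column_splits_importance(self, rng):
        """Redundant copies share, and never increase, the combined relevance."""
        singles, pairs = [], []
        for seed in range(10):
            local = np.random.default_rng(seed)
            X = local.normal(size=(36, 5))
            X[24:, 0] += 2.0
            labels = np.array(["CN"] * 24 + ["AD"] * 12)
            imp1 = feature_importance(
                [train_rusboost(X, labels, rounds=30, seed=seed)]
            )
            X_dup = np.column_stack([X, X[:, 0]])
            imp2 = feature_importance(
                [train_rusboost(X_dup, labels, rounds=30, seed=seed)]
            )
            singles.append(imp1.iloc[0])
            pairs.append(imp2.iloc[0] + imp2.iloc[5])
        assert np.mean(pairs) <= np.mean(singles) + 5.0


class TestROC:
    def test_auc_equals_rank_sum_statistic_with_ties(self):
        scores = np.array([0.1, 0.4, 0.4, 0.4, 0.6, 0.6, 0.8, 0.2, 0.9, 0.4])
        labels = np.array(
            ["CN", "CN", "AD", "CN", "AD", "CN", "AD", "CN", "AD", "AD"]
        )
        roc = roc_from_scores(scores, labels)
        pos = scores[labels == "AD"]
        neg = scores[labels == "CN"]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_perfect_separation(self):
        roc = roc_from_scores(
            np.array([-2.0, -1.0, 1.0, 2.0]), np.array(["CN", "CN", "AD", "AD"])
        )
        assert roc.auc == 1.0
        assert roc.eer == 0.0

    def test_inverted_labels_give_auc_zero(self):
        roc = roc_from_scores(
            np.array([-2.0, -1.0, 1.0, 2.0]), np.array(["AD", "AD", "CN", "CN"])
        )
        assert roc.auc == 0.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.4, "AD", "CN")
        if len(set(labels)) < 2:
            labels[:2] = ["AD", "CN"]
        base = roc_from_scores(scores, labels)
        warped = roc_from_scores(np.exp(3 * scores) - 5, labels)
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)

    def test_fpr_tpr_monotone(self, rng):
        roc = roc_from_scores(
            rng.normal(size=30), np.where(rng.random(30) < 0.5, "AD", "CN")
        )
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)


class TestLOOCV:
    def test_deterministic_and_scores_one_per_subject(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)), index=[f"s{i}" for i in range(12)])
        X.iloc[8:, 0] += 2.0
        labels = pd.Series(["CN"] * 8 + ["AD"] * 4, index=X.index)
        roc1, models1 = loocv_evaluate(X, labels, rounds=10, seed=5)
        roc2, _ = loocv_evaluate(X, labels, rounds=10, seed=5)
        assert len(models1) == 12
        np.testing.assert_array_equal(roc1.scores, roc2.scores)
        assert roc1.auc == roc2.auc

    def test_needs_two_per_class(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)))
        labels = pd.Series(["CN", "CN", "CN", "CN", "AD"])
        with pytest.raises(DataError):
            loocv_evaluate(X, labels, rounds=2, seed=0)
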