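import numpy as np
import pandas as pd
import pytest

from motioncue.decode import (
    CVConfig,
    classify_all_electrodes,
    lda_fit,
    lda_predict,
    leave_three_out_cv,
    nested_speed_analysis,
)
from motioncue.preprocess import EpochStack
from motioncue.stats import chance_level, ci_half_width
from oracles import enumerate_leave_three_out, gaussian_bayes_fit, gaussian_bayes_predict


def _gaussian_instance(rng, n_classes=3, n_per_class=10, p=5, sep=1.5):
    means = rng.normal(scale=sep, size=(n_classes, p))
    X = np.concatenate(
        [means[c] + rng.standard_normal((n_per_class, p)) for c in range(n_classes)]
    )
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    return X, y


class TestLDAAgainstBayesOracle:
    @pytest.mark.parametrize("shrinkage", [0.0, 0.2])
    def test_predictions_match_brute_force_gaussian_bayes(self, shrinkage):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            X, y = _gaussian_instance(rng)
            X_test = rng.standard_normal((20, X.shape[1])) * 2
            model = lda_fit(X, y, shrinkage=shrinkage)
            oracle = gaussian_bayes_fit(X, y, shrinkage=shrinkage)
            assert np.array_equal(
                lda_predict(model, X_test), gaussian_bayes_predict(oracle, X_test)
            )

    def test_training_data_agreement_too(self):
        rng = np.random.default_rng(5)
        X, y = _gaussian_instance(rng, n_classes=4, n_per_class=8)
        model = lda_fit(X, y, shrinkage=0.1)
        oracle = gaussian_bayes_fit(X, y, shrinkage=0.1)
        assert np.array_equal(lda_predict(model, X), gaussian_bayes_predict(oracle, X))


class TestLDAClosedForms:
    def test_1d_two_class_boundary_at_midpoint(self):
        X = np.array([[-0.5], [0.5], [1.5], [2.5]])
        y = np.array([1, 1, 2, 2])  # means 0 and 2, equal variance
        model = lda_fit(X, y, shrinkage=0.0)
        assert lda_predict(model, np.array([0.99])) == 1
        assert lda_predict(model, np.array([1.01])) == 2

    def test_tie_breaks_to_lower_class_index(self):
        X = np.array([[-0.5], [0.5], [1.5], [2.5]])
        y = np.array([1, 1, 2, 2])
        model = lda_fit(X, y, shrinkage=0.0)
        assert lda_predict(model, np.array([1.0])) == 1  # exact midpoint

    def test_full_shrinkage_is_nearest_class_mean(self):
        rng = np.random.default_rng(8)
        X, y = _gaussian_instance(rng, n_classes=3, n_per_class=6, p=4)
        model = lda_fit(X, y, shrinkage=1.0)
        probes = rng.standard_normal((30, 4))
        means = np.stack([X[y == c].mean(axis=0) for c in (1, 2, 3)])
        nearest = 1 + np.argmin(
            ((probes[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        assert np.array_equal(lda_predict(model, probes), nearest)

    def test_class_mean_predicted_as_its_class(self):
        rng = np.random.default_rng(9)
        X, y = _gaussian_instance(rng)
        model = lda_fit(X, y, shrinkage=1.0)
        for c in (1, 2, 3):
            assert lda_predict(model, X[y == c].mean(axis=0)) == c

    def test_singular_covariance_needs_shrinkage(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([1, 1, 2, 2])  # duplicated feature -> singular pooled cov
        with pytest.raises(ValueError, match="shrinkage"):
            lda_fit(X, y, shrinkage=0.0)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        X, y = _gaussian_instance(rng)
        model = lda_fit(X, y)
        with pytest.raises(ValueError):
            lda_predict(model, np.zeros(3))


class TestLeaveThreeOutCV:
    def test_null_features_score_at_chance(self):
        rng = np.random.default_rng(1)
        y = np.repeat(np.arange(1, 12), 45)
        X = rng.standard_normal((len(y), 13))
        entry = leave_three_out_cv(X, y, CVConfig(seed=0))
        chance = chance_level(11)
        # generous band: the Wald CI at the decision count, doubled for the
        # trial-sharing correlation between decisions
        half = 2 * ci_half_width(max(entry.gamma_hat, chance), entry.n_decisions, 0.01)
        assert abs(entry.gamma_hat - chance) <= half

    def test_separable_classes_give_perfect_diagonal(self):
        y = np.repeat(np.arange(1, 12), 9)
        X = np.tile(y[:, None] * 10.0, (1, 13)) + np.random.default_rng(2).normal(
            scale=0.01, size=(len(y), 13)
        )
        entry = leave_three_out_cv(X, y, CVConfig(n_repetitions=20,
                                                  n_train_veps_per_class=20, seed=1))
        assert entry.gamma_hat == 1.0
        assert np.all(entry.confusion == np.diag(np.diag(entry.confusion)))

    def test_confusion_matrix_accounting(self):
        rng = np.random.default_rng(4)
        y = np.repeat(np.arange(1, 6), 10)
        X = rng.standard_normal((len(y), 7))
        cfg = CVConfig(n_classes=5, n_repetitions=17, n_train_veps_per_class=10, seed=3)
        entry = leave_three_out_cv(X, y, cfg)
        assert entry.confusion.sum() == entry.n_decisions == 17 * 5
        # columns = true classes: one decision per class per repetition
        assert np.all(entry.confusion.sum(axis=0) == 17)
        assert entry.gamma_hat == np.trace(entry.confusion) / entry.n_decisions
        assert entry.n_trials == len(y)

    def test_identical_seed_identical_confusion(self):
        rng = np.random.default_rng(6)
        y = np.repeat(np.arange(1, 4), 8)
        X = rng.standard_normal((len(y), 4))
        cfg = CVConfig(n_classes=3, n_repetitions=25, n_train_veps_per_class=15, seed=11)
        e1 = leave_three_out_cv(X, y, cfg)
        e2 = leave_three_out_cv(X, y, cfg)
        assert np.array_equal(e1.confusion, e2.confusion)

    def test_insufficient_trials_per_class_rejected(self):
        y = np.repeat(np.arange(1, 4), 5)  # 5 < test(3) + train-average(3)
        X = np.zeros((len(y), 4))
        with pytest.raises(ValueError, match="need at least"):
            leave_three_out_cv(X, y, CVConfig(n_classes=3))

    def test_matches_exhaustive_enumeration_oracle(self):
        """CV estimate agrees with brute force over all C(6,3) held-out triples."""
        rng = np.random.default_rng(77)
        means = np.array([[0.0, 0.0], [1.6, 0.0], [0.0, 1.6]])
        X = np.concatenate([m + rng.standard_normal((6, 2)) for m in means])
        y = np.repeat(np.arange(1, 4), 6)
        cfg = CVConfig(n_classes=3, n_repetitions=400, n_train_veps_per_class=10,
                       shrinkage=0.1, seed=0)
        entry = leave_three_out_cv(X, y, cfg)
        oracle_acc, oracle_n = enumerate_leave_three_out(
            X, y, n_train_veps=10, avg_size=3, shrinkage=0.1,
            rng=np.random.default_rng(78), draws_per_triple=40,
        )
        se = np.sqrt(
            oracle_acc * (1 - oracle_acc) / oracle_n
            + entry.gamma_hat * (1 - entry.gamma_hat) / entry.n_decisions
        )
        assert abs(entry.gamma_hat - oracle_acc) <= 3 * max(se, 0.01)

    def test_label_permutation_destroys_decodability(self):
        rng = np.random.default_rng(13)
        y = np.repeat(np.arange(1, 12), 15)
        X = y[:, None] * 1.0 + rng.standard_normal((len(y), 13))
        cfg = CVConfig(n_repetitions=20, n_train_veps_per_class=20, seed=2)
        strong = leave_three_out_cv(X, y, cfg)
        chance = chance_level(11)
        assert strong.gamma_hat - ci_half_width(strong.gamma_hat, strong.n_trials) > chance
        y_perm = rng.permutation(y)
        nulled = leave_three_out_cv(X, y_perm, cfg)
        assert abs(nulled.gamma_hat - chance) <= 2 * ci_half_width(
            max(nulled.gamma_hat, chance), nulled.n_decisions
        )

    def test_accuracy_degrades_monotonically_with_noise(self):
        y = np.repeat(np.arange(1, 12), 9)
        signal = y[:, None] * np.linspace(0.5, 1.5, 13)
        cfg = CVConfig(n_repetitions=20, n_train_veps_per_class=20, seed=4)
        gammas = []
        for noise_sd in (1.0, 4.0, 16.0):
            rng = np.random.default_rng(99)  # paired noise draws across levels
            X = signal + noise_sd * rng.standard_normal(signal.shape)
            gammas.append(leave_three_out_cv(X, y, cfg).gamma_hat)
        assert gammas[1] <= gammas[0] + 0.03
        assert gammas[2] <= gammas[1] + 0.03


def _stack_from_arrays(data_by_electrode, labels_df):
    return EpochStack(
        data=np.stack(list(data_by_electrode.values())),
        channel_labels=list(data_by_electrode),
        labels=labels_df,
    )


@pytest.fixture(scope="module")
def toy_stack():
    rng = np.random.default_rng(10)
    y = np.repeat(np.arange(1, 12), 9)
    labels = pd.DataFrame({
        "trial_id": np.arange(len(y)),
        "speed_class": y,
        "direction_class": rng.permutation(y),
    })
    data = {
        "P4": y[:, None] * 2.0 + rng.standard_normal((len(y), 13)),
        "Cz": rng.standard_normal((len(y), 13)),
    }
    return _stack_from_arrays(data, labels)


class TestElectrodeMapsAndNesting:
    def test_per_electrode_maps(self, toy_stack):
        cfg = CVConfig(n_repetitions=15, n_train_veps_per_class=15)
        amap = classify_all_electrodes(toy_stack, cue="speed", config=cfg)
        assert amap.electrodes == ["P4", "Cz"]
        assert amap.gamma("P4") > 0.5 > amap.gamma("Cz")

    def test_missing_electrode_skipped(self, toy_stack, caplog):
        cfg = CVConfig(n_repetitions=5, n_train_veps_per_class=10)
        amap = classify_all_electrodes(
            toy_stack, cue="speed", config=cfg, electrodes=["P4", "Oz"]
        )
        assert amap.electrodes == ["P4"]

    def test_same_epochs_same_scheme_for_both_cues(self, toy_stack):
        """With identical labels, the two cues are the same computation."""
        labels = toy_stack.labels.copy()
        labels["direction_class"] = labels["speed_class"]
        stack = EpochStack(toy_stack.data, toy_stack.channel_labels, labels)
        cfg = CVConfig(n_repetitions=10, n_train_veps_per_class=10, seed=9)
        e_speed = leave_three_out_cv(stack.electrode("P4"), config=cfg)
        e_dir = leave_three_out_cv(
            stack.electrode("P4"), config=cfg.with_overrides(cue="direction")
        )
        assert np.array_equal(e_speed.confusion, e_dir.confusion)

    def test_nested_speed_chance_levels_on_null_data(self):
        rng = np.random.default_rng(20)
        y = np.repeat(np.arange(1, 12), 12)
        labels = pd.DataFrame({
            "trial_id": np.arange(len(y)), "speed_class": y, "direction_class": y,
        })
        stack = _stack_from_arrays(
            {"Cz": rng.standard_normal((len(y), 13))}, labels
        )
        cfg = CVConfig(n_repetitions=40, n_train_veps_per_class=15, seed=0)
        nested = nested_speed_analysis(stack, config=cfg, n_classes_range=[2, 3])
        for n in (2, 3):
            gamma = nested[n].gamma("Cz")
            chance = 1.0 / n
            n_dec = nested[n].entries["Cz"].n_decisions
            assert abs(gamma - chance) <= 2 * ci_half_width(max(gamma, chance), n_dec)
            # only the n slowest speeds enter the nested task
            assert nested[n].entries["Cz"].n_trials == 12 * n
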