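"""Training loop, metrics, benchmarks, grid search."""

import numpy as np
import pytest

from swaygrade.model import ModelConfig, build_model
from swaygrade.training import (
    TrainingCurves,
    bootstrap_ci,
    classify,
    dummy_regressor_rmse,
    grid_search,
    hyperparameter_grid,
    paired_t_test,
    random_pt_rmse,
    rmse,
    self_rating_rmse,
    train,
)


class TestRmse:
    def test_identical_vectors_give_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(np.sqrt(2.5))

    def test_single_pair_is_absolute_difference(self):
        assert rmse([4.0], [1.5]) == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestClassify:
    def test_half_rounds_up(self):
        out = classify([2.5, 2.5, 2.5], [3.0, 3.0, 3.0])
        assert list(out["classes"]) == [3, 3, 3]

    def test_perfect_predictions(self):
        preds = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = classify(preds, preds)
        assert out["accuracy"] == 1.0
        assert out["macro_f1"] == 1.0
        assert np.trace(out["confusion"]) == 5

    def test_three_record_toy_matches_hand_enumeration(self):
        # pred classes (1, 2, 2) vs GT classes (1, 2, 3):
        # class 1: P=R=1 -> F1=1; class 2: P=1/2, R=1 -> F1=2/3;
        # class 3: predicted never -> F1=0; macro = 5/9; accuracy = 2/3
        out = classify([1.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert out["accuracy"] == pytest.approx(2 / 3)
        assert out["macro_f1"] == pytest.approx(5 / 9)

    def test_macro_f1_cross_checked_against_sklearn(self, rng):
        from sklearn.metrics import f1_score

        preds = rng.uniform(0.8, 5.2, 200)
        gt = rng.integers(1, 6, 200).astype(float)
        out = classify(preds, gt)
        if len(np.union1d(out["classes"], gt.astype(int))) == 5:
            expected = f1_score(gt.astype(int), out["classes"],
                                average="macro")
            assert out["macro_f1"] == pytest.approx(expected)

    def test_confusion_totals_and_accuracy_identity(self, rng):
        preds = rng.uniform(0.8, 5.2, 100)
        gt = rng.integers(1, 6, 100).astype(float)
        out = classify(preds, gt)
        assert out["confusion"].sum() == 100
        assert out["accuracy"] == pytest.approx(
            np.trace(out["confusion"]) / 100)

    def test_out_of_bound_prediction_rejected(self):
        with pytest.raises(ValueError):
            classify([0.4], [1.0])


class TestPairedT:
    def test_equal_errors_not_significant(self):
        t, p, sig = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_closed_form_df2(self):
        # differences (1, 2, 3): t = 2*sqrt(3); two-tailed p at df=2 ~ 0.0742
        t, p, sig = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert p == pytest.approx(0.0742, abs=5e-4)
        assert not sig

    def test_zero_variance_nonzero_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBootstrapCI:
    def test_identical_errors_give_zero_width(self):
        point, lo, hi = bootstrap_ci(np.full(50, 0.7), seed=0)
        assert point == pytest.approx(0.7)
        assert lo == hi == pytest.approx(0.7)

    def test_seeded_reproducibility(self):
        errors = np.arange(20, dtype=float) / 10
        assert bootstrap_ci(errors, seed=3) == bootstrap_ci(errors, seed=3)

    def test_interval_covers_sample_rmse(self, rng):
        errors = rng.standard_normal(500)
        point, lo, hi = bootstrap_ci(errors, seed=1)
        assert lo <= point <= hi
        assert lo <= np.sqrt(np.mean(errors ** 2)) <= hi

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestDummyRegressor:
    def test_degenerate_distribution_gives_zero(self):
        assert dummy_regressor_rmse([3.0] * 10, [3.0] * 5) == 0.0

    def test_uniform_train_constant_test_equals_sqrt2(self):
        # E[(Y - 3)^2] = (4 + 1 + 0 + 1 + 4) / 5 = 2
        val = dummy_regressor_rmse([1.0, 2.0, 3.0, 4.0, 5.0], [3.0] * 200,
                                   n_draws=1000, seed=0)
        assert val == pytest.approx(np.sqrt(2), abs=0.02)

    def test_seeded_reproducibility(self):
        a = dummy_regressor_rmse([1.0, 2.0], [1.5] * 10, seed=7)
        assert a == dummy_regressor_rmse([1.0, 2.0], [1.5] * 10, seed=7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dummy_regressor_rmse([], [1.0])


class TestSelfRatingRmse:
    def test_agreement_gives_zero(self):
        assert self_rating_rmse([3, 4], [3.0, 4.0]) == 0.0

    def test_hand_arithmetic(self):
        assert self_rating_rmse([2, 3], [3.0, 3.0]) == pytest.approx(
            np.sqrt(0.5))

    def test_missing_self_ratings_excluded(self):
        assert self_rating_rmse([2, None, np.nan], [3.0, 1.0, 1.0]) == 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            self_rating_rmse([None], [3.0])


class TestRandomPtRmse:
    def test_unanimous_panels_give_exact_zero(self):
        mean, lo, hi = random_pt_rmse([(3, 3, 3), (2, 2)], seed=0)
        assert mean == 0.0 and lo == 0.0 and hi == 0.0

    def test_two_panel_worked_example_is_sqrt2_exactly(self):
        # panels (2, 4) and (3, 3): every draw gives sqrt((4 + 0) / 2)
        mean, lo, hi = random_pt_rmse([(2, 4), (3, 3)], seed=5)
        assert mean == pytest.approx(np.sqrt(2), abs=1e-12)
        assert lo == hi == pytest.approx(np.sqrt(2))

    def test_single_rating_panels_excluded(self):
        with_single = random_pt_rmse([(2, 4), (5,)], seed=1)
        without = random_pt_rmse([(2, 4)], seed=1)
        assert with_single[0] == without[0]

    def test_no_eligible_panel_rejected(self):
        with pytest.raises(ValueError):
            random_pt_rmse([(3,), (4,)])

    def test_monotone_in_rater_noise(self):
        from swaygrade.synthetic import LatentIntensity, simulate_ratings

        means = []
        for sd in (0.0, 0.3, 0.6, 1.0):
            panels = [simulate_ratings(LatentIntensity(3.0), 4, sd,
                                       seed=s).pt_ratings
                      for s in range(300)]
            means.append(random_pt_rmse(panels, n_boot=200, seed=0)[0])
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert means[0] == 0.0


def fold_tensors(tiny_store):
    from swaygrade.dataset import stratified_participant_folds
    from swaygrade.pipeline import assemble_fold_data, participant_mean_labels

    means = participant_mean_labels(tiny_store["study"])
    splits = stratified_participant_folds(sorted(means), means, k=5, seed=0)
    return assemble_fold_data(tiny_store, splits[0],
                              ("lumbar", "left_thigh"))


class TestTrain:
    def test_loss_decreases_on_learnable_signal(self, tiny_store):
        data = fold_tensors(tiny_store)
        model = build_model(ModelConfig(
            conv_filters=8, dense_sizes=(16, 8), dropout_rate=0.0,
            n_input_channels=2, seed=0))
        curves = train(model, data["train"], data["val"], epochs=12, seed=0)
        assert np.mean(curves.train_loss[:5]) > np.mean(curves.train_loss[-5:])
        assert len(curves.train_loss) == len(curves.val_rmse) == 12

    def test_deterministic_given_seed(self, tiny_store):
        data = fold_tensors(tiny_store)

        def fit():
            model = build_model(ModelConfig(
                conv_filters=8, dense_sizes=(8, 8), dropout_rate=0.2,
                n_input_channels=2, seed=1))
            train(model, data["train"], data["val"], epochs=3, seed=1)
            return model

        a, b = fit(), fit()
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_best_validation_snapshot_restored(self, tiny_store):
        data = fold_tensors(tiny_store)
        model = build_model(ModelConfig(
            conv_filters=8, dense_sizes=(8, 8), dropout_rate=0.0,
            n_input_channels=2, seed=2))
        curves = train(model, data["train"], data["val"], epochs=8, seed=2)
        preds = model.predict(data["val"]["grids"], data["val"]["scalars"])
        assert rmse(preds, data["val"]["labels"]) == pytest.approx(
            min(curves.val_rmse), abs=1e-6)

    def test_zero_epochs_rejected(self, tiny_store):
        data = fold_tensors(tiny_store)
        model = build_model(ModelConfig(
            conv_filters=8, dense_sizes=(8, 8), dropout_rate=0.0,
            n_input_channels=2))
        with pytest.raises(ValueError):
            train(model, data["train"], data["val"], epochs=0)

    def test_empty_training_set_rejected(self):
        model = build_model(ModelConfig(
            conv_filters=8, dense_sizes=(8, 8), dropout_rate=0.0,
            n_input_channels=2))
        empty = {"grids": np.zeros((0, 2, 64, 64)), "scalars": np.zeros((0, 8)),
                 "labels": np.zeros(0)}
        with pytest.raises(ValueError):
            train(model, empty, empty)


class TestGridSearch:
    def test_full_lattice_sizes(self):
        assert len(hyperparameter_grid(2)) == 81
        assert len(hyperparameter_grid(2, tie_dense=True)) == 27

    def test_singleton_grid_returned(self):
        cfg = ModelConfig(conv_filters=8, dense_sizes=(8, 8),
                          dropout_rate=0.0, n_input_channels=1)
        best, results = grid_search(lambda c: 1.0, [cfg])
        assert best == cfg and len(results) == 1

    def test_planted_best_always_selected(self):
        grid = hyperparameter_grid(2)
        target = grid[37]

        def evaluate(cfg):
            return 0.1 if cfg == target else 1.0 + grid.index(cfg) * 1e-3

        best, results = grid_search(evaluate, grid)
        assert best == target
        assert len(results) == 81

    def test_ties_broken_by_parameter_count(self):
        grid = hyperparameter_grid(1)
        best, _ = grid_search(lambda c: 1.0, grid)
        smallest = min(build_model(c).n_parameters() for c in grid)
        assert build_model(best).n_parameters() == smallest

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(lambda c: 0.0, [])


def test_training_curves_container():
    c = TrainingCurves(train_loss=[1.0], val_rmse=[0.5], best_epoch=0)
    assert len(c.train_loss) == len(c.val_rmse)
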