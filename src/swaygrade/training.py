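"""Training protocol, evaluation metrics, and rater-consensus benchmarks.

Models are trained on weighted mean-squared error with Adam (lr 0.001)
under participant-level stratified 5-fold cross-validation, keeping the
parameter snapshot with the best validation RMSE. Evaluation covers RMSE
with bootstrap confidence intervals, rounded 1-5 classification (accuracy,
macro F1, confusion matrix), and the consensus benchmarks: a dummy
regressor sampling the training-label marginal, participant self-ratings
against the PT consensus, and the "random PT" leave-rating-out benchmark
averaged over 1000 replicates. Paired two-tailed t-tests on per-repetition
squared errors compare benchmark error levels at alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .dataset import round_rating
from .model import Adam, BalanceCNN, ModelConfig, build_model

RANDOM_PT_REPLICATES = 1000
DEFAULT_BATCH_SIZE = 32
DEFAULT_EPOCHS = 200


@dataclass
class TrainingCurves:
    """Per-epoch weighted training loss (MSE) and validation RMSE."""

    train_loss: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class EvaluationReport:
    """Everything reported for one model / sensor-subset evaluation."""

    rmse: float
    rmse_ci: tuple
    accuracy: float
    accuracy_ci: tuple
    macro_f1: float
    macro_f1_ci: tuple
    confusion: np.ndarray  # (5, 5), rows = rounded GT
    benchmark_rmse: dict  # name -> (point, lo, hi)
    t_tests: dict  # comparison -> (t, p, significant)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse, "rmse_ci": list(self.rmse_ci),
            "accuracy": self.accuracy, "accuracy_ci": list(self.accuracy_ci),
            "macro_f1": self.macro_f1, "macro_f1_ci": list(self.macro_f1_ci),
            "confusion": self.confusion.tolist(),
            "benchmark_rmse": {k: list(v) for k, v in self.benchmark_rmse.items()},
            "t_tests": {k: {"t": v[0], "p": v[1], "significant": v[2]}
                        for k, v in self.t_tests.items()},
        }


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def rmse(predictions, gt) -> float:
    """Root mean squared error."""
    p = np.asarray(predictions, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError("length mismatch")
    if p.size == 0:
        raise ValueError("empty inputs")
    return float(np.sqrt(np.mean((p - g) ** 2)))


def classify(predictions, gt_labels) -> dict:
    """Round predictions to 1-5 classes and score against rounded GT.

    Rounding is half-away-from-zero with clamping to [1, 5] (the same rule
    used for weight classes). Macro F1 averages per-class F1 over classes
    present in either GT or predictions; a class absent from both is
    excluded from the macro average.
    """
    p = np.asarray(predictions, dtype=float)
    if np.any(p <= 0.5) or np.any(p >= 5.5):
        raise ValueError("predictions must lie strictly inside (0.5, 5.5)")
    pred_cls = round_rating(p)
    gt_cls = round_rating(gt_labels)
    confusion = np.zeros((5, 5), dtype=int)
    for g, q in zip(gt_cls, pred_cls):
        confusion[g - 1, q - 1] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    f1s = []
    for c in range(1, 6):
        tp = int(confusion[c - 1, c - 1])
        n_gt = int(confusion[c - 1].sum())
        n_pred = int(confusion[:, c - 1].sum())
        if n_gt == 0 and n_pred == 0:
            continue  # class absent everywhere: excluded from the macro
        f1s.append(2 * tp / (n_gt + n_pred) if (n_gt + n_pred) else 0.0)
    return {"classes": pred_cls, "accuracy": accuracy,
            "macro_f1": float(np.mean(f1s)), "confusion": confusion}


def paired_t_test(errors_a, errors_b, alpha: float = 0.05) -> tuple:
    """Paired two-tailed t-test on per-repetition error values."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0, False
        raise ValueError("zero-variance non-zero differences")
    res = sp_stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def bootstrap_ci(per_repetition_errors, statistic=None, n_boot: int = 1000,
                 seed: int = 0, alpha: float = 0.05) -> tuple:
    """Percentile bootstrap CI for a statistic of per-repetition errors.

    Default statistic: RMSE, i.e. sqrt(mean(e^2)) of the resampled errors.
    Returns (point, lo, hi).
    """
    errors = np.asarray(per_repetition_errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty input")
    if statistic is None:
        def statistic(e):
            return float(np.sqrt(np.mean(e ** 2)))
    rng = np.random.default_rng(seed)
    point = statistic(errors)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        stats[i] = statistic(rng.choice(errors, size=errors.size, replace=True))
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(point), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

def dummy_regressor_rmse(train_labels, test_labels, n_draws: int = 1000,
                         seed: int = 0) -> float:
    """Baseline predicting p(Y): draws from the empirical training-label
    distribution for every test record, averaged over ``n_draws`` replicates."""
    train = np.asarray(train_labels, dtype=float)
    test = np.asarray(test_labels, dtype=float)
    if train.size == 0 or test.size == 0:
        raise ValueError("empty label sets")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_draws)
    for i in range(n_draws):
        preds = rng.choice(train, size=test.size, replace=True)
        vals[i] = np.sqrt(np.mean((preds - test) ** 2))
    return float(vals.mean())


def self_rating_rmse(self_ratings, gt_labels) -> float:
    """RMSE of participant self-ratings against the PT consensus labels.

    Repetitions with a missing self-rating (None/NaN) are excluded.
    """
    pairs = [(s, g) for s, g in zip(self_ratings, gt_labels)
             if s is not None and np.isfinite(s)]
    if not pairs:
        raise ValueError("no repetitions with both self-rating and GT")
    s, g = map(np.asarray, zip(*pairs))
    return rmse(s.astype(float), g.astype(float))


def _expected_loo_sq(panel) -> float:
    """Exact mean over raters of (rating - leave-it-out mean)^2; NaN if <2."""
    p = np.asarray(panel, dtype=float)
    if len(p) < 2:
        return float("nan")
    loo = (p.sum() - p) / (len(p) - 1)
    return float(np.mean((p - loo) ** 2))


def random_pt_rmse(rating_panels, n_boot: int = RANDOM_PT_REPLICATES,
                   seed: int = 0) -> tuple:
    """Inter-rater benchmark: one random rating vs the leave-it-out mean.

    Per replicate, every repetition with >= 2 PT ratings contributes the
    squared error between one uniformly chosen rating and the mean of the
    remaining ratings; the per-replicate RMSEs are averaged over ``n_boot``
    replicates, with a percentile CI. Returns (mean, lo, hi).
    """
    panels = [np.asarray(p, dtype=float) for p in rating_panels
              if len(p) >= 2]
    if not panels:
        raise ValueError("no repetition has >= 2 ratings")
    rng = np.random.default_rng(seed)
    sums = np.array([p.sum() for p in panels])
    sizes = np.array([len(p) for p in panels])
    vals = np.empty(n_boot)
    for i in range(n_boot):
        picks = np.array([p[rng.integers(len(p))] for p in panels])
        loo_mean = (sums - picks) / (sizes - 1)
        vals[i] = np.sqrt(np.mean((picks - loo_mean) ** 2))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(vals.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(model: BalanceCNN, train_data: dict, val_data: dict,
          epochs: int = DEFAULT_EPOCHS, batch_size: int = DEFAULT_BATCH_SIZE,
          learning_rate: float | None = None, seed: int = 0) -> TrainingCurves:
    """Minimize weighted MSE with Adam; keep the best-validation snapshot.

    ``train_data`` / ``val_data``: dicts with keys ``grids`` (B, C, g, g),
    ``scalars`` (B, S), ``labels`` (B,), and (train only) ``weights`` (B,).
    The model is left holding the parameters of the epoch with the lowest
    validation RMSE. Deterministic given (data, seed).
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n = len(train_data["labels"])
    if n == 0:
        raise ValueError("empty training set")
    weights = np.asarray(train_data.get("weights",
                                        np.ones(n)), dtype=np.float32)
    labels = np.asarray(train_data["labels"], dtype=np.float32)
    rng = np.random.default_rng(seed)
    lr = learning_rate if learning_rate is not None else model.config.learning_rate
    opt = Adam(lr=lr)
    curves = TrainingCurves()
    best_rmse = np.inf
    best_params = model.copy_params()
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            g = train_data["grids"][idx]
            s = train_data["scalars"][idx]
            y = labels[idx]
            w = weights[idx]
            preds, cache = model.forward(g, s, train=True, dropout_rng=rng)
            resid = preds - y
            wsum = w.sum()
            loss = float(np.sum(w * resid ** 2) / wsum)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            d_pred = 2.0 * w * resid / wsum
            grads = model.backward(cache, d_pred)
            opt.step(model.params, grads)
            losses.append(loss)
        curves.train_loss.append(float(np.mean(losses)))
        val_preds = model.predict(val_data["grids"], val_data["scalars"])
        v = rmse(val_preds, val_data["labels"])
        curves.val_rmse.append(v)
        if v < best_rmse:
            best_rmse = v
            best_params = model.copy_params()
            curves.best_epoch = epoch
    model.set_params(best_params)
    return curves


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def hyperparameter_grid(n_input_channels: int, n_scalar_features: int = 8,
                        tie_dense: bool = False, seed: int = 0) -> list:
    """The stated search lattice: conv {8,16,32} x dense {8,16,32} (per
    layer, or tied) x dropout {0, 0.2, 0.5}; 81 configs free, 27 tied."""
    from .model import CONV_FILTER_GRID, DENSE_GRID, DROPOUT_GRID

    configs = []
    for f in CONV_FILTER_GRID:
        for d1 in DENSE_GRID:
            d2s = [d1] if tie_dense else DENSE_GRID
            for d2 in d2s:
                for p in DROPOUT_GRID:
                    configs.append(ModelConfig(
                        conv_filters=f, dense_sizes=(d1, d2), dropout_rate=p,
                        n_input_channels=n_input_channels,
                        n_scalar_features=n_scalar_features, seed=seed))
    return configs


def grid_search(evaluate, grid: list) -> tuple:
    """Exhaustive search of a config lattice.

    ``evaluate(config)`` returns the validation RMSE (averaged over folds by
    the caller's evaluator). Ties are broken by fewer parameters, then by
    lexicographic (conv_filters, dense_sizes, dropout_rate) order. Returns
    (best_config, results list of (config, score)).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    results = [(cfg, float(evaluate(cfg))) for cfg in grid]

    def sort_key(item):
        cfg, score = item
        return (score, build_model(cfg).n_parameters(),
                cfg.conv_filters, cfg.dense_sizes, cfg.dropout_rate)

    best = min(results, key=sort_key)
    return best[0], results


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def evaluate_model(preds, gt_labels, self_ratings, rating_panels,
                   train_labels, seed: int = 0,
                   n_boot: int = 1000) -> EvaluationReport:
    """Full evaluation of pooled test predictions against all benchmarks."""
    preds = np.asarray(preds, dtype=float)
    gt = np.asarray(gt_labels, dtype=float)
    errors = preds - gt
    point, lo, hi = bootstrap_ci(errors, n_boot=n_boot, seed=seed)
    cls = classify(preds, gt)

    rng = np.random.default_rng(seed)
    acc_ci = _bootstrap_class_metric(preds, gt, "accuracy", n_boot, rng)
    f1_ci = _bootstrap_class_metric(preds, gt, "macro_f1", n_boot, rng)

    dummy = dummy_regressor_rmse(train_labels, gt, seed=seed)
    self_r = self_rating_rmse(self_ratings, gt)
    pt_mean, pt_lo, pt_hi = random_pt_rmse(rating_panels, seed=seed)

    self_errors = np.asarray(
        [s - g for s, g in zip(self_ratings, gt) if s is not None], dtype=float)
    _, s_lo, s_hi = bootstrap_ci(self_errors, n_boot=n_boot, seed=seed + 1)

    # pairing unit: per-repetition squared errors on the pooled test set;
    # the random-PT squared error per repetition is the exact average over
    # raters of (rating - leave-it-out mean)^2, defined for panels >= 2
    pt_sq = np.array([_expected_loo_sq(p) for p in rating_panels])
    eligible = np.isfinite(pt_sq)
    t_tests = {}
    if eligible.sum() >= 3:
        t_tests["model_vs_random_pt"] = paired_t_test(
            errors[eligible] ** 2, pt_sq[eligible])
        if len(self_errors) == len(errors):
            t_tests["self_vs_random_pt"] = paired_t_test(
                self_errors[eligible] ** 2, pt_sq[eligible])

    return EvaluationReport(
        rmse=point, rmse_ci=(lo, hi),
        accuracy=cls["accuracy"], accuracy_ci=acc_ci,
        macro_f1=cls["macro_f1"], macro_f1_ci=f1_ci,
        confusion=cls["confusion"],
        benchmark_rmse={
            "model": (point, lo, hi),
            "dummy": (dummy, float("nan"), float("nan")),
            "self_rating": (self_r, s_lo, s_hi),
            "random_pt": (pt_mean, pt_lo, pt_hi),
        },
        t_tests=t_tests)


def _bootstrap_class_metric(preds, gt, key, n_boot, rng):
    n = len(preds)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(n, size=n)
        vals[i] = classify(preds[idx], gt[idx])[key]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return (float(lo), float(hi))
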