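"""Greedy beam-3 sequential forward IMU-subset search.

Stage 1 evaluates all 13 single-sensor models; every later stage extends
each of the top-`beam` subsets of the previous size with every unused
placement, de-duplicates subsets (as sets), re-evaluates each with full
retraining/re-tuning, and re-ranks by validation RMSE averaged over folds.

Two evaluators are provided: the bounded CNN (the default, expensive) and a
fast deterministic surrogate (ridge regression on stabilogram summary
features) that preserves the search's combinatorial behaviour so the
procedure itself is testable in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dataset as ds

DEFAULT_BEAM = 3


@dataclass
class SensorSubsetResult:
    """Score card for one evaluated sensor subset."""

    placements: tuple  # in order of addition
    mean_val_rmse: float
    ci: tuple = (float("nan"), float("nan"))
    score_var: float = 0.0
    test_report: object = None
    best_config: object = None
    is_best_of_size: bool = False

    def __post_init__(self):
        if len(self.placements) == 0:
            raise ValueError("placements must be non-empty")
        if len(set(self.placements)) != len(self.placements):
            raise ValueError("duplicate placements in subset")


def _normalize_score(score) -> tuple:
    """Evaluators may return rmse, (rmse, var) or (rmse, var, extras)."""
    if isinstance(score, tuple):
        rmse = float(score[0])
        var = float(score[1]) if len(score) > 1 else 0.0
        extras = score[2] if len(score) > 2 else {}
        return rmse, var, extras
    return float(score), 0.0, {}


def greedy_forward_select(all_placements, evaluate_subset,
                          max_size: int, beam: int = DEFAULT_BEAM,
                          seed: int = 0) -> dict:
    """Beam-limited sequential forward selection over sensor subsets.

    ``evaluate_subset(subset_tuple)`` -> validation RMSE (optionally
    ``(rmse, variance)``), averaged over folds by the evaluator. Returns
    ``{size: [SensorSubsetResult, ...]}`` with every evaluated subset,
    ranked; the per-size best is flagged. Ranking ties break on smaller
    score variance, then lexicographic placement order.
    """
    all_placements = tuple(all_placements)
    if beam < 1:
        raise ValueError("beam must be >= 1")
    if not (1 <= max_size <= len(all_placements)):
        raise ValueError("max_size out of range")

    def rank_key(res: SensorSubsetResult):
        return (res.mean_val_rmse, res.score_var, tuple(sorted(res.placements)))

    results: dict = {}
    frontier = [()]
    for size in range(1, max_size + 1):
        candidates = []
        seen = set()
        for parent in frontier:
            for placement in all_placements:
                if placement in parent:
                    continue
                subset = parent + (placement,)
                key = frozenset(subset)
                if key in seen:
                    continue  # subset reachable from several beam parents
                seen.add(key)
                candidates.append(subset)
        evaluated = []
        for subset in candidates:
            rmse, var, extras = _normalize_score(evaluate_subset(subset))
            evaluated.append(SensorSubsetResult(
                placements=subset, mean_val_rmse=rmse, score_var=var,
                **extras))
        evaluated.sort(key=rank_key)
        evaluated[0].is_best_of_size = True
        results[size] = evaluated
        frontier = [r.placements for r in evaluated[:beam]]
    return results


def rmse_vs_count_summary(results: dict):
    """Performance-vs-sensor-count table: one row per subset size.

    Columns: size, best subset, best RMSE (+CI when available), and the
    RMSEs of every suboptimal subset evaluated at that size.
    """
    import pandas as pd

    if not results:
        raise ValueError("empty results")
    rows = []
    for size in sorted(results):
        ranked = sorted(results[size],
                        key=lambda r: (r.mean_val_rmse, r.score_var,
                                       tuple(sorted(r.placements))))
        best = ranked[0]
        rows.append({
            "size": size,
            "best_subset": "+".join(best.placements),
            "best_rmse": best.mean_val_rmse,
            "ci_lo": best.ci[0], "ci_hi": best.ci[1],
            "n_evaluated": len(ranked),
            "suboptimal_rmses": [r.mean_val_rmse for r in ranked[1:]],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluators
# ---------------------------------------------------------------------------

def grid_summary_features(occupancy: np.ndarray, grid_size: int = 64,
                          bound: float = 3.2) -> np.ndarray:
    """Low-dimensional sway summaries of one occupancy grid.

    Occupancy-weighted RMS radius, per-axis spreads, edge-cell mass and
    occupancy entropy: enough to carry amplitude information for the
    surrogate evaluator without any learned convolution.
    """
    centers = (np.arange(grid_size) + 0.5) * (2 * bound / grid_size) - bound
    px = occupancy.sum(axis=0)
    py = occupancy.sum(axis=1)
    sx = np.sqrt(np.sum(px * centers ** 2))
    sy = np.sqrt(np.sum(py * centers ** 2))
    rad = np.sqrt(sx ** 2 + sy ** 2)
    edge = (occupancy[0].sum() + occupancy[-1].sum()
            + occupancy[1:-1, 0].sum() + occupancy[1:-1, -1].sum())
    nz = occupancy[occupancy > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return np.array([rad, sx, sy, edge, entropy])


@dataclass
class SurrogateEvaluator:
    """Deterministic ridge-on-summaries stand-in for the CNN evaluator.

    Precomputes per-placement summary features for every repetition, then
    scores a subset by ridge regression (scikit-learn, fixed alpha) from the
    selected placements' summaries plus the scalar features, reporting the
    validation RMSE averaged over the provided fold splits.
    """

    features: dict  # placement -> (n_reps, n_feat)
    scalars: np.ndarray  # (n_reps, S)
    labels: np.ndarray  # (n_reps,)
    participant_ids: np.ndarray  # (n_reps,)
    splits: list  # FoldSplit list
    alpha: float = 1.0
    include_scalars: bool = True
    n_calls: int = 0
    evaluated: list = field(default_factory=list)

    @classmethod
    def from_fold_data(cls, store: dict, splits: list, placements,
                       channel_types=("angle",), alpha: float = 1.0,
                       include_scalars: bool = True):
        """Build from a simulated angle store (see pipeline module)."""
        from . import stabilogram as sg
        from .pipeline import _rep_channels

        study = store["study"]
        reps = study["repetitions"]
        participants = {p.participant_id: p for p in study["participants"]}
        # surrogate normalization is global (no CNN in the loop, the ridge
        # centring absorbs scale); grids are only summarised, never learned on
        series: dict = {}
        for r in reps:
            chans = _rep_channels(store, r.repetition_id, placements,
                                  channel_types)
            for placement in placements:
                for ctype in channel_types:
                    ml, ap = chans[placement][ctype]
                    series.setdefault((placement, ctype, "ml"), []).append(ml)
                    series.setdefault((placement, ctype, "ap"), []).append(ap)
        stats = sg.fit_normalizer(series)
        features = {p: [] for p in placements}
        labels = np.empty(len(reps))
        scalars = np.empty((len(reps), len(ds.SCALAR_FEATURE_NAMES)))
        pids = np.empty(len(reps), dtype=int)
        for i, r in enumerate(reps):
            chans = _rep_channels(store, r.repetition_id, placements,
                                  channel_types)
            for placement in placements:
                feats = []
                for ctype in channel_types:
                    ml, ap = chans[placement][ctype]
                    grid = sg.make_stabilogram(
                        ml, ap, stats.get(placement, ctype, "ml"),
                        stats.get(placement, ctype, "ap"),
                        channel_type=ctype, placement=placement)
                    feats.append(grid_summary_features(grid.occupancy))
                features[placement].append(np.concatenate(feats))
            labels[i] = ds.gt_label(r.panel.pt_ratings)
            scalars[i] = ds.scalar_features(participants[r.participant_id],
                                            r.condition)
            pids[i] = r.participant_id
        return cls(features={p: np.asarray(v) for p, v in features.items()},
                   scalars=scalars, labels=labels, participant_ids=pids,
                   splits=splits, alpha=alpha, include_scalars=include_scalars)

    def __call__(self, subset) -> tuple:
        from sklearn.linear_model import Ridge
        from sklearn.preprocessing import StandardScaler

        self.n_calls += 1
        self.evaluated.append(tuple(subset))
        blocks = [self.features[p] for p in subset]
        if self.include_scalars:
            blocks.append(self.scalars)
        x = np.hstack(blocks)
        rmses = []
        for split in self.splits:
            tr_mask = np.isin(self.participant_ids, list(split.train_ids))
            va_mask = np.isin(self.participant_ids, list(split.val_ids))
            scaler = StandardScaler().fit(x[tr_mask])
            model = Ridge(alpha=self.alpha)
            model.fit(scaler.transform(x[tr_mask]), self.labels[tr_mask])
            pred = model.predict(scaler.transform(x[va_mask]))
            rmses.append(np.sqrt(np.mean((pred - self.labels[va_mask]) ** 2)))
        rmses = np.asarray(rmses)
        return float(rmses.mean()), float(rmses.var())


def exhaustive_select(all_placements, evaluate_subset) -> dict:
    """Oracle: evaluate every non-empty subset (for small placement counts).

    Returns ``{size: [SensorSubsetResult, ...]}`` ranked like the beam
    search, for exhaustive-vs-greedy comparisons.
    """
    from itertools import combinations

    all_placements = tuple(all_placements)
    results: dict = {}
    for size in range(1, len(all_placements) + 1):
        evaluated = []
        for combo in combinations(all_placements, size):
            rmse, var, extras = _normalize_score(evaluate_subset(combo))
            evaluated.append(SensorSubsetResult(
                placements=combo, mean_val_rmse=rmse, score_var=var, **extras))
        evaluated.sort(key=lambda r: (r.mean_val_rmse, r.score_var,
                                      tuple(sorted(r.placements))))
        evaluated[0].is_best_of_size = True
        results[size] = evaluated
    return results
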