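"""Model-ready dataset assembly.

Turns simulated (or recorded) repetitions into records the regressor
consumes: ordinal label-encoded exercise variables, participant scalar
features, stabilogram channel stacks, ground-truth labels (the mean of the
PT rating panel), inverse rating-frequency sample weights, and the
participant-level stratified 5-fold split with train / validation / test
roles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import CONDITION_LEVELS, ExerciseCondition

#: Ordinal label encodings, ascending expected challenge (1-based).
ENCODINGS = {
    name: {cat: i + 1 for i, cat in enumerate(levels)}
    for name, levels in CONDITION_LEVELS.items()
}

SCALAR_FEATURE_NAMES = ("age", "sex", "height", "weight",
                        "surface", "stance", "eyes", "head_turns")


@dataclass(frozen=True)
class ExerciseEncoding:
    surface: int
    stance: int
    eyes: int
    head_turns: int


@dataclass(frozen=True)
class FoldSplit:
    """Participant-id partition for one cross-validation iteration."""

    fold_index: int
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset

    def __post_init__(self):
        if (self.train_ids & self.val_ids or self.train_ids & self.test_ids
                or self.val_ids & self.test_ids):
            raise ValueError("train/val/test participant sets overlap")


@dataclass
class RepetitionRecord:
    """One repetition as the model sees it."""

    participant_id: int
    scalar_features: np.ndarray  # (8,) per SCALAR_FEATURE_NAMES
    stabilogram_stack: list
    gt_label: float
    self_rating: int
    pt_ratings: tuple
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not np.isclose(self.gt_label, float(np.mean(self.pt_ratings))):
            raise ValueError("gt_label must equal mean(pt_ratings)")


def encode_exercise(condition: ExerciseCondition) -> ExerciseEncoding:
    """Ordinal label encoding of the four sensory-condition variables."""
    try:
        return ExerciseEncoding(
            surface=ENCODINGS["surface"][condition.surface],
            stance=ENCODINGS["stance"][condition.stance],
            eyes=ENCODINGS["eyes"][condition.eyes],
            head_turns=ENCODINGS["head_turns"][condition.head_turns],
        )
    except KeyError as exc:  # pragma: no cover - constructor already validates
        raise ValueError(f"unknown category {exc}") from exc


def gt_label(pt_ratings) -> float:
    """Ground truth = arithmetic mean of the PT rating panel."""
    ratings = np.asarray(pt_ratings, dtype=float)
    if ratings.size == 0:
        raise ValueError("pt_ratings must be non-empty")
    return float(ratings.mean())


def round_rating(x) -> np.ndarray:
    """Round half away from zero and clamp to the 1-5 scale.

    The one rounding rule used everywhere: weight classes, classification.
    """
    x = np.asarray(x, dtype=float)
    return np.clip(np.floor(x + 0.5), 1, 5).astype(int)


def rating_frequency_weights(gt_labels) -> np.ndarray:
    """Inverse-frequency sample weights over rounded GT classes.

    w_c = N / (K * n_c) for the K classes present, so the mean weight over
    records is exactly 1.
    """
    labels = np.asarray(gt_labels, dtype=float)
    if labels.size == 0:
        raise ValueError("gt_labels must be non-empty")
    classes = round_rating(labels)
    uniq, counts = np.unique(classes, return_counts=True)
    k = len(uniq)
    n = labels.size
    per_class = {c: n / (k * cnt) for c, cnt in zip(uniq, counts)}
    return np.array([per_class[c] for c in classes])


def stratified_participant_folds(participant_ids, participant_mean_labels,
                                 k: int = 5, seed: int = 0,
                                 val_fraction: float = 0.2) -> list:
    """Stratified k-fold partition at the participant level.

    Participants are ordered by their mean GT label (seeded shuffle breaks
    ties) and dealt round-robin into k test folds, which balances the label
    distribution across folds. Within each fold iteration the remaining
    participants are split ~(1 - val_fraction)/val_fraction into train and
    validation by the same deal-by-rank scheme. Every participant appears in
    exactly one test fold; roles within a fold are disjoint.
    """
    ids = list(participant_ids)
    if len(ids) < k:
        raise ValueError("need at least k participants")
    labels = {pid: float(participant_mean_labels[pid]) for pid in ids}
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    ranked = sorted(shuffled, key=lambda pid: labels[pid])
    test_folds = [ranked[i::k] for i in range(k)]

    splits = []
    for fold_index in range(k):
        test_ids = set(test_folds[fold_index])
        rest = [pid for pid in ranked if pid not in test_ids]
        n_val = max(1, int(round(val_fraction * len(rest))))
        # evenly spaced ranks keep the validation labels stratified too
        val_pos = ((np.arange(n_val) + 0.5) * len(rest) / n_val).astype(int)
        val_ids = {rest[i] for i in val_pos}
        train_ids = set(rest) - val_ids
        splits.append(FoldSplit(
            fold_index=fold_index + 1,
            train_ids=frozenset(train_ids),
            val_ids=frozenset(val_ids),
            test_ids=frozenset(test_ids)))
    return splits


def scalar_features(profile, condition) -> np.ndarray:
    """(age, sex{F:0, M:1}, height, weight, surface, stance, eyes, head_turns)."""
    enc = encode_exercise(condition)
    return np.array([
        profile.age, 0.0 if profile.sex == "F" else 1.0,
        profile.height, profile.weight,
        enc.surface, enc.stance, enc.eyes, enc.head_turns,
    ], dtype=float)


def standardize_scalars(train_x: np.ndarray, *other_x) -> tuple:
    """Z-score scalar features with training-fold statistics only."""
    mean = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    return tuple((x - mean) / sd for x in (train_x, *other_x))


def write_split_manifest(path, splits) -> None:
    """JSON manifest: fold -> role -> sorted participant ids."""
    import json

    payload = {
        str(s.fold_index): {
            "train": sorted(s.train_ids),
            "val": sorted(s.val_ids),
            "test": sorted(s.test_ids),
        } for s in splits
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_split_manifest(path) -> list:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return [FoldSplit(fold_index=int(k),
                      train_ids=frozenset(v["train"]),
                      val_ids=frozenset(v["val"]),
                      test_ids=frozenset(v["test"]))
            for k, v in sorted(payload.items(), key=lambda kv: int(kv[0]))]
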