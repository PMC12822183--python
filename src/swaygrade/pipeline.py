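"""End-to-end composition: synthetic study -> orientation -> stabilograms ->
records -> trained bounded CNN -> evaluation report.

The sway simulation and orientation filtering run in chunks of repetitions
(the filter is batched over recordings), so a full cohort is processed
without holding raw 6-axis signals for more than one chunk at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from . import dataset as ds
from . import stabilogram as sg
from . import synthetic as syn
from . import training as tr
from .model import ModelConfig, build_model
from .orientation import EKFParams, ekf_orientation_batch


def simulate_angle_store(config: syn.CohortConfig, seed: int,
                         ekf_params: EKFParams | None = None,
                         chunk_recordings: int = 384,
                         channel_types=("angle",)) -> dict:
    """Simulate the study and filter every recording to pitch/roll series.

    Returns ``{"study", "angles", "raw"}`` where ``angles[rep_id][placement]
    = (pitch, roll)`` float32 arrays of EKF-estimated segment tilt, and
    ``raw`` (present when accel/gyro channels are requested) holds the
    aligned (ML, AP) component pairs per channel type.
    """
    study = syn.generate_study(config, seed, keep_recordings=False)
    reps = study["repetitions"]
    participants = {p.participant_id: p for p in study["participants"]}
    placements = config.placements
    need_raw = any(c in channel_types for c in ("accel", "gyro"))

    per_rep = len(placements)
    reps_per_chunk = max(1, chunk_recordings // per_rep)
    angles: dict = {}
    raw: dict = {}
    for lo in range(0, len(reps), reps_per_chunk):
        batch = reps[lo:lo + reps_per_chunk]
        recordings = []
        for r in batch:
            recs = syn.simulate_sway(
                participants[r.participant_id], r.condition,
                syn.LatentIntensity(r.intensity), config.duration,
                config.sample_rate,
                seed=int(syn.substream(seed, f"swayseed/{r.repetition_id}"
                                       ).integers(2 ** 31)),
                config=config.sway, placements=placements,
                inject_step_out=r.panel.step_out)
            recordings.append(recs)
        accel = np.stack([rec.accel for recs in recordings for rec in recs])
        gyro = np.stack([rec.gyro for recs in recordings for rec in recs])
        pitch, roll = ekf_orientation_batch(accel, gyro, config.sample_rate,
                                            ekf_params)
        for i, r in enumerate(batch):
            angles[r.repetition_id] = {}
            if need_raw:
                raw[r.repetition_id] = {}
            for j, placement in enumerate(placements):
                k = i * per_rep + j
                angles[r.repetition_id][placement] = (
                    pitch[k].astype(np.float32), roll[k].astype(np.float32))
                if need_raw:
                    raw[r.repetition_id][placement] = {
                        "accel": (accel[k, :, 1].astype(np.float32),
                                  accel[k, :, 0].astype(np.float32)),
                        "gyro": (gyro[k, :, 0].astype(np.float32),
                                 gyro[k, :, 1].astype(np.float32)),
                    }
    return {"study": study, "angles": angles, "raw": raw}


def _rep_channels(store: dict, rep_id: int, placements,
                  channel_types) -> dict:
    out = {}
    for placement in placements:
        chans = {}
        for ctype in channel_types:
            if ctype == "angle":
                pitch, roll = store["angles"][rep_id][placement]
                chans["angle"] = (roll, pitch)  # x = ML, y = AP
            else:
                chans[ctype] = store["raw"][rep_id][placement][ctype]
        out[placement] = chans
    return out


def assemble_fold_data(store: dict, split: ds.FoldSplit, placements,
                       channel_types=("angle",)) -> dict:
    """Build model-ready arrays for one fold split.

    The stabilogram normalizer and the scalar-feature standardization are
    fitted on training-fold repetitions only; grids enter the model as
    occupancy fractions.
    """
    study = store["study"]
    participants = {p.participant_id: p for p in study["participants"]}
    roles = {"train": split.train_ids, "val": split.val_ids,
             "test": split.test_ids}
    rep_by_role = {role: [r for r in study["repetitions"]
                          if r.participant_id in ids]
                   for role, ids in roles.items()}

    train_series: dict = {}
    for r in rep_by_role["train"]:
        chans = _rep_channels(store, r.repetition_id, placements,
                              channel_types)
        for placement in placements:
            for ctype in channel_types:
                ml, ap = chans[placement][ctype]
                train_series.setdefault((placement, ctype, "ml"), []).append(ml)
                train_series.setdefault((placement, ctype, "ap"), []).append(ap)
    stats = sg.fit_normalizer(train_series)

    out = {"norm_stats": stats, "placements": tuple(placements),
           "channel_types": tuple(channel_types)}
    scalars = {}
    for role, reps in rep_by_role.items():
        grids = np.empty((len(reps), len(placements) * len(channel_types),
                          sg.GRID_SIZE, sg.GRID_SIZE), dtype=np.float32)
        labels = np.empty(len(reps))
        feats = np.empty((len(reps), len(ds.SCALAR_FEATURE_NAMES)))
        self_ratings = []
        panels = []
        intensities = np.empty(len(reps))
        pids = np.empty(len(reps), dtype=int)
        for i, r in enumerate(reps):
            chans = _rep_channels(store, r.repetition_id, placements,
                                  channel_types)
            stack = sg.build_channel_stack(chans, placements, channel_types,
                                           stats)
            grids[i] = np.stack([s.occupancy for s in stack])
            labels[i] = ds.gt_label(r.panel.pt_ratings)
            feats[i] = ds.scalar_features(participants[r.participant_id],
                                          r.condition)
            self_ratings.append(r.panel.self_rating)
            panels.append(r.panel.pt_ratings)
            intensities[i] = r.intensity
            pids[i] = r.participant_id
        out[role] = {"grids": grids, "labels": labels,
                     "self_ratings": self_ratings, "panels": panels,
                     "latent_intensity": intensities, "participant_ids": pids}
        scalars[role] = feats
    std = ds.standardize_scalars(scalars["train"], scalars["val"],
                                 scalars["test"])
    for role, x in zip(("train", "val", "test"), std):
        out[role]["scalars"] = x.astype(np.float32)
    out["train"]["weights"] = ds.rating_frequency_weights(
        out["train"]["labels"])
    return out


def participant_mean_labels(study: dict) -> dict:
    """Mean GT label per participant (the fold-stratification variable)."""
    sums: dict = {}
    counts: dict = {}
    for r in study["repetitions"]:
        g = ds.gt_label(r.panel.pt_ratings)
        sums[r.participant_id] = sums.get(r.participant_id, 0.0) + g
        counts[r.participant_id] = counts.get(r.participant_id, 0) + 1
    return {pid: sums[pid] / counts[pid] for pid in sums}


@dataclass
class ExperimentResult:
    """One trained-and-evaluated fold (or pooled folds) of the pipeline."""

    report: tr.EvaluationReport
    curves: tr.TrainingCurves
    test_rmse: float
    dummy_rmse: float
    random_pt_rmse: float
    self_rating_rmse: float
    spearman_latent: float
    config: ModelConfig
    fold_results: list = field(default_factory=list)


def run_fold_experiment(cohort_config: syn.CohortConfig, seed: int,
                        placements=None, model_config: ModelConfig | None = None,
                        epochs: int = 40, fold_index: int = 0,
                        channel_types=("angle",),
                        store: dict | None = None) -> ExperimentResult:
    """Full pipeline on one cross-validation fold of a synthetic study."""
    placements = tuple(placements or cohort_config.placements)
    if store is None:
        import dataclasses as _dc

        cfg = _dc.replace(cohort_config, placements=placements)
        store = simulate_angle_store(cfg, seed, channel_types=channel_types)
    study = store["study"]
    means = participant_mean_labels(study)
    splits = ds.stratified_participant_folds(
        sorted(means), means, k=5, seed=seed)
    data = assemble_fold_data(store, splits[fold_index], placements,
                              channel_types)

    n_channels = len(placements) * len(channel_types)
    if model_config is None:
        model_config = ModelConfig(conv_filters=8, dense_sizes=(32, 8),
                                   dropout_rate=0.2,
                                   n_input_channels=n_channels, seed=seed)
    model = build_model(model_config)
    curves = tr.train(model, data["train"], data["val"], epochs=epochs,
                      seed=seed)
    preds = model.predict(data["test"]["grids"], data["test"]["scalars"])
    gt = data["test"]["labels"]
    report = tr.evaluate_model(
        preds, gt, data["test"]["self_ratings"], data["test"]["panels"],
        train_labels=data["train"]["labels"], seed=seed)
    rho = sp_stats.spearmanr(preds, data["test"]["latent_intensity"]).statistic
    return ExperimentResult(
        report=report, curves=curves,
        test_rmse=report.rmse,
        dummy_rmse=report.benchmark_rmse["dummy"][0],
        random_pt_rmse=report.benchmark_rmse["random_pt"][0],
        self_rating_rmse=report.benchmark_rmse["self_rating"][0],
        spearman_latent=float(rho), config=model_config)
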