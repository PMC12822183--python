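"""Synthetic cohort generator for balance-exercise intensity studies.

Emulates the statistical structure of a multi-IMU balance-training study:
participants with a latent steadiness ability, static standing exercises
graded by sensory-condition demand (surface, stance, eyes, head turns),
intensity-dependent multi-segment postural sway recorded by up to 13
body-worn IMUs at 128 Hz, panels of 1-5 integer physical-therapist (PT)
ratings around the latent intensity, and downward-biased self-ratings.

All randomness flows from a single master seed through named substreams
(cohort / schedule / sway / ratings) so each stage can be regenerated
independently and the full pipeline is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from scipy.spatial.transform import Rotation

GRAVITY = 9.81  # m/s^2
DEFAULT_SAMPLE_RATE = 128.0  # Hz
DEFAULT_DURATION = 30.0  # s

#: Canonical placement order for the 13 wearable IMUs.
PLACEMENTS = (
    "head", "upper_back", "lumbar",
    "left_arm", "right_arm", "left_wrist", "right_wrist",
    "left_thigh", "right_thigh", "left_shank", "right_shank",
    "left_foot", "right_foot",
)

#: Sensory-condition categories in ascending order of expected added challenge.
CONDITION_LEVELS = {
    "surface": ("firm", "foam", "rocker", "bosu"),
    "stance": ("feet_apart", "feet_together", "semi_tandem", "tandem", "single_leg"),
    "eyes": ("open", "closed"),
    "head_turns": ("none", "horizontal", "vertical"),
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """One balance-exercise participant.

    ``latent_ability`` is a unitless steadiness score (higher = steadier);
    it shifts the latent intensity of every exercise the participant performs.
    """

    participant_id: int
    age: float
    sex: str  # "F" | "M"
    height: float  # cm
    weight: float  # kg
    latent_ability: float

    def __post_init__(self):
        if not (18.0 <= self.age <= 90.0):
            raise ValueError(f"age {self.age} outside [18, 90]")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if not np.isfinite(self.latent_ability):
            raise ValueError("latent_ability must be finite")


@dataclass(frozen=True)
class ExerciseCondition:
    """Sensory-condition variables defining one static standing exercise."""

    surface: str
    stance: str
    eyes: str
    head_turns: str

    def __post_init__(self):
        for name in ("surface", "stance", "eyes", "head_turns"):
            value = getattr(self, name)
            if value not in CONDITION_LEVELS[name]:
                raise ValueError(f"unknown {name} category {value!r}")


@dataclass(frozen=True)
class LatentIntensity:
    """Latent 1-5 intensity linking condition demand and ability to ratings."""

    value: float

    def __post_init__(self):
        if not (1.0 <= self.value <= 5.0):
            raise ValueError(f"intensity {self.value} outside [1, 5]")


@dataclass
class IMURecording:
    """One sensor's synchronized 6-axis time series for one repetition.

    ``true_pitch`` / ``true_roll`` carry the noise-free simulator angles when
    the recording is synthetic; they exist only for oracle tests and are never
    consumed by the estimation pipeline.
    """

    placement: str
    sample_rate: float
    accel: np.ndarray  # (N, 3) m/s^2, segment/sensor frame
    gyro: np.ndarray  # (N, 3) rad/s
    timestamps: np.ndarray  # (N,) s
    true_pitch: np.ndarray | None = None
    true_roll: np.ndarray | None = None

    def __post_init__(self):
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel/gyro/timestamps lengths disagree")
        if n > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("timestamps must be strictly increasing and uniform")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class RatingPanel:
    """PT rating panel plus the exerciser's self-rating for one repetition."""

    pt_ratings: tuple
    self_rating: int
    step_out: bool = False

    def __post_init__(self):
        if len(self.pt_ratings) == 0:
            raise ValueError("pt_ratings must be non-empty")
        for r in (*self.pt_ratings, self.self_rating):
            if int(r) != r or not (1 <= r <= 5):
                raise ValueError(f"rating {r} not an integer in [1, 5]")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class IntensityParams:
    """Linear-in-encodings latent-intensity model, clamped to [1, 5].

    Weight values are per encoding step (encoding 1 contributes zero).
    """

    base: float = 1.0
    surface_weight: float = 0.5
    stance_weight: float = 0.5
    eyes_weight: float = 0.4
    head_turns_weight: float = 0.3

    @property
    def weights(self) -> dict:
        return {
            "surface": self.surface_weight,
            "stance": self.stance_weight,
            "eyes": self.eyes_weight,
            "head_turns": self.head_turns_weight,
        }


# Segment-specific compensatory gains: hip-strategy segments (thighs, lumbar)
# sway most with rising intensity; distal fixed points (feet) least.
DEFAULT_PLACEMENT_GAINS = {
    "head": 1.0, "upper_back": 1.2, "lumbar": 1.5,
    "left_arm": 0.9, "right_arm": 0.9, "left_wrist": 0.8, "right_wrist": 0.8,
    "left_thigh": 1.6, "right_thigh": 1.6, "left_shank": 1.0, "right_shank": 1.0,
    "left_foot": 0.7, "right_foot": 0.7,
}


@dataclass
class SwayConfig:
    """Statistical sway model: two band-limited Gaussian components.

    Slow drift (0.1-0.5 Hz) and faster tremor (0.5-2 Hz) are mixed by
    variance fraction, then scaled so the true-angle RMS grows linearly
    with latent intensity and with a per-placement gain.
    """

    amp_base_deg: float = 0.3  # RMS at intensity 1, gain 1
    amp_slope_deg: float = 0.55  # RMS increase per intensity step
    drift_band_hz: tuple = (0.1, 0.5)
    tremor_band_hz: tuple = (0.5, 2.0)
    drift_fraction: float = 0.7  # fraction of angle variance in the drift band
    gyro_noise_sd: float = 0.003  # rad/s white noise on the rate channels
    accel_noise_sd: float = 0.04  # m/s^2 white noise on the accel channels
    placement_gains: dict = field(default_factory=lambda: dict(DEFAULT_PLACEMENT_GAINS))
    step_out_enabled: bool = False
    step_out_threshold: float = 4.0  # latent intensity at which transients appear
    step_out_amp_deg: float = 8.0


@dataclass
class CohortConfig:
    """Master configuration for a synthetic study dataset."""

    n_participants: int = 47
    age_mean: float = 51.0
    age_sd: float = 18.0
    female_fraction: float = 30 / 47
    ability_sd: float = 0.75
    n_exercises: int = 8
    reps_per_exercise: int = 3
    pt_sd: float = 0.5
    self_bias: float = -0.5
    sample_rate: float = DEFAULT_SAMPLE_RATE
    duration: float = DEFAULT_DURATION
    intensity: IntensityParams = field(default_factory=IntensityParams)
    sway: SwayConfig = field(default_factory=SwayConfig)
    placements: tuple = PLACEMENTS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["placements"] = list(self.placements)
        return d


# ---------------------------------------------------------------------------
# Cohort and schedule
# ---------------------------------------------------------------------------

def generate_cohort(n_participants: int, seed: int, *,
                    age_mean: float = 51.0, age_sd: float = 18.0,
                    female_fraction: float = 30 / 47,
                    ability_sd: float = 0.75) -> list:
    """Draw a cohort of participant profiles.

    Ages follow a normal distribution (default 51 +/- 18 y) truncated to
    [18, 90]; sex is Bernoulli with the configured female fraction; height
    and weight are sex-conditional normals; latent ability is standard
    normal scaled by ``ability_sd``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = substream(seed, "cohort")
    a, b = (18.0 - age_mean) / age_sd, (90.0 - age_mean) / age_sd
    ages = sp_stats.truncnorm.rvs(a, b, loc=age_mean, scale=age_sd,
                                  size=n_participants, random_state=rng)
    sexes = np.where(rng.random(n_participants) < female_fraction, "F", "M")
    abilities = rng.normal(0.0, ability_sd, size=n_participants)
    profiles = []
    for i in range(n_participants):
        if sexes[i] == "F":
            height = rng.normal(166.0, 7.0)
            weight = rng.normal(70.0, 13.0)
        else:
            height = rng.normal(176.0, 7.0)
            weight = rng.normal(83.0, 12.0)
        profiles.append(ParticipantProfile(
            participant_id=i + 1,
            age=float(ages[i]),
            sex=str(sexes[i]),
            height=float(max(height, 120.0)),
            weight=float(max(weight, 35.0)),
            latent_ability=float(abilities[i]),
        ))
    return profiles


def truncated_age_moments(age_mean: float = 51.0, age_sd: float = 18.0) -> tuple:
    """Exact (mean, sd) of the truncated age distribution the cohort draws from."""
    a, b = (18.0 - age_mean) / age_sd, (90.0 - age_mean) / age_sd
    m, v = sp_stats.truncnorm.stats(a, b, loc=age_mean, scale=age_sd, moments="mv")
    return float(m), float(np.sqrt(v))


def all_conditions() -> list:
    """Every combination of the sensory-condition variables (4x5x2x3 = 120)."""
    out = []
    for s in CONDITION_LEVELS["surface"]:
        for st in CONDITION_LEVELS["stance"]:
            for e in CONDITION_LEVELS["eyes"]:
                for h in CONDITION_LEVELS["head_turns"]:
                    out.append(ExerciseCondition(s, st, e, h))
    return out


def condition_demand(condition: ExerciseCondition,
                     params: IntensityParams | None = None) -> float:
    """Summed demand-weight contribution of a condition's encodings."""
    params = params or IntensityParams()
    total = 0.0
    for name, weight in params.weights.items():
        level = CONDITION_LEVELS[name].index(getattr(condition, name))
        total += weight * level
    return total


def assign_schedule(profile: ParticipantProfile, n_exercises: int = 8,
                    reps_per_exercise: int = 3, seed: int = 0,
                    params: IntensityParams | None = None) -> list:
    """Pick ``n_exercises`` distinct conditions spanning the demand range.

    Conditions are ranked by demand and sampled at evenly spaced quantiles
    with a small seeded jitter, so every schedule covers easy-to-hard.
    Returns ``[(condition, repetition_index), ...]`` with 1-based rep index.
    """
    if not (1 <= n_exercises <= 8):
        raise ValueError("n_exercises must be in [1, 8]")
    if reps_per_exercise < 1:
        raise ValueError("reps_per_exercise must be >= 1")
    rng = substream(seed, f"schedule/{profile.participant_id}")
    conditions = all_conditions()
    order = np.argsort([condition_demand(c, params) for c in conditions],
                       kind="stable")
    n_total = len(conditions)
    if n_exercises == 1:
        anchors = np.array([rng.integers(n_total)])
    else:
        anchors = np.linspace(0, n_total - 1, n_exercises)
        jitter = rng.integers(-4, 5, size=n_exercises)
        anchors = np.clip(np.round(anchors + jitter).astype(int), 0, n_total - 1)
        anchors = np.unique(anchors)
        while len(anchors) < n_exercises:  # jitter collisions: fill nearest free slot
            free = np.setdiff1d(np.arange(n_total), anchors)
            anchors = np.sort(np.append(anchors, rng.choice(free)))
    schedule = []
    for idx in anchors:
        cond = conditions[order[idx]]
        for rep in range(1, reps_per_exercise + 1):
            schedule.append((cond, rep))
    return schedule


def latent_intensity(profile: ParticipantProfile, condition: ExerciseCondition,
                     params: IntensityParams | None = None) -> LatentIntensity:
    """Latent 1-5 intensity: clamp(base + demand - ability, 1, 5).

    Strictly non-decreasing in every condition encoding and non-increasing
    in ability (before the clamp binds).
    """
    params = params or IntensityParams()
    raw = params.base + condition_demand(condition, params) - profile.latent_ability
    return LatentIntensity(float(np.clip(raw, 1.0, 5.0)))


# ---------------------------------------------------------------------------
# Sway simulation
# ---------------------------------------------------------------------------

def _bandlimited_unit_noise(rng: np.random.Generator, n: int, band: tuple,
                            sample_rate: float) -> np.ndarray:
    """Zero-phase band-pass filtered white noise, rescaled to unit RMS."""
    white = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    sos = sp_signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="band",
                           output="sos")
    x = sp_signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _sway_angle_series(rng: np.random.Generator, n: int, target_rms: float,
                       config: SwayConfig, sample_rate: float) -> np.ndarray:
    if target_rms == 0.0:
        return np.zeros(n)
    drift = _bandlimited_unit_noise(rng, n, config.drift_band_hz, sample_rate)
    tremor = _bandlimited_unit_noise(rng, n, config.tremor_band_hz, sample_rate)
    mix = (np.sqrt(config.drift_fraction) * drift
           + np.sqrt(1.0 - config.drift_fraction) * tremor)
    mix_rms = np.sqrt(np.mean(mix ** 2))
    return mix * (target_rms / mix_rms)


def _angles_to_imu(pitch: np.ndarray, roll: np.ndarray, sample_rate: float,
                   rng: np.random.Generator, gyro_noise_sd: float,
                   accel_noise_sd: float) -> tuple:
    """Exact inverse kinematics: angles -> body-frame gyro and gravity accel.

    Orientation is segment-to-world R = Rz(0) Ry(pitch) Rx(roll). The gyro is
    the body angular velocity reproducing the orientation increments, so a
    filter that integrates it recovers the angles exactly in the noiseless
    case. The accelerometer reads the gravity vector (0, 0, -g) expressed in
    the segment frame plus white noise (no linear-acceleration term).
    """
    n = len(pitch)
    dt = 1.0 / sample_rate
    eul = np.zeros((n, 3))
    eul[:, 1] = pitch
    eul[:, 2] = roll
    rot = Rotation.from_euler("zyx", eul)
    # body-frame angular velocity from successive orientation increments
    delta = rot[:-1].inv() * rot[1:]
    omega = np.zeros((n, 3))
    omega[:-1] = delta.as_rotvec() / dt
    if n > 1:
        omega[-1] = omega[-2]
    g_world = np.array([0.0, 0.0, -GRAVITY])
    accel = rot.inv().apply(g_world)
    if gyro_noise_sd > 0:
        omega = omega + rng.normal(0.0, gyro_noise_sd, size=(n, 3))
    if accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, accel_noise_sd, size=(n, 3))
    return accel, omega


def simulate_sway(profile: ParticipantProfile, condition: ExerciseCondition,
                  intensity: LatentIntensity, duration: float = DEFAULT_DURATION,
                  sample_rate: float = DEFAULT_SAMPLE_RATE, seed: int = 0,
                  config: SwayConfig | None = None,
                  placements: tuple = PLACEMENTS,
                  inject_step_out: bool | None = None) -> list:
    """Simulate one repetition's IMU recordings for the requested placements.

    True pitch/roll per segment are band-limited Gaussian sway whose RMS
    scales linearly with latent intensity and a per-placement gain; the
    recordings carry the noise-free angles for oracle tests.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    config = config or SwayConfig()
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if inject_step_out is None:
        inject_step_out = (config.step_out_enabled
                           and intensity.value >= config.step_out_threshold)
    recordings = []
    for placement in placements:
        rng = substream(seed, f"sway/{profile.participant_id}/{placement}")
        gain = config.placement_gains.get(placement, 1.0)
        rms_deg = (config.amp_base_deg
                   + config.amp_slope_deg * (intensity.value - 1.0)) * gain
        target_rms = np.deg2rad(rms_deg)
        pitch = _sway_angle_series(rng, n, target_rms, config, sample_rate)
        roll = _sway_angle_series(rng, n, target_rms, config, sample_rate)
        if inject_step_out:
            # one-second half-sine lurch, the kinematic signature of a step out
            start = rng.integers(int(5 * sample_rate), int(max(6, duration - 6) * sample_rate))
            width = int(sample_rate)
            bump = np.deg2rad(config.step_out_amp_deg) * np.sin(
                np.pi * np.arange(width) / width)
            pitch[start:start + width] += bump[: max(0, n - start)]
        accel, gyro = _angles_to_imu(pitch, roll, sample_rate, rng,
                                     config.gyro_noise_sd, config.accel_noise_sd)
        recordings.append(IMURecording(
            placement=placement, sample_rate=sample_rate,
            accel=accel, gyro=gyro, timestamps=t,
            true_pitch=pitch, true_roll=roll,
        ))
    return recordings


# ---------------------------------------------------------------------------
# Rating panels
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (ratings are positive: floor(x + 0.5))."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def simulate_ratings(intensity: LatentIntensity, n_pts: int, pt_sd: float = 0.5,
                     self_bias: float = -0.5, seed: int = 0,
                     step_out: bool = False) -> RatingPanel:
    """Noisy ordinal ratings around the latent intensity.

    Each PT rating is ``clamp(round(I + N(0, pt_sd)), 1, 5)``; the
    self-rating adds a (negative by default) bias before the same noise,
    emulating exercisers overestimating their own steadiness.
    """
    if not (1 <= n_pts <= 5):
        raise ValueError("n_pts must be in [1, 5]")
    if pt_sd < 0:
        raise ValueError("pt_sd must be >= 0")
    rng = substream(seed, "ratings")
    pt = np.clip(_round_half_away(
        intensity.value + rng.normal(0.0, pt_sd, size=n_pts)), 1, 5)
    self_r = np.clip(_round_half_away(
        intensity.value + self_bias + rng.normal(0.0, pt_sd)), 1, 5)
    return RatingPanel(pt_ratings=tuple(int(r) for r in pt),
                       self_rating=int(self_r), step_out=step_out)


def rating_category_probabilities(intensity: float, sd: float) -> np.ndarray:
    """Exact category probabilities of clamp(round(I + N(0, sd)), 1, 5).

    Analytic enumeration oracle: interior categories are Phi bands of half
    width 0.5; the end categories absorb the tails.
    """
    if sd == 0:
        probs = np.zeros(5)
        probs[int(np.clip(np.floor(intensity + 0.5), 1, 5)) - 1] = 1.0
        return probs
    edges = np.array([-np.inf, 1.5, 2.5, 3.5, 4.5, np.inf])
    cdf = sp_stats.norm.cdf(edges, loc=intensity, scale=sd)
    return np.diff(cdf)


# ---------------------------------------------------------------------------
# Whole-study generation and CSV/YAML export
# ---------------------------------------------------------------------------

@dataclass
class RepetitionMeta:
    """Metadata for one simulated repetition (signals stored separately)."""

    repetition_id: int
    participant_id: int
    exercise_index: int
    repetition_index: int
    condition: ExerciseCondition
    intensity: float
    panel: RatingPanel


def generate_study(config: CohortConfig, seed: int,
                   keep_recordings: bool = True) -> dict:
    """Generate a full synthetic study: cohort, schedules, sway, ratings.

    Returns ``{"config", "participants", "repetitions", "recordings"}`` where
    ``recordings[rep_id]`` is the list of IMURecording (present only when
    ``keep_recordings``).  Deterministic given (config, seed).
    """
    participants = generate_cohort(
        config.n_participants, seed, age_mean=config.age_mean,
        age_sd=config.age_sd, female_fraction=config.female_fraction,
        ability_sd=config.ability_sd)
    reps: list[RepetitionMeta] = []
    recordings: dict[int, list] = {}
    rep_id = 0
    panel_rng = substream(seed, "panel_sizes")
    for profile in participants:
        schedule = assign_schedule(profile, config.n_exercises,
                                   config.reps_per_exercise, seed,
                                   config.intensity)
        ex_index = {}
        for cond, rep_index in schedule:
            ex_index.setdefault(cond, len(ex_index) + 1)
            inten = latent_intensity(profile, cond, config.intensity)
            step_out = (config.sway.step_out_enabled
                        and inten.value >= config.sway.step_out_threshold)
            n_pts = int(panel_rng.integers(1, 6))
            panel = simulate_ratings(
                inten, n_pts, config.pt_sd, config.self_bias,
                seed=int(substream(seed, f"panelseed/{rep_id}").integers(2 ** 31)),
                step_out=step_out)
            reps.append(RepetitionMeta(
                repetition_id=rep_id, participant_id=profile.participant_id,
                exercise_index=ex_index[cond], repetition_index=rep_index,
                condition=cond, intensity=inten.value, panel=panel))
            if keep_recordings:
                recordings[rep_id] = simulate_sway(
                    profile, cond, inten, config.duration, config.sample_rate,
                    seed=int(substream(seed, f"swayseed/{rep_id}").integers(2 ** 31)),
                    config=config.sway, placements=config.placements,
                    inject_step_out=step_out)
            rep_id += 1
    return {"config": config, "participants": participants,
            "repetitions": reps, "recordings": recordings}


def write_study(study: dict, out_dir) -> None:
    """Write a generated study to CSV/YAML files.

    Layout: ``cohort.csv`` (participant descriptors), ``repetitions.csv``
    (encodable condition, ratings, latent intensity for oracle use), one
    ``imu/rep{ID}_{placement}.csv`` per recording with columns
    t, ax, ay, az, gx, gy, gz, and ``config.yaml``.
    """
    import pathlib

    import pandas as pd
    import yaml

    out = pathlib.Path(out_dir)
    (out / "imu").mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(p) for p in study["participants"]]
                 ).to_csv(out / "cohort.csv", index=False)
    rows = []
    for r in study["repetitions"]:
        rows.append({
            "repetition_id": r.repetition_id,
            "participant_id": r.participant_id,
            "exercise_index": r.exercise_index,
            "repetition_index": r.repetition_index,
            "surface": r.condition.surface, "stance": r.condition.stance,
            "eyes": r.condition.eyes, "head_turns": r.condition.head_turns,
            "pt_ratings": "|".join(str(x) for x in r.panel.pt_ratings),
            "self_rating": r.panel.self_rating,
            "step_out": r.panel.step_out,
            "latent_intensity": r.intensity,
        })
    pd.DataFrame(rows).to_csv(out / "repetitions.csv", index=False)
    for rep_id, recs in study["recordings"].items():
        for rec in recs:
            df = pd.DataFrame({
                "t": rec.timestamps,
                "ax": rec.accel[:, 0], "ay": rec.accel[:, 1], "az": rec.accel[:, 2],
                "gx": rec.gyro[:, 0], "gy": rec.gyro[:, 1], "gz": rec.gyro[:, 2],
            })
            df.to_csv(out / "imu" / f"rep{rep_id}_{rec.placement}.csv",
                      index=False, float_format="%.6f")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(study["config"].to_dict(), fh, sort_keys=False)
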