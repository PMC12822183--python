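"""2-D stabilogram featurization of body-segment sway.

A stabilogram is a 64x64 occupancy grid of paired medial-lateral (x) and
anterior-posterior (y) signal samples after z-score normalization, with the
grid domain truncated to +/-3.2 standard deviations per axis (99.86% of a
standard normal axis falls inside). Normalization statistics are fitted on
training-fold data only, so validation and test grids never leak their own
scale into the representation.

Axis convention: x = medial-lateral (roll for angle channels), y =
anterior-posterior (pitch). Binning is half-open [lo, hi) with bin width
6.4/64 = 0.1 sd and the final cell closed; out-of-domain samples are clipped
to the nearest edge cell so every grid conserves sample mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

GRID_SIZE = 64
DOMAIN_BOUND = 3.2  # sd units
SD_FLOOR = 1e-8

CHANNEL_TYPES = ("angle", "accel", "gyro")
AXES = ("ml", "ap")


@dataclass
class NormStats:
    """Per (placement, channel_type, axis) mean/sd fitted on training data."""

    stats: dict = field(default_factory=dict)  # key -> (mean, sd)

    def get(self, placement: str, channel_type: str, axis: str) -> tuple:
        return self.stats[(placement, channel_type, axis)]

    def keys(self):
        return self.stats.keys()

    def to_records(self) -> list:
        return [{"placement": p, "channel_type": c, "axis": a,
                 "mean": m, "sd": s}
                for (p, c, a), (m, s) in sorted(self.stats.items())]

    @classmethod
    def from_records(cls, records) -> "NormStats":
        return cls({(r["placement"], r["channel_type"], r["axis"]):
                    (float(r["mean"]), float(r["sd"])) for r in records})


@dataclass
class Stabilogram:
    """64x64 occupancy grid over a truncated, normalized 2-D signal domain."""

    grid: np.ndarray  # (grid_size, grid_size) counts; grid[iy, ix]
    channel_type: str
    placement: str
    n_samples: int
    grid_size: int = GRID_SIZE
    bound: float = DOMAIN_BOUND

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.shape != (self.grid_size, self.grid_size):
            raise ValueError("grid shape mismatch")
        if int(self.grid.sum()) != self.n_samples:
            raise ValueError("grid mass does not equal n_samples")

    @property
    def occupancy(self) -> np.ndarray:
        """Counts divided by n_samples: the duration-free model input."""
        return self.grid.astype(np.float64) / max(self.n_samples, 1)


def inside_domain_fraction(bound: float = DOMAIN_BOUND) -> float:
    """Fraction of a standard-normal axis inside +/-bound sd: 2*Phi(b) - 1."""
    from scipy.stats import norm

    return float(2.0 * norm.cdf(bound) - 1.0)


def fit_normalizer(training_series: dict) -> NormStats:
    """Fit per-key mean/sd from training-fold value series.

    ``training_series`` maps (placement, channel_type, axis) to either one
    array or a list of arrays (one per training repetition); arrays are
    pooled before the moments are taken. Standard deviations are floored at
    a small epsilon so constant series cannot produce a degenerate scale.
    """
    stats = {}
    for key, series in training_series.items():
        if isinstance(series, (list, tuple)):
            if len(series) == 0:
                raise ValueError(f"empty series list for {key}")
            values = np.concatenate([np.asarray(s, dtype=float).ravel()
                                     for s in series])
        else:
            values = np.asarray(series, dtype=float).ravel()
        if values.size == 0:
            raise ValueError(f"empty series for {key}")
        mean = float(values.mean())
        sd = float(values.std())
        if sd < SD_FLOOR:
            logger.warning("near-constant series for %s; flooring sd at %g",
                           key, SD_FLOOR)
            sd = SD_FLOOR
        stats[key] = (mean, sd)
    return NormStats(stats)


def _bin_indices(z: np.ndarray, grid_size: int, bound: float) -> np.ndarray:
    width = 2.0 * bound / grid_size
    idx = np.floor((z + bound) / width).astype(np.int64)
    return np.clip(idx, 0, grid_size - 1)


def make_stabilogram(x_series: np.ndarray, y_series: np.ndarray,
                     x_stats: tuple, y_stats: tuple,
                     grid_size: int = GRID_SIZE, bound: float = DOMAIN_BOUND,
                     channel_type: str = "angle",
                     placement: str = "") -> Stabilogram:
    """Bin a normalized (ML, AP) signal pair into an occupancy grid.

    Each axis is z-scored with its training statistics, then binned into
    ``grid_size`` half-open cells over [-bound, +bound); samples outside the
    domain are clipped to the nearest edge cell, conserving mass.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    x = np.asarray(x_series, dtype=float).ravel()
    y = np.asarray(y_series, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y series must have equal length")
    zx = (x - x_stats[0]) / x_stats[1]
    zy = (y - y_stats[0]) / y_stats[1]
    ix = _bin_indices(zx, grid_size, bound)
    iy = _bin_indices(zy, grid_size, bound)
    grid = np.zeros((grid_size, grid_size), dtype=np.int64)
    np.add.at(grid, (iy, ix), 1)
    return Stabilogram(grid=grid, channel_type=channel_type,
                       placement=placement, n_samples=x.size,
                       grid_size=grid_size, bound=bound)


def build_channel_stack(rep_channels: dict, placements, channel_types,
                        stats: NormStats, grid_size: int = GRID_SIZE,
                        bound: float = DOMAIN_BOUND) -> list:
    """One stabilogram per (placement, channel_type), in the given order.

    ``rep_channels`` maps placement -> channel_type -> (ml_series, ap_series)
    for one repetition: angle uses (roll, pitch); accel the segment-frame
    (ML, AP) linear components; gyro the (roll-rate, pitch-rate) components.
    Placements iterate outermost so permuting the requested sensor order
    permutes the output stack identically.
    """
    if len(placements) == 0:
        raise ValueError("placements must be non-empty")
    for c in channel_types:
        if c not in CHANNEL_TYPES:
            raise ValueError(f"unknown channel type {c!r}")
    stack = []
    for placement in placements:
        if placement not in rep_channels:
            raise KeyError(f"placement {placement!r} absent from data")
        for ctype in channel_types:
            ml, ap = rep_channels[placement][ctype]
            stack.append(make_stabilogram(
                ml, ap,
                stats.get(placement, ctype, "ml"),
                stats.get(placement, ctype, "ap"),
                grid_size=grid_size, bound=bound,
                channel_type=ctype, placement=placement))
    return stack


def recording_channels(recording, orientation) -> dict:
    """Extract the (ML, AP) channel pairs for one recording + orientation.

    Segment frame: x forward, y left, z up. AP linear acceleration is the
    forward (x) accel component, ML the lateral (y); pitch rate is the gyro
    y component, roll rate the x component.
    """
    return {
        "angle": (orientation.roll, orientation.pitch),
        "accel": (recording.accel[:, 1], recording.accel[:, 0]),
        "gyro": (recording.gyro[:, 0], recording.gyro[:, 1]),
    }


def write_stacks_hdf5(path, stacks: dict, placements, channel_types,
                      stats: NormStats) -> None:
    """Persist stabilogram stacks to HDF5, one group per repetition.

    ``stacks`` maps repetition_id -> list of Stabilogram (channel order
    follows ``placements`` x ``channel_types``); normalization statistics
    and the channel ordering are stored as file-level metadata.
    """
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["placements"] = json.dumps(list(placements))
        fh.attrs["channel_types"] = json.dumps(list(channel_types))
        fh.attrs["norm_stats"] = json.dumps(stats.to_records())
        for rep_id, stack in stacks.items():
            grp = fh.create_group(f"rep{rep_id}")
            grids = np.stack([s.grid for s in stack])
            dset = grp.create_dataset("grids", data=grids, compression="gzip")
            dset.attrs["n_samples"] = stack[0].n_samples


def read_stacks_hdf5(path) -> tuple:
    """Inverse of :func:`write_stacks_hdf5`; returns (stacks, meta)."""
    import json

    import h5py

    stacks = {}
    with h5py.File(path, "r") as fh:
        meta = {
            "placements": json.loads(fh.attrs["placements"]),
            "channel_types": json.loads(fh.attrs["channel_types"]),
            "norm_stats": NormStats.from_records(
                json.loads(fh.attrs["norm_stats"])),
        }
        for name in fh:
            rep_id = int(name[3:])
            grids = fh[name]["grids"][...]
            n = int(fh[name]["grids"].attrs["n_samples"])
            stacks[rep_id] = [
                Stabilogram(grid=g, channel_type="", placement="",
                            n_samples=n) for g in grids]
    return stacks, meta
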