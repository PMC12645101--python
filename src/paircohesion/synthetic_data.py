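"""Synthetic receiver arrays, coupled pair movement, and beacon detections.

The generator emulates the data-collecting machinery of a grid-based automated
radio-telemetry study of a territorial, pair-living songbird:

* a rectangular array of receivers ("nodes") ~100-150 m apart covering on the
  order of 1 km**2;
* tags beaconing every 15 s, detected by nearby receivers with a probability
  that decays with distance and drops sharply when the tag is near the ground;
* received signal strength following the fitted RSS-distance law plus
  Gaussian noise in dB;
* pair members moving as mean-reverting (Ornstein-Uhlenbeck) processes around
  a shared territory center, with one member (the current "leader") moving
  independently and the other, with probability ``coupling`` per step,
  relocating toward the leader's position over a short following timescale.

Every downstream stage of the pipeline (localization, home-range overlap,
cohesion) can therefore be validated against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import REFERENCE_CURVE, CalibrationCurve, distance_to_rss
from .errors import InvalidParameterError

__all__ = [
    "ReceiverArray",
    "MovementConfig",
    "EmissionConfig",
    "TruthTrack",
    "CALIBRATION_DISTANCES_M",
    "generate_receiver_array",
    "simulate_pair_tracks",
    "emit_detections",
    "generate_calibration_walk",
]

#: Standard calibration-walk distance design (m): 18 set intervals, 1-200 m.
CALIBRATION_DISTANCES_M = (
    1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 12.5, 15.0,
    20.0, 25.0, 30.0, 40.0, 50.0, 75.0, 100.0, 150.0, 200.0,
)


@dataclass(frozen=True)
class ReceiverArray:
    """Planar receiver grid: unique string ids and (x, y) coordinates in m."""

    ids: tuple[str, ...]
    xy: np.ndarray  # shape (n, 2), meters

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(self.ids) < 1:
            raise InvalidParameterError("array needs at least one receiver")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidParameterError("receiver ids must be unique")
        if xy.shape != (len(self.ids), 2) or not np.all(np.isfinite(xy)):
            raise InvalidParameterError("coordinates must be finite (n, 2)")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) bounding rectangle in meters."""
        return (
            float(self.xy[:, 0].min()),
            float(self.xy[:, 1].min()),
            float(self.xy[:, 0].max()),
            float(self.xy[:, 1].max()),
        )

    def coords(self, receiver_id: str) -> np.ndarray:
        try:
            i = self.ids.index(receiver_id)
        except ValueError:
            from .errors import MissingReceiverError

            raise MissingReceiverError(receiver_id) from None
        return self.xy[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.ids, "x_m": self.xy[:, 0], "y_m": self.xy[:, 1]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReceiverArray":
        return cls(tuple(df["node_id"].astype(str)), df[["x_m", "y_m"]].to_numpy(float))


@dataclass(frozen=True)
class MovementConfig:
    """Coupled-pair movement parameters.

    ``home_range_sd`` is the stationary standard deviation (m, per axis) of
    the OU position process; ``ou_timescale`` its mean-reversion time (s).
    ``coupling`` is the per-step probability that the non-leading partner
    relocates toward the leader (over timescale ``follow_lag_mean`` s) instead
    of reverting to its own territory center.  Roles swap symmetrically with
    probability ``role_switch_per_min`` per minute.

    ``period_schedule`` optionally makes the home-range sd and coupling
    time-dependent (e.g. ranges expanding once breeding ends): a sorted tuple
    of (start_epoch_s, home_range_sd, coupling) segments, each in force from
    its start time until the next segment's; the scalar fields apply before
    the first segment.
    """

    centers: Mapping[str, tuple[float, float]]
    home_range_sd: float = 30.0
    ou_timescale: float = 600.0
    coupling: float = 0.8
    follow_lag_mean: float = 60.0
    step_interval: float = 15.0
    role_switch_per_min: float = 0.1
    period_schedule: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise InvalidParameterError("coupling must be in [0, 1]")
        for name in ("home_range_sd", "ou_timescale", "follow_lag_mean", "step_interval"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.role_switch_per_min < 0:
            raise InvalidParameterError("role_switch_per_min must be >= 0")
        starts = [seg[0] for seg in self.period_schedule]
        if starts != sorted(starts):
            raise InvalidParameterError("period_schedule must be sorted by start time")
        for _, sd, coup in self.period_schedule:
            if not sd > 0 or not 0.0 <= coup <= 1.0:
                raise InvalidParameterError("period_schedule sd must be > 0, coupling in [0, 1]")

    def params_at(self, t: float) -> tuple[float, float]:
        """(home_range_sd, coupling) in force at epoch time ``t``."""
        sd, coup = self.home_range_sd, self.coupling
        for start, seg_sd, seg_coup in self.period_schedule:
            if t >= start:
                sd, coup = seg_sd, seg_coup
            else:
                break
        return sd, coup


@dataclass(frozen=True)
class EmissionConfig:
    """Beacon emission and detection model.

    Detection probability is logistic in distance,
    ``p_max / (1 + exp((d - detect_midpoint)/detect_width))``, multiplied by
    ``ground_height_penalty`` when the tag is in the ``ground`` height class
    (tags ~10 cm off the ground are detected roughly an order of magnitude
    less often than elevated tags).  RSS is the inverse calibration curve at
    the true distance (clamped below at ``min_distance``) plus Gaussian noise.
    """

    curve: CalibrationCurve = REFERENCE_CURVE
    rss_noise_sd: float = 2.0
    max_detect_distance: float = 200.0
    p_max: float = 0.95
    detect_midpoint: float = 100.0
    detect_width: float = 25.0
    ground_height_penalty: float = 1.0 / 8.3
    min_distance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise InvalidParameterError("p_max must be in [0, 1]")
        if not 0.0 < self.ground_height_penalty <= 1.0:
            raise InvalidParameterError("ground_height_penalty must be in (0, 1]")
        for name in ("max_detect_distance", "detect_width", "min_distance"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def detect_prob(self, distance, height_class: str = "elevated"):
        """Detection probability at a distance (m); non-increasing in distance."""
        d = np.asarray(distance, dtype=float)
        p = self.p_max / (1.0 + np.exp((d - self.detect_midpoint) / self.detect_width))
        if height_class == "ground":
            p = p * self.ground_height_penalty
        p = np.where(d > self.max_detect_distance, 0.0, p)
        return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class TruthTrack:
    """Ground-truth trajectory of one individual on the beacon grid."""

    individual_id: str
    times: np.ndarray  # epoch seconds, strictly increasing at step_interval
    xy: np.ndarray  # shape (n, 2), meters
    pair_id: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xy", xy)
        if len(times) != len(xy):
            raise InvalidParameterError("times and positions must align")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise InvalidParameterError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(xy)):
            raise InvalidParameterError("positions must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "time_s": self.times,
                "x_m": self.xy[:, 0],
                "y_m": self.xy[:, 1],
                "pair_id": self.pair_id,
                "sex": self.sex,
            }
        )


def generate_receiver_array(
    nx: int,
    ny: int,
    spacing: float,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ReceiverArray:
    """Jittered rectangular receiver grid.

    ``nx * ny`` receivers at ``spacing`` meters, each displaced by iid
    Gaussian jitter with sd ``jitter_sd`` (0 for a perfect lattice).
    Deterministic for a fixed seed.
    """
    if nx < 1 or ny < 1:
        raise InvalidParameterError("nx and ny must be >= 1")
    if not spacing > 0:
        raise InvalidParameterError("spacing must be > 0")
    if jitter_sd < 0:
        raise InvalidParameterError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xy = np.column_stack([gx.ravel() * spacing + origin[0], gy.ravel() * spacing + origin[1]])
    xy = xy.astype(float)
    if jitter_sd > 0:
        xy += rng.normal(0.0, jitter_sd, size=xy.shape)
    ids = tuple(f"N{i + 1:03d}" for i in range(nx * ny))
    return ReceiverArray(ids, xy)


def simulate_pair_tracks(
    config: MovementConfig,
    duration: float,
    seed: int | None = None,
    start_time: float = 0.0,
    pair_id: str = "P01",
    sexes: tuple[str, str] = ("F", "M"),
) -> tuple[TruthTrack, TruthTrack]:
    """Simulate a coupled pair as leader-follower OU processes.

    The leader takes an exact-discretization OU step toward its territory
    center each ``step_interval``.  The partner, with probability
    ``coupling``, mean-reverts toward the leader's new position with
    timescale ``follow_lag_mean``; otherwise it takes its own OU step.  The
    per-step positional noise always uses the individual's intrinsic OU
    diffusion, so following tightens the pair without inflating step noise.
    Roles swap via a symmetric Markov chain.

    Returns the two tracks in the order of ``config.centers`` keys.
    """
    dt = config.step_interval
    if duration < 2 * dt:
        raise InvalidParameterError("duration must be >= 2 * step_interval")
    ids = list(config.centers)
    if len(ids) != 2:
        raise InvalidParameterError("centers must name exactly 2 individuals")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    times = start_time + np.arange(n) * dt

    centers = np.array([config.centers[i] for i in ids], dtype=float)
    phi_own = math.exp(-dt / config.ou_timescale)
    noise_factor = math.sqrt(1.0 - phi_own**2)
    phi_follow = math.exp(-dt / config.follow_lag_mean)
    p_switch = min(1.0, config.role_switch_per_min * dt / 60.0)

    pos = np.empty((2, n, 2))
    sd0, _ = config.params_at(times[0])
    pos[:, 0, :] = centers + rng.normal(0.0, sd0, size=(2, 2))  # stationary start
    leader = 0
    for t in range(1, n):
        sd, coupling = config.params_at(times[t])
        step_sd = sd * noise_factor
        if rng.random() < p_switch:
            leader = 1 - leader
        fol = 1 - leader
        z = rng.normal(0.0, step_sd, size=(2, 2))
        new_l = centers[leader] + (pos[leader, t - 1] - centers[leader]) * phi_own + z[0]
        pos[leader, t] = new_l
        if rng.random() < coupling:
            pos[fol, t] = new_l + (pos[fol, t - 1] - new_l) * phi_follow + z[1]
        else:
            pos[fol, t] = centers[fol] + (pos[fol, t - 1] - centers[fol]) * phi_own + z[1]

    return tuple(
        TruthTrack(ids[i], times, pos[i], pair_id=pair_id, sex=sexes[i]) for i in range(2)
    )


def emit_detections(
    tracks: Sequence[TruthTrack],
    array: ReceiverArray,
    emission: EmissionConfig,
    seed: int | None = None,
    height_class: str = "elevated",
    daylight: Sequence[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Turn ground-truth tracks into a noisy beacon-detection table.

    For each beacon time and each receiver within ``max_detect_distance``, a
    detection is emitted with probability ``emission.detect_prob``; its RSS is
    the inverse calibration curve at the true distance (clamped below at
    ``min_distance``) plus Gaussian dB noise.  ``daylight`` optionally
    restricts emission to half-open epoch-second intervals.

    Returns a DataFrame with columns tag_id, node_id, time_s, rss_db sorted
    by (time_s, tag_id, node_id); empty (with those columns) for an empty
    array or no detections.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for track in tracks:
        times = track.times
        mask_t = np.ones(len(times), dtype=bool)
        if daylight is not None:
            mask_t = np.zeros(len(times), dtype=bool)
            for lo, hi in daylight:
                mask_t |= (times >= lo) & (times < hi)
        t_used = times[mask_t]
        p_used = track.xy[mask_t]
        if len(t_used) == 0 or len(array.ids) == 0:
            continue
        # (n_times, n_receivers) distance matrix
        d = np.sqrt(((p_used[:, None, :] - array.xy[None, :, :]) ** 2).sum(axis=2))
        prob = emission.detect_prob(d, height_class=height_class)
        hit = rng.random(size=d.shape) < prob
        ti, ri = np.nonzero(hit)
        if len(ti) == 0:
            continue
        d_hit = np.maximum(d[ti, ri], emission.min_distance)
        rss = distance_to_rss(emission.curve, d_hit)
        rss = rss + rng.normal(0.0, emission.rss_noise_sd, size=len(ti))
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": track.individual_id,
                    "node_id": np.asarray(array.ids, dtype=object)[ri],
                    "time_s": t_used[ti],
                    "rss_db": rss,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["tag_id", "node_id", "time_s", "rss_db"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["time_s", "tag_id", "node_id"], kind="mergesort")
    return out.reset_index(drop=True)


def generate_calibration_walk(
    curve: CalibrationCurve = REFERENCE_CURVE,
    distances: Sequence[float] = CALIBRATION_DISTANCES_M,
    n_tags: int = 6,
    n_receivers: int = 4,
    rss_noise_sd: float = 2.0,
    seed: int | None = None,
    height_class: str = "elevated",
) -> pd.DataFrame:
    """Synthetic calibration walk: tags held at set distances from receivers.

    One observation per tag x receiver x distance, with observed RSS equal to
    the inverse curve at the true distance plus Gaussian dB noise.  Returns a
    DataFrame with columns tag_id, node_id, true_distance_m, height_class,
    rss_db.
    """
    if n_tags < 1 or n_receivers < 1:
        raise InvalidParameterError("n_tags and n_receivers must be >= 1")
    rng = np.random.default_rng(seed)
    dist = np.asarray(distances, dtype=float)
    if np.any(dist <= 0):
        raise InvalidParameterError("distances must be > 0")
    tags = [f"T{i + 1:02d}" for i in range(n_tags)]
    nodes = [f"N{i + 1:03d}" for i in range(n_receivers)]
    rows = []
    for tag in tags:
        for node in nodes:
            rss_true = distance_to_rss(curve, dist)
            rss_obs = rss_true + rng.normal(0.0, rss_noise_sd, size=len(dist))
            rows.append(
                pd.DataFrame(
                    {
                        "tag_id": tag,
                        "node_id": node,
                        "true_distance_m": dist,
                        "height_class": height_class,
                        "rss_db": rss_obs,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
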