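"""Dyadic proximity and following-behavior analysis.

Three complementary views of pair cohesion:

* **Separation series** — Euclidean distance between partners' simultaneous
  per-window locations, compared with a day-shift null: the focal bird on day
  x paired with its partner on day x+1 at the same time of day.  Independent
  movement should make the null and true distributions match; cohesive pairs
  show smaller true distances.
* **Movement and following events** — on the strongest-detection series, a
  movement event is a change of strongest receiver between consecutive
  localized windows (both above the confidence cutoff).  A following event is
  a leader's A->B relocation matched by its partner, which was at A at the
  leader's departure and next relocated to B.  Because detection gaps produce
  extreme lags, a per-dataset lag threshold at the 90th percentile of
  candidate lags (nearest-rank) separates plausible following from
  coincidence; following rates condition on both birds being observed within
  the threshold of the event.
* **Initiation attribution** — which pair member departs first from a shared
  receiver, yielding (a_first, b_first, simultaneous) shares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "CohesionConfig",
    "MovementEvent",
    "FollowingEvent",
    "separation_series",
    "extract_movement_events",
    "extract_following_events",
    "lag_threshold",
    "following_rate",
    "initiation_attribution",
]


@dataclass(frozen=True)
class CohesionConfig:
    """Settings for the proximity null and event detection.

    ``staleness_s`` bounds how long the partner may have gone unlocalized at
    location A before the leader's departure and still count as "present at
    A"; detections are too gappy for exact co-occurrence.
    """

    day_shift_days: int = 1
    lag_percentile: float = 90.0
    confidence_cutoff: float = -80.0
    window_s: float = 15.0
    staleness_s: float = 600.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lag_percentile <= 100.0:
            raise InvalidParameterError("lag_percentile must be in (0, 100]")
        if self.day_shift_days < 1:
            raise InvalidParameterError("day_shift_days must be >= 1")
        if not self.staleness_s > 0:
            raise InvalidParameterError("staleness_s must be > 0")


@dataclass(frozen=True)
class MovementEvent:
    """A change of strongest receiver between consecutive localized windows."""

    individual_id: str
    from_receiver: str
    to_receiver: str
    depart_time: float  # last localized window at the origin receiver
    arrive_time: float  # first localized window at the destination receiver


@dataclass(frozen=True)
class FollowingEvent:
    """A leader's A->B relocation mirrored by its partner within some lag."""

    pair_id: str
    leader_id: str
    follower_id: str
    location_a: str
    location_b: str
    leader_arrive_time: float
    follower_arrive_time: float
    lag_s: float


def separation_series(
    locs_a: pd.DataFrame,
    locs_b: pd.DataFrame,
    config: CohesionConfig = CohesionConfig(),
    mode: str = "true",
    pair_id: str = "",
) -> pd.DataFrame:
    """Per-window pair separation distances, observed or day-shift null.

    ``locs_a``/``locs_b`` are per-window estimate tables (columns
    window_start, x, y, optionally receiver_id) from the *same* localization
    method.  ``mode="true"`` matches identical windows; ``mode="null"``
    matches a's window on day x to b's window on day x+``day_shift_days`` at
    the same time of day (window index shifted by exactly the day offset).

    Returns columns: pair_id, window_start (a's clock), distance_m,
    same_receiver, kind.  Empty (with a warning) if no windows match.
    """
    if mode not in ("true", "null"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    shift = 0.0 if mode == "true" else config.day_shift_days * 86400.0
    a = locs_a[["window_start", "x", "y"]].copy()
    b = locs_b[["window_start", "x", "y"]].copy()
    has_recv = "receiver_id" in locs_a.columns and "receiver_id" in locs_b.columns
    if has_recv:
        a["receiver_id"] = locs_a["receiver_id"].to_numpy()
        b["receiver_id"] = locs_b["receiver_id"].to_numpy()
    b = b.rename(columns={c: c + "_b" for c in b.columns})
    b["window_start"] = b["window_start_b"] - shift  # b at day x+1 matches a at day x
    merged = a.merge(b, on="window_start", how="inner")
    if len(merged) == 0:
        logger.warning("no overlapping windows between the two series (mode=%s)", mode)
    out = pd.DataFrame(
        {
            "pair_id": pair_id,
            "window_start": merged["window_start"],
            "distance_m": np.sqrt(
                (merged["x"] - merged["x_b"]) ** 2 + (merged["y"] - merged["y_b"]) ** 2
            ),
            "same_receiver": (
                merged["receiver_id"] == merged["receiver_id_b"]
                if has_recv
                else pd.Series(False, index=merged.index)
            ),
            "kind": mode,
        }
    )
    return out.reset_index(drop=True)


def extract_movement_events(
    locs: pd.DataFrame, config: CohesionConfig = CohesionConfig()
) -> list[MovementEvent]:
    """Receiver changes between consecutive localized strongest-method windows.

    Unlocalized gaps are skipped: "previous detection" means the previous
    *localized* window, so A,(gap),B still yields one A->B event with
    depart/arrive at the observed windows.  Inputs are assumed above the
    confidence cutoff already (the strongest localizer enforces it).
    """
    df = locs.sort_values("window_start", kind="mergesort")
    tag = str(df["tag_id"].iloc[0]) if "tag_id" in df.columns and len(df) else ""
    recvs = df["receiver_id"].to_numpy()
    times = df["window_start"].to_numpy(float)
    events = []
    for i in range(1, len(df)):
        if recvs[i] != recvs[i - 1]:
            events.append(
                MovementEvent(
                    individual_id=tag,
                    from_receiver=str(recvs[i - 1]),
                    to_receiver=str(recvs[i]),
                    depart_time=float(times[i - 1]),
                    arrive_time=float(times[i]),
                )
            )
    return events


def extract_following_events(
    events_leader: Sequence[MovementEvent],
    locs_follower: pd.DataFrame,
    config: CohesionConfig = CohesionConfig(),
    pair_id: str = "",
) -> list[FollowingEvent]:
    """Candidate following events for each leader movement event.

    For a leader relocation A->B, the partner qualifies as a candidate
    follower when (i) its most recent localization at or before the leader's
    departure was at A and no older than ``staleness_s``, and (ii) its next
    localization at a different receiver after that is at B.  The candidate's
    lag is follower arrival minus leader arrival at B, floored at zero
    (sparse detections can record the follower at B first).  No lag threshold
    is applied here — thresholding happens downstream.
    """
    df = locs_follower.sort_values("window_start", kind="mergesort")
    fol = str(df["tag_id"].iloc[0]) if "tag_id" in df.columns and len(df) else ""
    times = df["window_start"].to_numpy(float)
    recvs = df["receiver_id"].to_numpy()
    out = []
    for ev in events_leader:
        i = int(np.searchsorted(times, ev.depart_time, side="right")) - 1
        if i < 0:
            continue
        if recvs[i] != ev.from_receiver:
            continue
        if ev.depart_time - times[i] > config.staleness_s:
            continue
        # follower's next localization at a receiver other than A
        j = i + 1
        while j < len(times) and recvs[j] == ev.from_receiver:
            j += 1
        if j >= len(times) or recvs[j] != ev.to_receiver:
            continue
        out.append(
            FollowingEvent(
                pair_id=pair_id,
                leader_id=ev.individual_id,
                follower_id=fol,
                location_a=ev.from_receiver,
                location_b=ev.to_receiver,
                leader_arrive_time=ev.arrive_time,
                follower_arrive_time=float(times[j]),
                lag_s=max(0.0, float(times[j]) - ev.arrive_time),
            )
        )
    return out


def lag_threshold(
    candidates: Sequence[FollowingEvent], config: CohesionConfig = CohesionConfig()
) -> float:
    """Nearest-rank percentile of candidate lags (default 90th).

    With the nearest-rank convention, at least ``lag_percentile`` percent of
    candidates fall at or below the returned threshold by construction.
    """
    lags = sorted(c.lag_s for c in candidates)
    if not lags:
        raise InsufficientDataError("no following-event candidates")
    rank = math.ceil(config.lag_percentile / 100.0 * len(lags))
    return float(lags[max(rank, 1) - 1])


def following_rate(
    events_leader: Sequence[MovementEvent],
    candidates: Sequence[FollowingEvent],
    threshold_s: float,
    locs_leader: pd.DataFrame,
    locs_follower: pd.DataFrame,
) -> dict:
    """Fraction of leader relocations followed by the partner within the lag.

    Denominator: leader movement events where *both* birds have at least one
    localization within ``threshold_s`` of the leader's arrival (events where
    either bird was unobserved that long are excluded, since following could
    not have been detected).  Numerator: events with a candidate whose lag is
    at or below the threshold.  Returns a dict with ``rate`` (NaN when the
    denominator is empty), ``n_events``, ``n_followed``, ``n_excluded``, and
    the per-event table under ``events`` (columns arrive_time, included,
    followed).
    """
    if not threshold_s > 0:
        raise InvalidParameterError("threshold_s must be > 0")
    t_leader = np.sort(locs_leader["window_start"].to_numpy(float))
    t_fol = np.sort(locs_follower["window_start"].to_numpy(float))

    def observed_near(ts: np.ndarray, t: float) -> bool:
        i = int(np.searchsorted(ts, t))
        before = ts[i - 1] if i > 0 else -np.inf
        after = ts[i] if i < len(ts) else np.inf
        return (t - before) <= threshold_s or (after - t) <= threshold_s

    followed_at = {}
    for c in candidates:
        key = (c.location_a, c.location_b, c.leader_arrive_time)
        if c.lag_s <= threshold_s:
            followed_at[key] = True
    rows = []
    for ev in events_leader:
        included = observed_near(t_leader, ev.arrive_time) and observed_near(
            t_fol, ev.arrive_time
        )
        followed = followed_at.get((ev.from_receiver, ev.to_receiver, ev.arrive_time), False)
        rows.append(
            {"arrive_time": ev.arrive_time, "included": included, "followed": followed and included}
        )
    events = pd.DataFrame(rows, columns=["arrive_time", "included", "followed"])
    n_inc = int(events["included"].sum())
    n_fol = int(events["followed"].sum())
    return {
        "rate": (n_fol / n_inc) if n_inc else float("nan"),
        "n_events": n_inc,
        "n_followed": n_fol,
        "n_excluded": len(events) - n_inc,
        "events": events,
    }


def initiation_attribution(
    locs_a: pd.DataFrame,
    locs_b: pd.DataFrame,
    config: CohesionConfig = CohesionConfig(),
) -> dict:
    """Who leaves a shared receiver first: shares of a-first/b-first/simultaneous.

    Episodes are maximal runs of matched windows where both birds' strongest
    receiver coincides.  At the end of each episode, each bird's departure
    window is its first subsequent localized window at a different receiver;
    the earlier departure wins, equal windows count as simultaneous.
    Episodes where either bird is never seen departing are skipped.  Shares
    sum to 1 over counted episodes (all zero when there are none).
    """
    cols = ["window_start", "receiver_id"]
    a = locs_a[cols].sort_values("window_start", kind="mergesort")
    b = locs_b[cols].sort_values("window_start", kind="mergesort")
    merged = a.merge(b, on="window_start", suffixes=("_a", "_b"), how="inner")
    shared = merged[merged["receiver_id_a"] == merged["receiver_id_b"]].reset_index(drop=True)
    counts = {"a_first": 0, "b_first": 0, "simultaneous": 0}
    if len(shared) == 0:
        return {**counts, "n_episodes": 0, "shares": {k: 0.0 for k in counts}}

    # episode boundaries: receiver changes or non-consecutive shared windows
    w = shared["window_start"].to_numpy(float)
    r = shared["receiver_id_a"].to_numpy()
    new_episode = np.ones(len(shared), dtype=bool)
    new_episode[1:] = (r[1:] != r[:-1]) | (np.diff(w) > config.window_s)
    episode_id = np.cumsum(new_episode)

    ta = a["window_start"].to_numpy(float)
    ra = a["receiver_id"].to_numpy()
    tb = b["window_start"].to_numpy(float)
    rb = b["receiver_id"].to_numpy()

    def depart_window(ts, rs, t_end, receiver):
        i = int(np.searchsorted(ts, t_end, side="right"))
        while i < len(ts) and rs[i] == receiver:
            i += 1
        return ts[i] if i < len(ts) else None

    for eid in np.unique(episode_id):
        mask = episode_id == eid
        t_end = w[mask].max()
        receiver = r[mask][0]
        da = depart_window(ta, ra, t_end, receiver)
        db = depart_window(tb, rb, t_end, receiver)
        if da is None or db is None:
            continue
        if da < db:
            counts["a_first"] += 1
        elif db < da:
            counts["b_first"] += 1
        else:
            counts["simultaneous"] += 1
    n = sum(counts.values())
    shares = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return {**counts, "n_episodes": n, "shares": shares}
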