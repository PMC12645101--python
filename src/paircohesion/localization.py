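"""Per-window tag localization from raw beacon detections.

Detections are grouped into epoch-aligned 15-second windows (half-open,
``[floor(t/15)*15, +15)``), keeping each receiver's strongest detection per
window.  Two localization methods are provided:

* **strongest** — the tag is placed at the receiver with the strongest
  detection, provided that detection is at or above the RSS cutoff (default
  -80 dB, i.e. within ~23.5 m of the receiver under the reference curve);
* **multilateration** — windows with at least ``min_receivers`` receivers and
  an above-cutoff strongest detection are localized by nonlinear least
  squares on RSS-derived distances, resampled ``n_resamples`` times around
  the calibration curve's residual spread to yield a mean position and a
  bivariate-normal error ellipse.

Diagnostics cover realized localization rates over daylight slots and the
distribution of localization gaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .calibration import CalibrationCurve, rss_to_distance
from .errors import InvalidParameterError, MissingReceiverError
from .synthetic_data import ReceiverArray

logger = logging.getLogger(__name__)

__all__ = [
    "LocalizationConfig",
    "DetectionWindow",
    "LocationEstimate",
    "window_detections",
    "localize_strongest",
    "localize_multilateration",
    "localize_windows",
    "localization_rate",
    "gap_distribution",
]


@dataclass(frozen=True)
class LocalizationConfig:
    """Windowing and localization settings."""

    window_s: float = 15.0
    rss_cutoff: float = -80.0
    min_receivers: int = 3
    n_resamples: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise InvalidParameterError("window_s must be > 0")
        if self.n_resamples < 2:
            raise InvalidParameterError("n_resamples must be >= 2")
        if self.min_receivers < 1:
            raise InvalidParameterError("min_receivers must be >= 1")


@dataclass(frozen=True)
class DetectionWindow:
    """All of one tag's detections in one aligned window.

    ``members`` holds at most one (receiver_id, rss) entry per receiver —
    the strongest detection of that receiver within the window.
    """

    tag_id: str
    window_start: float  # epoch seconds, aligned to the window grid
    members: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class LocationEstimate:
    """One per-window position fix."""

    tag_id: str
    window_start: float
    x: float
    y: float
    method: str  # "strongest" | "multilateration"
    n_receivers: int
    receiver_id: str | None = None  # strongest method only
    ellipse: tuple[float, float, float] | None = None  # (semi_major, semi_minor, theta_rad)


def _time_column(detections: pd.DataFrame) -> np.ndarray:
    if "time_s" in detections.columns:
        return np.asarray(detections["time_s"], dtype=float)
    if "time_utc" in detections.columns:
        t = pd.to_datetime(detections["time_utc"], utc=True)
        return t.astype("int64").to_numpy() / 1e9
    raise InvalidParameterError("detections need a time_s or time_utc column")


def window_detections(
    detections: pd.DataFrame, config: LocalizationConfig = LocalizationConfig()
) -> list[DetectionWindow]:
    """Group detections into aligned half-open windows, max RSS per receiver.

    Input order is irrelevant (records are sorted); exact duplicate records
    are dropped with a logged count.  Empty windows are omitted.
    """
    if len(detections) == 0:
        return []
    df = detections.copy()
    df["time_s"] = _time_column(df)
    if not np.all(np.isfinite(df["rss_db"])):
        raise InvalidParameterError("RSS values must be finite")
    n0 = len(df)
    df = df.drop_duplicates(subset=["tag_id", "node_id", "time_s", "rss_db"])
    if len(df) < n0:
        logger.info("dropped %d duplicate detection records", n0 - len(df))
    df["window_start"] = np.floor(df["time_s"] / config.window_s) * config.window_s
    best = (
        df.groupby(["tag_id", "window_start", "node_id"], sort=True)["rss_db"]
        .max()
        .reset_index()
    )
    windows = []
    for (tag, w), g in best.groupby(["tag_id", "window_start"], sort=True):
        members = tuple(sorted(zip(g["node_id"], g["rss_db"])))
        windows.append(DetectionWindow(str(tag), float(w), members))
    return windows


def localize_strongest(
    window: DetectionWindow,
    array: ReceiverArray,
    config: LocalizationConfig = LocalizationConfig(),
) -> LocationEstimate | None:
    """Place the tag at the receiver with the strongest above-cutoff detection.

    Returns None when every member is below the cutoff.  Ties at the maximum
    RSS resolve to the lowest receiver id.
    """
    if not window.members:
        return None
    best_rss = max(rss for _, rss in window.members)
    if best_rss < config.rss_cutoff:
        return None
    winner = min(rid for rid, rss in window.members if rss == best_rss)
    xy = array.coords(winner)  # raises MissingReceiverError if absent
    return LocationEstimate(
        tag_id=window.tag_id,
        window_start=window.window_start,
        x=float(xy[0]),
        y=float(xy[1]),
        method="strongest",
        n_receivers=len(window.members),
        receiver_id=winner,
    )


def _ellipse_from_cov(cov: np.ndarray) -> tuple[float, float, float]:
    """Semi-axes sqrt(2)*sqrt(eigenvalues) and orientation of the leading axis."""
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    theta = math.atan2(vecs[1, 0], vecs[0, 0])
    return (
        float(math.sqrt(2.0) * math.sqrt(vals[0])),
        float(math.sqrt(2.0) * math.sqrt(vals[1])),
        float(theta),
    )


def localize_multilateration(
    window: DetectionWindow,
    array: ReceiverArray,
    curve: CalibrationCurve,
    config: LocalizationConfig = LocalizationConfig(),
    rng: np.random.Generator | None = None,
) -> LocationEstimate | None:
    """Resampled nonlinear-least-squares multilateration for one window.

    Eligibility: at least ``min_receivers`` member receivers and a strongest
    detection at or above the cutoff.  Each resample draws per-receiver
    distances ``10**Normal(a + b*rss_i, residual_se)`` (log10-meter scale) and
    minimizes sum_i (||p - r_i|| - d_i)**2 over positions p bounded to the
    array box expanded by 200 m, starting from the inverse-distance-weighted
    receiver centroid.  The estimate is the mean of converged fits; the
    ellipse summarizes their spread.  Returns None if ineligible or if more
    than half the resamples fail to converge.
    """
    if not window.members:
        return None
    if len(window.members) < config.min_receivers:
        return None
    best_rss = max(rss for _, rss in window.members)
    if best_rss < config.rss_cutoff:
        return None
    if rng is None:
        rng = np.random.default_rng(config.seed)

    rec_xy = np.array([array.coords(rid) for rid, _ in window.members])
    rss = np.array([r for _, r in window.members], dtype=float)
    mu_log10 = curve.intercept + curve.slope * rss  # mean log10-distance
    w = 1.0 / np.maximum(10.0**mu_log10, 1e-6)
    x0 = (rec_xy * (w / w.sum())[:, None]).sum(axis=0)
    xmin, ymin, xmax, ymax = array.bounds
    lb = np.array([xmin - 200.0, ymin - 200.0])
    ub = np.array([xmax + 200.0, ymax + 200.0])
    x0 = np.clip(x0, lb, ub)

    fits = []
    n_failed = 0
    for _ in range(config.n_resamples):
        if curve.residual_se > 0:
            d = 10.0 ** rng.normal(mu_log10, curve.residual_se)
        else:
            d = 10.0**mu_log10

        def resid(p, d=d):
            return np.sqrt(((p - rec_xy) ** 2).sum(axis=1)) - d

        sol = least_squares(resid, x0, bounds=(lb, ub))
        if sol.success and np.all(np.isfinite(sol.x)):
            fits.append(sol.x)
        else:
            n_failed += 1
    if n_failed > config.n_resamples / 2:
        logger.warning(
            "window %s/%s: %d/%d resamples failed; no estimate",
            window.tag_id, window.window_start, n_failed, config.n_resamples,
        )
        return None
    fits = np.array(fits)
    mean = fits.mean(axis=0)
    cov = np.cov(fits.T) if len(fits) > 1 else np.zeros((2, 2))
    cov = np.atleast_2d(cov)
    if cov.shape != (2, 2):
        cov = np.zeros((2, 2))
    return LocationEstimate(
        tag_id=window.tag_id,
        window_start=window.window_start,
        x=float(mean[0]),
        y=float(mean[1]),
        method="multilateration",
        n_receivers=len(window.members),
        ellipse=_ellipse_from_cov(cov),
    )


def localize_windows(
    windows: Iterable[DetectionWindow],
    array: ReceiverArray,
    curve: CalibrationCurve | None = None,
    config: LocalizationConfig = LocalizationConfig(),
    method: str = "strongest",
) -> pd.DataFrame:
    """Localize many windows; returns a tidy estimates table.

    Columns: tag_id, window_start, x, y, method, n_receivers, receiver_id,
    ellipse_a_m, ellipse_b_m, ellipse_theta_rad.  One shared RNG (from
    ``config.seed``) drives all multilateration resampling, so results are
    reproducible for a fixed seed and window order.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for win in windows:
        if method == "strongest":
            est = localize_strongest(win, array, config)
        elif method == "multilateration":
            if curve is None:
                raise InvalidParameterError("multilateration needs a calibration curve")
            est = localize_multilateration(win, array, curve, config, rng=rng)
        else:
            raise InvalidParameterError(f"unknown method {method!r}")
        if est is None:
            continue
        ell = est.ellipse or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "tag_id": est.tag_id,
                "window_start": est.window_start,
                "x": est.x,
                "y": est.y,
                "method": est.method,
                "n_receivers": est.n_receivers,
                "receiver_id": est.receiver_id,
                "ellipse_a_m": ell[0],
                "ellipse_b_m": ell[1],
                "ellipse_theta_rad": ell[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tag_id", "window_start", "x", "y", "method", "n_receivers",
            "receiver_id", "ellipse_a_m", "ellipse_b_m", "ellipse_theta_rad",
        ],
    )


def _daylight_slots(
    daylight: Mapping | pd.DataFrame, lo: float, hi: float, window_s: float
) -> np.ndarray:
    """Aligned window starts within [lo, hi] that fall in a daylight interval.

    ``daylight`` maps date (or any key) to (start_epoch_s, end_epoch_s)
    half-open intervals, or is a DataFrame with sunrise_s / sunset_s columns.
    """
    if isinstance(daylight, pd.DataFrame):
        intervals = list(zip(daylight["sunrise_s"], daylight["sunset_s"]))
    else:
        intervals = list(daylight.values())
    if not intervals:
        raise InvalidParameterError("daylight table is empty")
    slots = []
    for start, end in intervals:
        s = np.arange(math.floor(start / window_s) * window_s, end, window_s)
        s = s[(s >= start) & (s < end)]
        s = s[(s >= math.floor(lo / window_s) * window_s) & (s <= hi)]
        slots.append(s)
    if not slots:
        return np.array([])
    return np.unique(np.concatenate(slots))


def localization_rate(
    estimates: pd.DataFrame,
    daylight: Mapping | pd.DataFrame,
    window_s: float = 15.0,
) -> pd.DataFrame:
    """Fraction of daylight windows localized, per tag and method.

    The tracked span per tag runs from its first to its last estimate (any
    method); the denominator is the number of aligned daylight windows in
    that span, the numerator the distinct localized windows per method.
    """
    if isinstance(daylight, pd.DataFrame):
        if len(daylight) == 0:
            raise InvalidParameterError("daylight table is empty")
    elif not daylight:
        raise InvalidParameterError("daylight table is empty")
    rows = []
    for tag, g in estimates.groupby("tag_id", sort=True):
        lo, hi = float(g["window_start"].min()), float(g["window_start"].max())
        slots = _daylight_slots(daylight, lo, hi, window_s)
        n_slots = len(slots)
        slot_set = set(slots.tolist())
        for method, gm in g.groupby("method", sort=True):
            localized = {w for w in gm["window_start"] if w in slot_set}
            rows.append(
                {
                    "tag_id": tag,
                    "method": method,
                    "n_daylight_slots": n_slots,
                    "n_localized": len(localized),
                    "rate": len(localized) / n_slots if n_slots else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["tag_id", "method", "n_daylight_slots", "n_localized", "rate"])


def gap_distribution(
    estimates: pd.DataFrame,
    daylight: Mapping | pd.DataFrame,
    window_s: float = 15.0,
) -> tuple[pd.DataFrame, dict]:
    """Lengths of unlocalized daylight runs, per tag, with summary fractions.

    Gaps are maximal runs of consecutive unlocalized daylight slots within
    each tag's tracked span; runs never span the night (each daylight
    interval is scanned separately, so an overnight gap splits at sunset and
    sunrise).  The summary reports the fraction of gaps shorter than 30 s and
    shorter than 10 min, over gap counts.
    """
    if isinstance(daylight, pd.DataFrame):
        intervals = list(zip(daylight["sunrise_s"], daylight["sunset_s"]))
    else:
        intervals = list(daylight.values())
    rows = []
    for tag, g in estimates.groupby("tag_id", sort=True):
        lo, hi = float(g["window_start"].min()), float(g["window_start"].max())
        have = set(g["window_start"].tolist())
        for start, end in intervals:
            s = np.arange(math.floor(start / window_s) * window_s, end, window_s)
            s = s[(s >= start) & (s < end) & (s >= lo) & (s <= hi)]
            run = 0
            run_start = None
            for w in s:
                if w in have:
                    if run:
                        rows.append({"tag_id": tag, "gap_start": run_start, "length_s": run * window_s})
                    run, run_start = 0, None
                else:
                    if run == 0:
                        run_start = float(w)
                    run += 1
            if run:
                rows.append({"tag_id": tag, "gap_start": run_start, "length_s": run * window_s})
    gaps = pd.DataFrame(rows, columns=["tag_id", "gap_start", "length_s"])
    n = len(gaps)
    summary = {
        "n_gaps": n,
        "frac_under_30s": float((gaps["length_s"] < 30).mean()) if n else np.nan,
        "frac_under_10min": float((gaps["length_s"] < 600).mean()) if n else np.nan,
    }
    return gaps, summary
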