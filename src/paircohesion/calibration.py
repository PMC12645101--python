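"""RSS-to-distance calibration for automated radio-telemetry receiver grids.

Received signal strength (RSS, negative dB) decays with tag-receiver distance.
Calibration walks — holding tags at known distances from receivers — yield
observations from which a log-linear law is fitted:

    log10(distance_m) = a + b * RSS

so that ``distance = 10**(a + b*RSS)`` with ``b < 0`` (weaker signal, larger
distance).  The residual standard error of the regression, on the log10-meter
scale, quantifies the spread used when resampling distances during
multilateration.

The module also computes per-test-point detection metrics (detection rate,
number of receivers, mean/max RSS) used to quantify how tag elevation above
ground affects detectability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SingularFitError

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "CalibrationObservation",
    "REFERENCE_CURVE",
    "fit_calibration",
    "rss_to_distance",
    "distance_to_rss",
    "point_detection_metrics",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted RSS-distance law ``distance_m = 10**(intercept + slope*rss)``.

    Parameters
    ----------
    intercept
        log10-meters at RSS = 0 dB.
    slope
        log10-meters per dB; negative for physical signal decay.
    residual_se
        Residual standard error of the log10(distance) regression, in
        log10-meters.  Zero means a noiseless (or unfitted) curve.
    n_obs
        Number of calibration observations behind the fit (0 for curves
        constructed directly from coefficients).
    """

    intercept: float
    slope: float
    residual_se: float = 0.0
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise InvalidParameterError("curve coefficients must be finite")
        if self.residual_se < 0:
            raise InvalidParameterError("residual_se must be >= 0")


#: Default calibration for CTT node-grid hardware with tags held at 1.5 m:
#: distance(m) = 10**(-1.27009 - 0.03302*RSS).  Maps -80 dB to a 23.5 m radius.
REFERENCE_CURVE = CalibrationCurve(intercept=-1.27009, slope=-0.03302)


@dataclass(frozen=True)
class CalibrationObservation:
    """One calibration-walk record: a tag at a known distance from a receiver."""

    true_distance_m: float
    rss_db: float
    tag_id: str = ""
    receiver_id: str = ""
    height_class: str = "elevated"

    def __post_init__(self) -> None:
        if not self.true_distance_m > 0:
            raise InvalidParameterError("true_distance_m must be > 0")


def _obs_to_frame(obs) -> pd.DataFrame:
    if isinstance(obs, pd.DataFrame):
        return obs
    return pd.DataFrame(
        {
            "true_distance_m": [o.true_distance_m for o in obs],
            "rss_db": [o.rss_db for o in obs],
        }
    )


def fit_calibration(obs: Iterable[CalibrationObservation] | pd.DataFrame) -> CalibrationCurve:
    """Fit the RSS-distance law by OLS of log10(distance) on RSS.

    Parameters
    ----------
    obs
        Either a sequence of :class:`CalibrationObservation` or a DataFrame
        with columns ``true_distance_m`` and ``rss_db``.  All tags and
        receivers are pooled into one global curve.

    Returns
    -------
    CalibrationCurve
        With ``residual_se`` set to the residual standard error of the
        regression (ddof = 2).

    Raises
    ------
    InsufficientDataError / SingularFitError
        For fewer than 3 observations or a degenerate design (fewer than two
        distinct RSS values), and when the fitted slope is non-negative
        (an unphysical curve where signal does not decay with distance).
    """
    df = _obs_to_frame(obs)
    d = np.asarray(df["true_distance_m"], dtype=float)
    rss = np.asarray(df["rss_db"], dtype=float)
    if np.any(d <= 0):
        raise InvalidParameterError("all true distances must be > 0")
    n = len(d)
    if n < 3:
        raise SingularFitError(f"need >= 3 calibration observations, got {n}")
    if np.unique(rss).size < 2:
        raise SingularFitError("all RSS values identical: design is singular")

    y = np.log10(d)
    X = np.column_stack([np.ones(n), rss])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise SingularFitError("rank-deficient calibration design")
    resid = y - X @ beta
    residual_se = float(np.sqrt(resid @ resid / (n - 2)))
    intercept, slope = float(beta[0]), float(beta[1])
    if slope >= 0:
        raise SingularFitError(
            f"fitted slope {slope:.4g} is non-negative; RSS does not decay "
            "with distance in these data"
        )
    return CalibrationCurve(intercept, slope, residual_se, n)


def rss_to_distance(curve: CalibrationCurve, rss):
    """Evaluate the calibration law: distance in meters at an RSS in dB.

    Vectorized over ``rss``.
    """
    rss = np.asarray(rss, dtype=float)
    if not np.all(np.isfinite(rss)):
        raise InvalidParameterError("rss must be finite")
    out = 10.0 ** (curve.intercept + curve.slope * rss)
    return float(out) if out.ndim == 0 else out


def distance_to_rss(curve: CalibrationCurve, d):
    """Invert the calibration law: RSS in dB at a distance in meters.

    Exact inverse of :func:`rss_to_distance`.  Vectorized over ``d``.
    """
    if curve.slope == 0:
        raise InvalidParameterError("slope 0: curve is not invertible")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise InvalidParameterError("distance must be > 0")
    out = (np.log10(d) - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


def point_detection_metrics(
    detections: pd.DataFrame,
    expected_beacons: int | Mapping,
    points: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-test-point detection summaries for elevation-effect analysis.

    Parameters
    ----------
    detections
        One row per received beacon, columns ``test_point_id``,
        ``height_class``, ``node_id``, ``time_s``, ``rss_db``.  A beacon
        received by several receivers in the same instant counts once toward
        the detection rate (distinct ``time_s`` per point).
    expected_beacons
        Expected number of beacon emissions per test point (e.g. 8 for a
        2-minute hold at 15-s intervals), or a mapping
        ``(test_point_id, height_class) -> count``.
    points
        Optional full roster of ``(test_point_id, height_class)`` so that
        points with zero detections still appear (rate 0, RSS missing).

    Returns
    -------
    DataFrame with columns test_point_id, height_class, detection_rate,
    n_receivers, mean_rss, max_rss.
    """

    def expected_for(key) -> float:
        exp = expected_beacons[key] if isinstance(expected_beacons, Mapping) else expected_beacons
        if not exp >= 1:
            raise InvalidParameterError(f"expected beacon count must be >= 1, got {exp}")
        return float(exp)

    rows = []
    grouped = {k: g for k, g in detections.groupby(["test_point_id", "height_class"], sort=True)}
    keys = list(points) if points is not None else sorted(grouped)
    for key in keys:
        key = tuple(key)
        g = grouped.get(key)
        if g is None or len(g) == 0:
            expected_for(key)
            rows.append(
                {
                    "test_point_id": key[0],
                    "height_class": key[1],
                    "detection_rate": 0.0,
                    "n_receivers": 0,
                    "mean_rss": np.nan,
                    "max_rss": np.nan,
                }
            )
            continue
        exp = expected_for(key)
        n_beacons = g["time_s"].nunique()
        rows.append(
            {
                "test_point_id": key[0],
                "height_class": key[1],
                "detection_rate": min(1.0, n_beacons / exp),
                "n_receivers": int(g["node_id"].nunique()),
                "mean_rss": float(g["rss_db"].mean()),
                "max_rss": float(g["rss_db"].max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "test_point_id",
            "height_class",
            "detection_rate",
            "n_receivers",
            "mean_rss",
            "max_rss",
        ],
    )
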