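"""Gridded utilization distributions, home-range areas, and dyad overlap.

An individual's utilization distribution (UD) is estimated as a Gaussian
kernel density on a regular grid (Silverman bandwidth per axis by default)
and normalized to unit mass.  The 95% home range is the smallest set of grid
cells containing 95% of the mass.  Space-use similarity between two
individuals is the Bhattacharyya coefficient BC = sum_cells sqrt(p*q),
ranging from 0 (disjoint) to 1 (identical).

The grid KDE is a deliberate stand-in for autocorrelated KDE (AKDE): the
overlap statistic and area extraction are identical, only the bandwidth does
not correct for movement autocorrelation (see docs/methods.md).

``split_and_summarize`` reproduces the analysis bookkeeping: locations are
assigned to (week, section-of-day, breeding period), weekly x section home
ranges are computed per individual, and per-period pooled UDs give one BC per
dyad, classified pair-bonded or not from metadata.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "UtilizationDistribution",
    "PeriodSplit",
    "estimate_ud",
    "home_range_area",
    "bhattacharyya",
    "common_grid",
    "split_and_summarize",
]

#: Half-open section-of-day edges, hours after sunrise.
SECTION_EDGES_H = (0.0, 3.0, 6.0, 9.0, 14.0)


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin (lower-left corner, m), square cell size, counts."""

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if not self.cell_size > 0 or self.nx < 1 or self.ny < 1:
            raise InvalidParameterError("cell_size must be > 0 and nx, ny >= 1")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return cx, cy

    def matches(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass(frozen=True)
class UtilizationDistribution:
    """Probability mass on a grid; ``mass[iy, ix]`` sums to 1."""

    grid: GridSpec
    mass: np.ndarray  # shape (ny, nx)

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if m.shape != (self.grid.ny, self.grid.nx):
            raise InvalidParameterError("mass shape must be (ny, nx)")
        if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("mass must be non-negative and sum to 1")

    @property
    def cell_area_m2(self) -> float:
        return self.grid.cell_size**2


def _silverman_bandwidth(x: np.ndarray) -> float:
    # per-axis Silverman factor for a 2-D KDE: sigma * n^(-1/6)
    s = float(np.std(x, ddof=1))
    return s * len(x) ** (-1.0 / 6.0)


def estimate_ud(
    points: np.ndarray,
    bandwidth: float | tuple[float, float] | None = None,
    grid: GridSpec | None = None,
    cell_size: float = 10.0,
    pad_bandwidths: float = 3.0,
    min_points: int = 10,
) -> UtilizationDistribution:
    """Gaussian-kernel utilization distribution on a regular grid.

    Parameters
    ----------
    points
        (n, 2) locations in meters; n >= ``min_points``.
    bandwidth
        Kernel sd in meters, scalar or per-axis; default Silverman's rule per
        axis (sigma * n**(-1/6)).
    grid
        Grid to evaluate on; default covers the points padded by
        ``pad_bandwidths`` bandwidths at ``cell_size`` resolution.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points must be (n, 2)")
    n = len(pts)
    if n < min_points:
        raise InsufficientDataError(f"need >= {min_points} points, got {n}")
    if bandwidth is None:
        # Silverman per axis, floored at half a cell: sub-cell bandwidths are
        # unresolvable on the grid and degenerate point sets (all locations at
        # one receiver) would otherwise underflow every kernel.
        bx = max(_silverman_bandwidth(pts[:, 0]), cell_size / 2.0)
        by = max(_silverman_bandwidth(pts[:, 1]), cell_size / 2.0)
    elif np.isscalar(bandwidth):
        bx = by = float(bandwidth)
    else:
        bx, by = (float(b) for b in bandwidth)
    if bx <= 0 or by <= 0:
        raise InvalidParameterError("bandwidth must be > 0")

    if grid is None:
        x0 = pts[:, 0].min() - pad_bandwidths * bx
        y0 = pts[:, 1].min() - pad_bandwidths * by
        x1 = pts[:, 0].max() + pad_bandwidths * bx
        y1 = pts[:, 1].max() + pad_bandwidths * by
        nx = max(1, int(np.ceil((x1 - x0) / cell_size)))
        ny = max(1, int(np.ceil((y1 - y0) / cell_size)))
        grid = GridSpec(float(x0), float(y0), cell_size, nx, ny)

    cx, cy = grid.centers()
    # separable Gaussian kernel: mass = Gy @ Gx.T, Gx (nx, n), Gy (ny, n)
    gx = np.exp(-0.5 * ((cx[:, None] - pts[None, :, 0]) / bx) ** 2)
    gy = np.exp(-0.5 * ((cy[:, None] - pts[None, :, 1]) / by) ** 2)
    mass = gy @ gx.T
    total = mass.sum()
    if total <= 0:
        raise InvalidParameterError("grid does not cover the points")
    return UtilizationDistribution(grid, mass / total)


def home_range_area(ud: UtilizationDistribution, level: float = 0.95) -> float:
    """Area (km**2) of the smallest cell set holding ``level`` of the UD mass.

    Cells are accumulated in descending mass order until the cumulative mass
    reaches ``level`` (greedy isopleth).  ``level=1.0`` returns the area of
    all positive-mass cells.
    """
    if not 0.0 < level <= 1.0:
        raise InvalidParameterError("level must be in (0, 1]")
    m = np.sort(ud.mass.ravel())[::-1]
    m = m[m > 0]
    cum = np.cumsum(m)
    k = int(np.searchsorted(cum, min(level, cum[-1]) - 1e-12) + 1)
    return k * ud.cell_area_m2 / 1e6


def bhattacharyya(ud_a: UtilizationDistribution, ud_b: UtilizationDistribution) -> float:
    """Bhattacharyya coefficient sum_cells sqrt(p*q) between two UDs.

    Both UDs must live on the same grid (use :func:`common_grid` when
    estimating to guarantee this).
    """
    if not ud_a.grid.matches(ud_b.grid):
        raise GridMismatchError("utilization distributions are on different grids")
    return float(np.sqrt(ud_a.mass * ud_b.mass).sum())


def common_grid(
    points_a: np.ndarray,
    points_b: np.ndarray,
    bandwidth: float,
    cell_size: float = 10.0,
    pad_bandwidths: float = 3.0,
) -> GridSpec:
    """Shared grid covering both point sets, padded by ``pad_bandwidths`` bw."""
    pts = np.vstack([np.asarray(points_a, float), np.asarray(points_b, float)])
    pad = pad_bandwidths * bandwidth
    x0, y0 = pts[:, 0].min() - pad, pts[:, 1].min() - pad
    x1, y1 = pts[:, 0].max() + pad, pts[:, 1].max() + pad
    nx = max(1, int(np.ceil((x1 - x0) / cell_size)))
    ny = max(1, int(np.ceil((y1 - y0) / cell_size)))
    return GridSpec(float(x0), float(y0), cell_size, nx, ny)


@dataclass(frozen=True)
class PeriodSplit:
    """Temporal bookkeeping: weeks, sections of day, and breeding period.

    ``sunrise_s`` maps UTC date -> sunrise epoch seconds.  Week 1 starts on
    ``week1_start``; dates strictly before ``breeding_end`` are "breeding",
    on/after it "post_breeding".  Sections of day are half-open bins of hours
    after sunrise: [0,3), [3,6), [6,9), [9,14); times at or beyond 14 h are
    assigned to section 4 with a logged warning, times before sunrise to
    section 1.
    """

    week1_start: dt.date
    breeding_end: dt.date
    sunrise_s: Mapping[dt.date, float]

    def assign(self, times_s: np.ndarray) -> pd.DataFrame:
        """Per-timestamp (date, week, section, period, hours_post_sunrise)."""
        t = np.asarray(times_s, dtype=float)
        dates = pd.to_datetime(t, unit="s", utc=True).date
        rows = []
        n_late = 0
        for ts, date in zip(t, dates):
            sunrise = self.sunrise_s.get(date)
            if sunrise is None:
                raise InvalidParameterError(f"no sunrise entry for {date}")
            h = (ts - sunrise) / 3600.0
            if h >= SECTION_EDGES_H[-1]:
                section = 4
                n_late += 1
            elif h < 0:
                section = 1
            else:
                section = int(np.searchsorted(SECTION_EDGES_H, h, side="right"))
            week = (date - self.week1_start).days // 7 + 1
            rows.append(
                {
                    "time_s": ts,
                    "date": date,
                    "week": week,
                    "section": section,
                    "period": "breeding" if date < self.breeding_end else "post_breeding",
                    "hours_post_sunrise": h,
                    "before_week1": week < 1,
                }
            )
        if n_late:
            logger.warning("%d locations beyond 14 h post sunrise assigned to section 4", n_late)
        out = pd.DataFrame(rows)
        if out["before_week1"].any():
            logger.warning("%d locations before the week-1 start date (kept, flagged)",
                           int(out["before_week1"].sum()))
        return out


def split_and_summarize(
    estimates: pd.DataFrame,
    metadata: pd.DataFrame,
    split: PeriodSplit,
    cell_size: float = 10.0,
    min_points: int = 10,
    bandwidth: float | None = None,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly/section home-range areas and per-period dyad overlap.

    Parameters
    ----------
    estimates
        Location table with columns tag_id, window_start (epoch s), x, y.
    metadata
        One row per tag: tag_id, sex, pair_id.
    split
        Temporal split configuration.
    bandwidth
        Kernel sd (m) for all UDs; default: Silverman per individual cell.

    Returns
    -------
    (areas, dyads)
        ``areas``: tag_id, week, section, period, n_points, area_km2 for every
        (individual, week, section) cell with >= ``min_points`` locations.
        ``dyads``: id_a, id_b, dyad_type, period, bc for every unordered tag
        pair with enough data in the period, dyad_type ``pair_bonded`` when
        metadata assigns both tags the same pair_id.
    """
    req = {"tag_id", "window_start", "x", "y"}
    if not req.issubset(estimates.columns):
        raise InvalidParameterError(f"estimates need columns {sorted(req)}")
    df = estimates.copy()
    assign = split.assign(df["window_start"].to_numpy(float))
    df = pd.concat([df.reset_index(drop=True), assign.drop(columns="time_s")], axis=1)

    area_rows = []
    for (tag, week, section, period), g in df.groupby(
        ["tag_id", "week", "section", "period"], sort=True
    ):
        if len(g) < min_points:
            continue
        ud = estimate_ud(
            g[["x", "y"]].to_numpy(float),
            bandwidth=bandwidth,
            cell_size=cell_size,
            min_points=min_points,
        )
        area_rows.append(
            {
                "tag_id": tag,
                "week": int(week),
                "section": int(section),
                "period": period,
                "n_points": len(g),
                "area_km2": home_range_area(ud, level=level),
            }
        )
    areas = pd.DataFrame(
        area_rows, columns=["tag_id", "week", "section", "period", "n_points", "area_km2"]
    )

    pair_of = dict(zip(metadata["tag_id"], metadata["pair_id"]))
    dyad_rows = []
    for period, gp in df.groupby("period", sort=True):
        pooled = {
            tag: g[["x", "y"]].to_numpy(float)
            for tag, g in gp.groupby("tag_id", sort=True)
            if len(g) >= min_points
        }
        for id_a, id_b in combinations(sorted(pooled), 2):
            pts_a, pts_b = pooled[id_a], pooled[id_b]
            bw = bandwidth
            if bw is None:
                bw = float(
                    np.mean(
                        [
                            max(_silverman_bandwidth(p[:, i]), cell_size / 2.0)
                            for p in (pts_a, pts_b)
                            for i in (0, 1)
                        ]
                    )
                )
            grid = common_grid(pts_a, pts_b, bw, cell_size=cell_size)
            ud_a = estimate_ud(pts_a, bandwidth=bw, grid=grid, min_points=min_points)
            ud_b = estimate_ud(pts_b, bandwidth=bw, grid=grid, min_points=min_points)
            dyad_rows.append(
                {
                    "id_a": id_a,
                    "id_b": id_b,
                    "dyad_type": (
                        "pair_bonded"
                        if pair_of.get(id_a) is not None and pair_of.get(id_a) == pair_of.get(id_b)
                        else "not_pair_bonded"
                    ),
                    "period": period,
                    "bc": bhattacharyya(ud_a, ud_b),
                }
            )
    dyads = pd.DataFrame(dyad_rows, columns=["id_a", "id_b", "dyad_type", "period", "bc"])
    return areas, dyads
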