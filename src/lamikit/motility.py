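"""Cell-track statistics: motility coefficients, displacement-vs-sqrt(time)
curves with LOWESS smoothing and bootstrap confidence intervals, and
neighbor-density clustering.

The motility coefficient summarizes a 3D track as a diffusion-like constant:
M = slope of the time-averaged mean squared displacement (MSD) versus lag
over the first third of available lags, divided by 6 (a pure 3D random walk
with diffusivity D has MSD = 6 D t, so M recovers D).  A log-log MSD fit
provides a diffusive-exponent diagnostic (~1 diffusive, ~2 ballistic, <1
confined/subdiffusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Track",
    "MotilitySummary",
    "motility_coefficient",
    "displacement_points",
    "lowess_curve",
    "displacement_curve",
    "cluster_density",
]


@dataclass(frozen=True)
class Track:
    """Time-stamped 3D positions of one tracked cell."""

    track_id: int
    t_min: np.ndarray     # minutes, strictly increasing
    positions: np.ndarray  # (n, 3) um

    def __post_init__(self):
        t = np.asarray(self.t_min, dtype=float)
        p = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(t) < 2 or len(t) != len(p):
            raise ValueError("track needs >= 2 time-stamped positions")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "positions", p)

    @property
    def duration(self) -> float:
        return float(self.t_min[-1] - self.t_min[0])


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Build tracks from a (track_id, t_min, x_um, y_um, z_um) table."""
    out = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("t_min")
        out.append(Track(int(tid), g["t_min"].to_numpy(), g[["x_um", "y_um", "z_um"]].to_numpy()))
    return out


@dataclass(frozen=True)
class MotilitySummary:
    track_id: int
    coefficient: float       # um^2 / min
    duration: float          # min
    exponent: float          # log-log MSD slope diagnostic


def _ta_msd(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD at integer multiples of the median sampling interval."""
    p = track.positions
    n = len(p)
    lags = np.arange(1, n)
    dt = float(np.median(np.diff(track.t_min)))
    msd = np.array([np.mean(np.sum((p[k:] - p[:-k]) ** 2, axis=1)) for k in lags])
    return lags * dt, msd


def motility_coefficient(track: Track, min_duration: float = 5.0) -> MotilitySummary | None:
    """Motility coefficient (MSD slope / 6) or None for too-short tracks."""
    if track.duration < min_duration:
        return None
    taus, msd = _ta_msd(track)
    n_fit = max(len(taus) // 3, 2)
    slope = np.polyfit(taus[:n_fit], msd[:n_fit], 1)[0]
    coeff = max(slope / 6.0, 0.0)
    pos = msd > 0
    if pos.sum() >= 2:
        exponent = float(np.polyfit(np.log(taus[pos]), np.log(msd[pos]), 1)[0])
    else:
        exponent = 0.0
    return MotilitySummary(track.track_id, float(coeff), track.duration, exponent)


def displacement_points(tracks: list[Track]) -> pd.DataFrame:
    """Pooled scatter of displacement from track start vs sqrt(elapsed time)."""
    rows = []
    for tr in tracks:
        disp = np.linalg.norm(tr.positions - tr.positions[0], axis=1)
        rt = np.sqrt(tr.t_min - tr.t_min[0])
        for r, d in zip(rt[1:], disp[1:]):
            rows.append((tr.track_id, r, d))
    return pd.DataFrame(rows, columns=["track_id", "sqrt_t", "displacement"])


def lowess_curve(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    bandwidth: float = 0.5,
    weighting: str = "tricubic",
) -> np.ndarray:
    """Locally linear regression evaluated on a fixed grid.

    ``bandwidth`` is in x units; ``weighting`` is "tricubic" or "gaussian".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        u = (x - g) / bandwidth
        if weighting == "tricubic":
            w = np.clip(1 - np.abs(u) ** 3, 0, None) ** 3
        elif weighting == "gaussian":
            w = np.exp(-0.5 * u**2)
        else:
            raise ValueError("weighting must be 'tricubic' or 'gaussian'")
        if w.sum() <= 0 or (w > 0).sum() < 2:
            continue
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 0 else 0.0
        out[i] = ym + slope * (g - xm)
    return out


def displacement_curve(
    tracks: list[Track],
    n_boot: int = 500,
    seed: int = 0,
    bandwidth: float = 0.5,
    weighting: str = "tricubic",
    n_grid: int = 25,
) -> dict:
    """Displacement vs sqrt(time) curve with bootstrap 95% confidence band.

    The LOWESS fit runs on the pooled per-timepoint scatter; the confidence
    band resamples whole *tracks* (not points) ``n_boot`` times, so the CI
    respects within-track correlation.

    Returns a dict with ``grid``, ``curve``, ``lo``, ``hi`` and the bootstrap
    curve matrix ``boot`` (n_boot, n_grid).
    """
    if len(tracks) < 10:
        raise ValueError("need >= 10 tracks")
    pts = displacement_points(tracks)
    grid = np.linspace(0.0, pts["sqrt_t"].max(), n_grid)
    curve = lowess_curve(pts["sqrt_t"].to_numpy(), pts["displacement"].to_numpy(), grid, bandwidth, weighting)
    rng = np.random.default_rng(seed)
    by_track = {tid: g for tid, g in pts.groupby("track_id")}
    ids = list(by_track)
    boot = np.full((n_boot, len(grid)), np.nan)
    for b in range(n_boot):
        pick = rng.choice(ids, size=len(ids), replace=True)
        sample = pd.concat([by_track[i] for i in pick])
        boot[b] = lowess_curve(
            sample["sqrt_t"].to_numpy(), sample["displacement"].to_numpy(), grid, bandwidth, weighting
        )
    with warnings.catch_warnings():
        # grid cells with no weighted support are NaN in every resample
        warnings.filterwarnings("ignore", message="All-NaN slice")
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
    return {"grid": grid, "curve": curve, "lo": lo, "hi": hi, "boot": boot}


def cluster_density(
    positions_by_time: dict | list,
    radius: float = 100.0,
) -> pd.DataFrame:
    """Neighbor density per time point.

    For each cell, the number of *other* cells within ``radius`` um divided by
    the total number of cells detected at that time point; the per-time-point
    value is the mean over cells.
    """
    if isinstance(positions_by_time, dict):
        items = sorted(positions_by_time.items())
    else:
        items = list(enumerate(positions_by_time))
    rows = []
    for t, pos in items:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        n = len(pos)
        if n == 0:
            warnings.warn(f"empty time point {t}; density undefined")
            rows.append((t, np.nan, 0))
            continue
        if n == 1:
            rows.append((t, 0.0, 1))
            continue
        tree = cKDTree(pos)
        counts = np.asarray(tree.query_ball_point(pos, r=radius, return_length=True)) - 1
        rows.append((t, float(np.mean(counts / n)), n))
    return pd.DataFrame(rows, columns=["t", "density", "n_cells"])
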