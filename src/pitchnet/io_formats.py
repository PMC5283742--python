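"""Reading, projecting and resampling positional and pass-event data.

CSV layouts (RFC-4180, UTF-8, header row mandatory):

* positions: ``time_s, team, player_id`` plus either ``x_m, y_m`` (pitch
  metres) or ``lat, lon`` (decimal degrees from a GPS unit);
* passes: ``time_s, team, passer_id, receiver_id, success``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PassLog, TrajectorySet

log = logging.getLogger(__name__)

# mean-Earth-radius degree length (spherical model, 6371008.8 m radius);
# keeps the local projection distance-true against great-circle geometry
M_PER_DEG = 6371008.8 * np.pi / 180.0


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


@dataclass
class RawPositions:
    """Per-player time-ordered samples before resampling.

    ``data`` maps (team, player_id) to a DataFrame with columns ``time_s``
    and either (``x_m``, ``y_m``) or (``lat``, ``lon``).
    """

    data: dict[tuple[str, str], pd.DataFrame]
    geodetic: bool
    n_rows: int
    n_dropped: int


def read_positions(path) -> RawPositions:
    """Read a positional CSV; duplicate timestamps collapse to their mean."""
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"empty positions file: {path}")
    required = {"time_s", "team", "player_id"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"positions file missing columns: {sorted(missing)}")
    if {"x_m", "y_m"} <= set(df.columns):
        coords, geodetic = ["x_m", "y_m"], False
    elif {"lat", "lon"} <= set(df.columns):
        coords, geodetic = ["lat", "lon"], True
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            raise SchemaError("latitude/longitude outside valid range")
    else:
        raise SchemaError("positions file needs (x_m, y_m) or (lat, lon) columns")

    n_rows = len(df)
    df = df.dropna(subset=["time_s", *coords])
    n_dropped = n_rows - len(df)
    data = {}
    for (team, pid), grp in df.groupby(["team", "player_id"], sort=True):
        collapsed = (grp.groupby("time_s", sort=True)[coords].mean()
                        .reset_index())
        data[(str(team), str(pid))] = collapsed
    if n_dropped:
        log.info("read_positions: dropped %d incomplete rows of %d", n_dropped, n_rows)
    return RawPositions(data=data, geodetic=geodetic,
                        n_rows=n_rows, n_dropped=n_dropped)


def project_latlon_to_pitch(raw: RawPositions, lat0: float | None = None,
                            lon0: float | None = None,
                            rotation_deg: float = 0.0) -> RawPositions:
    """Project geodetic samples onto a local metric plane.

    Local equirectangular projection about a reference point (default: the
    centroid of the data bounding box), then an in-plane rotation::

        x_east  = (lon - lon0) * cos(lat0) * 111195 m/deg
        y_north = (lat - lat0) * 111195 m/deg

    using the mean-Earth-radius degree length, which keeps pitch-scale
    displacements distance-true against great-circle geometry to well under
    0.5 % for displacements of a few hundred metres at |lat| <= 60 deg.
    """
    if not raw.geodetic:
        return raw
    all_lat = np.concatenate([d["lat"].to_numpy() for d in raw.data.values()])
    all_lon = np.concatenate([d["lon"].to_numpy() for d in raw.data.values()])
    if lat0 is None:
        lat0 = float((all_lat.min() + all_lat.max()) / 2.0)
    if lon0 is None:
        lon0 = float((all_lon.min() + all_lon.max()) / 2.0)
    if abs(lat0) > 89.0 or np.any(np.abs(all_lat) > 89.0):
        raise ValueError("unsupported latitude: projection degenerate near poles")
    c, s = np.cos(np.radians(rotation_deg)), np.sin(np.radians(rotation_deg))
    coslat = np.cos(np.radians(lat0))
    data = {}
    for key, grp in raw.data.items():
        x = (grp["lon"].to_numpy() - lon0) * coslat * M_PER_DEG
        y = (grp["lat"].to_numpy() - lat0) * M_PER_DEG
        data[key] = pd.DataFrame({
            "time_s": grp["time_s"].to_numpy(),
            "x_m": c * x - s * y,
            "y_m": s * x + c * y,
        })
    return RawPositions(data=data, geodetic=False,
                        n_rows=raw.n_rows, n_dropped=raw.n_dropped)


def resample_uniform(raw: RawPositions, hz: float = 5.0,
                     max_gap_s: float = 2.0) -> TrajectorySet:
    """Linearly interpolate every player onto a shared uniform grid.

    Grid spans the intersection-free union of all player time ranges at
    ``1/hz`` spacing.  Grid points falling inside a source gap longer than
    ``max_gap_s``, or outside a player's own range, are marked missing (NaN)
    rather than interpolated.
    """
    if raw.geodetic:
        raise ValueError("project geodetic data to pitch metres before resampling")
    t0 = min(float(d["time_s"].iloc[0]) for d in raw.data.values())
    t1 = max(float(d["time_s"].iloc[-1]) for d in raw.data.values())
    if t1 <= t0:
        raise ValueError("time span must be positive for resampling")
    dt = 1.0 / hz
    grid = t0 + np.arange(int(np.floor((t1 - t0) / dt)) + 1) * dt
    data = {}
    for key, grp in raw.data.items():
        t = grp["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"player {key} has fewer than 2 samples")
        xy = np.column_stack([
            np.interp(grid, t, grp["x_m"].to_numpy(float)),
            np.interp(grid, t, grp["y_m"].to_numpy(float)),
        ])
        xy[(grid < t[0]) | (grid > t[-1])] = np.nan
        gaps = np.diff(t)
        for gi in np.nonzero(gaps > max_gap_s)[0]:
            inside = (grid > t[gi]) & (grid < t[gi + 1])
            xy[inside] = np.nan
        data[key] = xy
    return TrajectorySet(times=grid, data=data, hz=hz)


def lowpass_positions(traj: TrajectorySet, window: int = 5) -> TrajectorySet:
    """Two-pass (forward/backward) moving-average smoothing of positions.

    With the default 5-sample window at 5 Hz this acts as a ~3 Hz low-pass.
    NaN samples stay NaN and do not leak into neighbours.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")

    def smooth(col: np.ndarray) -> np.ndarray:
        ser = pd.Series(col)
        fwd = ser.rolling(window, center=True, min_periods=1).mean()
        back = fwd.rolling(window, center=True, min_periods=1).mean()
        out = back.to_numpy()
        out[np.isnan(col)] = np.nan
        return out

    data = {k: np.column_stack([smooth(v[:, 0]), smooth(v[:, 1])])
            for k, v in traj.data.items()}
    return TrajectorySet(times=traj.times, data=data, hz=traj.hz,
                         period=traj.period, ball=traj.ball)


def excise_break(traj: TrajectorySet, period_s: float,
                 break_s: float = 600.0) -> TrajectorySet:
    """Remove the between-period break and close up the clock.

    For data recorded on a continuous clock with a break of ``break_s``
    after each ``period_s`` of play, samples falling inside breaks are
    dropped and later samples are shifted so that play time is contiguous.
    """
    t = traj.times
    cycle = period_s + break_s
    in_play = (t % cycle) < period_s
    shifted = (t // cycle) * period_s + (t % cycle)
    period = (t // cycle).astype(int)
    data = {k: v[in_play] for k, v in traj.data.items()}
    return TrajectorySet(times=shifted[in_play], data=data, hz=traj.hz,
                         period=period[in_play],
                         ball=None if traj.ball is None else traj.ball[in_play])


def read_passes(path, roster: dict[str, list[str]],
                goalkeepers: set[str] | frozenset[str] = frozenset()) -> PassLog:
    """Read a pass-event CSV and apply the ingest filters.

    Only successful passes are retained for network construction.  Rows with
    passer == receiver are rejected with a warning; rows involving a
    goalkeeper are dropped (goalkeepers are excluded from all analyses) with
    a logged count; any other id outside the roster raises.
    """
    df = pd.read_csv(path)
    missing = [c for c in PassLog.COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"passes file missing columns: {missing}")
    df["success"] = df["success"].astype(bool)

    self_pass = df["passer_id"] == df["receiver_id"]
    if self_pass.any():
        warnings.warn(f"rejected {int(self_pass.sum())} self-pass rows",
                      stacklevel=2)
    gk = (df["passer_id"].isin(goalkeepers) | df["receiver_id"].isin(goalkeepers))
    if gk.any():
        log.info("read_passes: dropped %d goalkeeper rows", int(gk.sum()))
    keep = df[~self_pass & ~gk]

    for team, players in roster.items():
        sub = keep[keep["team"] == team]
        known = set(players)
        bad = (set(sub["passer_id"]) | set(sub["receiver_id"])) - known
        if bad:
            raise SchemaError(f"unknown player ids for team {team}: {sorted(bad)}")

    n_rejected = int(self_pass.sum() + gk.sum())
    return PassLog(keep[keep["success"]].reset_index(drop=True),
                   n_rejected=n_rejected)


def trajectories_from_csv(path, hz: float = 5.0,
                          lat0: float | None = None, lon0: float | None = None,
                          rotation_deg: float = 0.0,
                          max_gap_s: float = 2.0,
                          smooth: bool = True) -> TrajectorySet:
    """Convenience chain: read -> (project) -> resample -> (low-pass)."""
    raw = read_positions(path)
    if raw.geodetic:
        raw = project_latlon_to_pitch(raw, lat0, lon0, rotation_deg)
    traj = resample_uniform(raw, hz=hz, max_gap_s=max_gap_s)
    return lowpass_positions(traj) if smooth else traj
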