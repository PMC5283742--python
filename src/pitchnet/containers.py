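"""In-memory containers shared across the pipeline.

``TrajectorySet`` holds per-player planar positions on a uniform sampling
grid (NaN marks missing samples); ``PassLog`` holds time-stamped directed
pass events.  Both convert losslessly to/from long-format DataFrames, which
is also the on-disk CSV layout used by :mod:`pitchnet.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PlayerKey = tuple[str, str]  # (team, player_id)


@dataclass
class TrajectorySet:
    """Uniformly sampled planar trajectories for a set of players.

    Attributes
    ----------
    times : ndarray, shape (N,)
        Sample times in seconds from kickoff (half-time break excised).
    data : dict
        ``(team, player_id) -> (N, 2)`` position array in metres; NaN rows
        mark missing samples.
    hz : float
        Sampling rate of the grid.
    period : ndarray of int, shape (N,) or None
        Period index (0-based) of each sample, if known.
    ball : ndarray, shape (N, 2) or None
        Ball trajectory, when simulated.
    """

    times: np.ndarray
    data: dict[PlayerKey, np.ndarray]
    hz: float
    period: np.ndarray | None = None
    ball: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def teams(self) -> list[str]:
        seen: dict[str, None] = {}
        for team, _ in self.data:
            seen.setdefault(team)
        return list(seen)

    def players(self, team: str | None = None) -> list[PlayerKey]:
        return [k for k in self.data if team is None or k[0] == team]

    def positions(self, team: str | None = None) -> np.ndarray:
        """Stack player positions into an (n_players, N, 2) array."""
        keys = self.players(team)
        return np.stack([self.data[k] for k in keys])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (team, pid), xy in self.data.items():
            rows.append(pd.DataFrame({
                "time_s": self.times,
                "team": team,
                "player_id": pid,
                "x_m": xy[:, 0],
                "y_m": xy[:, 1],
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, hz: float) -> "TrajectorySet":
        times = np.sort(df["time_s"].unique())
        index = pd.Index(times, name="time_s")
        data = {}
        for (team, pid), grp in df.groupby(["team", "player_id"], sort=True):
            ser = grp.set_index("time_s")[["x_m", "y_m"]].reindex(index)
            data[(str(team), str(pid))] = ser.to_numpy(float)
        return cls(times=np.asarray(times, float), data=data, hz=hz)


@dataclass
class PassLog:
    """Directed pass events: columns time_s, team, passer_id, receiver_id, success."""

    events: pd.DataFrame
    n_rejected: int = 0  # rows dropped at ingest (self-passes, goalkeepers, ...)

    COLUMNS = ["time_s", "team", "passer_id", "receiver_id", "success"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"PassLog missing columns: {missing}")
        self.events = self.events.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.events)

    def successful(self, team: str | None = None) -> pd.DataFrame:
        ev = self.events[self.events["success"].astype(bool)]
        if team is not None:
            ev = ev[ev["team"] == team]
        return ev.reset_index(drop=True)

    def n_successful(self, team: str | None = None) -> int:
        return len(self.successful(team))


@dataclass
class DyadMetrics:
    """Per-dyad regularity and passing summary for one team.

    One row per unordered pair of outfield teammates (45 for 10 players):
    ``player_a, player_b, apen, n_valid, passes_ab, passes_ba``.
    """

    team: str
    table: pd.DataFrame
    apen_params: dict = field(default_factory=dict)

    @property
    def n_dyads(self) -> int:
        return len(self.table)
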