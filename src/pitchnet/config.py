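"""Match configuration: pitch geometry, sampling, formation anchors, rosters.

The default setup is an 11-a-side match on a 106 x 65 m pitch, recorded at
5 Hz over two 25-minute periods.  Only the 10 outfield roles per team are
modelled; goalkeepers are excluded from every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: Outfield roles of a 1-4-3-3 (goalkeeper omitted): four defenders, three
#: central midfielders, three forwards.  Anchor coordinates are expressed in
#: the team's own attacking frame (attacking towards x = pitch_length).
FORMATION_433: dict[str, tuple[float, float]] = {
    "RB": (25.0, 10.0),
    "RCB": (20.0, 25.0),
    "LCB": (20.0, 40.0),
    "LB": (25.0, 55.0),
    "RCM": (48.0, 17.0),
    "DCM": (42.0, 32.5),
    "LCM": (48.0, 48.0),
    "RW": (75.0, 12.0),
    "CF": (80.0, 32.5),
    "LW": (75.0, 53.0),
}

#: Ball-coupling gains by role band: forwards chase the ball more than
#: defenders.  Heterogeneous gains keep a ball-driven component in every
#: dyad distance series (a shared gain would cancel out of all differences).
ROLE_COUPLING: dict[str, float] = {
    "RB": 0.10, "RCB": 0.08, "LCB": 0.08, "LB": 0.10,
    "RCM": 0.22, "DCM": 0.18, "LCM": 0.22,
    "RW": 0.32, "CF": 0.30, "LW": 0.32,
}

N_OUTFIELD = 10


class ConfigurationError(ValueError):
    """Raised when a match configuration violates its invariants."""


@dataclass
class MatchConfig:
    """Static description of one match.

    Parameters
    ----------
    pitch_length_m, pitch_width_m : float
        Pitch rectangle, metres.
    hz : float
        Positional sampling rate.
    period_min : float
        Minutes per period.
    n_periods : int
        Number of periods.
    formation : dict
        Role -> (x, y) anchor in the team's attacking frame; exactly 10
        outfield roles.
    teams : tuple of str
        The two team labels.  Player ids are ``"<team>_<role>"``.
    seed : int
        Base seed for all stochastic generation tied to this match.
    """

    pitch_length_m: float = 106.0
    pitch_width_m: float = 65.0
    hz: float = 5.0
    period_min: float = 25.0
    n_periods: int = 2
    formation: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(FORMATION_433))
    teams: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch_length_m <= 0 or self.pitch_width_m <= 0:
            raise ConfigurationError("pitch dimensions must be positive")
        if self.hz <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.period_min <= 0 or self.n_periods < 1:
            raise ConfigurationError("match duration must be positive")
        if len(self.formation) != N_OUTFIELD:
            raise ConfigurationError(
                f"formation must define exactly {N_OUTFIELD} outfield roles, "
                f"got {len(self.formation)}")
        for role, (x, y) in self.formation.items():
            if not (0 <= x <= self.pitch_length_m and 0 <= y <= self.pitch_width_m):
                raise ConfigurationError(f"anchor for {role} outside pitch: {(x, y)}")

    # -- derived quantities -------------------------------------------------

    @property
    def samples_per_period(self) -> int:
        return int(round(self.period_min * 60.0 * self.hz))

    @property
    def n_samples(self) -> int:
        return self.n_periods * self.samples_per_period

    @property
    def duration_s(self) -> float:
        return self.n_periods * self.period_min * 60.0

    @property
    def pitch_area_m2(self) -> float:
        return self.pitch_length_m * self.pitch_width_m

    @property
    def roles(self) -> list[str]:
        return list(self.formation.keys())

    def roster(self, team: str) -> list[str]:
        """Player ids of one team, in formation order."""
        return [f"{team}_{role}" for role in self.roles]

    def anchors(self, team: str) -> np.ndarray:
        """(10, 2) anchor array in pitch coordinates.

        The second team is mirrored through the pitch centre so the two
        sides face each other.
        """
        a = np.array([self.formation[r] for r in self.roles], float)
        if team == self.teams[1]:
            a = np.array([self.pitch_length_m, self.pitch_width_m]) - a
        return a

    def to_yaml(self, path) -> None:
        doc = {
            "pitch_length_m": self.pitch_length_m,
            "pitch_width_m": self.pitch_width_m,
            "hz": self.hz,
            "period_min": self.period_min,
            "n_periods": self.n_periods,
            "formation": {k: list(v) for k, v in self.formation.items()},
            "teams": list(self.teams),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MatchConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError(f"malformed config file: {path}")
        if "formation" in doc:
            doc["formation"] = {k: tuple(v) for k, v in doc["formation"].items()}
        if "teams" in doc:
            doc["teams"] = tuple(doc["teams"])
        return cls(**doc)
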