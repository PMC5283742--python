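"""Synthetic match generator.

Real tracking and notational data for youth matches are rarely deposited,
so the package ships a generator that produces matches with the statistical
structure the analysis pipeline assumes:

* formation-anchored, ball-coupled player movement whose positional
  regularity is controlled by a single noise knob;
* directed pass sequences with tunable network topology (uniform, hub);
* a plantable population correlation between directed-dyad pass counts and
  dyad positional regularity (approximate entropy), emulating the negative
  pass-regularity association the pipeline is designed to detect.

Movement model
--------------
Each outfield player follows a discretised Ornstein-Uhlenbeck process that
relaxes towards a moving target::

    target_i(t) = anchor_i + coupling_i * (ball(t) - pitch_centre)
    x_i(t+dt)   = x_i(t) + (target_i(t) - x_i(t)) * dt / tau + sigma_step * eta

with ``sigma_step`` chosen so that the stationary standard deviation around
the target equals ``noise_sd_m``.  The ball is an independent, slower OU
process around the pitch centre.  Ball-coupling gains differ by role, so
every dyad distance series keeps a smooth ball-driven component; raising
``noise_sd_m`` shifts spectral weight to the faster player jitter and makes
dyad distance series less regular (higher approximate entropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ConfigurationError, MatchConfig, N_OUTFIELD, ROLE_COUPLING
from .containers import PassLog, TrajectorySet

# Ball process constants (metres, seconds): slow OU spanning most of the pitch.
_BALL_TAU_S = 9.0
_BALL_SD_FRAC = (0.28, 0.30)  # stationary sd as fraction of (length, width)


@dataclass
class MovementParams:
    """Knobs of the player movement process.

    ball_coupling : float or per-role dict
        Gain in [0, 1] towards the ball displacement from the pitch centre.
        The default role-graded gains (defenders < midfielders < forwards)
        come from :data:`pitchnet.config.ROLE_COUPLING`.
    noise_sd_m : float
        Stationary jitter of a player around its moving target, metres.
    relaxation_s : float
        Mean-reversion time constant of the player process, seconds.
    static_ball : bool
        Pin the ball to the pitch centre (useful for degenerate checks).
    """

    ball_coupling: float | dict[str, float] = field(
        default_factory=lambda: dict(ROLE_COUPLING))
    noise_sd_m: float = 1.5
    relaxation_s: float = 3.0
    static_ball: bool = False

    def __post_init__(self) -> None:
        gains = (self.ball_coupling.values()
                 if isinstance(self.ball_coupling, dict) else [self.ball_coupling])
        if any(not 0.0 <= g <= 1.0 for g in gains):
            raise ConfigurationError("ball_coupling must lie in [0, 1]")
        if self.noise_sd_m < 0:
            raise ConfigurationError("noise_sd_m must be non-negative")
        if self.relaxation_s <= 0:
            raise ConfigurationError("relaxation_s must be positive")

    def coupling_vector(self, roles: list[str]) -> np.ndarray:
        if isinstance(self.ball_coupling, dict):
            return np.array([self.ball_coupling[r] for r in roles], float)
        return np.full(len(roles), float(self.ball_coupling))


@dataclass
class PassTopology:
    """Receiver distribution per passer plus the total pass budget."""

    transition_matrix: np.ndarray
    n_passes: int = 400
    hub_bias: float | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, float)
        if P.shape != (N_OUTFIELD, N_OUTFIELD):
            raise ConfigurationError(f"transition matrix must be {N_OUTFIELD}x{N_OUTFIELD}")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ConfigurationError("transition matrix must have zero diagonal")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition matrix rows must sum to 1")
        if self.n_passes < 0:
            raise ConfigurationError("n_passes must be non-negative")
        self.transition_matrix = P

    @classmethod
    def uniform(cls, n_passes: int = 400) -> "PassTopology":
        P = np.full((N_OUTFIELD, N_OUTFIELD), 1.0 / (N_OUTFIELD - 1))
        np.fill_diagonal(P, 0.0)
        return cls(P, n_passes)

    @classmethod
    def hub(cls, hub_index: int = 5, bias: float = 1.0,
            n_passes: int = 400) -> "PassTopology":
        """Topology funnelling play through one role.

        ``bias=1`` is the extreme case: every non-hub player passes only to
        the hub, and the hub distributes uniformly, so every pass chain
        alternates hub <-> others.
        """
        if not 0.0 <= bias <= 1.0:
            raise ConfigurationError("hub bias must lie in [0, 1]")
        base = np.full((N_OUTFIELD, N_OUTFIELD), 1.0 / (N_OUTFIELD - 1))
        np.fill_diagonal(base, 0.0)
        P = base.copy()
        for i in range(N_OUTFIELD):
            if i == hub_index:
                continue
            hub_row = np.zeros(N_OUTFIELD)
            hub_row[hub_index] = 1.0
            P[i] = (1.0 - bias) * base[i] + bias * hub_row
        return cls(P, n_passes, hub_bias=bias)


def simulate_trajectories(config: MatchConfig, params: MovementParams,
                          seed: int | None = None,
                          noise_sd_per_player: dict[str, np.ndarray] | None = None,
                          ) -> TrajectorySet:
    """Simulate both teams' outfield players and the ball.

    Parameters
    ----------
    seed : int, optional
        Overrides ``config.seed``.
    noise_sd_per_player : dict, optional
        ``team -> (10,) array`` of per-player stationary noise SDs, replacing
        the shared ``params.noise_sd_m`` (used by the fixture generator to
        make dyad regularity heterogeneous).

    Returns a :class:`TrajectorySet` with one (N, 2) series per outfield
    player, clamped to the pitch rectangle, plus the ball path.  Determinism:
    identical inputs and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    if n < 1:
        raise ConfigurationError("match duration too short for one sample")
    dt = 1.0 / config.hz
    centre = np.array([config.pitch_length_m / 2.0, config.pitch_width_m / 2.0])

    times = _match_times(config)
    period = np.repeat(np.arange(config.n_periods), config.samples_per_period)

    ball = _simulate_ball(config, rng, n, dt) if not params.static_ball \
        else np.tile(centre, (n, 1))

    theta = min(dt / params.relaxation_s, 1.0)
    data: dict[tuple[str, str], np.ndarray] = {}
    lo = np.zeros(2)
    hi = np.array([config.pitch_length_m, config.pitch_width_m])
    for team in config.teams:
        anchors = config.anchors(team)
        coupling = params.coupling_vector(config.roles)
        if noise_sd_per_player is not None:
            sd = np.asarray(noise_sd_per_player[team], float)
        else:
            sd = np.full(N_OUTFIELD, params.noise_sd_m)
        sigma_step = sd * np.sqrt(max(2.0 * theta - theta * theta, 0.0))
        # targets: (n, 10, 2)
        targets = anchors[None, :, :] + coupling[None, :, None] * (
            ball[:, None, :] - centre[None, None, :])
        noise = rng.standard_normal((n, N_OUTFIELD, 2))
        xy = np.empty((n, N_OUTFIELD, 2))
        xy[0] = targets[0]
        for t in range(1, n):
            xy[t] = (xy[t - 1] + theta * (targets[t] - xy[t - 1])
                     + sigma_step[None, :, None] * noise[t])
        np.clip(xy, lo, hi, out=xy)
        for j, pid in enumerate(config.roster(team)):
            data[(team, pid)] = xy[:, j, :]

    return TrajectorySet(times=times, data=data, hz=config.hz,
                         period=period, ball=ball)


def _match_times(config: MatchConfig) -> np.ndarray:
    # continuous clock; the between-period break is excised at generation
    return np.arange(config.n_samples) / config.hz


def _simulate_ball(config: MatchConfig, rng: np.random.Generator,
                   n: int, dt: float) -> np.ndarray:
    centre = np.array([config.pitch_length_m / 2.0, config.pitch_width_m / 2.0])
    sd = np.array([_BALL_SD_FRAC[0] * config.pitch_length_m,
                   _BALL_SD_FRAC[1] * config.pitch_width_m])
    theta = min(dt / _BALL_TAU_S, 1.0)
    sigma_step = sd * np.sqrt(max(2.0 * theta - theta * theta, 0.0))
    steps = rng.standard_normal((n, 2))
    ball = np.empty((n, 2))
    ball[0] = centre
    for t in range(1, n):
        ball[t] = ball[t - 1] + theta * (centre - ball[t - 1]) + sigma_step * steps[t]
    np.clip(ball, 0.0, [config.pitch_length_m, config.pitch_width_m], out=ball)
    return ball


def simulate_passes(config: MatchConfig, topology: PassTopology,
                    trajectories: TrajectorySet, team: str | None = None,
                    seed: int | None = None) -> PassLog:
    """Generate a pass chain from the topology's transition matrix.

    The first passer is uniform over the 10 outfield players; each receiver
    is drawn from the passer's transition row and becomes the next passer.
    Event times are sorted uniform draws over the match duration.  All
    generated events are successful passes between distinct teammates.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    teams = [team] if team is not None else list(config.teams)
    duration = float(trajectories.times[-1]) if trajectories.n_samples else 0.0
    frames = []
    for tm in teams:
        roster = config.roster(tm)
        m = topology.n_passes
        if m == 0:
            continue
        times = np.sort(rng.uniform(0.0, duration, size=m))
        passer = np.empty(m, dtype=int)
        receiver = np.empty(m, dtype=int)
        current = rng.integers(N_OUTFIELD)
        for k in range(m):
            passer[k] = current
            current = rng.choice(N_OUTFIELD, p=topology.transition_matrix[current])
            receiver[k] = current
        frames.append(pd.DataFrame({
            "time_s": times,
            "team": tm,
            "passer_id": [roster[i] for i in passer],
            "receiver_id": [roster[i] for i in receiver],
            "success": True,
        }))
    if not frames:
        ev = pd.DataFrame(columns=PassLog.COLUMNS)
        ev["success"] = ev["success"].astype(bool)
        return PassLog(ev)
    return PassLog(pd.concat(frames, ignore_index=True))


@dataclass
class MatchFixture:
    """A complete synthetic match: positions, passes, shots and goals."""

    config: MatchConfig
    trajectories: TrajectorySet
    passes: PassLog
    shots: dict[str, int]
    goals: dict[str, int]
    planted_rho: float
    noise_sd_per_player: dict[str, np.ndarray]


def make_match_fixture(config: MatchConfig, params: MovementParams | None = None,
                       topology: PassTopology | None = None,
                       planted_rho: float = -0.4,
                       seed: int | None = None) -> MatchFixture:
    """Generate a match with a planted pass-count / regularity correlation.

    Per team, per-player noise SDs are drawn log-uniformly around
    ``params.noise_sd_m`` (factor 1/4 to 4), which spreads dyad approximate
    entropy over a wide range.  Directed-dyad pass propensities are then
    coupled to the dyad noise scores through a Gaussian latent model so that
    the population correlation between directed pass counts and dyad ApEn
    equals ``planted_rho`` (non-positive: more passing within more regular
    dyads).  The latent coupling is inflated analytically to offset the
    multinomial sampling noise of finite pass counts; the residual mapping
    from noise score to measured ApEn is monotone but not exactly linear, so
    the planting is exact in expectation only (see the methods note).

    Shots and goals are drawn per team (shots ~ 6..18, goals binomial with
    scoring probability 0.15, goals <= shots by construction).
    """
    if not -1.0 <= planted_rho <= 0.0:
        raise ConfigurationError("planted_rho must lie in [-1, 0]")
    params = params or MovementParams()
    topology = topology or PassTopology.uniform()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # heterogeneous per-player noise -> heterogeneous dyad regularity
    noise_sd = {
        team: params.noise_sd_m * np.exp(rng.uniform(np.log(0.25), np.log(4.0),
                                                     size=N_OUTFIELD))
        for team in config.teams
    }
    traj = simulate_trajectories(config, params, seed=int(rng.integers(2**31)),
                                 noise_sd_per_player=noise_sd)

    coupling = params.coupling_vector(config.roles)
    ball_var = ((_BALL_SD_FRAC[0] * config.pitch_length_m) ** 2
                + (_BALL_SD_FRAC[1] * config.pitch_width_m) ** 2) / 2.0
    if params.static_ball:
        ball_var = 0.0
    frames = []
    for team in config.teams:
        counts = _planted_pass_counts(noise_sd[team], coupling, ball_var,
                                      topology.n_passes, planted_rho, rng)
        frames.append(_counts_to_events(counts, config.roster(team), team,
                                        float(traj.times[-1]), rng))
    events = pd.concat(frames, ignore_index=True).sort_values(
        "time_s", kind="stable").reset_index(drop=True)
    passes = PassLog(events)

    shots = {team: int(rng.integers(6, 19)) for team in config.teams}
    goals = {team: int(rng.binomial(shots[team], 0.15)) for team in config.teams}
    return MatchFixture(config=config, trajectories=traj, passes=passes,
                        shots=shots, goals=goals, planted_rho=planted_rho,
                        noise_sd_per_player=noise_sd)


def _planted_pass_counts(noise_sd: np.ndarray, coupling: np.ndarray,
                         ball_var: float, n_passes: int,
                         planted_rho: float, rng: np.random.Generator) -> np.ndarray:
    """Directed 10x10 pass-count matrix coupled to dyad regularity scores.

    The regularity score of dyad (i, j) is the ratio of its fast (jitter)
    to slow (ball-driven) variance,

        s_ij = (sd_i^2 + sd_j^2) / ((c_i - c_j)^2 * ball_var + v0),

    which predicts the dyad's ApEn rank (v0 = 0.25 m^2 regularises dyads
    with near-identical coupling).  Rank-normal scores of s are coupled to
    a Gaussian latent ``u = rho_lat * z + sqrt(1 - rho_lat^2) * eps`` and
    mapped affinely to multinomial propensities (an affine map preserves
    Pearson correlation).  ``rho_lat`` is ``planted_rho`` divided by the
    analytic multinomial attenuation factor, clipped to [-1, 0]; the
    residual nonlinearity of the score-to-ApEn map makes the planting
    approximate (exact in expectation only).
    """
    iu = np.triu_indices(N_OUTFIELD, k=1)
    fast = noise_sd[iu[0]] ** 2 + noise_sd[iu[1]] ** 2
    slow = (coupling[iu[0]] - coupling[iu[1]]) ** 2 * ball_var + 0.25
    s = fast / slow                                          # 45 dyad scores
    ranks = sps.rankdata(s, method="average")
    z45 = sps.norm.ppf((ranks - 0.5) / len(s))

    z = np.concatenate([z45, z45])                           # 90 directed dyads
    n_dir = len(z)
    offset = 3.2                                             # keeps weights > 0
    # multinomial attenuation of corr(count, latent): signal sd n*sd(p) vs
    # count noise sqrt(n*mean(p));  Var(u)=1, p = (u+offset)/(n_dir*offset)
    signal_var = (n_passes / (n_dir * offset)) ** 2 if n_passes else 1.0
    noise_var = n_passes / n_dir if n_passes else 0.0
    g = np.sqrt(signal_var / (signal_var + noise_var)) if n_passes else 1.0
    rho_lat = float(np.clip(planted_rho / max(g, 1e-12), -1.0, 0.0))

    eps = rng.standard_normal(n_dir)
    u = rho_lat * z + np.sqrt(max(1.0 - rho_lat ** 2, 0.0)) * eps
    w = np.maximum(u + offset, 0.05)
    p = w / w.sum()
    flat = rng.multinomial(n_passes, p)

    counts = np.zeros((N_OUTFIELD, N_OUTFIELD), dtype=int)
    counts[iu] = flat[:len(s)]
    counts[iu[1], iu[0]] = flat[len(s):]
    return counts


def _counts_to_events(counts: np.ndarray, roster: list[str], team: str,
                      duration: float, rng: np.random.Generator) -> pd.DataFrame:
    n = int(counts.sum())
    passer, receiver = [], []
    for i in range(N_OUTFIELD):
        for j in range(N_OUTFIELD):
            passer.extend([roster[i]] * counts[i, j])
            receiver.extend([roster[j]] * counts[i, j])
    order = rng.permutation(n)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return pd.DataFrame({
        "time_s": times,
        "team": team,
        "passer_id": np.array(passer, object)[order],
        "receiver_id": np.array(receiver, object)[order],
        "success": True,
    })


def write_fixture(fixture: MatchFixture, out_dir) -> dict[str, str]:
    """Write positional CSV, pass CSV and a JSON manifest; returns paths."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pos_path = out / "positions.csv"
    pass_path = out / "passes.csv"
    manifest_path = out / "manifest.json"
    fixture.trajectories.to_frame().to_csv(pos_path, index=False)
    fixture.passes.events.to_csv(pass_path, index=False)
    manifest = {
        "seed": fixture.config.seed,
        "planted_rho": fixture.planted_rho,
        "shots": fixture.shots,
        "goals": fixture.goals,
        "hz": fixture.config.hz,
        "pitch": [fixture.config.pitch_length_m, fixture.config.pitch_width_m],
        "noise_sd_per_player": {t: list(map(float, v))
                                for t, v in fixture.noise_sd_per_player.items()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"positions": str(pos_path), "passes": str(pass_path),
            "manifest": str(manifest_path)}
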