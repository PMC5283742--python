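"""End-to-end match analysis: networks, positioning, clustering, statistics.

For one match (two teams) the pipeline chains

    io -> passing network (+ centralities) -> dyad distances -> ApEn
       -> Voronoi dominant regions -> regularity clustering
       -> between-team effect sizes and pass-regularity correlations

and collects everything into a :class:`MatchReport` that can be written as
JSON plus CSV tables and GraphML exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import RegularityClassification, fit_regularity_classes
from .config import MatchConfig
from .containers import DyadMetrics, PassLog, TrajectorySet
from .network import (CentralityScores, PassingNetwork, build_adjacency,
                      centrality_scores, export_network)
from .positioning import ApEnParams, dyad_metrics, voronoi_summary
from .stats import (CorrelationResult, EffectResult, EffectError,
                    cohen_d_pooled, efficacy, mbi_label_from,
                    magnitude_of_d, pearson_ci, percent_difference)


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class TeamAnalysis:
    team: str
    network: PassingNetwork
    scores: CentralityScores
    dyads: DyadMetrics
    classification: RegularityClassification
    voronoi: pd.DataFrame
    shots: int | None = None
    goals: int | None = None
    efficacy_pct: float | None = None
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)


@dataclass
class MatchReport:
    config: MatchConfig
    teams: dict[str, TeamAnalysis]
    between: dict[str, EffectResult]
    performance_ranking: dict
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "teams": {
                t: {
                    "shots": ta.shots, "goals": ta.goals,
                    "efficacy_pct": ta.efficacy_pct,
                    "n_passes": ta.network.n_passes,
                    "centrality": ta.scores.to_frame().to_dict("records"),
                    "dyads": ta.classification.to_frame(ta.dyads.table)
                               .to_dict("records"),
                    "k_selected": ta.classification.k_selected,
                    "bic_trace": {str(k): v for k, v
                                  in ta.classification.bic_trace.items()},
                    "voronoi": ta.voronoi.to_dict("records"),
                    "correlations": {k: v.as_dict()
                                     for k, v in ta.correlations.items()},
                } for t, ta in self.teams.items()
            },
            "between_teams": {k: v.as_dict() for k, v in self.between.items()},
            "performance_ranking": self.performance_ranking,
        }

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t, ta in self.teams.items():
            ta.scores.to_frame().to_csv(out / f"centrality_{t}.csv", index=False)
            ta.classification.to_frame(ta.dyads.table).to_csv(
                out / f"dyads_{t}.csv", index=False)
            ta.voronoi.to_csv(out / f"voronoi_{t}.csv", index=False)
            adj = pd.DataFrame(ta.network.A, index=ta.network.nodes,
                               columns=ta.network.nodes)
            adj.to_csv(out / f"adjacency_{t}.csv")
            export_network(ta.network, ta.scores, out / f"network_{t}.graphml",
                           mean_area_m2=_areas_in_node_order(ta))
        path = out / "report.json"
        path.write_text(json.dumps(self.as_dict(), indent=2, default=_json_default))
        return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _areas_in_node_order(ta: TeamAnalysis) -> np.ndarray | None:
    vor = ta.voronoi[ta.voronoi["team"] == ta.team]
    lut = dict(zip(vor["player_id"], vor["mean_area_m2"]))
    if not all(n in lut for n in ta.network.nodes):
        return None
    return np.array([lut[n] for n in ta.network.nodes])


def analyze_team(traj: TrajectorySet, passes: PassLog, config: MatchConfig,
                 team: str, voronoi: pd.DataFrame,
                 apen_params: ApEnParams | None = None,
                 shots: int | None = None, goals: int | None = None,
                 convention: str = "reciprocal",
                 cluster_seed: int = 0, force_k: int | None = None,
                 ) -> TeamAnalysis:
    roster = config.roster(team)
    try:
        net = build_adjacency(passes, roster, team)
        scores = centrality_scores(net, convention)
    except Exception as exc:
        raise PipelineError(f"passing-network stage failed for team {team}: {exc}") from exc
    try:
        dyads = dyad_metrics(traj, net, team, apen_params)
    except Exception as exc:
        raise PipelineError(f"positioning stage failed for team {team}: {exc}") from exc
    try:
        classification = fit_regularity_classes(
            dyads.table["apen"].to_numpy(), seed=cluster_seed, force_k=force_k)
    except Exception as exc:
        raise PipelineError(f"clustering stage failed for team {team}: {exc}") from exc

    correlations = {}
    for mode in ("directed", "undirected"):
        try:
            correlations[mode] = correlate_passes_regularity(net, dyads, mode)
        except EffectError:
            pass  # degenerate (e.g. constant ApEn); omitted from the report
    eff = efficacy(goals, shots) if shots is not None and goals is not None else None
    return TeamAnalysis(team=team, network=net, scores=scores, dyads=dyads,
                        classification=classification, voronoi=voronoi,
                        shots=shots, goals=goals, efficacy_pct=eff,
                        correlations=correlations)


def correlate_passes_regularity(net: PassingNetwork, dyads: DyadMetrics,
                                mode: str = "directed") -> CorrelationResult:
    """Correlate pass counts with dyad ApEn across a team's dyads.

    ``directed`` pairs every directed dyad's pass count with its dyad ApEn
    (each unordered dyad contributes both directions: up to 90 pairs);
    ``undirected`` sums the two directions (up to 45 pairs).
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"unknown correlation mode: {mode!r}")
    tab = dyads.table.dropna(subset=["apen"])
    if mode == "directed":
        counts = np.concatenate([tab["passes_ab"].to_numpy(float),
                                 tab["passes_ba"].to_numpy(float)])
        apen = np.concatenate([tab["apen"].to_numpy(float)] * 2)
    else:
        counts = (tab["passes_ab"] + tab["passes_ba"]).to_numpy(float)
        apen = tab["apen"].to_numpy(float)
    if len(counts) < 4:
        raise EffectError("fewer than 4 usable dyads for correlation")
    if np.std(apen) == 0.0 or np.std(counts) == 0.0:
        # degenerate input: no spread to correlate; flagged, not raised
        return CorrelationResult(r=float("nan"), ci90=(float("nan"), float("nan")),
                                 n=len(counts), magnitude="undefined",
                                 clarity="unclear")
    return pearson_ci(counts, apen)


def compare_teams(report_a: TeamAnalysis, report_b: TeamAnalysis,
                  passes: PassLog | None = None, duration_s: float | None = None,
                  n_segments: int = 6) -> tuple[dict[str, EffectResult], dict]:
    """Between-team effect sizes and the performance designation.

    Closeness and betweenness use the 10 per-player scores of each team as
    the comparison groups (standardized difference, B relative to A).
    Pass totals are compared as percent differences over equal-length match
    segments (default six), which supplies a within-match variance basis;
    shot totals, available only as match totals, use a Poisson-based percent
    difference.  Teams are ranked into higher/lower performance by shots
    first and efficacy second; ties are flagged.
    """
    eff: dict[str, EffectResult] = {}
    for name in ("closeness", "betweenness"):
        a = getattr(report_a.scores, name)
        b = getattr(report_b.scores, name)
        res = cohen_d_pooled(a, b)
        if np.all(a > 0) and np.all(b > 0):
            pct = percent_difference(a, b)
            res.pct_diff, res.pct_ci90 = pct.pct_diff, pct.pct_ci90
            res.pct_limit = pct.pct_limit
        eff[name] = res
    if passes is not None and duration_s is not None:
        seg_a = _segment_counts(passes, report_a.team, duration_s, n_segments)
        seg_b = _segment_counts(passes, report_b.team, duration_s, n_segments)
        if np.all(seg_a > 0) and np.all(seg_b > 0):
            eff["passes"] = percent_difference(seg_a, seg_b)
        else:
            eff["passes"] = cohen_d_pooled(seg_a, seg_b)
    if report_a.shots and report_b.shots:
        eff["shots"] = _poisson_percent_difference(report_a.shots, report_b.shots)

    ranking = _rank_performance(report_a, report_b)
    return eff, ranking


def _segment_counts(passes: PassLog, team: str, duration_s: float,
                    n_segments: int) -> np.ndarray:
    ev = passes.successful(team)
    edges = np.linspace(0.0, duration_s, n_segments + 1)
    counts, _ = np.histogram(ev["time_s"].to_numpy(float), bins=edges)
    return counts.astype(float)


def _poisson_percent_difference(shots_a: int, shots_b: int) -> EffectResult:
    """Compare two match-total counts assuming Poisson variability.

    The standardized difference uses the pooled Poisson SD
    ``sqrt((a + b) / 2)``; the percent difference and its limits come from
    the log-ratio with SE ``sqrt(1/a + 1/b)``.
    """
    from scipy import stats as sps

    a, b = float(shots_a), float(shots_b)
    log_ratio = float(np.log(b / a))
    se_log = float(np.sqrt(1.0 / a + 1.0 / b))
    zc = float(sps.norm.ppf(0.95))
    d = (b - a) / np.sqrt((a + b) / 2.0)
    se_d = float(np.sqrt(2.0))  # delta method: Var(b - a) = a + b
    ci = (d - zc * se_d, d + zc * se_d)
    mbi, direction, probs = mbi_label_from(d, se_d, ci)
    return EffectResult(
        d=d, ci90=ci, se=se_d, df=None, magnitude=magnitude_of_d(d),
        mbi=mbi, mbi_direction=direction, probs=probs,
        pct_diff=100.0 * (np.exp(log_ratio) - 1.0),
        pct_ci90=(100.0 * (np.exp(log_ratio - zc * se_log) - 1.0),
                  100.0 * (np.exp(log_ratio + zc * se_log) - 1.0)),
        pct_limit=100.0 * (np.exp(zc * se_log) - 1.0),
        method={"estimator": "Poisson-variance standardized count difference"})


def _rank_performance(a: TeamAnalysis, b: TeamAnalysis) -> dict:
    def key(ta: TeamAnalysis):
        return (ta.shots or 0, ta.efficacy_pct or 0.0)

    ka, kb = key(a), key(b)
    if ka == kb:
        return {"higher": None, "lower": None, "tied": True,
                "criteria": "shots then efficacy"}
    hi, lo = (a, b) if ka > kb else (b, a)
    return {"higher": hi.team, "lower": lo.team, "tied": False,
            "criteria": "shots then efficacy"}


def run_match_analysis(traj: TrajectorySet, passes: PassLog, config: MatchConfig,
                       shots: dict[str, int] | None = None,
                       goals: dict[str, int] | None = None,
                       apen_params: ApEnParams | None = None,
                       convention: str = "reciprocal",
                       voronoi_stride_s: float = 1.0,
                       force_k: int | None = None) -> MatchReport:
    """Full two-team analysis of one match from in-memory inputs."""
    try:
        vor = voronoi_summary(traj, config.pitch_length_m, config.pitch_width_m,
                              stride_s=voronoi_stride_s)
    except Exception as exc:
        raise PipelineError(f"voronoi stage failed: {exc}") from exc
    teams = {}
    for team in config.teams:
        teams[team] = analyze_team(
            traj, passes, config, team, vor, apen_params,
            shots=None if shots is None else shots.get(team),
            goals=None if goals is None else goals.get(team),
            convention=convention, cluster_seed=config.seed, force_k=force_k)
    t0, t1 = config.teams
    duration = float(traj.times[-1]) if traj.n_samples else None
    between, ranking = compare_teams(teams[t0], teams[t1], passes, duration)
    provenance = {
        "package": "pitchnet", "version": __version__,
        "seed": config.seed, "distance_convention": convention,
        "apen": (apen_params or ApEnParams()).__dict__,
        "hz": config.hz, "n_samples": traj.n_samples,
    }
    return MatchReport(config=config, teams=teams, between=between,
                       performance_ranking=ranking, provenance=provenance)


def run_match_analysis_from_files(positions_path, passes_path, config_path,
                                  shots: dict[str, int] | None = None,
                                  goals: dict[str, int] | None = None,
                                  **kwargs) -> MatchReport:
    """File-based entry point: positional CSV + pass CSV + YAML config."""
    from .io_formats import read_passes, trajectories_from_csv

    config = MatchConfig.from_yaml(config_path)
    traj = trajectories_from_csv(positions_path, hz=config.hz, smooth=False)
    roster = {t: config.roster(t) for t in config.teams}
    passes = read_passes(passes_path, roster)
    return run_match_analysis(traj, passes, config, shots=shots, goals=goals,
                              **kwargs)
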