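"""Positional dynamics: dyad distances, approximate entropy, Voronoi regions.

Approximate entropy (ApEn) quantifies the regularity of a time series: low
values mean that patterns of ``m`` consecutive points that are close (within
tolerance ``r``) tend to stay close one step later, i.e. the series is
repeatable and predictable.  Following common practice in movement analysis
the defaults are ``m = 2`` and ``r = 0.2 * SD`` of the series; because ``r``
scales with the SD, ApEn is invariant under affine rescaling of the input.

The classical estimator (self-matches included) is::

    Phi^m(r) = (N - m + 1)^{-1} * sum_i ln C_i^m(r)
    C_i^m(r) = #{ j : max_k |x(i+k) - x(j+k)| <= r, 0 <= k < m } / (N - m + 1)
    ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r)

A player's dominant region is the part of the pitch closer to them than to
any other outfield player on either team: the planar Voronoi cell clipped
to the pitch rectangle.  Per frame the 20 cells partition the pitch, so
their areas always sum to the pitch area.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Point, box

from .containers import DyadMetrics, TrajectorySet


@dataclass
class ApEnParams:
    """Approximate-entropy parameters: embedding dimension and tolerance."""

    m: int = 2
    r_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("tolerance fraction r_frac must be positive")


def approximate_entropy(x: np.ndarray, params: ApEnParams | None = None) -> float:
    """Classical ApEn of a 1-D series, self-matches included.

    The tolerance is ``r_frac`` times the (population) SD of the series, so
    the statistic is scale-free.  A constant series returns exactly 0.
    Raises when fewer than ``m + 2`` samples remain.
    """
    p = params or ApEnParams()
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n <= p.m + 1:
        raise ValueError(f"ApEn needs more than m+1={p.m + 1} samples, got {n}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = p.r_frac * sd
    return _phi(x, p.m, r) - _phi(x, p.m + 1, r)


def _phi(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)
    templates = np.lib.stride_tricks.sliding_window_view(x, m)  # (n-m+1, m)
    n_t = n - m + 1
    # chunked Chebyshev distances keep memory bounded for long series
    counts = np.empty(n_t, dtype=np.int64)
    chunk = max(1, int(4e7) // max(n_t, 1))
    for start in range(0, n_t, chunk):
        d = cdist(templates[start:start + chunk], templates, metric="chebyshev")
        counts[start:start + chunk] = (d <= r).sum(axis=1)
    return float(np.mean(np.log(counts / n_t)))


def dyad_distance_series(traj: TrajectorySet, team: str) -> dict[tuple[str, str], np.ndarray]:
    """Euclidean distance per frame for every unordered pair of teammates.

    For 10 outfield players this yields C(10,2) = 45 series.  Frames where
    either player is missing are NaN.
    """
    players = traj.players(team)
    if len(players) < 2:
        raise ValueError(f"team {team!r} has fewer than 2 players")
    series = {}
    for (ta, pa), (tb, pb) in itertools.combinations(players, 2):
        diff = traj.data[(ta, pa)] - traj.data[(tb, pb)]
        series[(pa, pb)] = np.hypot(diff[:, 0], diff[:, 1])
    return series


def dyad_apen(traj: TrajectorySet, team: str, params: ApEnParams | None = None,
              per_period: bool = True, low_confidence_n: int = 100) -> pd.DataFrame:
    """ApEn of every dyad distance series of one team.

    By default ApEn is computed per period and averaged with sample-size
    weights, avoiding the artificial half-time discontinuity; set
    ``per_period=False`` to concatenate the whole match.  Dyads with fewer
    than ``low_confidence_n`` valid samples are flagged.
    """
    p = params or ApEnParams()
    series = dyad_distance_series(traj, team)
    if per_period and traj.period is not None:
        period_ids = np.unique(traj.period)
        segments = [(traj.period == pid) for pid in period_ids]
    else:
        segments = [np.ones(traj.n_samples, bool)]
    rows = []
    for (pa, pb), d in series.items():
        vals, weights = [], []
        for mask in segments:
            seg = d[mask]
            seg = seg[~np.isnan(seg)]
            if len(seg) > p.m + 1:
                vals.append(approximate_entropy(seg, p))
                weights.append(len(seg))
        n_valid = int(np.sum(~np.isnan(d)))
        apen = float(np.average(vals, weights=weights)) if vals else np.nan
        rows.append({"player_a": pa, "player_b": pb, "apen": apen,
                     "n_valid": n_valid,
                     "low_confidence": n_valid < low_confidence_n})
    return pd.DataFrame(rows)


def dyad_metrics(traj: TrajectorySet, net, team: str,
                 params: ApEnParams | None = None,
                 per_period: bool = True) -> DyadMetrics:
    """Join dyad ApEn with directed pass counts from the passing network."""
    p = params or ApEnParams()
    table = dyad_apen(traj, team, p, per_period=per_period)
    idx = {pid: i for i, pid in enumerate(net.nodes)}
    table["passes_ab"] = [int(net.A[idx[a], idx[b]])
                          for a, b in zip(table["player_a"], table["player_b"])]
    table["passes_ba"] = [int(net.A[idx[b], idx[a]])
                          for a, b in zip(table["player_a"], table["player_b"])]
    return DyadMetrics(team=team, table=table,
                       apen_params={"m": p.m, "r_frac": p.r_frac,
                                    "per_period": per_period})


# ---------------------------------------------------------------------------
# Voronoi dominant regions
# ---------------------------------------------------------------------------

def voronoi_frame(points: np.ndarray, pitch_length_m: float = 106.0,
                  pitch_width_m: float = 65.0) -> tuple[list, np.ndarray]:
    """Dominant regions of one frame: Voronoi cells clipped to the pitch.

    ``points`` is (k, 2) with all 20 outfield players of both teams (any
    k >= 1 accepted).  Positions are clamped to the pitch; exactly
    coincident points receive a deterministic 1e-6 m jitter keyed to their
    index.  Returns (polygons, areas) in input order; areas sum to the pitch
    area.  A single point owns the whole pitch.
    """
    pts = np.asarray(points, float).copy()
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("points must be a (k, 2) array with k >= 1")
    pitch = box(0.0, 0.0, pitch_length_m, pitch_width_m)
    pts[:, 0] = np.clip(pts[:, 0], 0.0, pitch_length_m)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, pitch_width_m)
    pts = _dejitter(pts)
    if len(pts) == 1:
        return [pitch], np.array([pitch.area])

    cells = shapely.voronoi_polygons(MultiPoint([tuple(p) for p in pts]),
                                     extend_to=pitch.buffer(2 * (pitch_length_m
                                                                 + pitch_width_m)))
    polys = [None] * len(pts)
    sites = [Point(p) for p in pts]
    for cell in cells.geoms:
        owners = [i for i, s in enumerate(sites) if cell.covers(s)]
        for i in owners:
            if polys[i] is None:
                polys[i] = cell.intersection(pitch)
    if any(p is None for p in polys):  # pragma: no cover - degenerate geometry
        raise RuntimeError("failed to assign a Voronoi cell to every player")
    areas = np.array([p.area for p in polys])
    return polys, areas


def _dejitter(pts: np.ndarray) -> np.ndarray:
    """Deterministically separate coincident points by ~1e-6 m."""
    seen: dict[tuple[float, float], int] = {}
    out = pts.copy()
    for i, p in enumerate(pts):
        key = (round(p[0], 9), round(p[1], 9))
        k = seen.get(key, 0)
        if k:
            ang = 2.399963229728653 * (i + 1)  # golden-angle spiral, index-keyed
            out[i] = p + 1e-6 * k * np.array([np.cos(ang), np.sin(ang)])
        seen[key] = k + 1
    return out


def voronoi_summary(traj: TrajectorySet, pitch_length_m: float = 106.0,
                    pitch_width_m: float = 65.0,
                    stride_s: float = 1.0) -> pd.DataFrame:
    """Mean dominant-region area and its CV per player across the match.

    Both teams' outfield players are tessellated jointly every ``stride_s``
    seconds.  Frames with any missing player are skipped.  The coefficient
    of variation uses the sample SD: ``cv_area_pct = 100 * SD(area) / mean``.
    """
    players = traj.players()
    stride = max(1, int(round(stride_s * traj.hz)))
    frames = range(0, traj.n_samples, stride)
    all_xy = traj.positions()  # (k, N, 2)
    areas = []
    for f in frames:
        pts = all_xy[:, f, :]
        if np.isnan(pts).any():
            continue
        _, a = voronoi_frame(pts, pitch_length_m, pitch_width_m)
        areas.append(a)
    if not areas:
        raise ValueError("no complete frames available for Voronoi summary")
    areas = np.array(areas)  # (n_frames, k)
    mean = areas.mean(axis=0)
    sd = areas.std(axis=0, ddof=1) if len(areas) > 1 else np.zeros_like(mean)
    return pd.DataFrame({
        "team": [t for t, _ in players],
        "player_id": [p for _, p in players],
        "mean_area_m2": mean,
        "cv_area_pct": 100.0 * np.divide(sd, mean, out=np.zeros_like(sd),
                                         where=mean > 0),
        "n_frames": len(areas),
    })
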