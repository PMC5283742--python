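"""Dyad distances, approximate entropy and Voronoi dominant regions."""

import numpy as np
import pytest

from conftest import apen_oracle, raster_voronoi_areas
from pitchnet.containers import TrajectorySet
from pitchnet.positioning import (ApEnParams, approximate_entropy,
                                  dyad_distance_series, voronoi_frame,
                                  voronoi_summary)

PITCH = (106.0, 65.0)


def _traj(data, hz=5.0):
    n = len(next(iter(data.values())))
    return TrajectorySet(times=np.arange(n) / hz,
                         data={k: np.asarray(v, float) for k, v in data.items()},
                         hz=hz)


# -- dyad distances ---------------------------------------------------------

def test_ten_players_yield_45_dyads(fixture_match):
    series = dyad_distance_series(fixture_match.trajectories, "A")
    assert len(series) == 45


def test_static_345_triangle_distance():
    traj = _traj({("A", "p1"): np.zeros((50, 2)),
                  ("A", "p2"): np.tile([3.0, 4.0], (50, 1))})
    d = dyad_distance_series(traj, "A")[("p1", "p2")]
    assert np.allclose(d, 5.0)


def test_identical_trajectories_zero_distance():
    xy = np.cumsum(np.ones((30, 2)), axis=0)
    traj = _traj({("A", "p1"): xy, ("A", "p2"): xy.copy()})
    d = dyad_distance_series(traj, "A")[("p1", "p2")]
    assert np.allclose(d, 0.0)


def test_single_player_errors():
    traj = _traj({("A", "p1"): np.zeros((10, 2))})
    with pytest.raises(ValueError):
        dyad_distance_series(traj, "A")


# -- approximate entropy ----------------------------------------------------

def test_apen_constant_series_is_zero():
    assert approximate_entropy(np.full(300, 3.7)) == 0.0


def test_apen_alternating_series_near_zero():
    x = np.tile([1.0, 2.0], 150)
    assert approximate_entropy(x, ApEnParams(m=2, r_frac=0.2)) < 0.05


def test_apen_matches_double_loop_oracle():
    rng = np.random.default_rng(1)
    for _ in range(10):
        x = rng.standard_normal(300)
        assert approximate_entropy(x) == pytest.approx(apen_oracle(x), abs=1e-10)


def test_apen_noise_exceeds_sine():
    """White noise is less regular than a sine of equal length (19/20 seeds)."""
    t = np.arange(1500)
    sine = np.sin(2 * np.pi * t / 100.0)
    apen_sine = approximate_entropy(sine)
    wins = sum(approximate_entropy(np.random.default_rng(s).standard_normal(1500))
               > apen_sine for s in range(20))
    assert wins >= 19


def test_apen_affine_invariance():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(400)
    base = approximate_entropy(x)
    assert approximate_entropy(3.5 * x - 11.0) == pytest.approx(base, abs=1e-12)
    assert approximate_entropy(-0.2 * x + 4.0) == pytest.approx(base, abs=1e-12)


def test_apen_nonnegative_on_random_inputs():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(30, 400))
        x = rng.standard_normal(n)
        assert approximate_entropy(x) >= 0.0


def test_apen_insufficient_data_errors():
    with pytest.raises(ValueError):
        approximate_entropy(np.array([1.0, 2.0, 3.0]), ApEnParams(m=2))


# -- Voronoi ----------------------------------------------------------------

def test_single_player_owns_whole_pitch():
    _, areas = voronoi_frame(np.array([[50.0, 30.0]]), *PITCH)
    assert areas[0] == pytest.approx(106.0 * 65.0)


def test_two_mirror_players_split_pitch():
    pts = np.array([[53.0 - 10.0, 32.5], [53.0 + 10.0, 32.5]])
    _, areas = voronoi_frame(pts, *PITCH)
    assert areas[0] == pytest.approx(3445.0)
    assert areas[1] == pytest.approx(3445.0)


def test_area_conservation_random_frames():
    rng = np.random.default_rng(5)
    for _ in range(30):
        pts = rng.uniform([0, 0], [106, 65], size=(20, 2))
        _, areas = voronoi_frame(pts, *PITCH)
        assert abs(areas.sum() - 6890.0) / 6890.0 < 1e-6


def test_player_inside_own_cell():
    rng = np.random.default_rng(6)
    pts = rng.uniform([0, 0], [106, 65], size=(20, 2))
    polys, _ = voronoi_frame(pts, *PITCH)
    from shapely.geometry import Point
    for p, poly in zip(pts, polys):
        assert poly.covers(Point(p))


def test_areas_match_raster_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        pts = rng.uniform([5, 5], [101, 60], size=(20, 2))
        _, areas = voronoi_frame(pts, *PITCH)
        oracle = raster_voronoi_areas(pts)
        np.testing.assert_allclose(areas, oracle, rtol=0.01)


def test_coincident_players_handled_deterministically():
    pts = np.array([[50.0, 30.0]] * 3 + [[20.0, 20.0]])
    polys1, a1 = voronoi_frame(pts, *PITCH)
    polys2, a2 = voronoi_frame(pts, *PITCH)
    np.testing.assert_array_equal(a1, a2)
    assert a1.sum() == pytest.approx(6890.0)


def test_voronoi_summary_static_positions_zero_cv(short_config):
    rng = np.random.default_rng(8)
    pts = rng.uniform([0, 0], [106, 65], size=(20, 2))
    data = {("A" if i < 10 else "B", f"p{i}"): np.tile(pts[i], (25, 1))
            for i in range(20)}
    out = voronoi_summary(_traj(data), *PITCH)
    assert np.allclose(out["cv_area_pct"], 0.0)
    assert len(out) == 20


def test_voronoi_summary_alternating_areas_cv():
    """Cell areas alternating 100/200 m2 give mean 150 and CV ~47.1%."""
    mean = np.mean([100.0, 200.0])
    cv = 100.0 * np.std([100.0, 200.0], ddof=1) / mean
    assert mean == 150.0
    assert cv == pytest.approx(47.14, abs=0.01)
    # the summary applies the same convention to a two-frame series
    # (two players swap a 2:1 split of the pitch between frames)
    L, W = 30.0, 1.0  # degenerate thin pitch for exact thirds
    a = np.array([[5.0, 0.5], [25.0, 0.5]])   # boundary at x=15
    b = np.array([[15.0, 0.5], [25.0, 0.5]])  # boundary at x=20
    data = {("A", "p1"): np.stack([a[0], b[0]]),
            ("B", "p2"): np.stack([a[1], b[1]])}
    out = voronoi_summary(_traj(data, hz=1.0), L, W, stride_s=1.0)
    p1 = out[out["player_id"] == "p1"].iloc[0]
    assert p1["mean_area_m2"] == pytest.approx((15.0 + 20.0) / 2.0)
    expected_cv = 100.0 * np.std([15.0, 20.0], ddof=1) / 17.5
    assert p1["cv_area_pct"] == pytest.approx(expected_cv)


def test_voronoi_summary_fixture_structure(fixture_match):
    cfg = fixture_match.config
    out = voronoi_summary(fixture_match.trajectories, cfg.pitch_length_m,
                          cfg.pitch_width_m, stride_s=10.0)
    assert len(out) == 20
    assert (out.groupby("team").size() == 10).all()
    assert (out["mean_area_m2"] > 0).all()
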