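import numpy as np
import pytest

from pitchnet.config import MatchConfig
from pitchnet.synthetic import (MovementParams, PassTopology,
                                make_match_fixture)


@pytest.fixture(scope="session")
def short_config():
    """A scaled-down match: 2 x 2.5 min at 5 Hz (1500 samples)."""
    return MatchConfig(period_min=2.5, n_periods=2, seed=11)


@pytest.fixture(scope="session")
def fixture_match(short_config):
    return make_match_fixture(short_config, MovementParams(),
                              PassTopology.uniform(400),
                              planted_rho=-0.4, seed=11)


def brute_force_census(lengths):
    """Exhaustive geodesic census by simple-path enumeration (oracle).

    Returns (dist, sigma, sigma_through) for a small weighted digraph,
    independent of the Dijkstra-based implementation.
    """
    L = np.asarray(lengths, float)
    n = L.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    paths: dict[tuple[int, int], list[tuple]] = {}
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            found = []

            def dfs(node, length, visited):
                if node == t:
                    found.append((length, tuple(visited)))
                    return
                for w in range(n):
                    if w not in visited and np.isfinite(L[node, w]) and w != node:
                        dfs(w, length + L[node, w], visited + [w])

            dfs(s, 0.0, [s])
            if found:
                best = min(f[0] for f in found)
                tol = 1e-12 * max(best, 1.0)
                geo = [p for ln, p in found if ln <= best + tol]
                dist[s, t] = best
                paths[(s, t)] = geo
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    sigma_through = np.zeros((n, n, n))
    for (s, t), geo in paths.items():
        sigma[s, t] = len(geo)
        for p in geo:
            for v in p[1:-1]:
                sigma_through[v, s, t] += 1
    return dist, sigma, sigma_through


def apen_oracle(x, m=2, r_frac=0.2):
    """Literal double-loop transcription of the ApEn definition (oracle)."""
    x = np.asarray(x, float)
    n = len(x)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = r_frac * sd

    def phi(mm):
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            count = 0
            for j in range(nt):
                d = 0.0
                for k in range(mm):
                    d = max(d, abs(x[i + k] - x[j + k]))
                if d <= r:
                    count += 1
            total += np.log(count / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def raster_voronoi_areas(points, length=106.0, width=65.0, cell=0.25):
    """Nearest-site rasterization oracle for dominant-region areas."""
    pts = np.asarray(points, float)
    gx = np.arange(cell / 2, length, cell)
    gy = np.arange(cell / 2, width, cell)
    X, Y = np.meshgrid(gx, gy)
    grid = np.column_stack([X.ravel(), Y.ravel()])
    d2 = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    owner = np.argmin(d2, axis=1)
    return np.bincount(owner, minlength=len(pts)) * cell * cell
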