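"""Shared fixtures and independent oracles.

The oracle implementations here deliberately avoid the library's own
code paths: graph-automorphism orbits come from networkx VF2 instead
of label refinement, Kendall tau from a literal pair-counting loop,
the toy energy from plain per-term python loops instead of the
vectorised evaluator, saddle points from a minimax flood fill over a
dense grid, and Kabsch RMSD from a rotation-grid search.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from bdekit.chemio import Structure
from bdekit.fixtures import FixtureSpec, default_toy_params, make_fixture
from bdekit.potentials import ToyFFParams, ToyForceField


@pytest.fixture(scope="session")
def toy_params() -> ToyFFParams:
    return default_toy_params()


@pytest.fixture(scope="session")
def toy_calc(toy_params) -> ToyForceField:
    return ToyForceField(toy_params)


@pytest.fixture(scope="session")
def butane() -> Structure:
    return make_fixture(FixtureSpec(name="butane"))


@pytest.fixture(scope="session")
def ethanol() -> Structure:
    return make_fixture(FixtureSpec(name="ethanol"))


def h2_structure(r: float) -> Structure:
    return Structure(["H", "H"], [[0, 0, 0], [r, 0, 0]], bonds=[(0, 1, 1)])


# ---------------------------------------------------------------------------
# oracle: graph-automorphism hydrogen orbits (networkx VF2)
# ---------------------------------------------------------------------------

def automorphism_h_orbits(s: Structure) -> list[frozenset[int]]:
    """Orbits of hydrogen atoms under element-preserving graph
    automorphisms, enumerated with VF2."""
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    g = nx.Graph()
    for i, sym in enumerate(s.symbols):
        g.add_node(i, element=sym)
    for i, j, order in s.bonds or []:
        g.add_edge(i, j, order=order)
    gm = GraphMatcher(g, g, node_match=categorical_node_match("element", None))
    orbit_of = {i: {i} for i in range(s.n_atoms)}
    for mapping in gm.isomorphisms_iter():
        for i, j in mapping.items():
            orbit_of[i].add(j)
    merged: dict[int, set[int]] = {}
    for i, orb in orbit_of.items():
        root = min(orb)
        merged.setdefault(root, set()).update(orb)
    return [
        frozenset(v) for v in merged.values()
        if s.symbols[min(v)] == "H"
    ]


# ---------------------------------------------------------------------------
# oracle: literal Kendall tau-b pair counting
# ---------------------------------------------------------------------------

def brute_force_tau_b(x, y) -> float:
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = (x[i] > x[j]) - (x[i] < x[j])
            sy = (y[i] > y[j]) - (y[i] < y[j])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) // 2
    return (c - d) / math.sqrt((n0 - tx) * (n0 - ty))


# ---------------------------------------------------------------------------
# oracle: hand-summed toy force-field energy (plain loops)
# ---------------------------------------------------------------------------

def hand_summed_toy_energy(s: Structure, p: ToyFFParams) -> float:
    pos = s.positions
    adj = {i: [] for i in range(s.n_atoms)}
    for i, j, _ in s.bonds:
        adj[i].append(j)
        adj[j].append(i)
    e = sum(p.get_atom_ref(sym) for sym in s.symbols)
    for i, j, _ in s.bonds:
        de, a, r0 = p.get_morse(s.symbols[i], s.symbols[j])
        if {s.symbols[i], s.symbols[j]} == {"C", "H"}:
            carbon = i if s.symbols[i] == "C" else j
            heavy = sum(1 for v in adj[carbon] if s.symbols[v] != "H")
            de -= p.ch_radical_stabilization * heavy
        r = np.linalg.norm(pos[i] - pos[j])
        e += de * ((1 - math.exp(-a * (r - r0))) ** 2 - 1)
    for j in range(s.n_atoms):
        for i, k in itertools.combinations(sorted(adj[j]), 2):
            kk, th0 = p.get_angle(s.symbols[i], s.symbols[j], s.symbols[k])
            u = pos[i] - pos[j]
            v = pos[k] - pos[j]
            cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            e += kk * (math.acos(np.clip(cos, -1, 1)) - th0) ** 2
    # graph distances by Floyd-Warshall for the 1-4+ LJ selection
    n = s.n_atoms
    dist = np.full((n, n), 1e9)
    np.fill_diagonal(dist, 0)
    for i, j, _ in s.bonds:
        dist[i, j] = dist[j, i] = 1
    for m in range(n):
        dist = np.minimum(dist, dist[:, m, None] + dist[None, m, :])
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] >= 3:
                eps, sig = p.get_nonbonded(s.symbols[i], s.symbols[j])
                r = np.linalg.norm(pos[i] - pos[j])
                e += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    return float(e)


# ---------------------------------------------------------------------------
# oracle: minimax saddle on a dense 2D grid (flood fill)
# ---------------------------------------------------------------------------

def grid_minimax_saddle(energy_fn, xs, ys, basin_a, basin_b) -> float:
    """Lowest energy level at which two basins of a 2D surface become
    connected on the grid: cells are added in order of increasing
    energy and merged via union-find until the cells nearest the two
    basin points share a component."""
    E = np.array([[energy_fn(x, y) for y in ys] for x in xs])
    ia = (int(np.argmin(np.abs(xs - basin_a[0]))), int(np.argmin(np.abs(ys - basin_a[1]))))
    ib = (int(np.argmin(np.abs(xs - basin_b[0]))), int(np.argmin(np.abs(ys - basin_b[1]))))
    parent: dict = {}

    def find(u):
        while parent.get(u, u) != u:
            parent[u] = parent.get(parent[u], parent[u])
            u = parent[u]
        return u

    added = np.zeros(E.shape, dtype=bool)
    for idx in np.argsort(E.ravel()):
        i, j = np.unravel_index(idx, E.shape)
        added[i, j] = True
        parent.setdefault((i, j), (i, j))
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < E.shape[0] and 0 <= nj < E.shape[1] and added[ni, nj]:
                parent[find((ni, nj))] = find((i, j))
        if find(ia) == find(ib):
            return float(E[i, j])
    raise RuntimeError("basins never connected on the grid")


# ---------------------------------------------------------------------------
# oracle: Kabsch RMSD by rotation-grid search + simplex polish
# ---------------------------------------------------------------------------

def grid_search_rmsd(a: Structure, b: Structure) -> float:
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    p = a.positions - a.positions.mean(axis=0)
    q = b.positions - b.positions.mean(axis=0)

    def rmsd_of(euler):
        r = Rotation.from_euler("zyx", euler)
        return float(np.sqrt(np.mean(np.sum((r.apply(p) - q) ** 2, axis=1))))

    best, best_euler = np.inf, None
    grid = np.linspace(-np.pi, np.pi, 13)
    for e1 in grid:
        for e2 in np.linspace(-np.pi / 2, np.pi / 2, 7):
            for e3 in grid:
                v = rmsd_of((e1, e2, e3))
                if v < best:
                    best, best_euler = v, (e1, e2, e3)
    res = minimize(rmsd_of, best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000})
    return float(min(best, res.fun))
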