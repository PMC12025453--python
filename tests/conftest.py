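"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
distances come from a hand-rolled Floyd-Warshall, shortest-path counts from
depth-limited path enumeration, and Dempster combination from exhaustive
iteration over all subset pairs of the frame.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from dsrank.evidence import Bpa
from dsrank.netcore import generate_named, load_fixture


@pytest.fixture(scope="session")
def karate() -> nx.Graph:
    return load_fixture("karate")


@pytest.fixture
def path3() -> nx.Graph:
    return generate_named("path", 3)


@pytest.fixture
def star5() -> nx.Graph:
    return generate_named("star", 5)


# ---------------------------------------------------------------- oracles


def floyd_warshall_distances(net: nx.Graph) -> dict:
    """O(n^3) all-pairs distances, independent of BFS."""
    nodes = list(net.nodes)
    inf = float("inf")
    d = {i: {j: (0 if i == j else inf) for j in nodes} for i in nodes}
    for u, v in net.edges:
        d[u][v] = d[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = d[i][k]
            if dik == inf:
                continue
            for j in nodes:
                if dik + d[k][j] < d[i][j]:
                    d[i][j] = dik + d[k][j]
    return d


def enumerate_shortest_paths(net: nx.Graph, s, t, dist) -> list[tuple]:
    """All geodesics s->t by depth-limited DFS over the distance table."""
    target_len = dist[s][t]
    if target_len == float("inf"):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        if len(path) - 1 >= target_len:
            return
        for w in net[u]:
            # only steps that stay on some geodesic
            if dist[s][w] == len(path) and dist[w][t] == target_len - len(path):
                extend(path + [w])

    extend([s])
    return paths


def brute_force_centralities(net: nx.Graph) -> dict:
    """DC/CC/HCC/BC for every node by direct definition over enumerated paths."""
    nodes = list(net.nodes)
    n = len(nodes)
    dist = floyd_warshall_distances(net)
    out = {v: {"dc": float(net.degree[v])} for v in nodes}
    for v in nodes:
        finite = [dist[v][j] for j in nodes if j != v and dist[v][j] != float("inf")]
        r = len(finite)
        out[v]["cc"] = (r / sum(finite)) * (r / (n - 1)) if finite else 0.0
        out[v]["hcc"] = sum(1.0 / d for d in finite) / (n - 1) if n > 1 else 0.0
        out[v]["bc"] = 0.0
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(net, s, t, dist)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v]["bc"] += through / len(paths)
    return out


def brute_force_dempster(m1: Bpa, m2: Bpa) -> dict[frozenset, float]:
    """Exhaustive Dempster combination over all 2^n x 2^n subset pairs."""
    elements = list(m1.frame)
    subsets = [
        frozenset(c)
        for r in range(len(elements) + 1)
        for c in itertools.combinations(elements, r)
    ]
    mass = {}
    conflict = 0.0
    for b in subsets:
        for c in subsets:
            w = m1.mass.get(b, 0.0) * m2.mass.get(c, 0.0)
            if w == 0.0:
                continue
            g = b & c
            if g:
                mass[g] = mass.get(g, 0.0) + w
            else:
                conflict += w
    if conflict >= 1.0 - 1e-12:
        return {}
    return {g: w / (1.0 - conflict) for g, w in mass.items()}


def random_bpa(frame: tuple, rng: random.Random, max_focal: int = 5) -> Bpa:
    """A random BPA with up to max_focal non-empty focal elements."""
    elements = list(frame)
    k = rng.randint(1, min(max_focal, 2 ** len(elements) - 1))
    focal = set()
    while len(focal) < k:
        size = rng.randint(1, len(elements))
        focal.add(frozenset(rng.sample(elements, size)))
    weights = [rng.random() + 1e-3 for _ in focal]
    total = sum(weights)
    return Bpa(tuple(frame), {s: w / total for s, w in zip(focal, weights)})


def random_connected_graph(n: int, rng: random.Random) -> nx.Graph:
    """Random spanning tree plus extra random edges: always connected."""
    net = nx.Graph()
    nodes = list(range(n))
    net.add_nodes_from(nodes)
    order = nodes[:]
    rng.shuffle(order)
    for i in range(1, n):
        net.add_edge(order[i], rng.choice(order[:i]))
    extra = rng.randint(0, n)
    for _ in range(extra):
        u, v = rng.sample(nodes, 2)
        net.add_edge(u, v)
    return net
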