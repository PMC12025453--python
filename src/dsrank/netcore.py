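"""Graph data model, I/O, synthetic generators and descriptive statistics.

Networks are undirected simple graphs held in :class:`networkx.Graph`
containers. Node labels are opaque and preserved verbatim from input;
matrix-facing code uses the graph's stable insertion order (see
:func:`node_order`). Self-loops and parallel edges are never admitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

#: distance value reported for unreachable node pairs
UNREACHABLE = math.inf


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


@dataclass(frozen=True)
class GraphStats:
    """Descriptive statistics of an undirected network.

    diameter and asp are computed over finite (reachable) unordered pairs;
    acc is the mean local clustering coefficient, with nodes of degree < 2
    contributing 0.
    """

    n: int
    m: int
    diameter: float
    asp: float
    acc: float


def node_order(net: nx.Graph) -> list:
    """Canonical node ordering used for all matrix rows and TSV output."""
    return list(net.nodes)


def _coerce_label(tok: str):
    # integer-looking labels become ints so generated graphs round-trip
    try:
        return int(tok)
    except ValueError:
        return tok


def read_edge_list(source: IO[str] | Iterable[str], sep: str | None = None) -> nx.Graph:
    """Read an undirected simple graph from an edge list.

    One edge per line, two labels separated by whitespace or commas (or by
    `sep` if given). Lines starting with ``#`` and blank lines are skipped.
    Duplicate lines and reversed duplicates collapse to a single edge;
    self-loop lines are dropped with a warning.

    Raises
    ------
    EdgeListParseError
        On a malformed line (naming its line number) or empty input.
    """
    net = nx.Graph()
    seen_any = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split(sep) if sep else line.replace(",", " ").split()
        if len(toks) != 2:
            raise EdgeListParseError(
                f"line {lineno}: expected two node labels, got {len(toks)}: {line!r}"
            )
        u, v = (_coerce_label(t) for t in toks)
        seen_any = True
        if u == v:
            logger.warning("line %d: dropping self-loop on node %r", lineno, u)
            net.add_node(u)
            continue
        net.add_edge(u, v)
    if not seen_any:
        raise EdgeListParseError("empty edge list: no edges or nodes found")
    return net


def write_edge_list(net: nx.Graph, sink: IO[str]) -> None:
    """Write one edge per line (space separated); isolated nodes as bare labels."""
    for u, v in net.edges:
        sink.write(f"{u} {v}\n")
    # isolated nodes survive as self-loop lines, which the reader drops
    # back to bare nodes
    for u in nx.isolates(net):
        sink.write(f"{u} {u}\n")


def write_scores(scores: "pd.DataFrame", sink: IO[str]) -> None:  # noqa: F821
    """Write a node -> metrics table as TSV with a header row."""
    if len(scores) == 0:
        raise ValueError("scores table is empty")
    scores.to_csv(sink, sep="\t", index_label="node", float_format="%.12g")


def load_fixture(name: str) -> nx.Graph:
    """Load a bundled network fixture by name (e.g. ``"karate"``)."""
    path = resources.files("dsrank.data").joinpath(f"{name}.edgelist")
    with path.open("r") as fh:
        return read_edge_list(fh)


def generate_ba(n: int, m_attach: int, seed: int) -> nx.Graph:
    """Barabasi-Albert preferential-attachment graph.

    Standard growth from a star seed: each of the n - m_attach new nodes
    attaches m_attach edges preferentially, giving m_attach * (n - m_attach)
    edges in total. Deterministic given `seed`; always connected.
    """
    if not 1 <= m_attach < n:
        raise ValueError(f"require 1 <= m_attach < n, got m_attach={m_attach}, n={n}")
    return nx.barabasi_albert_graph(n, m_attach, seed=seed)


def generate_named(kind: str, n: int, *, p: float | None = None, seed: int | None = None) -> nx.Graph:
    """Textbook topologies: star, path, cycle, complete, or Erdos-Renyi (``er``).

    ``star(n)`` has n nodes total (one hub, n-1 leaves). ``er`` requires
    edge probability `p` and a `seed`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "star":
        return nx.star_graph(n - 1)
    if kind == "path":
        return nx.path_graph(n)
    if kind == "cycle":
        return nx.cycle_graph(n)
    if kind == "complete":
        return nx.complete_graph(n)
    if kind == "er":
        if p is None or seed is None:
            raise ValueError("er generator requires p and seed")
        return nx.gnp_random_graph(n, p, seed=seed)
    raise ValueError(f"unknown graph kind {kind!r}")


def shortest_paths(net: nx.Graph) -> dict:
    """All-pairs BFS hop distances.

    Returns a nested mapping ``d[i][j]``; unreachable pairs are marked with
    :data:`UNREACHABLE` so that every pair is present.
    """
    nodes = node_order(net)
    table = {i: dict.fromkeys(nodes, UNREACHABLE) for i in nodes}
    for i, row in nx.all_pairs_shortest_path_length(net):
        for j, d in row.items():
            table[i][j] = float(d)
    return table


def graph_stats(net: nx.Graph) -> GraphStats:
    """Node/edge counts, diameter, average shortest path, average clustering.

    Diameter and ASP consider finite distances only (equivalent to the plain
    definitions on connected graphs); ACC is the Watts-Strogatz mean local
    clustering coefficient with degree-<2 nodes contributing 0.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    if n < 1:
        raise ValueError("graph must have at least one node")
    dists = [
        float(d)
        for i, row in nx.all_pairs_shortest_path_length(net)
        for j, d in row.items()
        if j != i
    ]  # ordered reachable pairs, each unordered pair counted twice
    diameter = max(dists) if dists else 0.0
    asp = (sum(dists) / len(dists)) if dists else 0.0
    acc = nx.average_clustering(net) if n else 0.0
    return GraphStats(n=n, m=m, diameter=diameter, asp=asp, acc=acc)
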