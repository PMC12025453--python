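"""The six per-node attribute indicators fused by the DS score.

Each function returns a :class:`CentralityVector` — a named, node-keyed
vector of nonnegative reals. Conventions:

* **DC** — raw (unnormalized) degree.
* **CC** — closeness, (n-1) / sum of distances; on disconnected graphs the
  value is computed within a node's reachable set and scaled by
  (r-1)/(n-1), so isolated nodes score 0 and no infinities appear.
* **HCC** — harmonic closeness, mean of reciprocal distances over the other
  n-1 nodes, with 1/d = 0 for unreachable partners.
* **BC** — raw betweenness: for every unordered pair s != t (both distinct
  from v), the fraction of s-t geodesics through v.
* **PR** — PageRank with uniform teleport. The undamped random-walk update
  diverges on bipartite graphs (stars, even cycles), so damping defaults to
  0.85; damping -> 1 recovers the plain update wherever it converges.
* **EC** — entries of the adjacency matrix's dominant eigenvector,
  nonnegative and L2-normalized, by power iteration.

Raw scales are immaterial downstream: the fusion pipeline column-normalizes
every metric, making the DS score invariant to positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .netcore import node_order

METRICS = ("dc", "cc", "hcc", "bc", "pr", "ec")

DEFAULT_DAMPING = 0.85
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance within max_iter."""


@dataclass(frozen=True)
class CentralityVector:
    """A single metric evaluated on every node of one network."""

    metric: str
    values: dict = field(hash=False)

    def __post_init__(self):
        for node, v in self.values.items():
            if not (v >= 0) or v != v or v == float("inf"):
                raise ValueError(f"{self.metric}[{node!r}] = {v} is not finite >= 0")

    def __getitem__(self, node):
        return self.values[node]


def degree_centrality(net: nx.Graph) -> CentralityVector:
    """Number of edges incident to each node."""
    return CentralityVector("dc", {v: float(d) for v, d in net.degree})


def closeness_centrality(net: nx.Graph) -> CentralityVector:
    """Reciprocal mean distance, with the (r-1)/(n-1) disconnected scaling."""
    return CentralityVector("cc", dict(nx.closeness_centrality(net, wf_improved=True)))


def harmonic_closeness(net: nx.Graph) -> CentralityVector:
    """Mean reciprocal distance to the other n-1 nodes."""
    n = net.number_of_nodes()
    raw = nx.harmonic_centrality(net)
    scale = 1.0 / (n - 1) if n > 1 else 0.0
    return CentralityVector("hcc", {v: raw[v] * scale for v in net})


def betweenness_centrality(net: nx.Graph) -> CentralityVector:
    """Raw geodesic-fraction betweenness (endpoints excluded, pairs unordered)."""
    return CentralityVector("bc", dict(nx.betweenness_centrality(net, normalized=False)))


def pagerank(
    net: nx.Graph,
    damping: float = DEFAULT_DAMPING,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityVector:
    """Damped random-walk stationary distribution; sums to 1.

    Converged when the successive L1 change drops below `tol`; raises
    :class:`ConvergenceError` otherwise.
    """
    if not 0.0 < damping <= 1.0:
        raise ValueError(f"damping must lie in (0, 1], got {damping}")
    n = net.number_of_nodes()
    try:
        # networkx declares convergence at L1 error < n * tol
        pr = nx.pagerank(net, alpha=damping, tol=tol / max(n, 1), max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"pagerank did not reach an L1 gap below {tol} in {max_iter} iterations"
        ) from exc
    return CentralityVector("pr", {v: float(x) for v, x in pr.items()})


def eigenvector_centrality(
    net: nx.Graph,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityVector:
    """Dominant adjacency eigenvector, nonnegative and L2-normalized."""
    if net.number_of_edges() == 0:
        raise ValueError("eigenvector centrality is undefined on an edgeless graph")
    try:
        ec = nx.eigenvector_centrality(net, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"eigenvector power iteration did not converge in {max_iter} iterations"
        ) from exc
    return CentralityVector("ec", {v: abs(float(x)) for v, x in ec.items()})


def all_centralities(
    net: nx.Graph,
    metrics: tuple[str, ...] = METRICS,
    damping: float = DEFAULT_DAMPING,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[CentralityVector]:
    """Evaluate the requested metrics in order (default dc, cc, hcc, bc, pr, ec)."""
    dispatch = {
        "dc": lambda: degree_centrality(net),
        "cc": lambda: closeness_centrality(net),
        "hcc": lambda: harmonic_closeness(net),
        "bc": lambda: betweenness_centrality(net),
        "pr": lambda: pagerank(net, damping=damping, tol=tol, max_iter=max_iter),
        "ec": lambda: eigenvector_centrality(net, tol=tol, max_iter=max_iter),
    }
    unknown = [m for m in metrics if m not in dispatch]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; choose from {METRICS}")
    out = []
    for m in metrics:
        vec = dispatch[m]()
        # uniform node coverage in canonical order
        vec = CentralityVector(m, {v: vec.values[v] for v in node_order(net)})
        out.append(vec)
    return out
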