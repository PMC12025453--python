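"""Targeted-attack robustness protocol.

Nodes are removed one at a time in the order given by a ranking computed
once on the intact network (static attack; an adaptive mode that re-ranks
after every removal is available behind a flag). After each removal two
summaries are recorded against the *intact* network's size N and global
efficiency eta_0:

* ``G = R / N`` — largest-connected-component fraction, non-increasing,
  reaching 0 when every node is gone;
* ``mu = 1 - eta / eta_0`` — relative efficiency loss, non-decreasing,
  reaching exactly 1 at full dismantlement because removed nodes contribute
  nothing to eta while N stays frozen.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx

from . import centrality as _centrality
from . import evidence as _evidence

STRATEGIES = ("ds",) + _centrality.METRICS + ("random",)


@dataclass(frozen=True)
class AttackCurve:
    """Dismantlement trajectory of one removal strategy."""

    strategy: str
    removed_nodes: tuple = field(hash=False)
    g_values: tuple = field(hash=False)   # g_values[k]: G after k removals
    mu_values: tuple = field(hash=False)  # mu_values[k]: mu after k removals

    @property
    def removed(self) -> tuple:
        return tuple(range(len(self.g_values)))

    def removals_to_collapse(self) -> int | None:
        """First removal count at which G hits 0, or None if never reached."""
        for k, g in enumerate(self.g_values):
            if g == 0.0:
                return k
        return None


def lcc_size(net: nx.Graph) -> int:
    """Node count of the largest connected component (0 for the empty graph)."""
    if net.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(net))


def efficiency(net: nx.Graph, original_n: int) -> float:
    """Global efficiency against a frozen original size.

    Mean of 1/d_ij over ordered pairs of the *original* network, where pairs
    involving removed nodes and unreachable pairs contribute 0.
    """
    if original_n < 2:
        raise ValueError("original_n must be >= 2")
    total = 0.0
    for i, row in nx.all_pairs_shortest_path_length(net):
        for j, d in row.items():
            if j != i:
                total += 1.0 / d
    return total / (original_n * (original_n - 1))


def ranking_for(
    net: nx.Graph,
    strategy: str,
    *,
    seed: int | None = None,
    damping: float = _centrality.DEFAULT_DAMPING,
    tol: float = _centrality.DEFAULT_TOL,
    max_iter: int = _centrality.DEFAULT_MAX_ITER,
) -> list:
    """Full node ranking under one strategy name (ds, a single metric, or random)."""
    if strategy == "random":
        if seed is None:
            raise ValueError("random strategy requires a seed")
        nodes = list(net.nodes)
        random.Random(seed).shuffle(nodes)
        return nodes
    if strategy == "ds":
        vectors = _centrality.all_centralities(net, damping=damping, tol=tol, max_iter=max_iter)
        V = _evidence.normalize_columns(_evidence.build_evaluation_matrix(vectors))
        return _evidence.rank_nodes(_evidence.ds_score(V))
    if strategy in _centrality.METRICS:
        (vec,) = _centrality.all_centralities(
            net, metrics=(strategy,), damping=damping, tol=tol, max_iter=max_iter
        )
        return _evidence.rank_nodes(vec)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def attack_curve(net: nx.Graph, ranking: list, k_max: int | None = None) -> AttackCurve:
    """Remove nodes in ranking order, tracking G and mu after each removal."""
    n0 = net.number_of_nodes()
    if k_max is None:
        k_max = len(ranking)
    if k_max > len(ranking):
        raise ValueError("k_max exceeds ranking length")
    missing = [v for v in ranking[:k_max] if v not in net]
    if missing:
        raise ValueError(f"ranking names nodes absent from the network: {missing[:5]}")
    work = net.copy()
    eta0 = efficiency(work, n0)
    g_values = [lcc_size(work) / n0]
    mu_values = [0.0]
    removed = []
    for v in ranking[:k_max]:
        work.remove_node(v)
        removed.append(v)
        g_values.append(lcc_size(work) / n0)
        eta = efficiency(work, n0) if work.number_of_nodes() else 0.0
        mu_values.append(1.0 - (eta / eta0 if eta0 > 0 else 0.0))
    return AttackCurve("custom", tuple(removed), tuple(g_values), tuple(mu_values))


def _adaptive_attack(net, strategy, k_max, seed, **kwargs) -> AttackCurve:
    n0 = net.number_of_nodes()
    work = net.copy()
    eta0 = efficiency(work, n0)
    g_values = [lcc_size(work) / n0]
    mu_values = [0.0]
    removed = []
    for step in range(k_max):
        step_seed = None if seed is None else seed + step
        target = ranking_for(work, strategy, seed=step_seed, **kwargs)[0]
        work.remove_node(target)
        removed.append(target)
        g_values.append(lcc_size(work) / n0)
        eta = efficiency(work, n0) if work.number_of_nodes() else 0.0
        mu_values.append(1.0 - (eta / eta0 if eta0 > 0 else 0.0))
    return AttackCurve(strategy, tuple(removed), tuple(g_values), tuple(mu_values))


def compare_strategies(
    net: nx.Graph,
    strategies: list[str],
    k_max: int | None = None,
    *,
    adaptive: bool = False,
    seed: int | None = None,
    **kwargs,
) -> list[AttackCurve]:
    """One attack curve per strategy, all of length k_max + 1.

    Static mode (default) ranks once on the intact network; adaptive mode
    re-ranks after every removal. The adaptive DS ranking can fail midway on
    fragmented remnants (total conflict), so static is the reference mode.
    """
    if k_max is None:
        k_max = net.number_of_nodes()
    curves = []
    for strategy in strategies:
        if adaptive and strategy != "random":
            curves.append(_adaptive_attack(net, strategy, k_max, seed, **kwargs))
        else:
            ranking = ranking_for(net, strategy, seed=seed, **kwargs)
            curve = attack_curve(net, ranking, k_max)
            curves.append(
                AttackCurve(strategy, curve.removed_nodes, curve.g_values, curve.mu_values)
            )
    return curves
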