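"""Influential-node ranking by Dempster-Shafer fusion of centrality evidence.

The package fuses six per-node centrality indicators (degree, closeness,
harmonic closeness, betweenness, PageRank, eigenvector) into a single DS
influence score by treating each column-normalized metric as a body of
evidence over the node set and combining them with Dempster's rule. It also
provides the targeted-attack protocol used to validate such rankings and a
visibility-graph builder for turning time series into networks.
"""

from __future__ import annotations

import pandas as pd

from . import centrality, evidence, netcore, robustness, visibility  # noqa: F401
from .centrality import METRICS, all_centralities
from .evidence import build_evaluation_matrix, ds_score, normalize_columns, rank_nodes
from .netcore import generate_ba, generate_named, graph_stats, load_fixture, read_edge_list
from .robustness import attack_curve, compare_strategies
from .visibility import TimeSeries, build_visibility_graph

__version__ = "0.1.0"

__all__ = [
    "METRICS",
    "TimeSeries",
    "all_centralities",
    "attack_curve",
    "build_evaluation_matrix",
    "build_visibility_graph",
    "compare_strategies",
    "ds_score",
    "generate_ba",
    "generate_named",
    "graph_stats",
    "load_fixture",
    "normalize_columns",
    "rank_nodes",
    "read_edge_list",
    "score_table",
]


def score_table(net, metrics=METRICS, **kwargs) -> pd.DataFrame:
    """Raw centralities plus DS score and DS rank for every node.

    Returns a DataFrame indexed by node with one column per requested
    metric, a ``ds`` column (the fused score, summing to 1) and a
    ``ds_rank`` column (1 = most influential; ties broken by node label).
    """
    vectors = all_centralities(net, metrics=tuple(metrics), **kwargs)
    B = build_evaluation_matrix(vectors)
    scores = ds_score(normalize_columns(B))
    table = B.copy()
    table["ds"] = scores
    order = rank_nodes(scores)
    table["ds_rank"] = [order.index(v) + 1 for v in table.index]
    return table
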