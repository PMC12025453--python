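"""Natural visibility graphs: mapping a univariate time series to a network.

Two observations (t_a, x_a) and (t_b, x_b) are linked iff the straight
chord between them passes strictly above every intermediate observation:
for all c with t_a < t_c < t_b,

    x_c < x_a + (x_b - x_a) * (t_c - t_a) / (t_b - t_a).

A point lying exactly on the chord blocks visibility (strict inequality),
so collinear runs contribute only consecutive edges. Consecutive points are
always linked (no intermediate point exists), hence every visibility graph
contains the time path. The edge set is invariant under x -> a*x + b with
a > 0 and under strictly increasing affine rescaling of the times.

Nodes are labeled by 1-based series position, so "node 677" is the 677th
observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TimeSeries:
    """Strictly increasing time points with real-valued observations."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) < 1:
            raise ValueError("series must contain at least one point")
        t = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(self.values)):
            raise ValueError("times and values must be finite")

    def __len__(self):
        return len(self.times)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "TimeSeries":
        """Series sampled at the integer times 1..n."""
        return cls(tuple(float(i) for i in range(1, len(values) + 1)),
                   tuple(float(x) for x in values))


def read_series_csv(source: IO[str]) -> TimeSeries:
    """Read a one-column (value) or two-column (time, value) CSV.

    A non-numeric first row is treated as a header. One-column input gets
    times 1..n.
    """
    df = pd.read_csv(source, header=None, comment="#")
    try:
        df = df.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].astype(float)  # first row was a header
    if df.empty:
        raise ValueError("empty time series input")
    if df.shape[1] == 1:
        return TimeSeries.from_values(df.iloc[:, 0].tolist())
    if df.shape[1] == 2:
        return TimeSeries(tuple(df.iloc[:, 0]), tuple(df.iloc[:, 1]))
    raise ValueError(f"expected 1 or 2 columns, got {df.shape[1]}")


def _node_labels(n: int) -> range:
    return range(1, n + 1)


def build_visibility_graph(series: TimeSeries) -> nx.Graph:
    """Construct the visibility graph of a series.

    Sweep: for a fixed left endpoint a, point b > a is visible iff the
    chord slope (x_b - x_a)/(t_b - t_a) strictly exceeds the maximum slope
    from a to any intermediate point — an exact restatement of the strict
    visibility criterion, evaluated in O(n^2).
    """
    t = np.asarray(series.times, dtype=float)
    x = np.asarray(series.values, dtype=float)
    n = len(series)
    net = nx.Graph()
    net.add_nodes_from(_node_labels(n))
    for a in range(n - 1):
        slopes = (x[a + 1:] - x[a]) / (t[a + 1:] - t[a])
        max_so_far = -np.inf
        for off, s in enumerate(slopes):
            if s > max_so_far:
                net.add_edge(a + 1, a + 2 + off)
            max_so_far = max(max_so_far, s)
    return net


def visibility_oracle(series: TimeSeries) -> nx.Graph:
    """Literal O(n^3) evaluation of the visibility criterion (test oracle).

    Checks every pair against every intermediate point directly; kept
    independent of the sweep in :func:`build_visibility_graph`.
    """
    t = np.asarray(series.times, dtype=float)
    x = np.asarray(series.values, dtype=float)
    n = len(series)
    net = nx.Graph()
    net.add_nodes_from(_node_labels(n))
    for a in range(n - 1):
        for b in range(a + 1, n):
            tc = t[a + 1:b]
            xc = x[a + 1:b]
            chord = x[a] + (x[b] - x[a]) * (tc - t[a]) / (t[b] - t[a])
            if np.all(xc < chord):
                net.add_edge(a + 1, b + 1)
    return net


def degree_distribution(net: nx.Graph) -> dict[int, int]:
    """Map degree -> number of nodes with that degree; frequencies sum to n."""
    dist: dict[int, int] = {}
    for _, d in net.degree:
        dist[d] = dist.get(d, 0) + 1
    return dist
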