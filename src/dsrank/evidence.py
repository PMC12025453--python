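"""Dempster-Shafer evidence machinery and the DS influence score.

The frame of discernment is the node set of the network. Each centrality
column, after column normalization, is treated as a basic probability
assignment (BPA) whose focal elements are the node singletons: the mass on
``{i}`` is that node's share of the column total. Fusing the m columns with
Dempster's rule then yields one comprehensive score per node.

With singleton-only evidence, Dempster's rule reduces to a renormalized
elementwise product: a node receives positive fused mass only if *every*
metric assigns it positive mass, and a node with a zero anywhere in its row
scores exactly 0. The general-subset combination engine is implemented in
full (and doubles as the oracle for that closed form); it errors on total
conflict (k = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .centrality import CentralityVector

MASS_TOL = 1e-9
CONFLICT_TOL = 1e-12


class TotalConflictError(ValueError):
    """Dempster combination is undefined: the conflict coefficient k = 1."""


@dataclass(frozen=True)
class Bpa:
    """A basic probability assignment over subsets of a frame of discernment.

    `frame` is the ordered tuple of mutually exclusive hypotheses; `mass`
    maps frozensets of frame elements to masses in [0, 1]. The empty set
    carries no mass and all masses sum to 1 (within 1e-9); subsets with
    positive mass are the focal elements.
    """

    frame: tuple
    mass: Mapping[frozenset, float]

    def __post_init__(self):
        if len(self.frame) == 0:
            raise ValueError("frame of discernment must be non-empty")
        if len(set(self.frame)) != len(self.frame):
            raise ValueError("frame elements must be distinct")
        universe = frozenset(self.frame)
        total = 0.0
        for subset, m in self.mass.items():
            if not subset:
                if m != 0.0:
                    raise ValueError("the empty set must carry zero mass")
                continue
            if not subset <= universe:
                raise ValueError(f"focal element {set(subset)} is not a subset of the frame")
            if not 0.0 <= m <= 1.0 + MASS_TOL:
                raise ValueError(f"mass {m} outside [0, 1]")
            total += m
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"masses sum to {total}, expected 1 within {MASS_TOL}")

    def focal_elements(self) -> list[frozenset]:
        return [s for s, m in self.mass.items() if m > 0.0]


def vacuous_bpa(frame: Sequence) -> Bpa:
    """The neutral element of combination: all mass on the full frame."""
    frame = tuple(frame)
    return Bpa(frame, {frozenset(frame): 1.0})


def dempster_combine(m1: Bpa, m2: Bpa) -> Bpa:
    """Fuse two BPAs by Dempster's rule of combination.

    The fused mass of a non-empty subset G is the total product mass of
    focal-element pairs intersecting in G, renormalized by 1 - k, where the
    conflict coefficient k collects the product mass of empty intersections.

    Raises
    ------
    TotalConflictError
        If k = 1 within 1e-12 (no two focal elements intersect).
    ValueError
        If the frames differ.
    """
    if m1.frame != m2.frame:
        raise ValueError("cannot combine BPAs over different frames of discernment")
    fused: dict[frozenset, float] = {}
    conflict = 0.0
    for b, mb in m1.mass.items():
        if mb == 0.0:
            continue
        for c, mc in m2.mass.items():
            if mc == 0.0:
                continue
            inter = b & c
            w = mb * mc
            if inter:
                fused[inter] = fused.get(inter, 0.0) + w
            else:
                conflict += w
    # normalize by the accumulated agreement mass rather than 1 - k: the two
    # are equal exactly, but subtracting a conflict near 1 cancels
    # catastrophically while the agreement sum stays well conditioned; with
    # no conflict at all the products already carry unit mass (keeps the
    # vacuous-BPA identity bit-exact)
    norm = sum(fused.values()) if conflict > 0.0 else 1.0
    if norm <= CONFLICT_TOL:
        raise TotalConflictError(
            f"totally conflicting evidence (k = {conflict!r}); Dempster's rule is undefined"
        )
    return Bpa(m1.frame, {s: w / norm for s, w in fused.items()})


def build_evaluation_matrix(vectors: Iterable[CentralityVector]) -> pd.DataFrame:
    """Stack centrality vectors into the n x m evaluation matrix.

    Rows are nodes in the first vector's order; column j is the j-th metric.
    All vectors must cover exactly the same node set.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("need at least one centrality vector")
    nodes = list(vectors[0].values)
    node_set = set(nodes)
    for vec in vectors[1:]:
        if set(vec.values) != node_set:
            raise ValueError(f"vector {vec.metric!r} covers a different node set")
    data = {vec.metric: [vec.values[v] for v in nodes] for vec in vectors}
    return pd.DataFrame(data, index=nodes)


def normalize_columns(B: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its sum so columns are unit-mass distributions.

    An all-zero column (no metric signal at all) becomes the uniform column
    1/n. Idempotent, and invariant to positive rescaling of any raw column.
    """
    arr = B.to_numpy(dtype=float)
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("evaluation matrix entries must be finite and >= 0")
    sums = arr.sum(axis=0)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j, s in enumerate(sums):
        out[:, j] = arr[:, j] / s if s > 0 else 1.0 / n
    return pd.DataFrame(out, index=B.index, columns=B.columns)


def columns_to_bpas(V: pd.DataFrame) -> list[Bpa]:
    """Read each normalized column as a singleton-focal BPA over the node frame."""
    frame = tuple(V.index)
    bpas = []
    for col in V.columns:
        mass = {
            frozenset([node]): float(v)
            for node, v in V[col].items()
            if v > 0.0
        }
        bpas.append(Bpa(frame, mass))
    return bpas


def ds_score(V: pd.DataFrame) -> pd.Series:
    """Comprehensive node scores: the Dempster fold of the column BPAs.

    Combines the m column BPAs left to right (the result is provably
    order-independent) and reads off the singleton masses. A node with a
    zero entry in any column scores 0; if every node has a zero somewhere,
    the evidence is totally conflicting and an error is raised.

    Returns a node-indexed Series summing to 1.
    """
    if V.shape[1] < 1:
        raise ValueError("need at least one metric column")
    bpas = columns_to_bpas(V)
    fused = bpas[0]
    try:
        for nxt in bpas[1:]:
            fused = dempster_combine(fused, nxt)
    except TotalConflictError as exc:
        raise TotalConflictError(
            "total conflict -- no node is supported by all metrics"
        ) from exc
    scores = pd.Series(0.0, index=V.index)
    for subset, m in fused.mass.items():
        (node,) = subset  # singleton inputs stay singleton under intersection
        scores[node] = m
    return scores


def rank_nodes(scores) -> list:
    """Nodes in descending score order; ties broken by ascending node label."""
    if isinstance(scores, CentralityVector):
        items = scores.values.items()
    elif isinstance(scores, pd.Series):
        items = scores.items()
    else:
        items = dict(scores).items()
    items = list(items)
    if not items:
        raise ValueError("cannot rank an empty score table")
    return [node for node, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]
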