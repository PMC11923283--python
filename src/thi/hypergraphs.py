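"""Undirected hypergraphs, random generators, and directed candidate/truth sets.

Ground-truth structures are undirected (a p-hyperedge couples into every member
node's equation), while inference produces *directed* hyperedges: an unordered
source set jointly influencing one target node.  Evaluation therefore compares
directed-vs-directed via :func:`directed_truth`.

Node indices are 0-based everywhere.  Hyperedges are stored as sparse sets of
frozensets; the symmetric adjacency tensors are never materialized densely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, Iterable, Optional, Set, Tuple

import numpy as np

Edge = FrozenSet[int]

__all__ = [
    "Hypergraph",
    "DirectedHyperedge",
    "random_hypergraph",
    "random_simplicial_complex",
    "directed_truth",
    "candidate_set",
    "write_hyperedge_list",
    "read_hyperedge_list",
]


@dataclass
class Hypergraph:
    """Undirected hypergraph with edges of cardinality 2, 3 and optionally 4.

    Parameters
    ----------
    n
        Number of nodes; members of every edge must lie in ``[0, n)``.
    edges2, edges3, edges4
        Sets of frozensets of the stated cardinality.
    """

    n: int
    edges2: Set[Edge] = field(default_factory=set)
    edges3: Set[Edge] = field(default_factory=set)
    edges4: Set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"node count must be positive, got {self.n}")
        for card, edges in ((2, self.edges2), (3, self.edges3), (4, self.edges4)):
            edges_norm = {frozenset(e) for e in edges}
            for e in edges_norm:
                if len(e) != card:
                    raise ValueError(f"edge {set(e)} does not have cardinality {card}")
                if any(v < 0 or v >= self.n for v in e):
                    raise ValueError(f"edge {set(e)} has nodes outside [0, {self.n})")
            setattr(self, f"edges{card}", edges_norm)

    def num_edges(self) -> Tuple[int, int, int]:
        return len(self.edges2), len(self.edges3), len(self.edges4)

    def relabel(self, perm: Iterable[int]) -> "Hypergraph":
        """Return a copy with node ``i`` renamed to ``perm[i]``."""
        p = list(perm)
        if sorted(p) != list(range(self.n)):
            raise ValueError("perm must be a permutation of range(n)")
        remap = lambda edges: {frozenset(p[v] for v in e) for e in edges}
        return Hypergraph(self.n, remap(self.edges2), remap(self.edges3), remap(self.edges4))


@dataclass(frozen=True)
class DirectedHyperedge:
    """An unordered source set jointly influencing one target node."""

    target: int
    sources: Edge

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", frozenset(self.sources))
        if not self.sources:
            raise ValueError("sources must be nonempty")
        if self.target in self.sources:
            raise ValueError("target cannot be one of its own sources")

    @property
    def order(self) -> int:
        """Interaction order p = |sources| + 1."""
        return len(self.sources) + 1


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


def random_hypergraph(n: int, p2: float, p3: float, seed: int) -> Hypergraph:
    """Erdős–Rényi-type random hypergraph.

    Every one of the C(n,2) node pairs is included independently with
    probability ``p2``, and every one of the C(n,3) triples independently with
    probability ``p3`` (the semantics of XGI's ``random_hypergraph``).
    Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _check_prob("p2", p2)
    _check_prob("p3", p3)
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(n), 2))
    triples = list(combinations(range(n), 3))
    keep2 = rng.random(len(pairs)) < p2
    keep3 = rng.random(len(triples)) < p3
    edges2 = {frozenset(e) for e, k in zip(pairs, keep2) if k}
    edges3 = {frozenset(e) for e, k in zip(triples, keep3) if k}
    return Hypergraph(n, edges2, edges3)


def random_simplicial_complex(n: int, p2: float, p3: float, seed: int) -> Hypergraph:
    """Random simplicial complex: like :func:`random_hypergraph`, but every
    included triple also contributes its three boundary pairs (downward
    closure)."""
    h = random_hypergraph(n, p2, p3, seed)
    edges2 = set(h.edges2)
    for tri in h.edges3:
        for pair in combinations(sorted(tri), 2):
            edges2.add(frozenset(pair))
    return Hypergraph(n, edges2, h.edges3)


def directed_truth(h: Hypergraph) -> Set[DirectedHyperedge]:
    """Directed ground truth: each undirected p-edge points into each member.

    ``{i,j}`` yields ``(i,{j})`` and ``(j,{i})``; ``{i,j,k}`` yields the three
    directed triads, and analogously for 4-edges.
    """
    out: Set[DirectedHyperedge] = set()
    for edges in (h.edges2, h.edges3, h.edges4):
        for e in edges:
            for v in e:
                out.add(DirectedHyperedge(v, frozenset(e - {v})))
    return out


def candidate_set(
    n: int,
    max_order: int,
    filter: Optional[Set[Edge]] = None,
) -> Set[DirectedHyperedge]:
    """All possible directed hyperedges up to ``max_order``.

    With a kept-pair ``filter``, a candidate survives only if *every* unordered
    pair of distinct nodes among ``{target} | sources`` is kept.
    Without a filter the count is ``n * (C(n-1,1) + C(n-1,2) [+ C(n-1,3)])``.
    """
    if max_order not in (2, 3, 4):
        raise ValueError(f"max_order must be in {{2, 3, 4}}, got {max_order}")

    def kept(nodes: Tuple[int, ...]) -> bool:
        if filter is None:
            return True
        return all(frozenset(p) in filter for p in combinations(nodes, 2))

    out: Set[DirectedHyperedge] = set()
    for t in range(n):
        others = [v for v in range(n) if v != t]
        for size in range(1, max_order):
            for srcs in combinations(others, size):
                if kept((t, *srcs)):
                    out.add(DirectedHyperedge(t, frozenset(srcs)))
    return out


# ---------------------------------------------------------------------------
# Hyperedge-list text format.
#
# Undirected: one line per edge, `order<TAB>node,node[,node][<TAB>weight]`.
# Directed:   `target<TAB>src[,src,...]<TAB>score`.
# Lines are sorted (by order, then lexicographic node indices) so files are
# byte-reproducible.


def write_hyperedge_list(path, h: Hypergraph) -> None:
    lines = []
    for edges in (h.edges2, h.edges3, h.edges4):
        for e in sorted(edges, key=lambda e: sorted(e)):
            nodes = ",".join(str(v) for v in sorted(e))
            lines.append(f"{len(e)}\t{nodes}")
    lines.sort(key=lambda s: (int(s.split("\t")[0]), [int(v) for v in s.split("\t")[1].split(",")]))
    with open(path, "w") as fh:
        fh.write(f"# nodes\t{h.n}\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_hyperedge_list(path) -> Hypergraph:
    n = None
    edges = {2: set(), 3: set(), 4: set()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# nodes"):
                    n = int(line.split("\t")[1])
                continue
            parts = line.split("\t")
            order = int(parts[0])
            nodes = frozenset(int(v) for v in parts[1].split(","))
            edges[order].add(nodes)
    if n is None:
        n = 1 + max((max(e) for es in edges.values() for e in es), default=0)
    return Hypergraph(n, edges[2], edges[3], edges[4])
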