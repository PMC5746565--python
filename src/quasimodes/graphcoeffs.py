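"""Directed graph of J^2 and graph-theoretic characteristic-polynomial coefficients.

The squared Jacobian is read as the adjacency matrix of a weighted digraph
(edge i -> j present iff (J^2)_{ji} != 0, self-loops included whenever a
diagonal entry is nonzero).  The coefficients of

    R(x) = det(x I + A) = x^n + a_1 x^{n-1} + ... + a_n,   A = J^2,

are assembled from the graph's *factors*: a factor of degree k is a set of
pairwise vertex-disjoint simple directed cycles jointly covering exactly k
vertices, its cardinality |f| is the number of cycles it contains, and

    a_k = sum over degree-k factors f of (-1)^(k - |f|) * prod_{c in f} w(c),

where the weight w(c) of a cycle v1 -> v2 -> ... -> vk -> v1 is the product
of its edge weights A_{v2 v1} A_{v3 v2} ... A_{v1 vk}.  This is the
permutation expansion of the principal minors regrouped by cycle cover:
a_1 = Tr(A) and a_n = det(A) fall out as special cases, and the generic
test oracle is direct determinant expansion.

Because A is a squared matrix it is generically dense, so the graph is
essentially complete; cycle and factor enumeration is exponential in n and
practical up to n of about 8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np

from .polyroots import Poly

__all__ = [
    "WeightedDigraph",
    "Cycle",
    "Factor",
    "graph_from_matrix",
    "enumerate_cycles",
    "enumerate_factors",
    "coefficient_via_factors",
    "char_poly_via_graph",
    "to_dot",
    "to_graphml",
    "cycles_factors_json",
]

_EXACT = (int, Fraction, np.integer)


@dataclass(frozen=True)
class WeightedDigraph:
    """Digraph with vertices 1..n and weighted edges; edge (i, j) has the
    weight of the underlying matrix entry A_{ji} (note the index order)."""

    n_vertices: int
    edges: dict  # (i, j) -> weight, 1-based vertices

    def weight(self, i: int, j: int):
        return self.edges[(i, j)]

    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self.edges


def graph_from_matrix(M, zero_tol: float | None = None) -> WeightedDigraph:
    """Digraph of a square matrix: edge i -> j iff |M_{ji}| > zero_tol.

    ``zero_tol`` defaults to 1e-12 relative to the largest entry for float
    matrices, and to exact zero for integer/Fraction (object) matrices.
    """
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    n = M.shape[0]
    exact = M.dtype == object or np.issubdtype(M.dtype, np.integer)
    if zero_tol is None:
        if exact:
            zero_tol = 0
        else:
            scale = float(np.max(np.abs(M.astype(float)))) if n else 0.0
            zero_tol = 1e-12 * max(1.0, scale)
    edges = {}
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            w = M[j - 1, i - 1]
            if (w != 0) if exact and zero_tol == 0 else (abs(w) > zero_tol):
                edges[(i, j)] = w
    return WeightedDigraph(n_vertices=n, edges=edges)


@dataclass(frozen=True)
class Cycle:
    """Simple directed cycle in canonical form: starts at its minimum
    vertex, direction preserved (so (1,2,3) and (1,3,2) are distinct)."""

    vertices: tuple
    weight: object

    @property
    def length(self) -> int:
        return len(self.vertices)

    @property
    def vertex_set(self) -> frozenset:
        return frozenset(self.vertices)


def _canonical(vertices) -> tuple:
    vertices = tuple(vertices)
    k = vertices.index(min(vertices))
    return vertices[k:] + vertices[:k]


def _cycle_weight(g: WeightedDigraph, vertices) -> object:
    w = None
    k = len(vertices)
    for idx in range(k):
        e = g.weight(vertices[idx], vertices[(idx + 1) % k])
        w = e if w is None else w * e
    return w


def enumerate_cycles(g: WeightedDigraph) -> list:
    """All simple directed cycles (self-loops included), canonicalized and
    sorted by (length, vertices)."""
    G = nx.DiGraph()
    G.add_nodes_from(range(1, g.n_vertices + 1))
    G.add_edges_from(g.edges.keys())
    cycles = []
    for vs in nx.simple_cycles(G):
        vs = _canonical(vs)
        cycles.append(Cycle(vertices=vs, weight=_cycle_weight(g, vs)))
    cycles.sort(key=lambda c: (c.length, c.vertices))
    return cycles


@dataclass(frozen=True)
class Factor:
    """A set of pairwise vertex-disjoint cycles covering `degree` vertices."""

    cycles: tuple  # sorted tuple of Cycle

    @property
    def degree(self) -> int:
        return sum(c.length for c in self.cycles)

    @property
    def cardinality(self) -> int:
        return len(self.cycles)

    @property
    def weight(self):
        w = None
        for c in self.cycles:
            w = c.weight if w is None else w * c.weight
        return w


def enumerate_factors(g: WeightedDigraph, k: int) -> list:
    """All factors of degree exactly k (disjoint cycle sets covering k vertices)."""
    if not 1 <= k <= g.n_vertices:
        raise ValueError(
            f"factor degree k={k} out of range 1..{g.n_vertices}")
    cycles = enumerate_cycles(g)
    factors = []

    def extend(start: int, chosen: list, used: frozenset, remaining: int):
        if remaining == 0:
            factors.append(Factor(tuple(chosen)))
            return
        for idx in range(start, len(cycles)):
            c = cycles[idx]
            if c.length > remaining or used & c.vertex_set:
                continue
            chosen.append(c)
            extend(idx + 1, chosen, used | c.vertex_set, remaining - c.length)
            chosen.pop()

    extend(0, [], frozenset(), k)
    return factors


def coefficient_via_factors(g: WeightedDigraph, k: int):
    """Coefficient a_k of x^(n-k) in det(x I + A) from degree-k factors.

    a_k = sum_f (-1)^(k - |f|) prod_{c in f} w(c); zero when the graph has
    no factor of degree k.
    """
    total = 0
    for f in enumerate_factors(g, k):
        total += (-1) ** (k - f.cardinality) * f.weight
    return total


def char_poly_via_graph(g: WeightedDigraph) -> Poly:
    """Assemble R(x) = det(x I + A) from the graph coefficient formula."""
    coeffs = [1] + [coefficient_via_factors(g, k)
                    for k in range(1, g.n_vertices + 1)]
    return Poly(coeffs)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def to_dot(g: WeightedDigraph) -> str:
    lines = ["digraph J2 {"]
    for v in range(1, g.n_vertices + 1):
        lines.append(f"  {v};")
    for (i, j), w in sorted(g.edges.items()):
        lines.append(f'  {i} -> {j} [label="{float(w):.6g}", weight={float(w):.6g}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(g: WeightedDigraph, path) -> None:
    G = nx.DiGraph()
    G.add_nodes_from(range(1, g.n_vertices + 1))
    for (i, j), w in g.edges.items():
        G.add_edge(i, j, weight=float(w))
    nx.write_graphml(G, path)


def cycles_factors_json(g: WeightedDigraph) -> str:
    cycles = enumerate_cycles(g)
    factors = {
        k: [
            {
                "cycles": [list(c.vertices) for c in f.cycles],
                "cardinality": f.cardinality,
                "weight": float(f.weight),
            }
            for f in enumerate_factors(g, k)
        ]
        for k in range(1, g.n_vertices + 1)
    }
    payload = {
        "n_vertices": g.n_vertices,
        "cycles": [
            {"vertices": list(c.vertices), "length": c.length,
             "weight": float(c.weight)}
            for c in cycles
        ],
        "factors": factors,
    }
    return json.dumps(payload, indent=2)
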