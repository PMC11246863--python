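"""Core types for the maximum-scoring path sets (MSPS) problem.

An MSPS instance is a vertex-weighted graph ``G`` (directed or undirected)
together with a startup penalty ``c >= 0``.  A feasible solution is a set of
vertex-disjoint simple paths; the score of a path is the sum of its vertex
weights minus ``c``, and the score of a solution is the sum of its path
scores.  The empty solution always scores 0, so the optimum is non-negative.

This module holds the data model shared by every solver plus a brute-force
oracle (:func:`solve_bruteforce`) that the fast solvers are verified against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "WeightedGraph",
    "Path",
    "PathSet",
    "ValidationReport",
    "BRUTEFORCE_EDGE_LIMIT",
    "canonical_edge",
    "path_score",
    "validate_path",
    "validate_path_set",
    "validate_solution_edges",
    "edges_to_path_set",
    "solve_bruteforce",
]

#: vertex identifiers are opaque strings ordered lexicographically; this order
#: is used for every tie-break in the package.
Vertex = str

#: a path is a non-empty ordered tuple of vertices; a single vertex is a legal
#: path of length 0 (no edges).
Path = tuple  # tuple[Vertex, ...]

Edge = tuple  # tuple[Vertex, Vertex]

BRUTEFORCE_EDGE_LIMIT = 18


class GraphError(ValueError):
    """Raised for malformed graphs, paths or solutions."""


def canonical_edge(u: Vertex, v: Vertex, directed: bool) -> Edge:
    """Canonical representation of an edge: ordered pair if *directed*,
    lexicographically sorted pair otherwise."""
    if directed or u <= v:
        return (u, v)
    return (v, u)


@dataclass(frozen=True)
class WeightedGraph:
    """A vertex-weighted graph without self-loops or parallel edges.

    Parameters
    ----------
    directed:
        Edge orientation matters if true.
    weights:
        Mapping from vertex identifier to its real-valued weight ``w(v)``
        (dimensionless score units).  The keys define the vertex set.
    edges:
        Iterable of vertex pairs.  Undirected edges are stored in canonical
        (sorted) order; duplicates collapse silently.
    """

    directed: bool
    weights: Mapping[Vertex, float]
    edges: frozenset = field(default_factory=frozenset)

    def __init__(self, directed: bool, weights: Mapping[Vertex, float],
                 edges: Iterable[Sequence[Vertex]] = ()):
        object.__setattr__(self, "directed", bool(directed))
        object.__setattr__(self, "weights", dict(weights))
        canon = set()
        for e in edges:
            u, v = e
            if u == v:
                raise GraphError(f"self-loop at vertex {u!r} is not allowed")
            if u not in self.weights or v not in self.weights:
                missing = u if u not in self.weights else v
                raise GraphError(f"edge ({u!r}, {v!r}) uses undeclared vertex {missing!r}")
            canon.add(canonical_edge(u, v, directed))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def vertices(self) -> frozenset:
        return frozenset(self.weights)

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def m(self) -> int:
        return len(self.edges)

    def weight(self, v: Vertex) -> float:
        return self.weights[v]

    def has_edge(self, u: Vertex, v: Vertex) -> bool:
        """True if the graph allows the step u -> v (either orientation when
        undirected)."""
        return canonical_edge(u, v, self.directed) in self.edges

    def sorted_vertices(self) -> list:
        return sorted(self.weights)

    def sorted_edges(self) -> list:
        return sorted(self.edges)

    def with_added(self, new_weights: Mapping[Vertex, float],
                   new_edges: Iterable[Sequence[Vertex]]) -> "WeightedGraph":
        """Return a copy extended by new vertices/edges (used by preprocessing)."""
        w = dict(self.weights)
        for v, wt in new_weights.items():
            if v in w:
                raise GraphError(f"vertex {v!r} already present")
            w[v] = wt
        return WeightedGraph(self.directed, w, list(self.edges) + list(new_edges))


@dataclass(frozen=True)
class PathSet:
    """A scored MSPS solution: pairwise vertex-disjoint simple paths."""

    paths: tuple = ()
    total_score: float = 0.0

    def __init__(self, paths: Iterable[Sequence[Vertex]] = (), total_score: float = 0.0):
        object.__setattr__(self, "paths", tuple(tuple(p) for p in paths))
        object.__setattr__(self, "total_score", float(total_score))

    def __iter__(self) -> Iterator[Path]:
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)

    def covered_vertices(self) -> frozenset:
        return frozenset(v for p in self.paths for v in p)


@dataclass
class ValidationReport:
    """Collected feasibility problems; empty report means feasible."""

    errors: list = field(default_factory=list)

    def add(self, message: str) -> None:
        self.errors.append(message)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __bool__(self) -> bool:  # truthy iff clean, so `if report:` reads naturally
        return self.ok

    def __str__(self) -> str:
        return "OK" if self.ok else "; ".join(self.errors)


def validate_path(path: Sequence[Vertex], graph: WeightedGraph) -> ValidationReport:
    report = ValidationReport()
    if len(path) == 0:
        report.add("path is empty")
        return report
    seen = set()
    for v in path:
        if v not in graph.weights:
            report.add(f"vertex {v!r} not in graph")
        if v in seen:
            report.add(f"vertex {v!r} repeated in path")
        seen.add(v)
    for u, v in zip(path, path[1:]):
        if not graph.has_edge(u, v):
            report.add(f"step ({u!r}, {v!r}) is not a graph edge")
    return report


def path_score(path: Sequence[Vertex], graph: WeightedGraph, c: float) -> float:
    """Score of one path: ``-c + sum of vertex weights``.

    Raises :class:`GraphError` if the path is invalid in *graph* or ``c < 0``.
    """
    if c < 0:
        raise GraphError("penalty c must be non-negative")
    report = validate_path(path, graph)
    if not report.ok:
        raise GraphError(f"invalid path {tuple(path)!r}: {report}")
    return -c + sum(graph.weights[v] for v in path)


def validate_path_set(ps: PathSet, graph: WeightedGraph, c: float,
                      tol: float = 1e-9) -> ValidationReport:
    """Check disjointness, path validity and score consistency of *ps*."""
    report = ValidationReport()
    seen = {}
    total = 0.0
    for i, p in enumerate(ps.paths):
        sub = validate_path(p, graph)
        if not sub.ok:
            report.add(f"path {i}: {sub}")
        else:
            total += path_score(p, graph, c)
        for v in p:
            if v in seen and seen[v] != i:
                report.add(f"vertex {v!r} shared by paths {seen[v]} and {i}")
            seen.setdefault(v, i)
    if report.ok and abs(total - ps.total_score) > tol:
        report.add(f"stated score {ps.total_score} != recomputed {total}")
    return report


# ---------------------------------------------------------------------------
# Solutions as edge sets (the cycles-allowed reformulation)
# ---------------------------------------------------------------------------

def validate_solution_edges(edges: Iterable[Edge], graph: WeightedGraph) -> ValidationReport:
    """Degree feasibility of an edge set: directed vertices take at most one
    incoming and one outgoing selected edge; undirected vertices at most two
    selected edges in total."""
    report = ValidationReport()
    edges = list(edges)
    indeg: dict = {}
    outdeg: dict = {}
    deg: dict = {}
    seen = set()
    for e in edges:
        u, v = e
        if not graph.has_edge(u, v):
            report.add(f"selected edge ({u!r}, {v!r}) not in graph")
            continue
        ce = canonical_edge(u, v, graph.directed)
        if ce in seen:
            report.add(f"edge {ce!r} selected twice")
        seen.add(ce)
        outdeg[u] = outdeg.get(u, 0) + 1
        indeg[v] = indeg.get(v, 0) + 1
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    if graph.directed:
        for v, d in indeg.items():
            if d > 1:
                report.add(f"vertex {v!r} has {d} incoming selected edges")
        for v, d in outdeg.items():
            if d > 1:
                report.add(f"vertex {v!r} has {d} outgoing selected edges")
    else:
        for v, d in deg.items():
            if d > 2:
                report.add(f"vertex {v!r} has {d} selected edges")
    return report


def _components(edges: Sequence[Edge]) -> list:
    """Connected components (as vertex sets) of the subgraph formed by edges,
    ignoring orientation."""
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return list(comps.values())


def solution_edges_score(edges: Iterable[Edge], graph: WeightedGraph, c: float) -> float:
    """Score of an edge-set solution: covered vertex weights minus ``c`` per
    connected component of the selected subgraph."""
    edges = list(edges)
    comps = _components(edges)
    covered = set().union(*comps) if comps else set()
    return sum(graph.weights[v] for v in covered) - c * len(comps)


def edges_to_path_set(edges: Iterable[Edge], graph: WeightedGraph, c: float) -> PathSet:
    """Decompose a degree-feasible edge set into maximal paths.

    Each component is a simple path or a simple cycle; a cycle is opened by
    dropping its lexicographically smallest edge, which leaves the score
    unchanged.  Output paths are sorted by their first vertex.
    """
    edges = sorted({canonical_edge(u, v, graph.directed) for u, v in edges})
    report = validate_solution_edges(edges, graph)
    if not report.ok:
        raise GraphError(f"infeasible edge set: {report}")

    # adjacency restricted to the selection
    succ: dict = {}
    pred: dict = {}
    adj: dict = {}
    for u, v in edges:
        succ[u] = v
        pred[v] = u
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    comps = _components(edges)
    kept = set(edges)
    for comp in comps:
        if graph.directed:
            is_cycle = all(v in succ and v in pred for v in comp)
        else:
            is_cycle = all(len(adj[v]) == 2 for v in comp)
        if is_cycle:
            drop = min(e for e in edges if e[0] in comp)
            kept.discard(drop)

    paths = []
    if graph.directed:
        succ = {u: v for u, v in kept}
        pred = {v: u for u, v in kept}
        starts = [v for v in succ if v not in pred]
        for s in sorted(starts):
            p = [s]
            while p[-1] in succ:
                p.append(succ[p[-1]])
            paths.append(tuple(p))
    else:
        nbr: dict = {}
        for u, v in kept:
            nbr.setdefault(u, []).append(v)
            nbr.setdefault(v, []).append(u)
        ends = sorted(v for v, ns in nbr.items() if len(ns) == 1)
        used = set()
        for s in ends:
            if s in used:
                continue
            p = [s]
            used.add(s)
            while True:
                nxt = [x for x in nbr[p[-1]] if x not in used]
                if not nxt:
                    break
                p.append(nxt[0])
                used.add(nxt[0])
            paths.append(tuple(p))

    paths.sort(key=lambda p: p[0])
    total = sum(path_score(p, graph, c) for p in paths)
    return PathSet(paths, total)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def solve_bruteforce(graph: WeightedGraph, c: float):
    """Exact MSPS optimum by exhaustive search over solution edge sets.

    Enumerates every degree-feasible subset of edges (paths and cycles),
    scores it as covered weight minus ``c`` per component, and adds
    ``max(0, w(v) - c)`` for each uncovered vertex as an optional singleton
    path.  Cycles in the best edge set are opened by
    :func:`edges_to_path_set`.  Intended as a test oracle: instances with more
    than ``BRUTEFORCE_EDGE_LIMIT`` edges are rejected.

    Returns ``(score, PathSet)``.
    """
    if c < 0:
        raise GraphError("penalty c must be non-negative")
    if graph.m > BRUTEFORCE_EDGE_LIMIT:
        raise GraphError(
            f"brute force limited to {BRUTEFORCE_EDGE_LIMIT} edges, got {graph.m}")

    edges = graph.sorted_edges()
    weights = graph.weights
    directed = graph.directed
    m = len(edges)
    best_score = 0.0
    best_edges: tuple = ()

    indeg: dict = {v: 0 for v in weights}
    outdeg: dict = {v: 0 for v in weights}
    chosen: list = []

    def evaluate():
        nonlocal best_score, best_edges
        score = solution_edges_score(chosen, graph, c)
        covered = {x for e in chosen for x in e}
        for v in weights:
            if v not in covered:
                score += max(0.0, weights[v] - c)
        if score > best_score + 1e-12:
            best_score = score
            best_edges = tuple(chosen)

    def rec(i: int):
        if i == m:
            evaluate()
            return
        rec(i + 1)  # exclude edge i first: ties keep the smaller solution
        u, v = edges[i]
        if directed:
            ok = outdeg[u] < 1 and indeg[v] < 1
        else:
            ok = (outdeg[u] + indeg[u]) < 2 and (outdeg[v] + indeg[v]) < 2
        if ok:
            outdeg[u] += 1
            indeg[v] += 1
            chosen.append(edges[i])
            rec(i + 1)
            chosen.pop()
            outdeg[u] -= 1
            indeg[v] -= 1

    rec(0)

    ps = edges_to_path_set(best_edges, graph, c)
    covered = ps.covered_vertices()
    extra = [(v,) for v in sorted(graph.weights)
             if v not in covered and graph.weights[v] - c > 0]
    if extra:
        paths = sorted(list(ps.paths) + extra, key=lambda p: p[0])
        total = sum(path_score(p, graph, c) for p in paths)
        ps = PathSet(paths, total)
    return ps.total_score, ps
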