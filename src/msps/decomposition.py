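"""Tree decompositions and the preprocessing pipeline for the treewidth DP.

A tree decomposition of a graph ``G = (V, E)`` is a tree of *bags* (vertex
subsets) such that (1) every vertex lies in some bag, (2) every edge has a
bag containing both endpoints, and (3) the bags containing any fixed vertex
induce a connected subtree.  Its width is the maximum bag size minus one.

Two constructions are provided:

* :func:`from_path_cover` builds a path decomposition of width at most ``k``
  for a DAG whose edges are covered by ``k`` given paths (the arc-width
  bound): sweeping vertices in topological order, the bag of ``v_i`` holds
  ``v_i`` plus, per cover path, the most recent earlier vertex of that path.
* :func:`preprocess` converts a graph and an arbitrary tree decomposition
  into the normal form consumed by the treewidth solver: singleton paths are
  encoded by a pendant zero-weight vertex ``v'`` for every ``v`` with
  ``w(v) >= c``; the tree is rooted and binarized so that every internal bag
  has exactly two children and every leaf is an empty bag; each edge is
  assigned to the unique bag closest to the root that contains both of its
  endpoints; terminals ``T(X) = X ∩ parent(X)`` are precomputed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .graph_core import (
    GraphError,
    PathSet,
    ValidationReport,
    WeightedGraph,
    edges_to_path_set,
    path_score,
)

__all__ = [
    "TreeDecomposition",
    "RootedDecomposition",
    "validate",
    "width",
    "from_path_cover",
    "preprocess",
    "postprocess_solution",
    "single_bag_decomposition",
    "bag_per_edge_decomposition",
]


@dataclass(frozen=True)
class TreeDecomposition:
    """Bags keyed by integer id plus tree edges between bag ids.

    Bag insertion order is preserved; the first bag is the default root for
    :func:`preprocess`.
    """

    bags: Mapping[int, frozenset]
    tree_edges: frozenset

    def __init__(self, bags: Mapping[int, Iterable], tree_edges: Iterable = ()):
        object.__setattr__(self, "bags", {int(i): frozenset(b) for i, b in bags.items()})
        te = set()
        for e in tree_edges:
            i, j = e
            if i == j:
                raise GraphError("tree edge connecting a bag to itself")
            te.add(frozenset((int(i), int(j))))
        object.__setattr__(self, "tree_edges", frozenset(te))

    def neighbors(self, i: int) -> list:
        return sorted(j for e in self.tree_edges for j in e if i in e and j != i)

    def is_tree(self) -> bool:
        ids = list(self.bags)
        if not ids:
            return False
        if len(self.tree_edges) != len(ids) - 1:
            return False
        seen = {ids[0]}
        stack = [ids[0]]
        while stack:
            for j in self.neighbors(stack.pop()):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(ids)


def width(td: TreeDecomposition) -> int:
    """Maximum bag size minus one."""
    if not td.bags:
        raise GraphError("empty decomposition has no width")
    return max(len(b) for b in td.bags.values()) - 1


def validate(td: TreeDecomposition, graph: WeightedGraph) -> ValidationReport:
    """Check the three tree-decomposition conditions of *td* against *graph*."""
    report = ValidationReport()
    if not td.bags:
        report.add("decomposition has no bags")
        return report
    for e in td.tree_edges:
        for i in e:
            if i not in td.bags:
                report.add(f"tree edge {set(e)} references unknown bag {i}")
                return report
    if not td.is_tree():
        report.add("bag graph is not a tree (must be connected and acyclic)")
    covered = set().union(*td.bags.values())
    for v in sorted(graph.vertices - covered):
        report.add(f"vertex {v!r} is in no bag (condition 1)")
    for u, v in graph.sorted_edges():
        if not any(u in b and v in b for b in td.bags.values()):
            report.add(f"edge ({u!r}, {v!r}) has no bag with both endpoints (condition 2)")
    # condition 3: bags containing v induce a connected subtree
    if td.is_tree():
        for v in graph.sorted_vertices():
            holding = [i for i, b in td.bags.items() if v in b]
            if len(holding) <= 1:
                continue
            seen = {holding[0]}
            stack = [holding[0]]
            hold = set(holding)
            while stack:
                for j in td.neighbors(stack.pop()):
                    if j in hold and j not in seen:
                        seen.add(j)
                        stack.append(j)
            if len(seen) != len(holding):
                report.add(f"bags containing {v!r} are disconnected (condition 3)")
    return report


def single_bag_decomposition(graph: WeightedGraph) -> TreeDecomposition:
    """The trivial decomposition: one bag holding every vertex."""
    return TreeDecomposition({1: graph.vertices}, [])


def bag_per_edge_decomposition(graph: WeightedGraph) -> TreeDecomposition:
    """Width-1 decomposition of a tree (or path) graph: one bag per edge.

    The underlying undirected structure must be a connected tree.  Bags of
    the edges incident to each vertex are linked so that condition 3 holds.
    """
    verts = graph.sorted_vertices()
    if graph.m != graph.n - 1:
        raise GraphError("bag-per-edge decomposition requires a tree graph")
    if graph.n == 1:
        return single_bag_decomposition(graph)
    adj: dict = {v: [] for v in verts}
    for u, v in graph.sorted_edges():
        adj[u].append(v)
        adj[v].append(u)
    root = verts[0]
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in sorted(adj[u], reverse=True):
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    if len(order) != graph.n:
        raise GraphError("bag-per-edge decomposition requires a connected tree")
    bags = {}
    rep: dict = {}  # vertex -> id of a bag containing it, used as attachment point
    edges = []
    next_id = 1
    for v in order[1:]:
        p = parent[v]
        bags[next_id] = frozenset((p, v))
        if p in rep:
            edges.append((rep[p], next_id))
        rep.setdefault(p, next_id)
        rep[v] = next_id
        next_id += 1
    return TreeDecomposition(bags, edges)


# ---------------------------------------------------------------------------
# Lemma-1 style construction from a path cover of a DAG
# ---------------------------------------------------------------------------

def _topological_order(graph: WeightedGraph) -> list:
    """Kahn's algorithm with lexicographic tie-breaking; raises on cycles."""
    indeg = {v: 0 for v in graph.weights}
    succ: dict = {v: [] for v in graph.weights}
    for u, v in graph.edges:
        indeg[v] += 1
        succ[u].append(v)
    heap = [v for v, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        u = heapq.heappop(heap)
        order.append(u)
        for v in succ[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, v)
    if len(order) != graph.n:
        raise GraphError("graph contains a cycle; path-cover decomposition needs a DAG")
    return order


def from_path_cover(graph: WeightedGraph, paths: Sequence[Sequence[str]]) -> TreeDecomposition:
    """Path decomposition of a DAG from paths covering all edges and vertices.

    With ``k`` cover paths every bag has at most ``k + 1`` vertices, so the
    result has width at most ``k``.  Bags are chained in topological order.
    """
    if not graph.directed:
        raise GraphError("path-cover decomposition is defined for directed graphs")
    paths = [tuple(p) for p in paths]
    covered_v = {v for p in paths for v in p}
    missing = graph.vertices - covered_v
    if missing:
        raise GraphError(f"cover paths miss vertices {sorted(missing)}")
    covered_e = {(u, v) for p in paths for u, v in zip(p, p[1:])}
    for e in covered_e - set(graph.edges):
        raise GraphError(f"cover path step {e!r} is not a graph edge")
    for e in sorted(set(graph.edges) - covered_e):
        raise GraphError(f"edge {e!r} is not covered by any path")

    order = _topological_order(graph)
    pos = {v: i for i, v in enumerate(order)}
    for p in paths:
        for u, v in zip(p, p[1:]):
            if pos[u] >= pos[v]:
                raise GraphError(f"cover path step {(u, v)!r} violates topological order")

    last: list = [None] * len(paths)  # most recent vertex of each path seen so far
    bags = {}
    for i, v in enumerate(order, start=1):
        bag = {v}
        for j, p in enumerate(paths):
            if last[j] is not None:
                bag.add(last[j])
        bags[i] = frozenset(bag)
        for j, p in enumerate(paths):
            if v in p:
                last[j] = v
    edges = [(i, i + 1) for i in range(1, len(order))]
    return TreeDecomposition(bags, edges)


# ---------------------------------------------------------------------------
# Rooted, binarized decomposition with terminals and edge assignment
# ---------------------------------------------------------------------------

@dataclass
class RootedDecomposition:
    """Normal form consumed by the treewidth solver.

    Every internal bag has exactly two children (``left``, ``right``), every
    leaf bag is empty, each graph edge is assigned to exactly one bag
    containing both endpoints, and ``terminals[i] = bags[i] ∩ bags[parent]``
    (empty at the root).  ``aux_map`` sends each pendant auxiliary vertex
    ``v'`` added by :func:`preprocess` back to its original vertex ``v``.
    """

    graph: WeightedGraph
    bags: dict
    root: int
    children: dict
    parent: dict
    terminals: dict
    edge_assignment: dict
    aux_map: dict = field(default_factory=dict)

    def postorder(self) -> list:
        out = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for ch in reversed(self.children.get(node, ())):
                    stack.append((ch, False))
        return out

    def as_tree_decomposition(self) -> TreeDecomposition:
        edges = [(p, i) for i, p in self.parent.items()]
        return TreeDecomposition(self.bags, edges)

    def check(self) -> ValidationReport:
        """Verify the normal-form invariants (used by tests)."""
        report = ValidationReport()
        for i, b in self.bags.items():
            ch = self.children.get(i, ())
            if b and len(ch) != 2:
                report.add(f"nonempty bag {i} has {len(ch)} children")
            if not ch and b:
                report.add(f"leaf bag {i} is not empty")
        assigned: dict = {}
        for i, edges in self.edge_assignment.items():
            for e in edges:
                if e in assigned:
                    report.add(f"edge {e!r} assigned to bags {assigned[e]} and {i}")
                assigned[e] = i
                u, v = e
                if u not in self.bags[i] or v not in self.bags[i]:
                    report.add(f"edge {e!r} assigned to bag {i} missing an endpoint")
        for e in self.graph.edges:
            if e not in assigned:
                report.add(f"edge {e!r} not assigned to any bag")
        if self.terminals[self.root]:
            report.add("root bag has terminals")
        for i, p in self.parent.items():
            if self.terminals[i] != self.bags[i] & self.bags[p]:
                report.add(f"terminals of bag {i} are not X ∩ parent(X)")
        return report


def _aux_name(v: str, taken: set) -> str:
    name = v + "'"
    while name in taken:
        name += "'"
    return name


def preprocess(graph: WeightedGraph, td: TreeDecomposition, c: float,
               root: int | None = None):
    """Normalize *graph* and *td* for the treewidth DP.

    Returns ``(preprocessed_graph, RootedDecomposition)``.  The preprocessed
    problem allows cycles and forbids trivial one-vertex paths; a pendant
    zero-weight vertex ``v'`` with edge ``(v, v')`` stands in for the
    singleton path ``(v)`` whenever ``w(v) >= c`` makes that path worth
    considering.  See :func:`postprocess_solution` for the way back.
    """
    if c < 0:
        raise GraphError("penalty c must be non-negative")
    report = validate(td, graph)
    if not report.ok:
        raise GraphError(f"invalid tree decomposition: {report}")

    bags = {i: set(b) for i, b in td.bags.items()}
    adjacency: dict = {i: set() for i in bags}
    for e in td.tree_edges:
        i, j = tuple(e)
        adjacency[i].add(j)
        adjacency[j].add(i)

    if root is None:
        root = next(iter(bags))
    if root not in bags:
        raise GraphError(f"root bag {root} does not exist")

    # orient the tree away from the chosen root
    parent: dict = {}
    children: dict = {i: [] for i in bags}
    depth = {root: 0}
    stack = [root]
    seen = {root}
    while stack:
        u = stack.pop()
        for v in sorted(adjacency[u]):
            if v not in seen:
                seen.add(v)
                parent[v] = u
                depth[v] = depth[u] + 1
                children[u].append(v)
                stack.append(v)

    next_id = max(bags) + 1

    # (a) pendant auxiliary vertices for every v with w(v) >= c,
    # attached as a leaf bag {v, v'} below the root-most bag containing v
    taken = set(graph.weights)
    aux_map: dict = {}
    new_weights: dict = {}
    new_edges: list = []
    rootmost: dict = {}
    for i in sorted(bags, key=lambda i: (depth[i], i)):
        for v in bags[i]:
            rootmost.setdefault(v, i)
    for v in graph.sorted_vertices():
        if graph.weights[v] >= c:
            a = _aux_name(v, taken)
            taken.add(a)
            aux_map[a] = v
            new_weights[a] = 0.0
            new_edges.append((v, a))
            host = rootmost[v]
            bags[next_id] = {v, a}
            children[next_id] = []
            parent[next_id] = host
            depth[next_id] = depth[host] + 1
            children[host].append(next_id)
            next_id += 1
    pgraph = graph.with_added(new_weights, new_edges)

    # (b) binarize: a bag with more than two children becomes a left-leaning
    # chain of duplicates, each taking over one original child
    for i in list(bags):
        ch = children[i]
        node = i
        while len(ch) > 2:
            dup = next_id
            next_id += 1
            bags[dup] = set(bags[node])
            keep = ch[0]
            rest = ch[1:]
            children[node] = [dup, keep]
            parent[keep] = node
            parent[dup] = node
            depth[dup] = depth[node] + 1
            children[dup] = rest
            for r in rest:
                parent[r] = dup
            # depths below shift; recompute lazily afterwards
            node = dup
            ch = children[node]

    # recompute depths after binarization
    depth = {root: 0}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in children[u]:
            depth[v] = depth[u] + 1
            stack.append(v)

    # (c) empty leaves so that every nonempty bag has exactly two children
    for i in list(bags):
        need = 0
        if len(children[i]) == 1:
            need = 1
        elif len(children[i]) == 0 and bags[i]:
            need = 2
        for _ in range(need):
            leaf = next_id
            next_id += 1
            bags[leaf] = set()
            children[leaf] = []
            parent[leaf] = i
            depth[leaf] = depth[i] + 1
            children[i].append(leaf)

    # (d) assign each edge to the bag closest to the root containing both ends
    edge_assignment: dict = {i: [] for i in bags}
    for e in pgraph.sorted_edges():
        u, v = e
        candidates = [i for i, b in bags.items() if u in b and v in b]
        host = min(candidates, key=lambda i: (depth[i], i))
        edge_assignment[host].append(e)

    terminals = {i: frozenset() if i == root else frozenset(bags[i] & bags[parent[i]])
                 for i in bags}

    rd = RootedDecomposition(
        graph=pgraph,
        bags={i: frozenset(b) for i, b in bags.items()},
        root=root,
        children={i: tuple(ch) for i, ch in children.items()},
        parent=parent,
        terminals=terminals,
        edge_assignment={i: tuple(es) for i, es in edge_assignment.items()},
        aux_map=aux_map,
    )
    return pgraph, rd


def postprocess_solution(sel: Iterable, rd: RootedDecomposition,
                         graph: WeightedGraph, c: float) -> PathSet:
    """Convert a solution edge set on the preprocessed graph back to a
    :class:`PathSet` on the original graph.

    Cycles are opened by :func:`~msps.graph_core.edges_to_path_set`; each
    pendant edge ``(v, v')`` collapses to the singleton path ``(v)``.  The
    total score is unchanged.
    """
    aux = set(rd.aux_map)
    plain = []
    singles = set()
    aux_partner: dict = {}
    for e in sel:
        u, v = e
        a = u if u in aux else (v if v in aux else None)
        if a is None:
            plain.append(e)
        else:
            o = v if a == u else u
            if a in aux_partner:
                raise GraphError(f"auxiliary vertex {a!r} incident to several edges")
            if o != rd.aux_map[a]:
                raise GraphError(f"auxiliary vertex {a!r} joined to unexpected vertex {o!r}")
            aux_partner[a] = o
            singles.add(o)
    ps = edges_to_path_set(plain, graph, c)
    singles -= ps.covered_vertices()
    paths = sorted(list(ps.paths) + [(v,) for v in singles], key=lambda p: p[0])
    total = sum(path_score(p, graph, c) for p in paths)
    return PathSet(paths, total)
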