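"""Seeded random instance generators.

Every solver in the package is exercised on synthetic instances; these
generators produce them reproducibly from an integer seed.  Weights are
integers drawn uniformly from a small symmetric range (default [-3, 3]),
which mimics per-position log-odds-style scores where roughly half the
positions are "interesting": the optimum then balances extending paths
against paying the startup penalty, exercising every branch of the DPs.

Kinds
-----
``path``
    A chain of ``n`` weighted vertices (the classic segment-set setting).
``tree``
    A random tree plus its width-1 bag-per-edge decomposition.
``ttsp``
    A random series/parallel composition with a given number of edge
    leaves, mirroring pangenome graphs built from elastic degenerate
    strings.
``dag_from_paths``
    A DAG merged from ``k`` vertex sequences over a shared vertex pool —
    the shape of a pangenome DAG built from a multiple sequence alignment
    of ``k`` sequences — returned together with the covering paths.
``generic``
    An Erdős–Rényi-style graph with given vertex and edge counts.
"""

from __future__ import annotations

import random

from .decomposition import bag_per_edge_decomposition
from .graph_core import GraphError, WeightedGraph
from .ttsp import TTSPGraph, ttsp_from_composition

__all__ = [
    "random_path_instance",
    "random_tree_instance",
    "random_ttsp_instance",
    "random_dag_from_paths",
    "random_generic_instance",
    "generate_random_instance",
]


def _weights(rng: random.Random, vertices, weight_range) -> dict:
    lo, hi = weight_range
    return {v: float(rng.randint(lo, hi)) for v in sorted(vertices)}


def _names(n: int) -> list:
    pad = len(str(max(n - 1, 0)))
    return [f"v{i:0{pad}d}" for i in range(n)]


def random_path_instance(n: int, seed: int, directed: bool = True,
                         weight_range=(-3, 3)) -> WeightedGraph:
    """A path graph of ``n`` vertices in lexicographic chain order."""
    if n < 1:
        raise GraphError("path instance needs n >= 1")
    rng = random.Random(seed)
    verts = _names(n)
    edges = list(zip(verts, verts[1:]))
    return WeightedGraph(directed, _weights(rng, verts, weight_range), edges)


def random_tree_instance(n: int, seed: int, directed: bool = True,
                         weight_range=(-3, 3)):
    """A random tree (each vertex attaches to a random earlier vertex) and
    its bag-per-edge decomposition of width 1.  Directed edges point away
    from the root."""
    if n < 2:
        raise GraphError("tree instance needs n >= 2")
    rng = random.Random(seed)
    verts = _names(n)
    edges = [(verts[rng.randrange(i)], verts[i]) for i in range(1, n)]
    graph = WeightedGraph(directed, _weights(rng, verts, weight_range), edges)
    return graph, bag_per_edge_decomposition(graph)


def _random_composition(rng: random.Random, leaves: int):
    if leaves == 1:
        return ("e",)
    split = rng.randint(1, leaves - 1)
    kind = rng.choice(("S", "P"))
    return (kind, _random_composition(rng, split),
            _random_composition(rng, leaves - split))


def random_ttsp_instance(leaf_edges: int, seed: int,
                         weight_range=(-3, 3)) -> TTSPGraph:
    """A uniformly random series/parallel composition with the given number
    of edge leaves, with random integer vertex weights."""
    if leaf_edges < 1:
        raise GraphError("ttsp instance needs at least one leaf edge")
    rng = random.Random(seed)
    spec = _random_composition(rng, leaf_edges)
    lo, hi = weight_range
    return ttsp_from_composition(spec, weight_fn=lambda v: float(rng.randint(lo, hi)))


def random_dag_from_paths(n: int, k: int, seed: int,
                          weight_range=(-3, 3)):
    """A DAG covered by ``k`` paths over a pool of ``n`` vertices.

    A random total order on the pool guarantees acyclicity; each path is an
    increasing random subsequence, and vertices missed by every path are
    inserted into one of them, so the paths cover all vertices and (by
    construction) all edges.  Returns ``(graph, cover_paths)``.
    """
    if n < 1 or k < 1:
        raise GraphError("dag_from_paths needs n >= 1 and k >= 1")
    rng = random.Random(seed)
    pool = _names(n)
    order = pool[:]
    rng.shuffle(order)
    rank = {v: i for i, v in enumerate(order)}
    paths = []
    for _ in range(k):
        size = rng.randint(1, n)
        sub = sorted(rng.sample(pool, size), key=rank.get)
        paths.append(sub)
    missing = set(pool) - {v for p in paths for v in p}
    for v in sorted(missing):
        p = paths[rng.randrange(k)]
        p.append(v)
        p.sort(key=rank.get)
    edges = {(u, v) for p in paths for u, v in zip(p, p[1:])}
    graph = WeightedGraph(True, _weights(rng, pool, weight_range), edges)
    return graph, [tuple(p) for p in paths]


def random_generic_instance(n: int, m: int, seed: int, directed: bool = True,
                            weight_range=(-3, 3)) -> WeightedGraph:
    """An Erdős–Rényi-style graph with ``n`` vertices and ``m`` edges."""
    if n < 1 or m < 0:
        raise GraphError("generic instance needs n >= 1 and m >= 0")
    max_m = n * (n - 1) if directed else n * (n - 1) // 2
    if m > max_m:
        raise GraphError(f"at most {max_m} edges possible, asked for {m}")
    rng = random.Random(seed)
    verts = _names(n)
    if directed:
        universe = [(u, v) for u in verts for v in verts if u != v]
    else:
        universe = [(u, v) for i, u in enumerate(verts) for v in verts[i + 1:]]
    edges = rng.sample(universe, m)
    return WeightedGraph(directed, _weights(rng, verts, weight_range), edges)


def generate_random_instance(kind: str, seed: int, **params):
    """Dispatching front end over the specific generators above."""
    table = {
        "path": random_path_instance,
        "tree": random_tree_instance,
        "ttsp": random_ttsp_instance,
        "dag_from_paths": random_dag_from_paths,
        "generic": random_generic_instance,
    }
    if kind not in table:
        raise GraphError(f"unknown instance kind {kind!r}")
    return table[kind](seed=seed, **params)
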