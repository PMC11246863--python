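"""Independent oracles used to double-check the solvers.

These deliberately avoid the package's solution machinery: the partition
oracle enumerates vertex-disjoint path sets directly (no edge-subset
reformulation, no cycle handling), and the Hamiltonian check enumerates
vertex permutations.
"""

from __future__ import annotations

import itertools

from msps.graph_core import WeightedGraph


def _adjacency(graph: WeightedGraph):
    succ = {v: [] for v in graph.weights}
    pred = {v: [] for v in graph.weights}
    for u, v in graph.edges:
        succ[u].append(v)
        pred[v].append(u)
        if not graph.directed:
            succ[v].append(u)
            pred[u].append(v)
    return succ, pred


def score_by_path_partition(graph: WeightedGraph, c: float) -> float:
    """Exact MSPS optimum by enumerating vertex-disjoint simple path sets.

    Recursion on the set of unassigned vertices: the smallest one is either
    left unused or placed on some simple path (enumerated by extending
    backward and forward within the unassigned set).
    """
    succ, pred = _adjacency(graph)
    weights = graph.weights

    def paths_through(v, allowed):
        def extend(path, nbrs):
            yield path
            for u in nbrs[path[-1]]:
                if u in allowed and u not in path:
                    yield from extend(path + (u,), nbrs)

        for back in extend((v,), pred):
            blocked = set(back)
            for fwd in extend((v,), succ):
                if blocked.intersection(fwd) - {v}:
                    continue
                yield tuple(reversed(back))[:-1] + fwd

    def best(remaining: frozenset) -> float:
        if not remaining:
            return 0.0
        v = min(remaining)
        result = best(remaining - {v})  # v unused
        for p in paths_through(v, remaining):
            score = -c + sum(weights[x] for x in p)
            result = max(result, score + best(remaining - set(p)))
        return result

    return best(frozenset(weights))


def has_hamiltonian_path(graph: WeightedGraph) -> bool:
    """Permutation-based Hamiltonian path check (independent of any solver)."""
    verts = sorted(graph.weights)
    for perm in itertools.permutations(verts):
        if all(graph.has_edge(u, v) for u, v in zip(perm, perm[1:])):
            return True
    return False


def best_segment_sets(weights, c: float) -> float:
    """Brute force over all disjoint segment sets of a weight sequence."""
    n = len(weights)
    best = 0.0

    def rec(i, acc):
        nonlocal best
        best = max(best, acc)
        for a in range(i, n):
            for b in range(a + 1, n + 1):
                # segments may touch: disjointness is on vertices only
                rec(b, acc - c + sum(weights[a:b]))

    rec(0, 0.0)
    return best
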