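"""File formats: PACE-style graphs (.gr) and tree decompositions (.td),
weight tables, path-cover files and solution output.

The PACE dialects are the community standard for treewidth tooling.  A .gr
file has a header ``p tw <n> <m>`` followed by one edge per line; a .td
file has ``s td <bags> <width+1> <n>``, ``b <id> <vertices...>`` lines and
bag-edge lines.  Both use integer vertex ids, so named vertices travel in a
sidecar TSV (``<int> <name>`` per line); without a sidecar the integers
themselves are the names.  Comment lines starting with ``c`` are allowed
everywhere.  Vertex weights live in a separate two-column table because the
PACE formats carry none.  Weights are printed with ``repr`` so that
write/read round-trips are exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .decomposition import TreeDecomposition, width as td_width
from .graph_core import GraphError, PathSet, WeightedGraph

__all__ = [
    "read_names", "write_names",
    "read_weights", "write_weights",
    "read_graph", "write_graph",
    "read_td", "write_td",
    "read_cover", "write_cover",
    "read_solution", "write_solution",
]

log = logging.getLogger("msps")


class FormatError(GraphError):
    """Malformed input file."""


def _lines(path) -> list:
    return Path(path).read_text().splitlines()


def read_names(path) -> dict:
    """Sidecar table mapping integer ids to vertex names."""
    names = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip() or line.startswith("c"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected '<int> <name>'")
        names[int(parts[0])] = parts[1]
    return names


def write_names(names: Mapping[int, str], path) -> None:
    Path(path).write_text("".join(f"{i}\t{names[i]}\n" for i in sorted(names)))


def read_weights(path) -> dict:
    """Two-column table ``<key> <value>`` (vertex weights or character scores)."""
    weights = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip() or line.startswith("c "):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected '<key> <value>'")
        weights[parts[0]] = float(parts[1])
    return weights


def write_weights(weights: Mapping[str, float], path) -> None:
    Path(path).write_text(
        "".join(f"{v}\t{weights[v]!r}\n" for v in sorted(weights)))


def read_graph(path, weights_path=None, directed: bool = False,
               names_path=None) -> WeightedGraph:
    """Read a PACE-style .gr edge list plus an optional weight table.

    Vertices missing from the weight table default to weight 0 with a
    warning; duplicate edge lines collapse with a warning; self-loops are
    rejected.
    """
    names = read_names(names_path) if names_path else {}
    header = None
    edges = []
    declared = set()
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip() or line.startswith("c"):
            continue
        parts = line.split()
        if parts[0] == "p":
            if len(parts) != 4 or parts[1] != "tw":
                raise FormatError(f"{path}:{lineno}: malformed header, expected 'p tw n m'")
            header = (int(parts[2]), int(parts[3]))
            declared = {names.get(i, str(i)) for i in range(1, header[0] + 1)}
            continue
        if header is None:
            raise FormatError(f"{path}:{lineno}: edge line before 'p tw' header")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected '<u> <v>'")
        u, v = (names.get(int(x), str(int(x))) for x in parts)
        for name, raw in ((u, parts[0]), (v, parts[1])):
            if name not in declared:
                raise FormatError(
                    f"{path}:{lineno}: edge uses undeclared vertex {raw}")
        if u == v:
            raise FormatError(f"{path}:{lineno}: self-loop at {u}")
        edges.append((u, v))
    if header is None:
        raise FormatError(f"{path}: missing 'p tw' header")

    weights = {v: 0.0 for v in declared}
    if weights_path is not None:
        table = read_weights(weights_path)
        for v in table:
            if v not in declared:
                raise FormatError(f"{weights_path}: weight for unknown vertex {v}")
        missing = sorted(declared - set(table))
        if missing:
            log.warning("vertices %s have no weight; defaulting to 0", missing)
        weights.update(table)

    graph = WeightedGraph(directed, weights, edges)
    if graph.m < len(edges):
        log.warning("%s: %d duplicate edge line(s) collapsed", path,
                    len(edges) - graph.m)
    return graph


def write_graph(graph: WeightedGraph, path, weights_path=None,
                names_path=None) -> None:
    verts = graph.sorted_vertices()
    ids = {v: i for i, v in enumerate(verts, start=1)}
    out = [f"p tw {graph.n} {graph.m}"]
    for u, v in graph.sorted_edges():
        out.append(f"{ids[u]} {ids[v]}")
    Path(path).write_text("\n".join(out) + "\n")
    if names_path is not None:
        write_names({i: v for v, i in ids.items()}, names_path)
    if weights_path is not None:
        write_weights(graph.weights, weights_path)


def read_td(path, names_path=None) -> TreeDecomposition:
    names = read_names(names_path) if names_path else {}
    bags = {}
    edges = []
    header = None
    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip() or line.startswith("c"):
            continue
        parts = line.split()
        if parts[0] == "s":
            if len(parts) != 5 or parts[1] != "td":
                raise FormatError(f"{path}:{lineno}: malformed 's td' header")
            header = tuple(int(x) for x in parts[2:])
            continue
        if parts[0] == "b":
            bags[int(parts[1])] = frozenset(
                names.get(int(x), str(int(x))) for x in parts[2:])
            continue
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected bag-edge line '<i> <j>'")
        edges.append((int(parts[0]), int(parts[1])))
    if header is None:
        raise FormatError(f"{path}: missing 's td' header")
    return TreeDecomposition(bags, edges)


def write_td(td: TreeDecomposition, path, names_path=None,
             names: Optional[Mapping[str, int]] = None) -> None:
    verts = sorted(set().union(*td.bags.values())) if td.bags else []
    ids = dict(names) if names else {v: i for i, v in enumerate(verts, start=1)}
    out = [f"s td {len(td.bags)} {td_width(td) + 1} {len(verts)}"]
    for i in td.bags:
        out.append("b " + " ".join([str(i)] + [str(ids[v]) for v in sorted(td.bags[i])]))
    for e in sorted(tuple(sorted(x)) for x in td.tree_edges):
        out.append(f"{e[0]} {e[1]}")
    Path(path).write_text("\n".join(out) + "\n")
    if names_path is not None:
        write_names({i: v for v, i in ids.items()}, names_path)


def read_cover(path) -> list:
    """Path-cover file: one whitespace-separated vertex sequence per line."""
    paths = []
    for line in _lines(path):
        if not line.strip() or line.startswith("c "):
            continue
        paths.append(tuple(line.split()))
    return paths


def write_cover(paths: Sequence[Sequence[str]], path) -> None:
    Path(path).write_text("".join(" ".join(p) + "\n" for p in paths))


def write_solution(ps: PathSet, path, format: str = "tsv",
                   graph: Optional[WeightedGraph] = None, c: float = 0.0) -> None:
    """Write a solution as TSV (one path per row) or JSON.

    Per-path scores are filled in when *graph* (and *c*) are given,
    otherwise the score column holds ``-``; vertices and the total score
    round-trip either way.
    """
    from .graph_core import path_score

    def score_of(p):
        return repr(path_score(p, graph, c)) if graph is not None else "-"

    if format == "json":
        payload = {
            "score": ps.total_score,
            "paths": [{"vertices": list(p),
                       "score": (path_score(p, graph, c) if graph is not None else None)}
                      for p in ps.paths],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")
        return
    if format != "tsv":
        raise FormatError(f"unknown solution format {format!r}")
    lines = [f"# total_score\t{ps.total_score!r}"]
    for i, p in enumerate(ps.paths, start=1):
        lines.append("\t".join([str(i), score_of(p)] + list(p)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_solution(path, format: str = "tsv") -> PathSet:
    if format == "json":
        payload = json.loads(Path(path).read_text())
        return PathSet([p["vertices"] for p in payload["paths"]], payload["score"])
    lines = _lines(path)
    if not lines or not lines[0].startswith("# total_score\t"):
        raise FormatError(f"{path}: missing total_score header")
    total = float(lines[0].split("\t")[1])
    paths = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        paths.append(tuple(parts[2:]))
    return PathSet(paths, total)
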