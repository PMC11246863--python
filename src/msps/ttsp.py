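"""Two-terminal series-parallel (TTSP) directed graphs and their MSPS solver.

A single edge ``(s, t)`` is a TTSP graph with terminals ``s`` and ``t``.
Two TTSP graphs combine in *series* (identifying ``t1`` with ``s2``) or in
*parallel* (identifying both terminal pairs).  Every TTSP graph carries a
binary decomposition tree whose leaves are edges and whose internal nodes
are series/parallel compositions; the *modules* of the graph.  TTSP graphs
are acyclic, have treewidth at most 2, and arise naturally from
elastic-degenerate strings (EDS): each alternative of each degenerate
symbol becomes a chain of one-character vertices strung between shared
zero-weight ε-vertices, alternatives compose in parallel, and consecutive
symbols compose in series.

The solver (:func:`solve_ttsp_directed`) keeps four table entries per
module — is the source used, is the target used — and combines children in
one pass over the decomposition tree, giving linear time in the number of
edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Optional, Union

from .graph_core import (
    GraphError,
    PathSet,
    WeightedGraph,
    edges_to_path_set,
    path_score,
)
from .decomposition import TreeDecomposition

__all__ = [
    "TTSPNode",
    "TTSPGraph",
    "EDS",
    "ParseError",
    "parse_eds",
    "eds_to_ttsp",
    "parse_composition",
    "ttsp_from_composition",
    "with_weights",
    "solve_ttsp_directed",
    "ttsp_to_tree_decomposition",
]

EDGE, SERIES, PARALLEL = "edge", "series", "parallel"


@dataclass(frozen=True, eq=False)
class TTSPNode:
    """One module of a TTSP decomposition tree.

    ``kind`` is ``edge``, ``series`` or ``parallel``; ``s``/``t`` are the
    module's terminals.  A series node merges ``left.t`` with ``right.s``
    (the internal vertex), a parallel node shares both terminals with its
    children.  Node identity (not structure) is used as the dictionary key
    in the solver, so equal subtrees stay distinct.
    """

    kind: str
    s: str
    t: str
    left: Optional["TTSPNode"] = None
    right: Optional["TTSPNode"] = None

    def __post_init__(self):
        if self.kind == EDGE:
            if self.s == self.t:
                raise GraphError("TTSP edge module needs distinct terminals")
            if self.left is not None or self.right is not None:
                raise GraphError("edge module cannot have children")
        elif self.kind == SERIES:
            if self.left is None or self.right is None:
                raise GraphError("series module needs two children")
            if self.left.t != self.right.s:
                raise GraphError("series children must share the internal vertex")
            if (self.s, self.t) != (self.left.s, self.right.t):
                raise GraphError("series terminals must be (left.s, right.t)")
        elif self.kind == PARALLEL:
            if self.left is None or self.right is None:
                raise GraphError("parallel module needs two children")
            for ch in (self.left, self.right):
                if (ch.s, ch.t) != (self.s, self.t):
                    raise GraphError("parallel children must share both terminals")
        else:
            raise GraphError(f"unknown module kind {self.kind!r}")

    @property
    def mid(self) -> str:
        """Internal vertex of a series composition."""
        if self.kind != SERIES:
            raise GraphError("only series modules have an internal vertex")
        return self.left.t

    def postorder(self) -> Iterator["TTSPNode"]:
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                if node.right is not None:
                    stack.append((node.right, False))
                if node.left is not None:
                    stack.append((node.left, False))

    def preorder(self) -> Iterator["TTSPNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            if node.right is not None:
                stack.append(node.right)
            if node.left is not None:
                stack.append(node.left)

    def leaf_edges(self) -> set:
        return {(n.s, n.t) for n in self.postorder() if n.kind == EDGE}


@dataclass(frozen=True)
class TTSPGraph:
    """A weighted directed TTSP graph together with its decomposition tree.

    Parallel composition can create duplicate edges; they are collapsed in
    the graph (multiplicity never changes the optimum) while the tree keeps
    one leaf per composition step.
    """

    graph: WeightedGraph
    root: TTSPNode

    def __post_init__(self):
        if not self.graph.directed:
            raise GraphError("TTSPGraph is directed")
        if self.root.leaf_edges() != set(self.graph.edges):
            raise GraphError("decomposition tree edges do not match the graph")


def series(a: TTSPNode, b: TTSPNode) -> TTSPNode:
    return TTSPNode(SERIES, a.s, b.t, a, b)


def parallel(a: TTSPNode, b: TTSPNode) -> TTSPNode:
    return TTSPNode(PARALLEL, a.s, a.t, a, b)


# ---------------------------------------------------------------------------
# elastic-degenerate strings
# ---------------------------------------------------------------------------

#: an alternative inside a degenerate symbol: plain string or nested EDS
Alternative = Union[str, "EDS"]


@dataclass(frozen=True)
class EDS:
    """Parsed elastic-degenerate string.

    ``symbols`` is a tuple whose elements are either a literal string (one
    maximal run of plain characters) or a tuple of distinct alternatives,
    each a string (possibly empty) or a nested :class:`EDS`.
    """

    symbols: tuple

    def __post_init__(self):
        if not self.symbols:
            raise GraphError("EDS needs at least one symbol")


class ParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


_SPECIAL = set("{},")


def parse_eds(text: str) -> EDS:
    """Parse the textual EDS dialect.

    Literal runs stand for themselves; ``{alt1,alt2,...}`` is a degenerate
    symbol whose alternatives may be empty (``{A,}``) or nested generalized
    EDSs (``{C{G,T},A}``).  Whitespace is ignored everywhere.
    """
    pos = 0

    def skip_ws():
        nonlocal pos
        while pos < len(text) and text[pos].isspace():
            pos += 1

    def parse_sequence(depth: int) -> list:
        nonlocal pos
        symbols: list = []
        while True:
            skip_ws()
            if pos >= len(text):
                break
            ch = text[pos]
            if ch == "{":
                open_pos = pos
                pos += 1
                alts: list = []
                while True:
                    inner = parse_sequence(depth + 1)
                    if not inner:
                        alts.append("")
                    elif len(inner) == 1 and isinstance(inner[0], str):
                        alts.append(inner[0])
                    else:
                        alts.append(EDS(tuple(inner)))
                    skip_ws()
                    if pos >= len(text):
                        raise ParseError("unbalanced '{'", open_pos)
                    if text[pos] == ",":
                        pos += 1
                        continue
                    if text[pos] == "}":
                        pos += 1
                        break
                    raise ParseError(f"unexpected character {text[pos]!r}", pos)
                if alts == [""]:
                    raise ParseError("empty symbol set", open_pos)
                if len(set(alts)) != len(alts):
                    raise ParseError("duplicate alternatives in symbol", open_pos)
                symbols.append(tuple(alts))
            elif ch == "}" or ch == ",":
                if depth == 0:
                    raise ParseError(f"unexpected character {ch!r}", pos)
                break
            else:
                start = pos
                while (pos < len(text) and text[pos] not in _SPECIAL
                       and not text[pos].isspace()):
                    pos += 1
                symbols.append(text[start:pos])
        return symbols

    symbols = parse_sequence(0)
    if pos < len(text):
        raise ParseError(f"unexpected character {text[pos]!r}", pos)
    if not symbols:
        raise ParseError("empty EDS", 0)
    return EDS(tuple(symbols))


def eds_to_ttsp(eds: EDS, char_weight: Mapping[str, float]) -> TTSPGraph:
    """Convert an EDS to its weighted TTSP graph.

    A zero-weight ε-vertex sits before the first symbol, between every pair
    of consecutive symbols, and after the last symbol; these are shared by
    all alternatives.  Each alternative becomes a series chain of
    one-character vertices between its flanking ε-vertices (an empty
    alternative becomes a direct edge), alternatives of one symbol compose
    in parallel, and symbols compose in series.  Nested EDSs apply the same
    flanking rule recursively, reusing the outer ε-vertices as their ends.
    """
    weights: dict = {}
    counter = [0]

    def fresh_aux() -> str:
        name = f"$e{counter[0]}"
        counter[0] += 1
        weights[name] = 0.0
        return name

    def fresh_char(ch: str) -> str:
        if ch not in char_weight:
            raise GraphError(f"no weight given for character {ch!r}")
        name = f"{counter[0]}:{ch}"
        counter[0] += 1
        weights[name] = float(char_weight[ch])
        return name

    def build_string(s: str, a: str, b: str) -> TTSPNode:
        inner = [fresh_char(ch) for ch in s]
        chain = [a] + inner + [b]
        node = TTSPNode(EDGE, chain[0], chain[1])
        for u, v in zip(chain[1:], chain[2:]):
            node = series(node, TTSPNode(EDGE, u, v))
        return node

    def build_alternative(alt: Alternative, a: str, b: str) -> TTSPNode:
        if isinstance(alt, EDS):
            return build_eds(alt, a, b)
        return build_string(alt, a, b)

    def build_symbol(symbol, a: str, b: str) -> TTSPNode:
        if isinstance(symbol, str):
            return build_string(symbol, a, b)
        node = build_alternative(symbol[0], a, b)
        for alt in symbol[1:]:
            node = parallel(node, build_alternative(alt, a, b))
        return node

    def build_eds(e: EDS, a: str, b: str) -> TTSPNode:
        cuts = [a] + [fresh_aux() for _ in e.symbols[1:]] + [b]
        node = build_symbol(e.symbols[0], cuts[0], cuts[1])
        for sym, u, v in zip(e.symbols[1:], cuts[1:], cuts[2:]):
            node = series(node, build_symbol(sym, u, v))
        return node

    source = fresh_aux()
    sink = fresh_aux()
    root = build_eds(eds, source, sink)
    graph = WeightedGraph(True, weights, root.leaf_edges())
    return TTSPGraph(graph, root)


# ---------------------------------------------------------------------------
# composition scripts: nested expressions over "e", "S(x,y)", "P(x,y)"
# ---------------------------------------------------------------------------

CompositionSpec = tuple  # ("e",) | ("S", spec, spec) | ("P", spec, spec)


def parse_composition(text: str) -> CompositionSpec:
    """Parse a composition-script expression like ``S(e, P(e, e))``."""
    pos = 0

    def skip_ws():
        nonlocal pos
        while pos < len(text) and text[pos].isspace():
            pos += 1

    def expr() -> CompositionSpec:
        nonlocal pos
        skip_ws()
        if pos >= len(text):
            raise ParseError("unexpected end of composition script", pos)
        ch = text[pos]
        if ch in "eE":
            pos += 1
            return ("e",)
        if ch in "SsPp":
            kind = ch.upper()
            pos += 1
            skip_ws()
            if pos >= len(text) or text[pos] != "(":
                raise ParseError(f"expected '(' after {kind}", pos)
            pos += 1
            a = expr()
            skip_ws()
            if pos >= len(text) or text[pos] != ",":
                raise ParseError("expected ','", pos)
            pos += 1
            b = expr()
            skip_ws()
            if pos >= len(text) or text[pos] != ")":
                raise ParseError("expected ')'", pos)
            pos += 1
            return (kind, a, b)
        raise ParseError(f"unexpected character {ch!r}", pos)

    result = expr()
    skip_ws()
    if pos < len(text):
        raise ParseError(f"unexpected character {text[pos]!r}", pos)
    return result


def ttsp_from_composition(spec: CompositionSpec,
                          weight_fn: Optional[Callable[[str], float]] = None
                          ) -> TTSPGraph:
    """Materialize a composition spec, naming vertices ``v0, v1, ...``
    top-down.  ``weight_fn`` maps a vertex name to its weight (default 0)."""
    counter = [0]
    edges: set = set()
    vertices: list = []

    def fresh() -> str:
        name = f"v{counter[0]}"
        counter[0] += 1
        vertices.append(name)
        return name

    def build(node: CompositionSpec, s: str, t: str) -> TTSPNode:
        if node[0] == "e":
            edges.add((s, t))
            return TTSPNode(EDGE, s, t)
        _, a, b = node
        if node[0] == "S":
            m = fresh()
            return TTSPNode(SERIES, s, t, build(a, s, m), build(b, m, t))
        return TTSPNode(PARALLEL, s, t, build(a, s, t), build(b, s, t))

    s, t = fresh(), fresh()
    root = build(spec, s, t)
    weights = {v: (weight_fn(v) if weight_fn else 0.0) for v in vertices}
    return TTSPGraph(WeightedGraph(True, weights, edges), root)


def with_weights(ttsp: TTSPGraph, weights: Mapping[str, float]) -> TTSPGraph:
    """Copy of *ttsp* with the given vertex weights (missing vertices keep
    their current weight)."""
    w = dict(ttsp.graph.weights)
    for v, wt in weights.items():
        if v not in w:
            raise GraphError(f"unknown vertex {v!r}")
        w[v] = float(wt)
    return TTSPGraph(WeightedGraph(True, w, ttsp.graph.edges), ttsp.root)


# ---------------------------------------------------------------------------
# the series-parallel DP
# ---------------------------------------------------------------------------

def solve_ttsp_directed(ttsp: TTSPGraph, c: float):
    """Optimal MSPS on a directed TTSP graph via its decomposition tree.

    Per module ``H`` the table holds ``M[H, u_s, u_t]``: the best score with
    the source/target used in the solution iff ``u_s``/``u_t`` is 1.  For a
    single edge the entries follow directly (with both terminals used, one
    joint path is optimal).  A series composition either skips the internal
    vertex or uses it in both children, subtracting its double-counted
    contribution ``w(mid) - c``.  A parallel composition lets each used
    terminal come from exactly one child.  Returns ``(score, PathSet)``;
    ε-vertices of EDS-derived graphs may appear inside the output paths.
    """
    if c < 0:
        raise GraphError("penalty c must be non-negative")
    graph = ttsp.graph
    w = graph.weights
    M: dict = {}
    choice: dict = {}

    STATES = ((0, 0), (1, 0), (0, 1), (1, 1))
    for node in ttsp.root.postorder():
        if node.kind == EDGE:
            M[id(node)] = {
                (0, 0): 0.0,
                (1, 0): w[node.s] - c,
                (0, 1): w[node.t] - c,
                (1, 1): w[node.s] + w[node.t] - c,
            }
            choice[id(node)] = None
            continue
        ml, mr = M[id(node.left)], M[id(node.right)]
        table: dict = {}
        picks: dict = {}
        if node.kind == SERIES:
            dup = w[node.mid] - c  # counted in both children when mid is used
            for us, ut in STATES:
                options = [
                    (ml[(us, 0)] + mr[(0, ut)], ((us, 0), (0, ut))),
                    (ml[(us, 1)] + mr[(1, ut)] - dup, ((us, 1), (1, ut))),
                ]
                table[(us, ut)], picks[(us, ut)] = max(options, key=lambda o: o[0])
                # keep the first maximum: max() already prefers earlier entries
        else:  # parallel: each used terminal comes from exactly one child
            combos = {
                (0, 0): [((0, 0), (0, 0))],
                (1, 0): [((1, 0), (0, 0)), ((0, 0), (1, 0))],
                (0, 1): [((0, 1), (0, 0)), ((0, 0), (0, 1))],
                (1, 1): [((1, 1), (0, 0)), ((0, 0), (1, 1)),
                         ((1, 0), (0, 1)), ((0, 1), (1, 0))],
            }
            for state, opts in combos.items():
                scored = [(ml[a] + mr[b], (a, b)) for a, b in opts]
                table[state], picks[state] = max(scored, key=lambda o: o[0])
        M[id(node)] = table
        choice[id(node)] = picks

    root_table = M[id(ttsp.root)]
    best_state = max(STATES, key=lambda st: root_table[st])
    optimum = root_table[best_state]

    used_edges: set = set()
    used_vertices: set = set()
    stack = [(ttsp.root, best_state)]
    while stack:
        node, state = stack.pop()
        if node.kind == EDGE:
            us, ut = state
            if us:
                used_vertices.add(node.s)
            if ut:
                used_vertices.add(node.t)
            if us and ut:
                used_edges.add((node.s, node.t))
            continue
        ls, rs = choice[id(node)][state]
        stack.append((node.left, ls))
        stack.append((node.right, rs))

    ps = edges_to_path_set(used_edges, graph, c)
    singles = sorted(used_vertices - ps.covered_vertices())
    paths = sorted(list(ps.paths) + [(v,) for v in singles], key=lambda p: p[0])
    total = sum(path_score(p, graph, c) for p in paths)
    return optimum, PathSet(paths, total)


def ttsp_to_tree_decomposition(ttsp: TTSPGraph) -> TreeDecomposition:
    """Tree decomposition mirroring the module tree: an edge or parallel
    module gets the bag ``{s, t}``, a series module ``{s, mid, t}``.  The
    result always has width at most 2."""
    ids: dict = {}
    bags: dict = {}
    edges: list = []
    for i, node in enumerate(ttsp.root.preorder(), start=1):
        ids[id(node)] = i
        if node.kind == SERIES:
            bags[i] = frozenset((node.s, node.mid, node.t))
        else:
            bags[i] = frozenset((node.s, node.t))
    # connect children to parents in a second pass
    for node in ttsp.root.preorder():
        for ch in (node.left, node.right):
            if ch is not None:
                edges.append((ids[id(node)], ids[id(ch)]))
    return TreeDecomposition(bags, edges)
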