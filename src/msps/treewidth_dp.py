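"""MSPS on graphs of bounded treewidth: DP over a rooted tree decomposition.

The solver consumes the normal form produced by
:func:`msps.decomposition.preprocess`: a binary rooted decomposition whose
leaves are empty bags, with every graph edge assigned to exactly one bag and
terminals ``T(X) = X ∩ parent(X)``.  On the preprocessed graph a solution is
just a set of edges in which every vertex has at most one incoming and one
outgoing selected edge (undirected: at most two incident edges); components
may be cycles, and trivial one-vertex paths are encoded by pendant
auxiliary edges.

Bags are processed bottom-up.  For each bag ``X`` the table ``M[X, C]``
stores, per *configuration* ``C``, the best score over solutions restricted
to the edges assigned in ``X``'s subtree.  A configuration gives, for each
of the two solution-edge slots of each terminal: whether the slot is used
and, if so, the first terminal reached by following the solution path out
of that slot (or a marker that no terminal is reached).  Internal bags are
filled by enumerating richer *extended configurations* with two slots per
bag vertex; each slot additionally records whether its edge lives in the
left subtree, the right subtree, or the bag itself.  An extended
configuration determines unique child configurations (``child_conf``),
projects onto a configuration of ``X`` (``reduce_conf``), and contributes a
local weight correction plus a path-penalty correction (``penalties``).

Slot counts bound the work per bag: at most ``(3|X| + 4)^(2|X|)`` extended
configurations and at most ``(|T| + 2)^(2|T|)`` table entries.  The
enumerator only constructs configurations that pass the structural validity
rules (reciprocal pointers, subtree membership, assigned-edge existence) and
optionally prunes slots that no feasible child configuration supports, so
the counts seen in practice are far below these bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .graph_core import (
    GraphError,
    PathSet,
    WeightedGraph,
    canonical_edge,
    solve_bruteforce,
)
from .decomposition import (
    RootedDecomposition,
    TreeDecomposition,
    from_path_cover,
    postprocess_solution,
    preprocess,
    single_bag_decomposition,
)

__all__ = [
    "NO_TERMINAL",
    "LEFT",
    "RIGHT",
    "BAG",
    "BagContext",
    "ExtendedConfiguration",
    "ChildSupport",
    "DPStats",
    "bag_context",
    "enumerate_extended_configs",
    "is_valid",
    "reduce_conf",
    "child_conf",
    "penalties",
    "local_weight_delta",
    "solve",
    "solve_msps",
]


class _NoTerminal:
    """Pointer marker: following this slot's path never meets a terminal."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_TERMINAL"


NO_TERMINAL = _NoTerminal()

LEFT, RIGHT, BAG = "L", "R", "B"
_SIDES = (LEFT, RIGHT)


def _skey(state):
    """Total order on configuration slot values (unused last, vertices first)."""
    if state is None:
        return (2, "")
    if state is NO_TERMINAL:
        return (1, "")
    return (0, state)


@dataclass(frozen=True)
class BagContext:
    """Everything the per-bag subroutines need to know about one bag."""

    directed: bool
    bag: tuple                 # sorted bag vertices
    terminals: tuple           # sorted terminals T = X ∩ parent(X)
    edges: tuple               # edges assigned to this bag
    child_bags: tuple          # (left vertex set, right vertex set)
    child_terminals: tuple     # sorted terminal tuples of the two children

    @property
    def bag_set(self) -> frozenset:
        return frozenset(self.bag)

    @property
    def terminal_set(self) -> frozenset:
        return frozenset(self.terminals)


def bag_context(rd: RootedDecomposition, i: int) -> BagContext:
    left, right = rd.children[i]
    return BagContext(
        directed=rd.graph.directed,
        bag=tuple(sorted(rd.bags[i])),
        terminals=tuple(sorted(rd.terminals[i])),
        edges=tuple(rd.edge_assignment[i]),
        child_bags=(frozenset(rd.bags[left]), frozenset(rd.bags[right])),
        child_terminals=(tuple(sorted(rd.terminals[left])),
                         tuple(sorted(rd.terminals[right]))),
    )


class ExtendedConfiguration:
    """Slot assignment for every vertex of a bag.

    ``slots`` maps slot keys to ``None`` (unused) or ``(origin, target)``
    where origin is one of ``LEFT``/``RIGHT``/``BAG`` and target is a bag
    vertex or :data:`NO_TERMINAL`.  Slot keys are ``(v, 'in')``/``(v, 'out')``
    for directed graphs and ``(v, 0)``/``(v, 1)`` for undirected ones (the
    two undirected slots are interchangeable).  ``links`` pairs up the
    reciprocal slots of each solution segment crossing the bag.
    """

    __slots__ = ("directed", "slots", "links")

    def __init__(self, directed: bool, slots: dict, links: tuple = ()):
        self.directed = directed
        self.slots = slots
        self.links = links

    def slot_keys(self, v) -> tuple:
        return ((v, "in"), (v, "out")) if self.directed else ((v, 0), (v, 1))

    def key(self) -> tuple:
        """Canonical hashable form (undirected slot pairs are sorted)."""

        def xs(st):
            if st is None:
                return (2, "", "")
            o, t = st
            return (0 if t is not NO_TERMINAL else 1, o, t if t is not NO_TERMINAL else "")

        verts = sorted({v for v, _ in self.slots})
        out = []
        for v in verts:
            a, b = (self.slots.get(k) for k in self.slot_keys(v))
            pair = (xs(a), xs(b))
            if not self.directed:
                pair = tuple(sorted(pair))
            out.append((v,) + pair)
        return tuple(out)

    def used_vertices(self) -> list:
        return sorted({v for (v, _), st in self.slots.items() if st is not None})

    def origins(self, v) -> set:
        return {st[0] for k in self.slot_keys(v)
                if (st := self.slots.get(k)) is not None}

    def bag_edges(self, directed: bool) -> list:
        """Edges of the bag used by this configuration."""
        out = []
        for o, a, b in self.links:
            if o == BAG:
                if directed:
                    out.append((a[0], b[0]) if a[1] == "out" else (b[0], a[0]))
                else:
                    out.append(canonical_edge(a[0], b[0], False))
        return out


@dataclass(frozen=True)
class ChildSupport:
    """Per-slot states that at least one feasible child configuration allows.

    Used to prune the extended-configuration enumeration: a slot pointing
    into a subtree is only worth generating if some entry of that child's
    table realizes it.  ``pairs`` holds endpoint pairs of subtree segments
    (``(v, u)``: a solution path leaves v, runs through the subtree, and
    re-emerges at u), ``none_out``/``none_in`` hold vertices whose
    out/in slot may point into the subtree without returning.
    """

    pairs: frozenset
    none_out: frozenset
    none_in: frozenset

    @classmethod
    def from_table(cls, table: dict, terminals: tuple, directed: bool) -> "ChildSupport":
        pairs, nout, nin = set(), set(), set()
        for config in table:
            for t, entry in zip(terminals, config):
                if directed:
                    tin, tout = entry
                    if tout is NO_TERMINAL:
                        nout.add(t)
                    elif tout is not None:
                        pairs.add((t, tout))
                    if tin is NO_TERMINAL:
                        nin.add(t)
                else:
                    for s in entry:
                        if s is NO_TERMINAL:
                            nout.add(t)
                            nin.add(t)
                        elif s is not None:
                            pairs.add((t, s) if t <= s else (s, t))
        return cls(frozenset(pairs), frozenset(nout), frozenset(nin))


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_extended_configs(ctx: BagContext,
                               support: Optional[tuple] = None
                               ) -> Iterator[ExtendedConfiguration]:
    """Yield structurally valid extended configurations of a bag, each once.

    Configurations are built from reciprocal slot pairs (links), so pointer
    reciprocity, subtree membership and bag-edge existence hold by
    construction; :func:`is_valid` accepts every yielded configuration.
    When *support* (a pair of :class:`ChildSupport`) is given, slots that no
    feasible child configuration can realize are skipped — such
    configurations would only ever score minus infinity.

    The order is deterministic: vertices in lexicographic order, unused
    slots first, then no-terminal pointers, then links by target vertex with
    origins ordered left < right < bag.
    """
    if ctx.directed:
        yield from _enumerate_directed(ctx, support)
    else:
        yield from _enumerate_undirected(ctx, support)


def _side_allows(support, side_idx, ctx, kind, *args) -> bool:
    child = ctx.child_bags[side_idx]
    if kind == "none_out":
        (v,) = args
        if v not in child:
            return False
        return support is None or v in support[side_idx].none_out
    if kind == "none_in":
        (v,) = args
        if v not in child:
            return False
        return support is None or v in support[side_idx].none_in
    v, u = args
    if v not in child or u not in child:
        return False
    if support is None:
        return True
    key = (v, u) if (ctx.directed or v <= u) else (u, v)
    return key in support[side_idx].pairs


def _enumerate_directed(ctx: BagContext, support) -> Iterator[ExtendedConfiguration]:
    verts = ctx.bag
    n = len(verts)
    bag_out = {v: [] for v in verts}
    for u, v in ctx.edges:
        bag_out[u].append(v)
    for v in bag_out:
        bag_out[v].sort()

    out_state: dict = {}
    in_state: dict = {}
    in_taken: set = set()
    links: list = []

    def finalize() -> ExtendedConfiguration:
        slots = {}
        for v in verts:
            slots[(v, "out")] = out_state.get(v)
            slots[(v, "in")] = in_state.get(v)
        return ExtendedConfiguration(True, slots, tuple(links))

    def rec_in(i: int) -> Iterator[ExtendedConfiguration]:
        if i == n:
            yield finalize()
            return
        v = verts[i]
        if v in in_taken:
            yield from rec_in(i + 1)
            return
        in_state[v] = None
        yield from rec_in(i + 1)
        for si, s in enumerate(_SIDES):
            if _side_allows(support, si, ctx, "none_in", v):
                in_state[v] = (s, NO_TERMINAL)
                yield from rec_in(i + 1)
        in_state[v] = None

    def rec_out(i: int) -> Iterator[ExtendedConfiguration]:
        if i == n:
            yield from rec_in(0)
            return
        v = verts[i]
        out_state[v] = None
        yield from rec_out(i + 1)
        for si, s in enumerate(_SIDES):
            if _side_allows(support, si, ctx, "none_out", v):
                out_state[v] = (s, NO_TERMINAL)
                yield from rec_out(i + 1)
        for u in verts:
            if u in in_taken:
                continue
            choices = [s for si, s in enumerate(_SIDES)
                       if _side_allows(support, si, ctx, "pair", v, u)]
            if u in bag_out[v]:
                choices.append(BAG)
            for s in choices:
                out_state[v] = (s, u)
                in_state[u] = (s, v)
                in_taken.add(u)
                links.append((s, (v, "out"), (u, "in")))
                yield from rec_out(i + 1)
                links.pop()
                in_taken.discard(u)
                del in_state[u]
        out_state[v] = None

    yield from rec_out(0)


def _enumerate_undirected(ctx: BagContext, support) -> Iterator[ExtendedConfiguration]:
    verts = ctx.bag
    n = len(verts)
    index = {v: i for i, v in enumerate(verts)}
    bag_adj = {v: set() for v in verts}
    for u, v in ctx.edges:
        bag_adj[u].add(v)
        bag_adj[v].add(u)

    cap = {v: 2 for v in verts}
    ends: dict = {v: [] for v in verts}  # per-vertex slot contents, filled in order
    links: list = []

    # item indices per vertex: 0 = leave slot unused, 1/2 = point into
    # left/right subtree without returning, then links ordered by
    # (target vertex, origin L < R < B)
    def items_for(v):
        items = [("skip",)]
        for si, s in enumerate(_SIDES):
            if _side_allows(support, si, ctx, "none_out", v):
                items.append(("none", s))
        for u in verts[index[v]:]:
            for si, s in enumerate(_SIDES):
                if _side_allows(support, si, ctx, "pair", v, u):
                    items.append(("link", s, u))
            if u in bag_adj[v] and u != v:
                items.append(("link", BAG, u))
        return items

    def finalize() -> ExtendedConfiguration:
        slots = {}
        out_links = []
        slot_of: dict = {}
        for v in verts:
            for k in (0, 1):
                entry = ends[v][k] if k < len(ends[v]) else None
                if entry is None:
                    slots[(v, k)] = None
                elif entry[0] == "none":
                    slots[(v, k)] = (entry[1], NO_TERMINAL)
                else:  # ("link", link_id, origin, other)
                    _, lid, o, other = entry
                    slots[(v, k)] = (o, other)
                    slot_of.setdefault(lid, []).append((v, k))
        for lid, (o, _u, _v) in enumerate(links):
            a, b = slot_of[lid] if len(slot_of[lid]) == 2 else (slot_of[lid][0],) * 2
            out_links.append((o, a, b))
        return ExtendedConfiguration(False, slots, tuple(out_links))

    # capacity is consumed one item at a time in non-decreasing item order,
    # which enumerates each unordered slot pair exactly once
    def fill2(i: int, min_idx: int) -> Iterator[ExtendedConfiguration]:
        if i == n:
            yield finalize()
            return
        v = verts[i]
        if cap[v] == 0:
            yield from fill2(i + 1, 0)
            return
        items = items_for(v)
        for idx in range(min_idx, len(items)):
            item = items[idx]
            if item[0] == "skip":
                cap[v] -= 1
                ends[v].append(None)
                yield from (fill2(i, idx) if cap[v] else fill2(i + 1, 0))
                ends[v].pop()
                cap[v] += 1
            elif item[0] == "none":
                cap[v] -= 1
                ends[v].append(("none", item[1]))
                yield from (fill2(i, idx) if cap[v] else fill2(i + 1, 0))
                ends[v].pop()
                cap[v] += 1
            else:
                _, s, u = item
                if u == v:
                    if s == BAG or cap[v] < 2:
                        continue
                    lid = len(links)
                    links.append((s, v, v))
                    cap[v] -= 2
                    ends[v].append(("link", lid, s, v))
                    ends[v].append(("link", lid, s, v))
                    yield from fill2(i + 1, 0)
                    ends[v].pop()
                    ends[v].pop()
                    cap[v] += 2
                    links.pop()
                else:
                    if cap[u] == 0:
                        continue
                    if s == BAG and any(
                            e is not None and e[0] == "link" and e[2] == BAG and e[3] == u
                            for e in ends[v]):
                        continue
                    lid = len(links)
                    links.append((s, v, u))
                    cap[v] -= 1
                    cap[u] -= 1
                    ends[v].append(("link", lid, s, u))
                    ends[u].append(("link", lid, s, v))
                    yield from (fill2(i, idx) if cap[v] else fill2(i + 1, 0))
                    ends[u].pop()
                    ends[v].pop()
                    cap[v] += 1
                    cap[u] += 1
                    links.pop()

    yield from fill2(0, 0)


# ---------------------------------------------------------------------------
# subroutines: is_valid, reduce_conf, child_conf, penalties, weight delta
# ---------------------------------------------------------------------------

def is_valid(E: ExtendedConfiguration, ctx: BagContext) -> bool:
    """Structural validity of an extended configuration.

    Checks that (a) every used pointer is reciprocated via the same origin,
    (b) subtree pointers stay within the child's bag, (c) bag pointers use
    an edge actually assigned to this bag with the right orientation,
    (d) double pointers (two-vertex cycles) are mutually consistent and
    (e) for undirected bags the symmetric slots admit a consistent pairing.
    """
    slots = E.slots
    bag_set = ctx.bag_set
    for (v, k), st in slots.items():
        if st is None:
            continue
        o, t = st
        if o == BAG and t is NO_TERMINAL:
            return False
        if t is not NO_TERMINAL and t not in bag_set:
            return False
        if o in _SIDES:
            side = ctx.child_bags[0] if o == LEFT else ctx.child_bags[1]
            if v not in side or (t is not NO_TERMINAL and t not in side):
                return False
    if ctx.directed:
        assigned = set(ctx.edges)
        for v in ctx.bag:
            st = slots.get((v, "out"))
            if st is not None and st[1] is not NO_TERMINAL:
                o, u = st
                if slots.get((u, "in")) != (o, v):
                    return False
                if o == BAG and (v, u) not in assigned:
                    return False
            st = slots.get((v, "in"))
            if st is not None and st[1] is not NO_TERMINAL:
                o, u = st
                if slots.get((u, "out")) != (o, v):
                    return False
                if o == BAG and (u, v) not in assigned:
                    return False
        return True
    # undirected: count pointers per unordered pair and origin
    assigned = set(ctx.edges)
    counts: dict = {}
    for (v, k), st in slots.items():
        if st is None or st[1] is NO_TERMINAL:
            continue
        o, u = st
        counts[(canonical_edge(v, u, False), o)] = counts.get(
            (canonical_edge(v, u, False), o), 0) + (2 if v == u else 1)
    for ((a, b), o), cnt in counts.items():
        if a == b:
            if o == BAG or cnt != 4:  # self pair: both slots point home, counted twice
                return False
            continue
        ca = sum(1 for k in ((a, 0), (a, 1)) if slots.get(k) == (o, b))
        cb = sum(1 for k in ((b, 0), (b, 1)) if slots.get(k) == (o, a))
        if ca != cb:
            return False
        if o == BAG:
            if ca > 1 or (a, b) not in assigned:
                return False
    return True


def _link_partner_map(E: ExtendedConfiguration) -> dict:
    by_slot = {}
    for o, a, b in E.links:
        by_slot[a] = b
        by_slot[b] = a
    return by_slot


def _derive_links(E: ExtendedConfiguration, ctx: BagContext) -> ExtendedConfiguration:
    """Reconstruct the reciprocal-slot pairing for a configuration given only
    per-slot states (used when callers build configurations by hand)."""
    if E.links:
        return E
    if not is_valid(E, ctx):
        raise GraphError("cannot derive links of an invalid extended configuration")
    links = []
    if ctx.directed:
        for v in ctx.bag:
            st = E.slots.get((v, "out"))
            if st is not None and st[1] is not NO_TERMINAL:
                links.append((st[0], (v, "out"), (st[1], "in")))
    else:
        free = {k for k, st in E.slots.items() if st is not None and st[1] is not NO_TERMINAL}
        for v in ctx.bag:
            for k in ((v, 0), (v, 1)):
                if k not in free:
                    continue
                o, u = E.slots[k]
                partner = next(kk for kk in ((u, 0), (u, 1))
                               if kk in free and kk != k and E.slots[kk] == (o, v))
                free.discard(k)
                free.discard(partner)
                links.append((o, k, partner))
    return ExtendedConfiguration(E.directed, E.slots, tuple(links))


def reduce_conf(E: ExtendedConfiguration, ctx: BagContext) -> tuple:
    """Project an extended configuration onto the bag's terminals.

    Pointer targets are re-expressed relative to the terminal set by chasing
    pointers through non-terminal bag vertices: at every intermediate vertex
    the slot we arrived on points back, so the other slot carries the path
    forward; an unused or no-terminal forward slot means the path never
    reaches a terminal.
    """
    E = _derive_links(E, ctx)
    tset = ctx.terminal_set
    by_slot = _link_partner_map(E)
    limit = 2 * len(ctx.bag) + 2

    def chase(slot):
        st = E.slots.get(slot)
        if st is None:
            return None
        if st[1] is NO_TERMINAL:
            return NO_TERMINAL
        cur = by_slot[slot]
        for _ in range(limit):
            u, ku = cur
            if u in tset:
                return u
            if ctx.directed:
                other = (u, "out" if ku == "in" else "in")
            else:
                other = (u, 1 - ku)
            st2 = E.slots.get(other)
            if st2 is None or st2[1] is NO_TERMINAL:
                return NO_TERMINAL
            cur = by_slot[other]
        raise GraphError("pointer chase did not terminate (is_valid bug)")

    entries = []
    for t in ctx.terminals:
        if ctx.directed:
            entries.append((chase((t, "in")), chase((t, "out"))))
        else:
            pair = sorted((chase((t, 0)), chase((t, 1))), key=_skey)
            entries.append(tuple(pair))
    return tuple(entries)


def child_conf(E: ExtendedConfiguration, ctx: BagContext, side: int) -> tuple:
    """Configuration of the chosen child (0 = left, 1 = right) that is
    consistent with *E*: a terminal slot is used iff *E* marks its origin as
    that subtree, and pointer targets carry over verbatim (the first bag
    vertex on a subtree segment is also the first child terminal)."""
    origin = LEFT if side == 0 else RIGHT
    entries = []
    for t in ctx.child_terminals[side]:
        if ctx.directed:
            sin = E.slots.get((t, "in"))
            sout = E.slots.get((t, "out"))
            entries.append((
                sin[1] if sin is not None and sin[0] == origin else None,
                sout[1] if sout is not None and sout[0] == origin else None,
            ))
        else:
            pair = []
            for k in ((t, 0), (t, 1)):
                st = E.slots.get(k)
                pair.append(st[1] if st is not None and st[0] == origin else None)
            entries.append(tuple(sorted(pair, key=_skey)))
    return tuple(entries)


def _count_components(vertices: Iterable, edges: Iterable) -> int:
    parent = {v: v for v in vertices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(parent)
    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            n -= 1
    return n


def _config_components(config: tuple, terminals: tuple) -> int:
    used = []
    edges = []
    for t, entry in zip(terminals, config):
        touched = False
        for s in entry:
            if s is not None:
                touched = True
                if s is not NO_TERMINAL:
                    edges.append((t, s))
        if touched:
            used.append(t)
    return _count_components(used, edges)


def penalties(E: ExtendedConfiguration, c_left: tuple, c_right: tuple,
              ctx: BagContext, c: float) -> float:
    """Path-penalty correction when joining the two subtrees through a bag.

    Components of the slot-pointer graph over the bag's used vertices each
    pay one penalty here; components already paid for inside a child (those
    touching that child's terminals) get their penalty refunded, since they
    are either re-counted here or merged into a larger component that is.
    Components lying entirely inside one subtree never touch the bag and are
    untouched.
    """
    E = _derive_links(E, ctx)
    used = E.used_vertices()
    edges = [(a[0], b[0]) for _, a, b in E.links]
    own = _count_components(used, edges)
    refund = (_config_components(c_left, ctx.child_terminals[0])
              + _config_components(c_right, ctx.child_terminals[1]))
    return c * (refund - own)


def local_weight_delta(E: ExtendedConfiguration, ctx: BagContext,
                       weights) -> float:
    """Weight correction at a bag: vertices whose solution edges all lie in
    this bag are new (+w); vertices used by both subtrees were counted twice
    (-w); vertices used by exactly one subtree were counted exactly once."""
    delta = 0.0
    for v in E.used_vertices():
        origins = E.origins(v)
        if origins == {BAG}:
            delta += weights[v]
        elif LEFT in origins and RIGHT in origins:
            delta -= weights[v]
    return delta


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

@dataclass
class DPStats:
    """Per-bag enumeration and table-size counters (for complexity checks)."""

    bags: list = field(default_factory=list)

    def record(self, bag_id: int, size: int, n_terminals: int,
               ext_configs: int, table_size: int) -> None:
        self.bags.append({
            "bag": bag_id, "size": size, "terminals": n_terminals,
            "ext_configs": ext_configs, "table_size": table_size,
        })

    @property
    def total_ext_configs(self) -> int:
        return sum(b["ext_configs"] for b in self.bags)


def solve(graph: WeightedGraph, rd: RootedDecomposition, c: float,
          stats: Optional[DPStats] = None, prune: bool = True):
    """Optimal MSPS score on a preprocessed graph, bottom-up over the bags.

    Returns ``(score, selected_edges)`` where the edge set is a feasible
    solution of the cycles-allowed problem on the preprocessed graph; feed
    it to :func:`msps.decomposition.postprocess_solution` to obtain paths on
    the original graph.  Configurations never realized by any valid
    extended configuration simply stay out of the tables (score minus
    infinity); ties between equal-scoring extended configurations keep the
    first one in enumeration order.
    """
    if c < 0:
        raise GraphError("penalty c must be non-negative")
    tables: dict = {}
    best: dict = {}
    weights = graph.weights
    for i in rd.postorder():
        ch = rd.children[i]
        if not ch:
            if rd.bags[i]:
                raise GraphError(f"leaf bag {i} is not empty; run preprocess first")
            tables[i] = {(): 0.0}
            best[i] = {}
            continue
        ctx = bag_context(rd, i)
        tl, tr = tables[ch[0]], tables[ch[1]]
        support = None
        if prune:
            support = (
                ChildSupport.from_table(tl, ctx.child_terminals[0], ctx.directed),
                ChildSupport.from_table(tr, ctx.child_terminals[1], ctx.directed),
            )
        table: dict = {}
        chosen: dict = {}
        count = 0
        for E in enumerate_extended_configs(ctx, support):
            count += 1
            cl = child_conf(E, ctx, 0)
            sl = tl.get(cl)
            if sl is None:
                continue
            cr = child_conf(E, ctx, 1)
            sr = tr.get(cr)
            if sr is None:
                continue
            score = (sl + sr + local_weight_delta(E, ctx, weights)
                     + penalties(E, cl, cr, ctx, c))
            config = reduce_conf(E, ctx)
            cur = table.get(config)
            if cur is None or score > cur:
                table[config] = score
                chosen[config] = (E, cl, cr)
        if not table:
            raise GraphError(f"no feasible configuration at bag {i}")
        tables[i] = table
        best[i] = chosen
        if stats is not None:
            stats.record(i, len(ctx.bag), len(ctx.terminals), count, len(table))
    root_table = tables[rd.root]
    if () not in root_table:
        raise GraphError("root table lacks the empty configuration")
    optimum = root_table[()]

    sel: set = set()
    stack = [(rd.root, ())]
    while stack:
        i, config = stack.pop()
        ch = rd.children[i]
        if not ch:
            continue
        E, cl, cr = best[i][config]
        sel.update(E.bag_edges(graph.directed))
        stack.append((ch[0], cl))
        stack.append((ch[1], cr))
    return optimum, frozenset(sel)


# ---------------------------------------------------------------------------
# end-to-end dispatch
# ---------------------------------------------------------------------------

def _as_path_order(graph: WeightedGraph):
    """Vertex order of a simple path graph, or None if the graph is not one."""
    if graph.n == 0:
        return None
    if graph.m != graph.n - 1:
        return None
    if graph.n == 1:
        return graph.sorted_vertices()
    nbr: dict = {v: [] for v in graph.weights}
    succ: dict = {}
    pred: dict = {}
    for u, v in graph.edges:
        nbr[u].append(v)
        nbr[v].append(u)
        succ.setdefault(u, []).append(v)
        pred.setdefault(v, []).append(u)
    if any(len(ns) > 2 for ns in nbr.values()):
        return None
    if graph.directed:
        if any(len(x) > 1 for x in succ.values()) or any(len(x) > 1 for x in pred.values()):
            return None
        starts = [v for v in graph.weights if v not in pred]
        if len(starts) != 1:
            return None
        order = [starts[0]]
        while order[-1] in succ:
            order.append(succ[order[-1]][0])
        return order if len(order) == graph.n else None
    ends = [v for v, ns in nbr.items() if len(ns) == 1]
    if len(ends) != 2:
        return None
    order = [min(ends)]
    prev = None
    while True:
        nxt = [x for x in nbr[order[-1]] if x != prev]
        if not nxt:
            break
        prev = order[-1]
        order.append(nxt[0])
    return order if len(order) == graph.n else None


def solve_msps(graph, c: float, method: str = "auto",
               td: Optional[TreeDecomposition] = None,
               cover: Optional[Sequence[Sequence[str]]] = None):
    """Solve MSPS end-to-end on the original graph.

    *graph* may be a :class:`~msps.graph_core.WeightedGraph` or a
    :class:`~msps.ttsp.TTSPGraph`.  ``method`` is one of ``auto``,
    ``sequence``, ``ttsp``, ``treewidth`` or ``bruteforce``; ``auto`` picks
    the most specific applicable solver.  Returns ``(score, PathSet)``.
    """
    from . import ttsp as ttsp_mod

    ttsp_graph = None
    if isinstance(graph, ttsp_mod.TTSPGraph):
        ttsp_graph = graph
        graph = ttsp_graph.graph

    if graph.n == 0:
        return 0.0, PathSet()

    if method == "auto":
        if ttsp_graph is not None:
            method = "ttsp"
        elif td is not None or cover is not None:
            method = "treewidth"
        elif _as_path_order(graph) is not None:
            method = "sequence"
        elif graph.m <= 18:
            method = "bruteforce"
        else:
            raise GraphError("no usable decomposition: pass td=, cover= or a TTSP graph")

    if method == "bruteforce":
        return solve_bruteforce(graph, c)

    if method == "sequence":
        order = _as_path_order(graph)
        if order is None:
            raise GraphError("sequence method requires a simple path graph")
        from .sequence_dp import solve_sequence
        score, intervals = solve_sequence([graph.weights[v] for v in order], c)
        paths = [tuple(order[a:b]) for a, b in intervals]
        return score, PathSet(paths, score)

    if method == "ttsp":
        if ttsp_graph is None:
            raise GraphError("ttsp method requires a TTSPGraph input")
        return ttsp_mod.solve_ttsp_directed(ttsp_graph, c)

    if method == "treewidth":
        if td is None:
            if cover is not None:
                td = from_path_cover(graph, cover)
            elif ttsp_graph is not None:
                td = ttsp_mod.ttsp_to_tree_decomposition(ttsp_graph)
            else:
                td = single_bag_decomposition(graph)
        pgraph, rd = preprocess(graph, td, c)
        score, sel = solve(pgraph, rd, c)
        ps = postprocess_solution(sel, rd, graph, c)
        return score, ps

    raise GraphError(f"unknown method {method!r}")
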