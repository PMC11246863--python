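# Methods

## Problem and conventions

An MSPS instance is a graph *G = (V, E)* — directed or undirected, no
self-loops or parallel edges — with real vertex weights *w(v)* and a
startup penalty *c ≥ 0*.  A solution is a set of vertex-disjoint simple
paths; a single vertex is a legal path of length 0.  The score of a path is
its weight sum minus *c*; the score of a solution is the sum over its
paths; the empty solution scores 0.  Weights are dimensionless scores
(log-odds-like in the motivating applications); *c* trades off the number
of reported paths against their total weight: at *c* = 0 the optimum is
simply Σ max(0, w(v)), and once *c* exceeds the total positive weight the
empty solution is optimal.

Vertex identifiers are opaque strings ordered lexicographically; that
order drives every tie-break in the package (topological-order ties,
cycle-breaking, enumeration order), so all solvers are deterministic.
When several solutions attain the optimum any of them is correct; the
implemented tie-breaks prefer solutions with fewer used vertices (a
singleton whose weight equals *c* scores 0 and is *not* reported).

Scores of the small integer/half-integer test instances are exactly
representable in floating point, so solver-vs-oracle comparisons in the
tests are exact; for general real weights an absolute tolerance of 1e-9 is
used when checking that a reported path set reproduces its claimed score.

## Sequence DP

On a path graph the problem is the classic maximum-scoring segment set
problem.  `sequence_dp` implements the two-state linear scan

    M[1,0] = 0,  M[1,1] = w₁ − c
    M[i,0] = max(M[i−1,0], M[i−1,1])
    M[i,1] = max(M[i−1,0] + wᵢ − c, M[i−1,1] + wᵢ)

with the answer max(M[n,0], M[n,1]).  Opening a segment directly after a
closed one is never considered: merging two adjacent segments saves one
penalty, so the restriction is lossless.  Traceback ties prefer the
"vertex unused" predecessor, which yields the minimum-coverage optimum.
Reported intervals are 0-based half-open (the recurrence's indices are
1-based).

## Series-parallel DP

For a directed TTSP graph with a binary module tree, `ttsp` keeps four
values per module *H*: *M*[*H*, u_s, u_t], the best score with the source
and target used iff u_s, u_t.  Edge modules are immediate (with both
terminals used, joining them into one path dominates).  A series
composition through the internal vertex *t₁* either leaves *t₁* unused or
uses it in both children, in which case its weight and one penalty were
counted twice and (w(t₁) − c) is subtracted once.  A parallel composition
lets each used terminal come from exactly one child (using a terminal in
both children would need two incoming or two outgoing edges at it); the
(1,1) entry takes the best of four child-state combinations.  Multi-edges
created by parallel composition are collapsed in the graph — multiplicity
cannot change the optimum — while the module tree keeps one leaf per
composition.

The EDS conversion places one zero-weight ε-vertex before the first
symbol, between consecutive symbols and after the last one; every
alternative of a symbol runs between its flanking ε-vertices as a chain of
one-character vertices (an empty alternative is a direct edge), and nested
generalized EDSs reuse the same flanking rule recursively.  ε-vertices
never carry score but may appear inside reported paths.

## Treewidth DP

### Preprocessing

The general solver works on a reformulated problem: a solution is any edge
set in which each vertex has at most one incoming and one outgoing
selected edge (undirected: at most two incident edges), components may be
paths *or cycles* — a cycle scores like the path obtained by dropping any
one of its edges, so the reformulation is score-equivalent and no
acyclicity of the input is needed — and trivial one-vertex components are
forbidden.  To keep singleton paths reachable, every vertex *v* with
w(v) ≥ c gets a pendant auxiliary vertex *v′* of weight 0, an edge
(v, v′), and a leaf bag {v, v′} attached below the root-most bag
containing *v* (any bag containing *v* is correct; the root-most one is
fixed for determinism).  A selected pendant edge is translated back to the
singleton path (v) in postprocessing; cycles are opened by dropping their
lexicographically smallest edge.

The tree decomposition is then normalized: rooted (at the first bag by
input order; configurable), binarized by expanding any bag with more than
two children into a left-leaning chain of duplicate bags, and padded with
empty leaf bags so that every internal bag has exactly two children and
every leaf is empty.  Each edge is assigned to the unique bag closest to
the root containing both endpoints (the intersection of two connected
subtrees is a subtree, so the root-most such bag is unique).  Terminals of
a bag are its intersection with its parent; the root has none.  The
normalization is linear: the bag count stays below 3·(original bags +
pendant bags) + 2 in all generated cases, matching the linear bound the
analysis needs.

### Configurations

For a bag *X* with terminals *T*, a *configuration* records per terminal
two slots (incoming/outgoing in directed graphs; an unordered pair
otherwise): unused, or used with a pointer to the first terminal reached
by following the solution path out of that slot — or a NO_TERMINAL marker
when the path ends without meeting one.  At most (|T|+2)^(2|T|)
configurations exist; undirected slot pairs are stored canonically sorted
so symmetric duplicates collapse.

An *extended configuration* refines this to all bag vertices and labels
every used slot with its *origin*: left subtree, right subtree, or the bag
itself — at most (3|X|+4)^(2|X|) candidates.  Validity requires reciprocal
pointers via the same origin, subtree pointers to stay within the child's
bag (condition 3 of the decomposition makes this necessary), bag pointers
to use an edge actually assigned to the bag with the right orientation,
and, undirected, a consistent pairing of the symmetric slots.  The
enumerator builds configurations constructively from reciprocal slot pairs
("links"), so everything it yields is valid by construction; an
independent declarative `is_valid` predicate is kept for testing, and an
exhaustive cross-check on small bags confirms the two describe the same
set.  When child tables are known, slots no feasible child configuration
can realize are skipped during enumeration (they could only score −∞);
this pruning is what keeps single-bag decompositions of dense little
graphs fast, and it never changes any table value.

### Combining bags

Leaves hold the single empty configuration with score 0.  For an internal
bag, each extended configuration *E* determines one configuration per
child (slots whose origin is that subtree, targets copied verbatim — the
first bag vertex on a subtree segment is also the first child terminal).
Its score is the sum of the two child table entries plus two corrections:

* **weights** — add w(v) for vertices all of whose used slots are
  bag-origin (new to the solution here); subtract w(v) for vertices used
  by both subtrees (counted twice below); vertices used by exactly one
  subtree are already counted exactly once;
* **penalties** — subtract *c* for every connected component of the
  slot-pointer graph over the bag's used vertices (each maximal solution
  component touching *X* appears there as one connected piece, whether
  path or cycle — components are counted uniformly on that auxiliary
  graph), and refund *c* for every component visible in each child
  configuration, since those were charged in the child and are either
  re-charged here or merged into something bigger that is.

*M*[*X*, *C*] is the maximum over valid *E* with reduce(*E*) = *C*, where
reduce chases pointers through non-terminal vertices (the slot we arrived
on points back, the other one carries on) until a terminal or a dead end.
A missing child entry makes *E* infeasible; infeasibility is represented
by absence from the table, never by a large negative number.  Ties keep
the first *E* in the deterministic enumeration order (vertices
lexicographic; unused slots first, then no-terminal pointers, then links
by target with origins left < right < bag).  The root's empty
configuration holds the optimum; traceback down the stored best extended
configurations collects the bag-origin edges into the solution edge set.

## Synthetic instances

All tests run on seeded synthetic instances (`msps.generate`); integer
weights uniform on [−3, 3] emulate per-position scores where roughly half
the positions are interesting, and penalties {0, 0.5, 1, 2} span the
regimes from "report every positive vertex" to "merge or drop".  Five
shapes are generated: plain paths, random trees (with their width-1
decompositions), random series/parallel compositions (up to 50 edge
leaves, the scale of a short EDS), DAGs merged from k ≤ 4 covering
sequences (the multiple-sequence-alignment pangenome shape, ≤ 8 vertices
so the brute-force oracle stays exact), and Erdős–Rényi graphs (n ≤ 7,
m ≤ 14 — the treewidth solver sees these through the trivial single-bag
decomposition, which exercises the largest extended-configuration spaces
the suite enumerates).  These sizes keep the full verification suite —
including 300-instance exact agreement with the brute-force oracle and
100-instance cross-solver sweeps — in the tens of seconds.  What the
generators do *not* emulate: realistic genome-scale graphs, correlated
scores along a path, or decompositions of large width; passing tests
certify exact optimality on thin graphs, not performance on wide ones.

## Known limitations and non-goals

* No treewidth *computation*: a decomposition must be supplied (file,
  path cover, or TTSP structure); only the trivial single-bag fallback is
  built in, and it is exponential in n.  Likewise no TTSP recognition of
  arbitrary graphs: series-parallel structure comes from an EDS or a
  composition script.
* The bespoke undirected series-parallel recurrence is not implemented;
  undirected TTSP instances are solved through the general treewidth DP on
  the module-tree decomposition (width ≤ 2), which is asymptotically the
  same and keeps one code path.
* Wall-clock time grows superexponentially with width; bags beyond ~6–7
  vertices are impractical in pure Python.  The per-bag enumeration counts
  are exposed via `DPStats` and checked against the stated bounds, and an
  operation-count test verifies linear scaling in the number of bags at
  fixed width (operation counts rather than wall-clock, to stay
  deterministic).
* Weighted edges, walks with repeated vertices, and diploid two-solution
  variants are out of scope.
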