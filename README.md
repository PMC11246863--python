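# msps — maximum-scoring path sets on pangenome graphs

Genome analyses often boil down to finding dense clusters of interesting
positions: CpG islands, GC-rich regions, ChIP-seq peak clusters, runs of
conserved or fast-evolving sites.  On a single sequence the classic recipe
assigns every position a score (positive where something interesting was
observed, negative elsewhere) and looks for disjoint high-scoring segments,
charging a startup penalty *c* per segment to control how many segments are
reported.  Pangenomics replaces the single sequence with a **sequence
graph** whose vertices carry the per-position scores and whose paths spell
out the individual genomes — so the segmentation problem becomes:

> **Maximum-scoring path sets (MSPS).**  Given a vertex-weighted graph
> *G = (V, E)* with weights *w(v)* and a penalty *c ≥ 0*, find a set of
> vertex-disjoint simple paths {π₁, …, π_ℓ} maximizing
> Σᵢ w(πᵢ), where w(π) = −c + Σ_{u ∈ π} w(u).

The empty set is feasible, so the optimum is never negative.  MSPS is
NP-hard in general (a Hamiltonian path is exactly a solution of score
n − c on unit weights), but pangenome graphs are usually *thin*: this
package solves MSPS exactly, in time linear in the graph size, whenever a
tree decomposition of small width is available.

## Solvers

| solver | graphs | time |
|---|---|---|
| `solve_sequence` | path graphs (plain sequences) | O(n) |
| `solve_ttsp_directed` | directed two-terminal series-parallel (TTSP) graphs, e.g. built from elastic degenerate strings (EDS) | O(m) |
| `treewidth_dp.solve` / `solve_msps` | any directed or undirected graph with a tree decomposition of width k (cycles allowed) | O(n · f(k)), linear for constant k |
| `solve_bruteforce` | anything tiny (≤ 18 edges) | exponential; the test oracle |

The treewidth solver works bottom-up over a rooted, binarized tree
decomposition.  Per bag *X* with terminals *T = X ∩ parent(X)* it keeps a
table *M*[*X*, *C*] indexed by *configurations*: for each of a terminal's
two solution-edge slots, whether it is used and which terminal the path
leaving through it reaches next.  Bags are joined by enumerating richer
*extended configurations* (two slots per bag vertex, each also recording
whether its edge lives in the left subtree, the right subtree, or the bag)
with at most (3|X|+4)^(2|X|) candidates per bag and (|T|+2)^(2|T|) stored
entries — constants for constant width.

Decomposition constructions included:

* **EDS → TTSP graph** (`eds_to_ttsp`): each alternative becomes a chain of
  one-character vertices between shared zero-weight ε-vertices; nesting
  (generalized EDS) is supported.
* **TTSP → tree decomposition** (`ttsp_to_tree_decomposition`): one bag per
  module-tree node, width ≤ 2 (serial bags have exactly 3 vertices).
* **Path cover → path decomposition** (`from_path_cover`): a DAG covered by
  *k* paths (e.g. a pangenome built from *k* sequences) gets a valid path
  decomposition of width ≤ *k* by a single topological sweep.

## Worked example

```python
from msps import WeightedGraph, solve_msps

g = WeightedGraph(True, {"a": 5.0, "b": -2.0, "c": 3.0}, [("a", "b"), ("b", "c")])
print(solve_msps(g, 1.0))   # (6.0, PathSet(paths=(('a',), ('c',)), total_score=6.0))
print(solve_msps(g, 3.0))   # (3.0, PathSet(paths=(('a', 'b', 'c'),), total_score=3.0))
```

At *c* = 1 it pays to report two separate hits, `a` (5 − 1) and `c`
(3 − 1), total 6.  At *c* = 3 a second startup penalty is too expensive, so
the bridge `b` is absorbed into one path scoring 5 − 2 + 3 − 3 = 3.

The same machinery runs on a pangenome given as an elastic degenerate
string.  With CG-content scores (C, G: +2; A, T: −1):

```python
from msps import solve_msps
from msps.ttsp import parse_eds, eds_to_ttsp

tg = eds_to_ttsp(parse_eds("A{CG,T}C{A,}G"), {"C": 2, "G": 2, "A": -1, "T": -1})
score, ps = solve_msps(tg, 0.5)
print(score)                       # 7.5
print([" ".join(p) for p in ps.paths])
# ['7:C 8:G $e3 10:C $e4 $e5 12:G']
```

The optimal GC-rich region follows the `CG` branch of the first degenerate
symbol and the empty branch of the second (`$e…` are the zero-weight
ε-vertices shared between symbols), scoring 2+2+2+2 − 0.5 = 7.5.

A command-line interface mirrors the library (`msps solve`, `msps
from-eds`, `msps decompose-paths`, `msps decompose-ttsp`, `msps validate`,
`msps random`) using PACE-style `.gr`/`.td` files with a weight table and a
vertex-name sidecar; see `msps --help`.

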