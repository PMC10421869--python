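# Methods

`clockrank` prioritizes candidate proteins associated with a seed process
(canonically, the plant circadian core clock) purely from the topology of an
undirected protein–protein interaction (PPI) network, then filters the
candidates by statistical and functional coherence. This note records the
model, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## The two mining branches

**Random walk with restart (RWR).** With column-stochastic operator
`W[i,j] = 1/deg(j)` for each edge `{i,j}` and restart vector `P_0` uniform
over the seed proteins, the walk iterates

    P_{i+1} = (1 − r)·W·P_i + r·P_0

until `‖P_{i+1} − P_i‖_1 < ε`. The map is a contraction with factor
`(1 − r)`, so the L1 gap decays geometrically and convergence is reached in
roughly `log(ε/2)/log(1 − r)` steps (about 10 at the defaults). A note on
the operator: with a column-normalized adjacency matrix, applying the
*transpose* would not conserve probability mass; `clockrank` applies the
column-stochastic operator directly, the standard restart-walk formulation,
under which `Σ P_i = 1` at every step (when no zero-degree node carries
mass — zero-degree nodes have all-zero columns and are flagged). Nodes with
stationary probability strictly above `τ` (seeds excluded) are the raw RWR
candidates.

Defaults: `r = 0.8`, `ε = 1e-6`, `τ = 1e-5`, `max_iterations = 10000`
(a safety stop for pathological tolerances, never reached at the defaults).

**Graphlet degree vectors (GDV).** Each node is summarized by the counts of
the 15 automorphism orbits of the nine connected 2–4-node graphlets
(orbit 0 is the degree); similarity between two signatures is

    S_GDV(u, v) = 1 − Σ|u_i − v_i| / Σ(u_i + v_i),

one minus a Bray–Curtis distance, computed by default on the 11
non-redundant orbits {0,1,2,4,5,6,7,8,9,10,11} (the triangle, diamond and
K4 orbits are linear combinations of the rest); a full-15 mode is
available. Before this branch runs, nodes with degree < 3 are removed in a
single simultaneous pass (degrees measured on the input network, no
cascade): sparse regions of observed PPI networks are the least completely
mapped, and degree-≤2 signatures are mostly noise. Nodes at exactly degree
3 are kept. The similarity threshold is found adaptively: starting at 0.96
and stepping down by 0.01 until every seed has at least one non-seed,
non-self node at or above the threshold; all (seed, node) pairs at or above
the selected value are raw GDV candidates, each node remembering its
best-matching seed.

Orbit counting enumerates, per node, every connected induced subgraph on
≤ 4 nodes through it exactly once (rooted extension-set enumeration) and
classifies the node's orbit from the induced edge count and within-subgraph
degrees; the kernel is JIT-compiled over CSR adjacency, which keeps the
rewired-network null (below) tractable at benchmark scale. No 5-node
graphlets and no algebraic counting shortcuts are used.

## Permutation significance

Both branches get an empirical FDR `p(g) = θ(g)/n` with strict exceedance
counting and `n = 1000` permutations by default; candidates with
`p < α = 0.05` survive. No small-sample `+1` correction is applied, so
`p = 0` is attainable and anticonservative — a deliberate match to the
plain `θ/n` definition.

* **RWR null**: `n` seed sets of the same size drawn uniformly without
  replacement from all nodes; `θ(g)` counts null walks whose probability at
  `g` strictly exceeds the observed one. All null walks are iterated as one
  batched matrix recursion.
* **GDV null**: `n` degree-preserving rewired networks, each produced by
  `10·|E|` *attempted* double edge swaps ({a,b},{c,d} → {a,d},{c,b};
  proposals creating self-loops or duplicates are skipped), a standard
  mixing heuristic. Node labels and the exact degree multiset are
  preserved, and rewiring is applied to the same degree-filtered network
  the real signatures were computed on (the filter set is degree-determined,
  hence identical across the ensemble). `θ(g)` counts null networks where
  the similarity of the *same labeled pair* (candidate, best real seed)
  strictly exceeds the real value; comparing against any seed instead is a
  switchable variant.

Randomness derives from one root seed via per-permutation spawned streams,
so each branch is independently and bitwise reproducible; null networks are
streamed, never stored.

## Enrichment filter (MAS)

For gene `g` with closed neighborhood `H(g)` (`n = |H(g)|`) and a term `A`
annotating `M` of the `N` network proteins (`m` of them in `H(g)`), the
enrichment score is the upper-tail hypergeometric surprisal

    S(g, A) = −log10 Σ_{k=m..n} C(M,k)·C(N−M, n−k) / C(N,n),

computed via the scipy survival function and capped at 300 when the tail
underflows (cosine similarity is scale-sensitive; an unbounded spike would
dominate a whole vector). `N` is the full network node count; annotations
of genes absent from the network are ignored. Terms are opaque labels — no
ontology-graph propagation. The per-term scores form `ES(g)`; functional
similarity `Γ(g, g′)` is the cosine of two ES vectors aligned on the union
of their term sets (missing terms 0, all-zero vectors give 0). A
candidate's MAS is its maximum `Γ` over the seed proteins, and the final
filter requires `MAS ≥ 0.75` *inclusively* in both the GO namespace and the
pathway namespace. The inclusive comparison is a choice between two
readings of the cutoff ("above 0.75" vs "0.75 or above"); strictness is
configurable.

The final candidate set is the union of the two branches' survivors, with
per-branch provenance flags and the overlap count reported.

## Synthetic benchmark

The generator emulates the qualitative features the method exploits in a
real interactome: a preferential-attachment backbone (heavy-tailed degrees,
short paths — scale-free, small-world-like), a planted 30-node module drawn
from backbone nodes of degree ≥ 3 and additionally wired internally with
probability 0.3 per pair, 9 module nodes designated seeds (the remaining
21 are the recovery ground truth), and two annotation namespaces (40 GO-like,
20 pathway-like terms) in which one fifth of the terms are "clock-like":
module nodes carry each such term with probability 0.8 versus a 0.05
background rate. Defaults: 800 nodes, attachment parameter 3 (mean degree
≈ 6, of the order of sparse plant interactomes). Every quantity is
reproducible from one generator seed, and module membership guarantees
survival of the degree-3 filter by construction.

What passing on this benchmark shows: the full funnel (propagation →
thresholding → permutation FDR → dual-namespace MAS) preferentially
recovers a topologically coherent, annotation-coherent planted module, with
correctly calibrated null p-values. What it does not show: performance on a
real interactome, whose degree correlations, community structure,
annotation incompleteness and ascertainment biases the generator does not
model; the headline candidate counts reported for any real network are not
reproduced and not targeted.

## Numerical and design notes

* Self-loops and duplicate/reversed edge rows are dropped at read time
  (both walks and orbit counts assume a simple graph); node ids are exact
  case-sensitive strings.
* Two all-zero GDV signatures compare as similarity 1 (identical empty
  wiring); unreachable after the degree filter.
* The GDV threshold grid is evaluated with a 1e-12 slack to absorb float
  drift in repeated 0.01 decrements; the grid effectively always terminates
  at or above 0 because similarities are nonnegative.
* Seeds are excluded from raw RWR candidates by default (the output is
  clock-*associated* proteins); configurable.
* The degree filter applies to the GDV branch and to the seed mapping
  (degree < 3 seeds are dropped before both branches); the RWR branch runs
  on the unfiltered network.
* A candidate with no computable enrichment in a namespace gets MAS 0
  there (dropped, never an error).
* Problem sizes used by the test suite and the acceptance script — full
  enumeration oracles up to 30-node graphs, 150–200 permutations, five
  generator seeds — were chosen as the smallest scales at which the
  stochastic properties under test are stable.

## Known limitations

* Orbit counting is exact enumeration; very dense hubs (thousands of
  neighbors) make the per-node subgraph count explode. Fine at the
  intended 10³–10⁴-node PPI scale, not for dense graphs.
* The attempt-based edge-swap null mixes well for sparse networks but has
  no formal mixing guarantee; `swaps_per_edge` is exposed.
* Empirical p-values are lower-bounded by 1/n; at n = 1000 the α = 0.05
  cut is well resolved, but ranking within very small p-values is not.
* MAS inherits every bias of the annotation maps; unannotated candidates
  can never pass, which is a feature for precision and a limitation for
  novelty.
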