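# Methods

This note documents the model, the algorithms, the tunable parameters and
the numerical choices of `ms2patterns`, in the order data flows through the
package, together with what the synthetic benchmark does and does not
establish.

## Spectrum preprocessing

A spectrum is a peak list with a precursor m/z. Peaks at identical m/z are
pooled on construction. Before graph building each spectrum is reduced to
its `top_peaks = 15` most intense fragments: pattern mining is exponential
in vertex count, and the most intense peaks carry most of the usable
fragment information. Intensity ties at the cutoff go to the higher m/z
(heavier fragments tend to be more structure-specific, and the rule is
deterministic). The precursor peak gets no special treatment by default;
`keep_precursor` forces the peak matching the precursor m/z (10 ppm) into
the selection for libraries where the precursor's presence matters.

Multi-collision-energy spectra of one compound can be merged first: the
pooled peak list is clustered by single linkage left-to-right, breaking the
chain when the gap exceeds `max(10 ppm · mz, 0.001 Da)` (a gap exactly at
the bound still merges), with intensities summed and m/z averaged by
intensity. Merging conserves total intensity exactly and every merged m/z
lies within the range of its cluster.

## The difference alphabet

All pairwise differences of the reduced library are binned with a Gaussian
KDE whose bandwidth follows instrument accuracy: `h(d) = max(dmz,
d · ppm · 1e-6)`, defaults `ppm = 15`, `dmz = 0.005` Da. `max()` is the
natural combination of a relative tolerance with an absolute floor for low
masses; 15 ppm keeps patterns robust to small mass deviations at the cost
of occasionally wide bins. The data are first split into chunks separated
by gaps larger than four bandwidths (where the density is numerically
zero), and the density of each chunk is evaluated on a grid of step
`min-bandwidth / 5` — resolution well below the narrowest kernel. Bins are
delimited by interior density minima; their reported interval hugs the
member data with one bandwidth of slack (padding bins out to the full
kernel support would make unrelated neighbouring clusters look adjacent and
merge them into chemically meaningless wide bins). The bin center is the
density mode.

Bins supported by fewer than `f = 2` distinct spectra are dropped — `f`
counts spectra, not raw differences, matching the graph-counted support
used by the miner. Adjacent surviving bins closer than one bandwidth at
their midpoint are merged.

Formula annotation: inside 14–200 Da a bin keeps every CHNOPS formula
within the local bandwidth of its center that passes the Senior
realizability conditions (even valence sum; valence sum ≥ 2·(atoms − 1)),
plus every sum of two realizable formulas (combinations, e.g. H4O2 = H2O +
H2O, which is not realizable by itself but is a real two-step loss).
Combination depth is capped at two: "all combinations" is unbounded and
explodes combinatorially, and two steps already express consecutive or
parallel losses. The same summed formula may appear once per decomposition,
because the decomposition is what carries the chemical reading. In-window
bins with no candidate are discarded; bins above 200 Da are kept without
formulas; bins below 14 Da are discarded. The element set is configurable
(halogens opt-in). Monoisotopic masses are hard-coded to six decimals in
one table shared by every module.

## Fragmentation graphs

Vertices are the reduced peaks, edges run heavier → lighter whenever the
difference falls in a bin (half-open intervals `[lower, upper)` make the
assignment unambiguous), so graphs are structurally acyclic. When several
edges with one label share a source or a target — typically a symptom of
poor MS/MS extraction — only the edge closest to the bin center survives,
with exact ties resolved by smaller target then smaller source m/z.
Afterwards the out-edges (and in-edges) of any vertex carry pairwise
distinct labels; the miner's vertex identification rests on this.

Because labels are mass differences, two edges of a directed 2-path force a
closing edge between its endpoints whenever the summed difference is itself
binned. The consistency checker audits this: for every 2-path (u, v, w) it
verifies that the direct edge (u, w) exists and that its bin contains
`mz(u) − mz(w)`. By default every 2-path is inspected;
`min_path_support = ε` restricts the audit to frequent 2-paths — the paths
whose closure the mining actually relies on. The audit only reports; in
`repair` mode a missing or mislabeled closing edge is added back when the
difference falls inside an existing bin, but the exact correction procedure
of the reference method is not public, so reporting is the default.

## Mining closed frequent AFG patterns

Patterns are Acyclic Flow Graphs: rooted DAGs with a directed path from the
root to every vertex. A frequent AFG always contains the depth-1 star of
root out-edges (closure applied along each root-to-vertex path), so it is
determined by any of its spanning trees, and mining reduces to mining
trees.

* **k-path tree.** A prefix tree over the label alphabet indexing every
  potentially frequent directed path of length ≤ k. Each node stores the
  path's last label `l`, the label `h` of the unique edge joining the
  path's endpoints, and the occurrence list `o` of (graph, start vertex)
  couples; occurrences whose closing edge is absent are dropped, and if —
  on noisy data — occurrences disagree on `h`, the variant supported by
  most graphs is kept with a warning. The default `k` is the longest
  directed path in the database, at most 14 (15-peak graphs cannot contain
  longer paths); any `k ≥ 1` yields the same pattern set, deeper trees just
  prune the enumeration harder.
* **Enumeration.** Subtrees of the k-path tree are generated exactly once
  by right-most path extension (new nodes attach to the right-most path,
  sibling labels strictly increasing). Each candidate must (1) map to a
  proper spanning tree — its vertices' `h` labels pairwise distinct,
  otherwise two tree leaves resolve to one graph vertex; (2) equal the
  k-LMDF spanning tree of the AFG it induces — the depth-first,
  minimum-label-first spanning tree capped at depth k — so isomorphic
  patterns are generated once; (3) have occurrences (the intersection of
  its nodes' `o` lists, legitimate because all paths share the root) in at
  least `ε` distinct graphs. All three criteria prune whole enumeration
  branches: a failing support or duplicate-`h` subtree passes both defects
  to every extension, and canonicality is prefix-closed — removing the
  last pre-order vertex of the k-LMDF tree N(G) leaves exactly N(G minus
  that vertex), because that vertex is entered only at the final step of
  the depth-first search, so deleting it perturbs no earlier choice.
* **Reconstruction and closedness.** A surviving subtree is mapped onto its
  first occurrence and every edge between mapped vertices is added (on
  exact data these closure edges recur in all occurrences; a debug check
  verifies this and reports violations). The pattern is reported when
  closed: `E_out` — the labels of edges leaving a mapped root beyond the
  pattern's own star, unioned over the occurrences within each graph and
  intersected across support graphs — and the analogous `E_in` for edges
  entering the root are both empty. The per-graph union (rather than a
  plain intersection over occurrences) is what matches graph-counted
  support: one occurrence per graph carrying the extension suffices for a
  same-support supergraph to exist. Support counts distinct graphs;
  multiple occurrences within a graph are all tracked but count once.
* **Ordering.** Labels are totally ordered by their dense ids (ascending
  bin center), which fixes "minimum label" in the canonical form. Sibling
  label ties cannot occur (out-edge labels are unique per vertex) and this
  is asserted, not handled. Single-edge patterns are reported — single
  m/z differences do explain real network components. `ε` is an absolute
  graph count, default 2; `max_pattern_size` optionally caps reported edge
  counts and prunes enumeration at the corresponding vertex count.

The k-LMDF code emitted for each pattern appends the full edge list written
on min-path vertex names, making equal codes equivalent to isomorphism even
for AFGs from databases where the closure property does not hold.

## Scoring and network coupling

A pattern's support `D(P)` is scored against a target spectrum set `D(T)`
as a binary classifier: precision `|D(P)∩D(T)|/|D(P)|`, recall
`|D(P)∩D(T)|/|D(T)|`, F1 their harmonic mean (0 when both are 0).
Singleton concepts are rejected; concepts with identical member sets
collapse to the deepest when depth metadata exists, otherwise all are kept
and flagged. Network coupling consumes a 3-column edge list (or GraphML) —
spectral similarity is never computed here — and extracts connected
components, greedily chosen pairwise-disjoint maximal cliques of a minimum
size (largest first, lexicographic ties, re-examined on the residual graph
after each pick), and pairs above a similarity threshold. Patterns are
ranked per component by recall, then precision, then pattern edge count
(the "size" used in tie-splitting; vertex count would order identically for
all but closure-heavy patterns), then id.

## Synthetic benchmark

The generator emulates what a small library looks like to this pipeline —
not fragmentation chemistry. Each spectrum is a precursor peak plus peaks
at subset-sums of neutral losses below it, with Gaussian per-peak mass
jitter (default 3 ppm, Orbitrap-scale) and uniform noise peaks (default 5)
in a low intensity band so the planted peaks always survive top-15
selection (a low-band mode exists to stress selection instead). Planted
patterns are loss cascades over a vocabulary of real losses (H2O, NH3, CO,
CO2, CH2O2, CH4S, ...; pairwise separation > 0.02 Da so bins never
collide); their templates are chosen so every pairwise offset difference is
either formula-feasible in 14–200 Da or below the window. Defaults: 20
spectra, 350–900 Da precursors, one pattern planted in 5 carriers.

Background (non-carrier) spectra come in two flavours. `private` (default)
gives each background its own random losses, rejection-sampled so that no
within-spectrum difference falls within 0.05 Da of a planted value: the
planted support is then exact by construction and recovery can be asserted
without slack. `families` groups backgrounds into trios sharing one
feasible loss cascade, emulating the families of related compounds that
make real libraries dense in shared differences; this mode is used to
study triangle closure at realistic graph density. Neither mode reproduces
real data's intensity structure, isotopes, adducts or correlated mass
errors — passing the benchmark shows the pipeline's combinatorial machinery
is correct under controlled mass arithmetic, not that real libraries will
yield chemically meaningful patterns.

The brute-force miner enumerates every rooted induced flow subgraph of
every graph (≤ 8 vertices guarded), groups them by an exhaustive canonical
naming (vertices named by their lexicographically smallest root label
path), filters by graph-counted support and discards patterns dominated by
a strictly larger equal-support pattern found by embedding search. On exact
databases — where every frequent path closes — it mines exactly the class
the k-path-tree algorithm targets, and the two outputs are compared
set-equal on 200 seeded random databases. Oracle databases place vertices
on an integer mass lattice with a low-mass floor, which keeps closure exact
while letting topology vary freely.

## Known limitations

* When per-peak mass jitter on heavy ions approaches the `dmz` bandwidth
  floor (≈ 5 ppm at 700–900 Da against 0.005 Da), difference clusters can
  split across bins and planted support erodes; raising `dmz` trades this
  against wider, less specific bins (the same trade-off that produces
  occasional wide bins at 15 ppm on real data).
* Coincidental near-equal differences between unrelated spectra form
  legitimate low-support bins; on sparse synthetic libraries these dominate
  the all-2-paths triangle audit, which is why the validity rate is
  measured on frequent 2-paths over libraries dense enough (hundreds of
  triangles) for a sub-1% rate to be resolvable.
* Support on binned (non-exact) data counts occurrences of the spanning
  tree; the closure edges are verified separately rather than per
  occurrence. On exact data the two notions coincide.
* The reference correction rule for labeling errors and the exact
  supplementary binning details are not public; the repair mode and the
  bin-boundary/merge rules above are this package's own reasoned choices.
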