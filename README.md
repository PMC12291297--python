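# ms2patterns

Exact fragmentation-pattern mining in MS/MS spectral libraries.

Identifying unknown metabolites from tandem mass spectrometry is hard when a
spectrum matches nothing in a database. One powerful signal that remains is
*shared fragmentation*: groups of related compounds lose the same neutral
masses (H2O, CO, NH3, amino-acid residues, ...) in the same arrangement.
`ms2patterns` finds these shared arrangements *de novo* — without knowing any
molecular formula — by

1. representing every spectrum as a **fragmentation graph**: a directed
   acyclic graph whose vertices are the most intense fragment ions and whose
   edges are binned m/z differences (heavier → lighter), drawn from one
   label alphabet `L(D)` shared across the whole library, and
2. mining all **closed frequent rooted subgraphs** (fragmentation patterns)
   of the library with a dedicated frequent-subgraph-mining algorithm.

Patterns are *exact*: every m/z difference of a pattern is present in every
spectrum of its support. They can then be scored against chemical-class
memberships (precision / recall / F1) or used to annotate the components of
a precomputed molecular network (e.g. a GNPS export).

## The method in brief

For a library `D` of spectra reduced to their `n = 15` most intense peaks:

* **Alphabet.** All pairwise differences `mz_i − mz_j` are pooled and binned
  by a Gaussian kernel density estimate with location-dependent bandwidth
  `h(d) = max(dmz, d · ppm · 10⁻⁶)` (defaults `ppm = 15`, `dmz = 0.005` Da);
  bins are split at density minima, kept when ≥ `f = 2` distinct spectra
  contribute, and annotated with candidate neutral formulas (CHNOPS
  enumeration under the Senior conditions, plus two-formula combinations
  such as H2O + H2O) inside the 14–200 Da window. In-window bins with no
  feasible formula are discarded; heavier bins are kept unannotated.
* **Graphs.** Each spectrum becomes a DAG with an edge per binned
  difference. Because labels are mass differences, two edges of a path force
  the closing edge between its endpoints (18.0106 + 43.9898 = 62.0004:
  H2O → CO2 closes as CH2O3), so every frequent pattern is an **acyclic flow
  graph** (AFG) containing the star of edges leaving its root.
* **Mining.** A *k-path tree* indexes every potentially frequent directed
  path of length ≤ k with its last label `l`, closing label `h` and
  occurrence list `o`. Candidate patterns are subtrees of this tree,
  enumerated once each by right-most path extension and kept when they map
  to a proper spanning tree (distinct `h` per vertex), are in k-LMDF
  canonical form (left-most depth-first, minimum label first), and reach the
  support threshold `ε` (default 2 graphs). Surviving subtrees are rebuilt
  into full AFGs from their occurrences and reported when **closed**: no
  one-edge root extension (incoming or outgoing) shared by the whole support
  exists (the E_in / E_out check).

## Worked example

Simulate a 20-spectrum library in which 5 spectra carry a planted
double-water loss cascade, then mine it:

```sh
ms2patterns simulate --out lib.mgf --truth truth.json --seed 3 --jitter-ppm 0
ms2patterns mine lib.mgf --out patterns.json --min-supp 5
```

```
wrote 20 spectra to lib.mgf
INFO ms2patterns.pipeline: alphabet: 8 labels
INFO ms2patterns.pipeline: graphs: 20, edges: 27
INFO ms2patterns.pipeline: mining: 5 candidates, 0 infrequent, 1 non-spanning,
                           1 non-canonical, 2 non-closed, 1 patterns
1 closed patterns -> patterns.json
```

The bundle contains one closed pattern, supported by exactly the five
carrier spectra:

```
pattern 0  support ['S001', 'S003', 'S004', 'S012', 'S019']
   0 -> 1   18.0106  H2O
   0 -> 2   36.0211  H4O2 (= H2O + H2O)
   1 -> 2   18.0106  H2O
```

Read: the pattern's root ion (vertex 0) loses water to vertex 1, which loses
water again to vertex 2; the transversal 36.0211 difference is the sum of
both steps — chemically meaningless as a single loss, but a real, frequent
m/z difference that makes the pattern a triangle rather than a chain. The
noise differences of the library form bins too (e.g. 284.1024), but none of
them reaches support 5, so no spurious pattern is reported.

Downstream, `ms2patterns score` evaluates every pattern against a
two-column `spectrum-id ↔ concept` table as a binary classifier (a pattern
supported by 3 spectra all inside a 4-member concept scores precision 1.0,
recall 0.75, F1 0.86), and `ms2patterns explain` extracts connected
components, disjoint cliques and high-similarity pairs from a molecular
network edge list and reports the pattern of highest recall for each
(precision, then pattern size, split ties).

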