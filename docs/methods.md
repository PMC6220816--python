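# Methods

This note records the models and algorithms implemented in `genefunc`,
the defaults they run with, and the design choices made where more than
one reasonable concretization existed.

## Evidence model

The unit of evidence is a *positive report*: one published association of
a gene's variant with the phenotype in one clinical setting. Reports are
deduplicated to at most one record per (gene, setting) pair, so a gene's
score is the number of distinct settings implicating it, never the number
of publications. Setting labels come from a controlled vocabulary
(default: the eight persisting-pain settings — back, inflammatory,
musculoskeletal, neuropathic, visceral, widespread, idiopathic,
miscellaneous); an unknown label is a hard error rather than a silent new
category, and one symbol carrying two different NCBI ids aborts parsing
as a data-entry guard. Gene identity is the symbol (case-insensitive in
set operations), with the NCBI id carried as provenance.

## Ontology and annotation

An ontology is a rooted DAG of terms. The three edge relations
(`is_a`, `part_of`, `regulates`) are treated identically for ancestry and
propagation — the analyses here never need to distinguish them.
Annotations follow the true-path rule: a gene annotated to a term is
implicitly annotated to every ancestor, so the root annotates the entire
universe *N*. A namespace filter (default `biological_process`) is
applied at parse time; obsolete terms are kept as flagged, edge-less
records and annotations to them are dropped with a warning count. The
OBO reader is deliberately minimal (ids, names, namespaces, obsolete
flags, the three relations); full evidence-code semantics of GAF files
are out of scope — the GAF reader takes columns 2 and 5 and skips `NOT`
qualifiers only.

## Overrepresentation analysis

For query size *n*, universe *N*, term size *K* and overlap *k*, the raw
p-value is the hypergeometric upper tail P(X ≥ k), computed via scipy's
log-space survival function. Defaults: raw threshold `tp = 1e-6`,
Bonferroni family-wise cut-off 0.05, and `min_term_size = 1`, i.e. every
term annotating at least one background gene is tested and counts toward
the Bonferroni factor *m*. A term is significant only if it passes both
thresholds. Query genes missing from the universe are dropped with a
warning (a gene unknown to the ontology cannot be tested), and *n* is the
resolved query size. Only enrichment is tested; depletion and FDR-style
corrections are deliberately absent.

## Feature matrix

The clustering feature space is the binary genes × significant-terms
matrix with entry 1 where the (propagated) annotation holds. Columns
constant across all genes — the root term is the canonical case — carry
no Euclidean distance information and are removed; rows left all-zero are
dropped with a warning. Row and column order is lexicographic, making
exports byte-reproducible.

## ESOM, height matrices, watershed

The SOM is a 25 × 35 toroid grid (875 neurons, comfortably more than the
~100 data rows it is sized for, which is what makes the map *emergent*),
trained online for 25 epochs: per epoch the rows are shuffled (seeded),
each row's best-matching unit (BMU) is found by Euclidean distance (ties
to the lowest (row, col) index), and all neurons move toward the row by
`rate * exp(-d²/2σ²)` with toroidal grid distance `d`. Rate decays
linearly 0.5 → 0.05 and radius `σ` from max(rows, cols)/2 → 1 across
epochs; weights initialize uniformly within each column's data range.
Everything is driven by one seeded generator, so training is
bit-reproducible.

Heights: the **U-matrix** is the mean weight distance to the 8 toroidal
neighbours (on degenerate grids smaller than 3 × 3 the mean runs over the
distinct neighbours). The **P-matrix** counts data rows within radius
*r* of each neuron's weight; `r="auto"` uses the 20th percentile of all
pairwise data distances (a Pareto-radius heuristic — the radius itself is
recorded in the grid's JSON sidecar). The **U\*-matrix** attenuates U by
density: `U* = U * clip((Pmax − P)/(Pmax − Pmedian), 0, 1)`, 0 everywhere
when the density grid is flat. Dense valleys are flattened; ridges in
sparse regions survive.

Clusters are read algorithmically rather than visually: cells are
processed in ascending U\* height (ties by grid position), each local
minimum seeds a basin, cells join the lowest-minimum neighbouring basin,
and two basins merge when the ridge where they meet is lower than
`ridge_threshold` (default 0.5) times the landscape maximum. Genes
inherit the basin of their BMU; labels are compacted to 1..k in order of
basin depth. A flat landscape yields a single cluster with a warning.

## Computed ABC analysis

Items sorted by descending value (id as tiebreak) give the curve
(x_i = i/n, y_i = S_i/S_n). Two landmarks are computed:

* **Pareto point** — the curve vertex minimizing distance to (0, 1),
  earliest on ties;
* **break-even** — the boundary just before the first item whose segment
  slope `n·v_i/S_n` drops to ≤ 1, i.e. x = (i\*−1)/n.

The A|B limit is the smaller of the two x-positions, B|C the larger.
Items are assigned by position and then any equal-value group straddling
a limit is demoted whole toward C (a group across A|B goes to B; one
across B|C, or across both, goes to C), so equal scores never split
across sets. Consequences worth knowing: an all-equal vector puts
everything in C, and on the packaged evidence table the partition is
A = the 22 multi-setting genes, B = ∅, C = the 88 singletons — the
A ∪ B selection used downstream. The curve is piecewise linear; no
smoothing is applied.

## Functional abstraction

The induced DAG is the union of the significant terms and all their
ancestors; non-significant nodes kept for connectivity are `connector`s,
and induced nodes without induced children are the DAG's leaves.
Headlines are chosen by greedy weighted set-cover over all non-root
induced nodes, scored `coverage · precision / (1 + depth)`: coverage is
the fraction of all significant terms in the candidate's induced
descendant closure (self included), precision the significant fraction of
that closure, and depth the longest path from the root (so among equal
covers the more general term wins, while the root itself is excluded as
vacuous). Selection stops when all significant terms are covered, the
`min_coverage` fraction (default 1.0) is reached, or `max_areas`
(default 7, a conciseness cap) headlines are chosen. The exact scoring
is recorded with each area, and ties break on term id. The gene × area
matrix marks gene membership in each headline's propagated annotation
set.

## Synthetic data

`SynthSpec` defaults describe the study conditions the pipeline is tested
under: a 250-term, depth-5 ontology (each term with 1..2 parents, built
level by level so it is acyclic and single-rooted by construction) over
1000 genes; three disjoint planted modules of 20 genes, each enriched in
its own disjoint block of 8 terms with hit probability `p_in = 0.9`
against background probability `p_out = 0.01`; and evidence tables in
which 80% of genes have one setting and the rest a uniform 2..5.
`terms_per_module = 8` sets the size of each planted enriched block.
These corpora emulate the *statistical* structure the analyses assume —
enriched term blocks, a sparse annotation background, Pareto-like setting
counts — and deliberately not the topology of a real ontology release
(term-size power laws, cross-namespace links) or literature biases in
which genes get studied. Passing tests therefore demonstrate that the
algorithms recover known structure under these conditions, not that any
particular real-data result is correct.

## Numerical and degenerate-input choices

* Fisher tails come from `hypergeom.sf`, exact to ~1e-12 relative against
  integer enumeration up to N = 30; `k = 0` returns exactly 1.0.
* BMU ties, watershed cell order, set-cover ties and ABC item ties all
  break deterministically (grid index / term id / item id).
* Pipeline stage seeds derive from the config seed by SHA-256 of the
  stage name, so stages are individually reproducible and all derived
  seeds stay below 2³¹.
* Problem sizes in the test suite (universes of 600–1000 genes, 10 seeds
  per clustering condition, exhaustive Fisher checks to N = 30) were
  chosen to exercise each method's operating regime while keeping the
  whole suite under a minute of CPU apart from the clustering benchmark.

## Known limitations

* Counts that depend on a specific ontology release (how many processes
  come out significant for the packaged gene table, the exact cluster
  sizes, the identities of the seven published functional areas) are not
  reproducible from fixtures and are not targeted by tests; the packaged
  area grid is a transcription used for validating the bookkeeping, not a
  recomputation.
* The ESOM training schedule is one reasonable concretization; published
  ESOM implementations differ in neighbourhood kernels and decay, and
  cluster counts on weakly separated data are sensitive to
  `ridge_threshold`.
* The abstraction scoring is a documented stand-in for "informational
  value and conciseness", which have no single canonical definition.
* Annotation evidence codes are ignored; modules in the generator are
  disjoint, so overlapping-pathway recovery is untested.
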