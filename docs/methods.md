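# Methods

## Distance-threshold species delimitation

Distances are uncorrected p-distances with pairwise deletion: for each pair
only sites where both symbols are unambiguous nucleotides (A/C/G/T) are
compared; gaps (`-`), missing data (`?`, `N`) and partial IUPAC ambiguities
(R, Y, …) are excluded. Partial ambiguities are treated as missing rather
than as fractional matches — simpler and conservative, and at mtDNA
divergences the difference is negligible. A pair with fewer than
`min_overlap` jointly resolved sites (default 100) has an *undefined*
distance. Undefined distances never link in clustering; this prevents
spurious lumping through terminals represented by short fragment stubs,
and mirrors the practice of excluding barcode-less terminals from counts.

Two clustering rules share the same distance currency:

* **single linkage** — connected components of the graph joining pairs with
  defined `p ≤ t`. This is the reference method for headline counts: it is
  order-independent and matches the intuition that a chain of terminals
  each within *t* of the next is one variable species.
* **greedy** — an incremental rule for comparability with similarity-based
  tools: terminals are processed in descending ungapped length (ties broken
  by id), and each joins the first cluster whose *representative* is within
  *t*, else founds a new cluster. A similarity threshold *s* from such
  tools maps to `t = 1 − s` (0.98 → 2%, 0.95 → 5%). Greedy clustering never
  produces fewer clusters than single linkage.

Distances are computed on the given alignment, not by alignment-free
identity, so both methods see exactly the same data. The default threshold
sweep covers 1–10% in 1% steps; the grid is configurable because published
grids for this workflow are stated inconsistently (similarity steps that do
not reproduce the reported threshold set), so no single grid is hard-coded.

mOTU representatives are the longest-ungapped sequence per cluster, ties
broken by lexicographically smallest id — deterministic, and biased toward
the most informative sequence. Counts can exclude clusters in which no
member carries a required fragment (typically *cox1*), since such clusters
are delimited on other markers and are not comparable with barcode counts.

## Alignment quality screens

Three screens flag violations of the stationarity/reversibility/homogeneity
assumptions behind standard substitution models:

* **RCFV** (relative composition frequency variation): with per-taxon state
  frequencies `f_ts` over resolved sites and across-taxa means `m_s`,
  `RCFV = Σ_t Σ_s |f_ts − m_s| / n_taxa`. The exclusion rule flags a
  partition as compositionally heterogeneous at RCFV ≥ 0.1. Taxa with no
  resolved sites in a partition are excluded from the frequency
  calculation with a warning; a partition with fewer than two usable taxa
  is dropped with reason `insufficient_data`.
* **Bowker's maximum symmetry test** per taxon pair: the 4×4 substitution
  count matrix `n_ij` is tabulated over jointly resolved sites and
  `S = Σ_{i<j, n_ij+n_ji>0} (n_ij − n_ji)²/(n_ij + n_ji)` is referred to a
  chi-square with df equal to the number of included pairs (the standard
  df convention — pairs with zero total contribute neither to S nor to
  df). If no off-diagonal pair has counts (e.g. identical sequences), the
  result is degenerate with p = 1. A partition is dropped when its
  *minimum* pairwise p-value falls below α = 0.05; min-p was chosen over
  the proportion-failing aggregate because it matches the "any strongly
  asymmetric pair disqualifies the partition" reading of the exclusion
  rule, and both quantities are reported so the choice is transparent and
  configurable.
* **Completeness** `Ca`: the fraction of matrix cells that are unambiguous
  nucleotides, overall and per taxon. Replacing cells with `?` can never
  raise it.

The pairwise-symmetry summary is the matrix of Bowker p-values plus the
fraction of failing pairs; no additional pooled statistic is invented.

## Tree comparison and backbone constraints

Splits are nontrivial bipartitions, canonicalized as the side not
containing the lexicographically smallest shared leaf. Trees over different
taxon sets are compared after restriction to their shared leaves (at least
four required). The Robinson–Foulds distance is the size of the symmetric
difference of split sets; the normalized value divides by `2(n−3)`, the
maximum for binary unrooted trees. Multifurcating inputs are accepted; they
simply cannot attain normalized 1.0, and no rescaling is applied.

Replicate-run stability is summarized by the pairwise normalized RF matrix.
Rogue terminals are ranked by an instability score: the mean, over tree
pairs, of the drop in normalized RF when the leaf is pruned — a
reproducible surrogate for visual cophylogeny inspection of wandering
terminals.

A backbone constraint is a tree over anchor taxa (multifurcations allowed);
taxa not on the backbone are free. A full tree complies when its
restriction to the anchors displays every nontrivial backbone split, so
compliance is invariant to where free taxa attach.

## Quartet support and likelihood mapping

For each internal branch of a binary reference tree, the four blocks of the
branch's quadripartition are enumerated; branches incident to polytomies
have no unique quadripartition and are skipped. Quartets take one leaf per
block (exhaustive up to a per-branch cap of 1000, uniform seeded sampling
above it). A gene tree's induced quartet topology is read from topological
path lengths via the four-point condition, which also detects unresolved
(polytomous) quartets; gene-tree branches at or below a support threshold
can be collapsed first. Frequencies are reported over resolved induced
quartets; a branch with no usable quartet in any gene tree reports NaN.

FcLM evaluates, per sampled quartet, the maximized log-likelihood of the
three quartet topologies under JC69 with all five branch lengths optimized
numerically (L-BFGS-B, bounds [1e-8, 20] expected substitutions/site, two
starting points 0.1 and 0.5 to avoid flat-likelihood local optima, site
patterns compressed to at most 256 counts). Weights are the softmax of the
three log-likelihoods; each quartet is assigned to the basin of its argmax
topology, with ties (top-two weight difference below 1e-6, e.g. identical
sequences) reported as unresolved. The classical seven-region simplex
geometry is deliberately not implemented: the reported quantity is the
basin share, which is what single-percentage FcLM summaries correspond to,
and the three-basin + unresolved partition is sufficient for that. JC69 is
used rather than richer models because the quartet-mapping mechanics — not
model realism — are what the package tests; quartets whose four sequences
share fewer than `min_overlap` sites are skipped and counted.

## Inventory accounting

A region table row holds described species counts and mOTU counts per
threshold; an mOTU increments every region where at least one member
occurs, so a TOTAL row (each mOTU once) and a TOTAL_BY_OCCURRENCE row
(column sums) are both emitted — published tables of this kind are additive
only when regions rarely share mOTUs, and emitting both makes the
difference visible. Ratios are rounded half-up to two decimals (the
convention that reproduces published ratio columns from their integer
counts); a ratio with zero described species renders as an em dash.
Endemic mOTUs are those whose occurrences fall in a single region or
landmass. Turnover counts mOTUs spanning at least two landmasses, once per
barrier class among the landmass pairs they span; barrier classes
(deep sea > 200 m, shelf < 100 m, contiguous) are data supplied as a
symmetric landmass-pair map, never hard-coded geography.

## Synthetic data generator

The generator emulates the statistical structure the inventory machinery
assumes:

* a Yule species tree (direct pure-birth simulation; the tips are extended
  past the last split by one more exponential draw so every pendant branch
  is positive), scaled to a root height of `tree_depth` (default 0.5
  expected substitutions/site) and rescaled up if needed so the minimum
  inter-tip path is at least `inter_min` (default 0.08);
* per species, 5 terminals by default (uniform bounds configurable), each
  on a pendant branch U(0, `intra_max`/2), so within-species pairwise
  divergence is at most `intra_max` (default 0.005) and half that in
  expectation;
* JC69 sequence simulation per fragment (optional gamma site rates), with
  fragment lengths 1100/800/1210 matching a typical three-fragment mtDNA
  panel, and per-terminal fragment missingness with defaults 0.077 (cox1),
  0.630 (rrnL), 0.502 (nad5) reflecting how much rarer the non-barcode
  fragments are in voucher panels; a terminal that would lose every
  fragment keeps the most reliably sequenced one;
* island geography: each species draws a home landmass, stays endemic with
  probability `endemism_p` (default 0.95), otherwise adds further
  landmasses with probability `dispersal_p` each (at least one forced).
  The default is chosen to keep the regime "very high endemism" — real
  inventories of poorly dispersing beetles find ≈99% landmass endemism —
  while still exercising the turnover classifier at the 50-species desk
  scale. Terminals cycle round-robin over their species' landmasses, and
  the emitted truth records the realized occupancy, so truth-recovery
  comparisons are exact by construction.

Distances are stated in expected substitutions/site and converted to
observable p-distances through the JC expectation
`P(d) = ¾(1 − e^(−4d/3))`, so the barcode gap (0.5% within, ≥ 8% between,
i.e. ≈ 7.7% observable) is probabilistic: at fragment length ~1000 the
binomial noise is ~0.8% SD, leaving the 2% and 5% thresholds several SDs
inside the gap. The generator does **not** emulate alignment error,
indels, pseudogenes/numts, introgression, or incomplete lineage sorting
between species — so passing recovery tests shows the thresholding and
accounting machinery is correct under a clean barcode gap, not that real
data will have one.

All randomness derives from one mandatory seed through
`numpy.random.SeedSequence` stream splitting (one child per stage: tree,
populations, per-fragment sequences, geography, subtribe assignment,
missingness), making stages individually reproducible and emitted files
byte-identical across runs.

## Numerical choices and tie rules

* NJ and UPGMA break ties by the lowest row-index pair, so output is
  deterministic for a fixed input order; both reject matrices with
  undefined entries rather than imputing silently. Tiny negative NJ branch
  lengths from floating-point noise are clamped to zero.
* Greedy clustering is order-independent because its processing order is
  (descending ungapped length, id), not file order.
* Partition coordinates are 1-based inclusive in files (RAxML-style
  `DNA, cox1 = 1-1100`) and 0-based half-open internally; the conversion
  happens in exactly one place.
* The missing-fragment fill character is `?`, distinct from the alignment
  gap `-`; both are missing downstream.
* Pipeline problem sizes (replicate count 5 for stability, quartet caps,
  50-species default simulations) are desk-scale defaults chosen so a full
  run completes in seconds while every code path is exercised; all are
  configurable upward.

## Known limitations

* The RF-stability stage builds replicate trees by NJ on bootstrap-resampled
  columns — a desk-scale stand-in for replicate heuristic ML searches, and
  its absolute RF values are not comparable to those from constrained ML
  replicates on real data.
* Quartet support requires a binary reference tree around the branch of
  interest; branches at polytomies are skipped rather than approximated.
* FcLM is JC69-only; systematic bias from compositional heterogeneity —
  one motivation for likelihood mapping on real data — is therefore
  outside what the implementation can itself exhibit.
* The greedy clusterer reproduces the decision rule of similarity-based
  tools on the given alignment; it is not a reimplementation of any
  specific tool's alignment-free identity computation.
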