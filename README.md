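# motuinv

A toolkit for DNA-based biodiversity inventories of hyperdiverse taxa —
built around the workflow used for large tropical beetle radiations, where
thousands of voucher specimens are sequenced for a few mitochondrial
fragments (*cox1*, *rrnL*, *nad5*), clustered into molecular operational
taxonomic units (mOTUs) at fixed distance thresholds, anchored to a
phylogenomic backbone, and summarized as regional diversity, endemism and
turnover tables.

It is aimed at systematists and biodiversity scientists who need the
quantitative steps of such an inventory as tested, scriptable components
rather than a chain of one-off external tools.

## What it computes

**mOTU delimitation.** Pairwise uncorrected distances with pairwise
deletion: for sequences *x*, *y*, `p(x,y) = mismatches / jointly resolved
sites`, undefined below a minimum overlap. Clustering at threshold *t*
either by single linkage (connected components of the graph linking pairs
with `p ≤ t`) or by a greedy CD-HIT-style rule (longest sequences first,
join the first cluster whose representative is within *t*; similarity *s*
corresponds to `t = 1 − s`). Threshold sweeps, representative selection,
and counts that exclude clusters lacking the barcode fragment.

**Alignment QC.** Per-partition screens for violations of
stationarity/reversibility/homogeneity: relative composition frequency
variation `RCFV = Σ_t Σ_s |f_ts − mean_s| / n_taxa` (heterogeneity "high"
at RCFV ≥ 0.1), Bowker's maximum symmetry test
`S = Σ_{i<j} (n_ij − n_ji)² / (n_ij + n_ji)` with df = number of non-empty
pairs and rejection at p < 0.05, and the completeness score `Ca` (fraction
of unambiguous cells). Partitions failing either rule are dropped with the
reason recorded.

**Tree comparison.** Robinson–Foulds distances on the shared leaf set
(normalized by `2(n−3)`), RF matrices over replicate runs, a
rogue-terminal ranking (mean RF reduction when a leaf is pruned), and
backbone constraints: writing a constraint tree over anchor taxa and
checking whether a full tree, restricted to the anchors, displays every
backbone split.

**Quartet measures.** Per-branch quartet support from gene trees — for the
quadripartition (A,B | C,D) around an internal branch, the frequencies
(q1, q2, q3) of the three quartet resolutions across gene trees, with
optional collapsing of weakly supported gene-tree branches — and
four-cluster likelihood mapping (FcLM): per sampled quartet, maximized
Jukes–Cantor log-likelihoods of the three topologies give weights
`p_i ∝ exp(ℓ_i)`, and quartets are assigned to likelihood basins.

**Inventory accounting.** Per-region described-species versus mOTU counts
with half-up-rounded analyzed/described ratios, endemism tables, and
cross-landmass turnover classified by sea barrier (deep sea > 200 m,
inundated shelf < 100 m, contiguous).

**Synthetic data.** A generator with known truth: Yule species tree with a
guaranteed interspecific floor, terminals sampled within an intraspecific
ceiling (the "barcode gap"), Jukes–Cantor sequence simulation, island
geography with tunable endemism, and per-fragment missingness — used by
the test suite for parameter-recovery checks.

## Worked example

Simulate a 12-species dataset, delimit mOTUs, and build the inventory
tables:

```
$ motuinv simulate --seed 7 --n-species 12 --out demo
$ motuinv cluster demo/cox1.fasta -t 0.05 --out demo/motus.tsv
12 mOTUs at 0.05
$ motuinv sweep demo/cox1.fasta --grid 0.01,0.02,0.05,0.08 --out demo/sweep.tsv
$ cat demo/sweep.tsv
threshold       motus
0.01    12
0.02    12
0.05    12
0.08    11
$ motuinv inventory demo/motus.tsv --metadata demo/metadata.tsv \
      --barriers demo/barriers.yaml --out demo/inv
global landmass endemism: 0.917
$ cat demo/inv/turnover_counts.tsv
        motus
deep_sea        1
shelf   0
contiguous      0
```

The sweep is flat at the true species number (12) across the barcode gap
and only starts lumping once the threshold reaches the interspecific scale
(11 mOTUs at 8%). One simulated species spans two landmasses separated by
deep sea; the other eleven are single-landmass endemics, giving the 0.917
endemism proportion.

`motuinv run config.yaml --out outdir` executes the whole pipeline
(simulate/load → distances → clustering and sweep → representatives → QC →
backbone compliance → replicate-tree stability → quartet support →
inventory tables) and writes a checksum manifest; reruns with the same
seed are byte-identical.

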