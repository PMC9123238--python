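# Methods

This note documents the models and procedures `hsfkit` implements, the
defaults that matter, what the synthetic generators do and do not
emulate, and the numerical/design choices made where the design was
genuinely open.

## Family cataloguing

A gene is a family member iff it carries at least one profile-domain hit
with the family accession (default `PF00447`, the HSF-type DNA-binding
domain) and a per-domain e-value **strictly below** `e_max = 1e-4`. The
boundary value 1e-4 is excluded; membership is therefore monotone
non-decreasing in `e_max` and idempotent under re-selection. The
per-domain (independent) e-value is used rather than the full-sequence
one; this is configurable at the IO layer by choosing which HMMER column
set to ingest. Optional secondary hit tables (e.g. a second domain
database used for validation) are combined by intersection — no member
without support in both tables.

Isoform handling: one record per locus, keeping the longest protein;
exact length ties break to the lexicographically smallest gene id so the
result is order-independent. Summary statistics report counts, count
ratios (family / genome genes, 0–1 internally; percent only at the
reporting layer, rounded half-to-even), log2 family counts with zero
counts reported as missing rather than −∞, and mean-protein-length
ratios.

## Motif states and Dollo trajectories

Per species and motif, the state is *complete* (all family genes carry
it), *absent* (none), or *partial* (some). For trajectory placement a
motif is treated as present in a species when the state is complete or
partial — partial loss within a species is reported in the state table
and deliberately not collapsed into the trajectory. No fractional
threshold distinguishes partial from complete; the all/some/none
trichotomy is the model.

Under Dollo parsimony the gain is placed on the branch above the MRCA of
all carrier species; the losses are the maximal carrier-free subtrees
below the gain node. That set is the unique minimal explanation given a
single gain at the MRCA, and no higher gain placement can do better
(moving the gain up can only add carrier-free subtrees); the test suite
verifies minimality by exhaustive enumeration of all (gain, loss-set)
scenarios on trees up to 7 leaves, including polytomies. A motif present
nowhere yields an empty trajectory rather than an error.

## LCA reconciliation

Gene trees must be rooted and binary; species trees may be
multifurcating. With *M(v)* the LCA in the species tree of the species
below gene-tree node *v*: *v* is a duplication iff *M(v) = M(c)* for
some child *c*, else a speciation. Losses on a gene-tree edge (*u*→*v*)
with species-path length *d* from *M(u)* to *M(v)*: *d*−1 if *u* is a
speciation (its split *is* the first speciation on the path), *d* if a
duplication (the copy starts at *M(u)* and must survive every speciation
on the way down). Each unit loss is attributed to the off-path sibling
branch of the species node the lineage passes — with species tree (A,B)
and gene tree (a1,(a2,b1)), the copy ancestral to a1 is lost on the
branch to B. When the passed node is a polytomy the off-path side is not
a single branch; the loss is then recorded on the name-sorted first
off-path child, an explicitly arbitrary but deterministic choice that
leaves totals unchanged.

This reconciliation minimises duplications + losses; the suite checks
optimality against exhaustive search over all valid node mappings —
completely for gene trees up to 4 leaves over 2–3-species trees, and on
a seeded sample of 300 gene trees with 5–6 leaves over a 4-species tree.
The full cross product at 6 leaves (≈ 3.8 M reconciliations, each with
its own exhaustive oracle) adds no property coverage and is out of
proportion for a test suite, so the sample stands in for it. No
automated rooting is applied; midpoint rooting is available only as an
explicit CLI flag and is logged when used.

## Duplicate classification

Gene-rank coordinates (the 1-based order of genes along each chromosome)
drive all distance rules, matching MCScanX semantics and making planted
ground truth exact. Collinear blocks are chained per chromosome pair by
O(n²) dynamic programming: strictly monotone anchor ranks on both
chromosomes (increasing, or increasing/decreasing for inverted blocks),
consecutive-anchor gaps ≤ `max_rank_gap = 25`, blocks below
`min_pairs = 5` discarded. The longest chain is extracted, its anchors
retired, and the search repeats; ties break toward the smallest starting
rank (and same-orientation first), so the output is invariant to input
order. Defaults mirror MCScanX's; all are exposed.

Classification precedence per gene: block anchor → `wgd_segmental`;
homolog at rank distance 1 on the same chromosome → `tandem`; within
`proximal_max_gap = 10` → `proximal`; any homolog → `dispersed`; none →
`singleton`. Every gene gets exactly one class.

The χ² enrichment test is 2×2 (focal class vs rest × family vs genome)
without continuity correction, flagged at *p* < .01. When the genome
side is known only as a proportion, a one-sample χ²(1) goodness-of-fit
against expected counts *n·p* / *n·(1−p)* is used instead; a zero
expected cell raises with a pointer to an exact test. When all five
classes are screened, Bonferroni over the five tests is the caller's
responsibility (a helper reports per-class results).

## Networks and enrichment

Regulatory edges are kept at score ≥ 0.60 (inclusive, as the source
database defines its cutoff). Downstream genes are targets of family
regulators, upstream genes are regulators of family targets, and the
feedback set is their intersection.

Co-expression uses the Pearson correlation across the provided sample
columns (sample, n−1 normalisation) with **strict** thresholds: an edge
requires PCC > .95 or PCC < −.95 exactly as printed. At least 3 samples
are required; zero-variance genes cannot carry a correlation and are
excluded with a warning. Whether the correlation uses only the
heat-treatment series or also tissue samples is a data choice, not a
code path: the caller passes whichever columns apply (the simulator's
default is the 5-sample heat series). Edges within one family can be
kept or dropped (`cross_family_only`); the default keeps them, since the
analysis correlates *any* two genes of the chosen families.

Term enrichment: only annotated genes enter the counts (n = annotated
targets, N = annotated background); per term, *p* = upper-tail
hypergeometric P(X ≥ k), equivalent to a one-sided Fisher test;
*q* = Bonferroni min(1, m·p) with m = the number of terms observed at
least once among targets (keeping q well-defined and matching common
practice); fold = (k/n)/(K/N); significant iff q < .05 and fold > 2.

## Promoters and the heat-shock element

Promoters are the `length = 2000` bases immediately upstream of the
translation initiation site (CDS start, not transcript start), truncated
at chromosome edges, reverse-complemented for minus-strand genes so
every promoter reads 5′→3′ toward its gene. The HSE scan matches the
13-nt consensus `GAAnnTTnnnGAA` with n ∈ {A,C,G,T}; windows containing N
never match. Both strands are scanned by default (the minus strand as
`TTCnnnAAnnTTC` on the forward sequence, reported with strand − and
forward-coordinate offset); a single-strand mode reproduces a stricter
reading. All overlapping matches are reported — the downstream
"HSE-positive" predicate is ≥ 1 hit, so overlap handling cannot change
gene-level conclusions. Offsets are 0-based internally, 1-based
inclusive in written tables (stated in the file header).

The HSE-restricted subnetwork keeps co-expression edges whose Hsp-family
endpoints are all HSE-positive; Hsf endpoints are always kept.

## Pan-genome retention

Syntenic assignment (which copy pairs with which reference gene) is an
input table — producible by running the collinear chainer cross-species
— so the triplication bookkeeping is independently testable. Each
(reference gene, accession, subgenome) slot holds at most one copy;
conflicting duplicates are rejected rather than collapsed because the
0–3 copy framing assumes a single surviving homeolog per subgenome
(LF, MF1, MF2). The matrix entry is the number of retained subgenomes;
summaries report distinct syntenic copies and their ratio to the
accession's family size, and the loss report flags genes with zero
copies per accession and genes lost in every accession.

## Synthetic data

The generators are test instruments: they emulate the statistical
structure each analysis assumes, not real genomes.

- **Birth–death families**: one ancestral gene enters the root; along
  each branch every lineage duplicates at rate λ or dies at rate μ with
  exponential waiting times, and splits at speciations. The species tree
  is clock-scaled to unit root-to-tip depth so rates read as expected
  events per gene per tree height (defaults λ = 0.5, μ = 0.2, a mildly
  expanding family). The event log records every event's true branch;
  with μ = 0 the LCA reconciliation must recover the log exactly, which
  the suite checks over 500 replicates. With μ > 0 inferred counts are a
  parsimony lower bound — unobservable events are expected.
- **Planted genomes**: tandem (adjacent ranks), proximal (gap 2–10),
  segmental (copied runs of ≥ 5 genes on another chromosome) and
  dispersed (cross-chromosome singleton pairs) duplicates, spaced 26
  ranks apart — one more than the chaining gap cap — so features cannot
  interact and the labels are exact truth. Default 1000 genes with
  5/5/2(×6)/5 planted features.
- **Expression**: genes in a block share a standard-normal latent
  per-condition profile; a gene's FPKM is exp(αg + zc + σε), a per-gene
  multiplicative abundance offset on the shared profile. At σ = 0
  within-block PCCs are exactly 1 *after* exponentiation (a per-gene
  slope on the log scale would break that exactness), cross-block
  profiles are independent, and values are positive and right-skewed
  like FPKM. Because a handful of samples can produce chance cross-block
  correlations above the .95 edge threshold (exponentiation makes shared
  large values especially potent), latent profiles are redrawn until
  every cross-block pair of *exponentiated* profiles correlates at
  |PCC| ≤ 0.9, keeping the emitted truth exact at σ = 0. The default design is the heat series (control, T1, T4, T8,
  T12 at 38 °C), optionally plus a six-tissue panel (root, stem, leaf,
  flower, silique, callus); default noise σ = 0.3. Not emulated: library
  size effects, mean–variance coupling, and condition autocorrelation —
  so passing recovery tests show threshold/bookkeeping correctness, not
  robustness to real expression noise.
- **Promoters**: i.i.d. uniform background with HSE instances planted at
  non-overlapping recorded offsets/strands; the optional disruption is a
  fixed G→C at consensus position 1, which must abolish the match. The
  uniform background gives the closed-form expected hit rate
  2·(L−12)/4⁸ per promoter used in the Monte-Carlo check (within 3
  standard errors at 10⁵ trials).
- **Regulatory edges**: scored directed edges with planted downstream /
  upstream / feedback structure plus decoy edges strictly below the 0.60
  cutoff that assembly must drop.

All generators take an explicit `numpy.random.Generator`; identical seed
and configuration give identical output.

## Published-count arithmetic in `scripts/acceptance.py`

The survey-scale statistics (mean family size over 111 proteomes,
network coverage percentages, hub shares) are functions of published
count margins, not of raw data this package could re-derive offline. The
acceptance script therefore reconstructs minimal inputs realising those
margins — a per-species count vector with the published total, species
count and extremes; a co-expression network with the published edge
total, negative-edge count, node coverage, hub negative degree and
top-hub family composition — and recomputes every reported statistic by
running the package's summary functions on them. The synthetic-recovery
metrics in the same script run the full pipeline on seeded generator
output and report measured rates.

## Known limitations

- Loss *placement* inside species-tree polytomies is deterministic but
  arbitrary (totals are unaffected).
- The reconciliation is duplication–loss only; transfers are out of
  scope, and bootstrap-aware rearrangement of weakly supported gene-tree
  edges is not attempted.
- The block chainer is a clean-room chainer aimed at rank-coordinate
  exactness; it does not score gaps or e-values like full synteny
  pipelines and extracts anchor-disjoint blocks greedily.
- Motif matrices, gene trees and syntenic assignments are inputs:
  motif discovery, phylogeny inference and cross-species anchor calling
  are upstream of this package.
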