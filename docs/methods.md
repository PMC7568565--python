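# Methods

`wolbmag` implements the bespoke computational stages of a pipeline that
recovers and curates *Wolbachia* metagenome-assembled genomes (MAGs) from
host shotgun sequencing data: positivity screening and titer estimation,
taxonomy-guided contig binning, coinfection quality control, balanced
core-genome construction, and lineage/CI gene-enrichment testing. The
surrounding heavy machinery (read mapping, assembly, annotation, gene
clustering, alignment, tree inference) is deliberately out of scope; the
package consumes those tools' outputs in plain-text form and produces the
decisions and statistics in between.

## Positivity screening, prevalence and titer

A sample is *Wolbachia*-positive when the breadth of coverage (fraction of
reference positions covered at ≥ 1×) of at least one reference genome
strictly exceeds 50%. "Larger than" is read literally as a strict
inequality for both the breadth and depth thresholds, and the boundary
behaviour is tested explicitly: a breadth of exactly 0.50 is negative.

Prevalence is the proportion of positive samples per host species. Two
reporting guards limit small-sample noise: hosts with fewer than 7
screened samples are not reported at all, and hosts with zero positives
are reported only when at least 50 samples were screened (otherwise a 0%
figure would mostly reflect screening effort, not biology). A separate
threshold (4× mean depth by default) marks the samples deep enough for
assembly; the reporting level for prevalence is configurable so screens
can be summarised at 1× detection or at assembly-grade depth.

The titer approximates symbiont cells per host cell:

    titer = (wolbachia_reads / L_wolbachia) / (host_reads / L_host)

with host reads taken as total minus *Wolbachia* reads. This ignores other
contaminants (so the host denominator is an upper bound and the titer a
slight underestimate in contaminated samples) and ignores ploidy and
mitochondrial copy number — normalisation is by genome length only.

## Contig binning

A contig of length `L_c` joins the draft genome when some reference
supports it at > 75% identity over a query span strictly greater than

    required(L_c) = 1000 · log10(L_c / 100)   bp,  capped at L_c.

The three anchor points — 100% of a 1000 bp contig, 65% of 2000 bp, 20% of
10 kb — pin down the formula's precedence unambiguously. Contigs shorter
than 1000 nt are removed first, so the logarithm's argument is always
comfortably above 1.

Two deliberate readings where the rule under-specifies multi-alignment
handling:

* the span per reference is the **union** of query intervals over all
  qualifying alignments (overlapping HSPs merged, never double-counted) —
  the conservative reading, checked against a position-set oracle;
* spans are **not** pooled across references: a contig must be supported
  by a single reference genome.

Boundary semantics: a span exactly equal to the requirement is rejected
(strict inequality as printed). One edge case needs care: at `L_c = 1000`
the rule value equals the contig length itself, so a strict inequality
could never hold even for a perfect full-length alignment; a span covering
the contig end to end therefore always accepts. This affects only contigs
of exactly 1000 bp given the length floor.

## Coinfection detection and the quality gate

For each assembly position with depth `n`, let `k` be the number of reads
not carrying the most frequent base (all three alternatives pooled). Under
a single-strain null, those bases are sequencing errors, so
`k ~ Binomial(n, ε)` with `ε = 0.01`; the position is polymorphic when the
upper-tail probability `P(X ≥ k)` falls below α = 0.05. No
multiple-testing correction is applied across positions: the test is a
per-site screen whose genome-wide *rate* is the quantity of interest, not
an inference about any individual site. At 100× depth the rejection
threshold is k\* = 4 non-primary reads.

The polymorphic rate is the number of polymorphic positions divided by the
assembly length (positions with zero depth are never assessed; dividing by
assessed positions instead is available as an option). Dominance is the
mean primary-base fraction over polymorphic positions (median available),
and defined as 1.0 when there are none.

The quality gate combines four criteria; failures are enumerated, not
short-circuited:

1. coverage ≥ 20×;
2. core-gene fraction ≥ 50% — genomes at 33–50% whose other criteria pass
   are demoted to `core-tree-only` (usable for core-tree placement, not
   for the quality-controlled set);
3. total length within 750,000–1,700,000 bp (inclusive), the span of
   reference genome lengths;
4. the chimera rule: rate < 0.01 passes outright; 0.01 ≤ rate ≤ 0.05
   passes only with dominance > 0.80; rate > 0.05 fails. Both band edges
   fall inside the dominance-checked band (the fail condition is strictly
   "greater than 0.05").

Low-confidence region screening flags ≥ 50 bp runs of depth ≥ 4× the
median, and ≥ 50 bp spans whose local density of variant sites (secondary
base at ≥ 5% of coverage) is ≥ 4× the genome-wide density. The variation
statistic's aggregation is not fully pinned down by its source; we assess
sliding 50 bp windows and merge qualifying windows, with a window-mean
variant-fraction mode available as an alternative. Region coordinates are
1-based inclusive throughout; BED-style output converts to 0-based
half-open and says so in its header.

## Balanced core genome

Supergroups contribute wildly different numbers of genomes, so the core is
defined over a balanced panel: within each supergroup, genomes are
clustered by k-medoids (k = 5, Jaccard distance on gene presence/absence
profiles) and the five medoids become that supergroup's representatives;
supergroups with ≤ 5 genomes contribute everything they have. A gene
family is core when **every** supergroup has at least one representative
carrying it. Supergroup L is excluded from the core definition by default
(a single divergent reference would otherwise veto the whole core);
configurable.

k-medoids minimises the total distance of genomes to their nearest medoid.
Instances with at most ~20,000 candidate medoid sets are solved exactly by
enumeration; larger instances use a deterministic PAM (greedy BUILD,
best-improvement SWAP, lexicographic tie-breaks). There is no random
component, so identical seeds trivially give identical results.

Per-genome core-gene calls from representative-vs-genome alignments accept
a hit iff E-value < 1e-10, identity > 66%, and aligned length within
[50%, 125%] of the family's mean representative gene length (window
closed, identity strict, as printed). Families with multiple accepted
targets in more than 10% of genomes (strictly more) are dropped as
putative multi-copy genes; within retained families only single-hit calls
are kept.

Near-identical genomes are collapsed by complete-linkage hierarchical
clustering on a pairwise distance matrix cut at 0.005 (complete linkage
guarantees every cluster's diameter stays within the threshold; a cut at 0
collapses exact duplicates). One representative per cluster is kept,
lexicographically smallest id by default. Gene families present in fewer
than 5 genomes are dropped before gene-content analyses.

## Enrichment and CI candidates

Each family's presence split between two genome groups forms a 2×2 table
tested with Fisher's exact test. One-sided "greater" p-values are computed
as hypergeometric upper tails, vectorised across families.

*Lineage-specific changes*: the focal host lineage is compared against
each closely related lineage separately; a family is reported only when
significant at α = 0.05 with the same direction in **every** comparison.
Raw p-values are used here — the repeated comparisons act as confirmatory
replicates, and the coincidence requirement is itself the stringency
control.

*CI candidates*: genomes with identical core profiles are collapsed first
(clonal resequencing would otherwise inflate counts); rare families are
dropped; then a family is a candidate iff one-sidedly enriched in the
wRi-like CI lineage vs the non-CI wAu-like group AND in wMel vs wAu, both
at Bonferroni-corrected p < 1e-5 (denominator = families tested after the
rare filter, logged per run). Finally, the nematode outgroup correction:
a candidate is removed when the wAu-vs-nematode comparison shows
significant enrichment in wAu, which unmasks wAu-specific gains that would
otherwise masquerade as CI-associated losses. The exact statistical form
of this correction was an open design point; the implemented rule realises
its stated purpose, is prominently configurable, and CI outputs on real
data should not be read as a replication of any particular published gene
list.

## Synthetic data

Every generator plants a recoverable truth and draws from its own RNG
stream derived from `(seed, generator-tag)`, so adding a generator never
perturbs another's output and identical seeds reproduce outputs bit for
bit.

* **Pangenome** (defaults: 5 supergroups × 10 genomes, 316 core + 6060
  accessory families): the planted core is present in every genome;
  planted CI families are present exactly in the CI-labelled lineages;
  accessory families belong to one home supergroup (round-robin) and are
  sampled there as independent Bernoulli(p = 0.3 by default) per genome.
  Supergroup-restricted accessory content mirrors the strong lineage
  structure of real accessory genomes and makes the planted core exactly
  identifiable — a property the recovery tests rely on. What this does
  *not* emulate: families shared across some-but-not-all supergroups, gene
  gain/loss along a phylogeny, or annotation noise; exact-recovery results
  on synthetic data therefore demonstrate correctness of the selection
  logic, not robustness to those real-data complications.
* **Pileup** (defaults: 100 kb, 100× Poisson depth): per-read errors are
  uniform over the three alternative bases. The default error rate is
  0.001, the ceiling implied by the Q30 base-quality filter applied when
  real pileups are built (Phred 30 = 1e-3 error probability); the site
  *test* still assumes the conservative ε = 0.01. Passing
  `error_rate=0.01` emulates unfiltered reads — at 100× depth that makes
  ~1.8% of clean sites exceed the per-site threshold by construction,
  which is the expected behaviour of the test, not a defect.
* **Contig alignments**: lengths log-uniform over [1 kb, 50 kb] to
  exercise the binning rule across its regime; Wolbachia-truth contigs get
  an alignment safely above the requirement, host-truth contigs get none,
  a low-identity one, or a half-requirement span — the margins guarantee
  exact truth recovery.
* **Read counts**: infection is Bernoulli(prevalence); host reads are
  Poisson around 1e6; infected samples draw Wolbachia reads Poisson around
  `titer · host_reads · L_w / L_h` (the titer formula inverted).

## Numerical choices

* Binomial tails via `scipy.stats.binom.sf`; the test suite checks them to
  1e-12 absolute against an exact big-integer rational term-wise summation
  for depths up to 10,000.
* One-sided Fisher p-values via `scipy.stats.hypergeom.sf`; checked
  against exact `math.comb`/`Fraction` enumeration and against
  `scipy.stats.fisher_exact`.
* Complete linkage via `scipy.cluster.hierarchy`; checked against a naive
  agglomerative oracle.
* All tie-breaks (medoids, dedup representatives) are lexicographic for
  reproducibility.
* Degenerate inputs raise: empty depth vectors, zero-depth site tests,
  contigs at or below the 100 bp rule pivot, all-zero Jaccard profiles,
  asymmetric distance matrices, zero median depth in the region screen.

## Problem sizes in the test suite

The suite validates planted-truth recovery at desk scale: pangenomes of
~50–250 genomes × 6376 families over 20 seeds, pileups of 50–100 kb at
100× depth, and oracle equivalence on instances small enough to enumerate
(n ≤ 9 clusterings, group sizes ≤ 50 for exact Fisher enumeration, depths
≤ 10,000 for the binomial oracle). The headline counts of any real screen
(tens of thousands of samples, >1000 MAGs) depend on archive-scale inputs
and are intentionally outside the test suite's claims.

## Known limitations

* Host reads are approximated as total − Wolbachia; heavily contaminated
  samples bias titers downward.
* The coinfection test detects mixtures; it does not deconvolve or phase
  strains.
* PAM beyond the exhaustive-enumeration limit is a local search; it
  matched the exhaustive optimum on every tested instance but carries no
  global guarantee.
* The nematode outgroup correction is one defensible operationalisation
  of its stated purpose, not the only one.
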