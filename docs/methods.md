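# Methods

## Problem and model

The pipeline identifies microRNAs regulated by a transcription factor (the
reference case is p53 activated by doxorubicin) from small RNA-seq of two
conditions with two biological replicates, where each replicate comparison is
a pair of libraries without within-condition replication.  Expression per
miRNA and library is the raw read count; library-size normalization is reads
per million clean reads (RPM).  Because each comparison is library-vs-library,
significance uses the Audic–Claverie statistic: conditional on the count *x*
in the first library, the count *y* in the second is distributed as

p(y | x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1+N₂/N₁)^(x+y+1) ),

the posterior predictive of a Poisson rate under a flat prior — equivalently
a negative binomial NB(y; x+1, N₁/(N₁+N₂)).  The two-sided p-value doubles
the smaller of P(Y ≤ y) and P(Y ≥ y), capped at 1.  Replicate structure
enters only through the selection filter, not the test.

### Numerical notes on the test

Tail sums are evaluated in log-gamma space.  The lower tail is an exact
finite sum.  When y lies in the upper tail (lower sum > 0.5), computing
P(Y ≥ y) as 1 − P(Y ≤ y−1) cancels catastrophically for small tails, so the
upper tail is summed directly from y upward in chunks until a geometric
remainder bound falls below 10⁻¹⁷ of the accumulated sum (term ratios tend
to (N₂/N₁)/(1+N₂/N₁) < 1).  P-values smaller than the smallest normal
float are floored at it so the (0, 1] contract holds.  The doubled-tail
construction is symmetric under (x, N₁) ↔ (y, N₂) only up to the point mass
p(y|x) — an exact consequence of the incomplete-beta reflection — and the
property tests assert exactly that bound rather than naive equality.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| RPM pseudo-value for zero counts | 0.01 RPM | only in fold-change ratios; keeps published extremes (|log₂fc| ≈ 10) representable |
| selection: min \|log₂fc\| | 1 | published criterion, both replicates, consistent sign |
| selection: min reads | > 10 raw reads in ≥ 1 of the 4 libraries | published criterion; raw (not normalized) counts, strict inequality |
| selection: max p | 0.01 raw p in ≥ 1 replicate comparison | published criterion; raw p matches the printed table values |
| multiple testing | Benjamini–Hochberg | the method was unspecified; BH is the field default, configurable |
| promoter window | 10 000 bp upstream, 1 000 bp downstream of TSS | published definition; strand-aware, clipped at chromosome edges |
| minus-strand window | [pos − D + 1, pos + U + 1) | the mirror image of the plus-strand [pos − U, pos + D); never spelled out upstream, fixed here so length = U + D either way |
| peak overlap rule | any ≥ 1 bp | most permissive reading of "sites around the TSS"; configurable minimum |
| peak position for distances | interval midpoint | the peaks are summit-less BED intervals |
| enrichment test | hypergeometric upper tail | the original analysis used web tools (EASE-style scores); the plain hypergeometric is exact and testable — a documented divergence |
| enrichment universe | annotation genes ∩ target-table gene space | no background was stated |
| clustering | Ward linkage, Euclidean, k = 2 | linkage was unspecified; complete and average linkage do *not* split the published 33-miRNA fold-change matrix by direction (mild up-regulated rows join the down cluster), Ward does — verified numerically before freezing. Only the k = 2 partition is contractual, not leaf order |
| counting of multi-matching reads | count toward every matching mature miRNA | the source analysis is silent; `multi="best"` gives fewest-mismatch-then-name assignment |

Read-cleaning class definitions (the source names the classes but never
defines them; these are standard conventions of the era, applied in fixed
order so classes partition the input): low quality = mean Phred < 20 or
> 10 % N; 5′ adapter contaminant = read starts with the 8-base adapter-5′
prefix; no 3′ adapter = no exact 8-base adapter-3′ seed anywhere; no insert
= empty trimmed insert; poly(A) = ≥ 80 % A in the insert; length bounds
18–30 nt (the gel-selected insert range).  Adapter matching is exact for
determinism.

## What the synthetic generator emulates — and what it does not

The generator's world: a toy genome (2 × 2 Mb) carrying ~50 miRNA precursors
(60–110 nt, random strand, 22-nt mature), half of them intragenic with a
host transcript; four 50-nt-tag FASTQ libraries whose mature-miRNA
abundances follow a log-normal base profile (σ = 1, the typical heavy skew
of small-RNA libraries) with planted log₂ fold changes applied
multiplicatively in the treated condition; contamination injected mutually
exclusively per read at planted rates (defaults total ≈ 7.5 %, mirroring a
clean run where ~98 % of tags survive); promoter peaks planted for a chosen
miRNA subset plus decoys outside all promoter windows; target tables with
controlled inter-source Jaccard overlap; annotation sets with planted 5×
over-represented categories; a G(n, p) PPI graph.  The study-shaped default
truth plants 12 up + 21 down DEMs, 18 of them bound, 7 multi-site.

Two deliberate design choices make the planted truth identifiable:

* **Compositional balance.** Library proportions sum to 1, so planting only
  the fold changes would shift every null miRNA's relative abundance by the
  net planted mass.  The generator rescales the planted-up group's base
  weights against the planted-down group so gained mass equals lost mass;
  null proportions are then exact and each planted miRNA's RPM ratio equals
  its planted fold change in expectation.
* **Precursor spacing.** Precursors are placed ≥ 32 kb apart by default so
  the promoter windows of distinct miRNAs are disjoint and a planted peak
  can be attributed to exactly one miRNA (set `min_spacing=0` for dense
  placement).

Not emulated: sequencing error profiles, ligation bias, hairpin secondary
structure, isomiR ends, multi-locus miRNA families, ChIP-seq reads (peaks
are generated directly), genome-build heterogeneity across peak sources.  A
green planted-truth test therefore establishes that the *computations*
recover what was planted under a clean, identifiable world — not that the
method is robust to real-library artifacts.

## Degenerate inputs and tie-breaks

Empty read sets, empty universes, empty query sets and zero library totals
are errors; an empty DEM set is an error for site summaries; a site-less
summary reports counts of 0 with fractions as not-applicable.  Conflicting
strong fold changes across replicates exclude the miRNA (logged, not an
error).  A single-miRNA cluster input degenerates to one cluster with a
warning.  Cluster ids are relabelled by decreasing mean fold change, so
cluster 1 is the up-regulated cluster whenever the partition splits by
direction.  FFLs exclude gene = TF.  PPI edges are context for export only
and never enter loop detection.

## Pipeline orchestration

`run_pipeline` runs simulate → clean/count → DE → promoters → targets →
network from one config; all randomness derives from one seed through
`numpy.random.SeedSequence` children, and the manifest records a SHA-256 per
output, so equal configs give bit-identical trees.  Stage toggles run the
pipeline through a prefix of stages; resuming later stages from previously
written intermediate files is not implemented (stages exchange in-memory
objects), a known limitation.

## Known limitations

* The ≤ 1-mismatch matcher is a deliberate simplification of a genome
  aligner + reference-database BLAST; no indels, no seeding heuristics.
* The enrichment test intentionally diverges from EASE-adjusted scores of
  DAVID-era web tools; adjusted p-values are not comparable to theirs.
* Published database-scale counts (thousands of target genes per source)
  depend on database versions and are out of reach of the synthetic world;
  the generator's set sizes (200 predicted per source, 20 validated per
  miRNA) are chosen for testability, not realism.
* The full binding-site table behind the published placement percentages is
  not machine-readable here; the placement-summary checks run on a synthetic
  stand-in with the same structure (18 bound, 7 multi-site, 33/36 upstream,
  25/36 within 5 kb).
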