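# p53mirnet

Identifying transcription-factor-regulated microRNAs from two-condition,
two-replicate small RNA-seq count data, and placing them in a regulatory
network — the canonical use case being p53 (TP53) activation by a
DNA-damaging agent in a cancer cell line.

The package is aimed at computational biologists who have (or want to
simulate) small RNA libraries for a control and a perturbed condition and
want to go from raw 50-nt tags to:

1. **clean miRNA counts** — quality/adapter/poly(A) filtering in a fixed,
   auditable order, then full-length matching of inserts to mature miRNA
   sequences with at most one substitution;
2. **robust differentially expressed miRNAs (DEMs)** — reads-per-million
   normalization and the Audic–Claverie exact test for a count *x* in a
   library of *N₁* clean reads against a count *y* in a library of *N₂*:

   $$p(y \mid x) = \left(\frac{N_2}{N_1}\right)^{y} \frac{(x+y)!}{x!\,y!\,(1 + N_2/N_1)^{x+y+1}},$$

   with the two-sided p-value 2·min(P(Y ≤ y), P(Y ≥ y)) capped at 1 and
   Benjamini–Hochberg control across miRNAs.  A miRNA is a robust DEM when
   |log₂ fold change| > 1 with a consistent sign in both replicate
   comparisons, its raw count exceeds 10 in at least one library, and
   p < 0.01 in at least one comparison;
3. **promoter binding sites** — a three-step TSS assignment (curated
   resource → host-gene transcript start → precursor 5′ end), strand-aware
   promoter windows of 10 kb upstream / 1 kb downstream, and any-overlap
   intersection with ChIP-seq peak intervals;
4. **integrated target sets and enrichment** — per miRNA,
   (predicted-by-A ∩ predicted-by-B) ∪ validated, tested against flat
   category annotations with the hypergeometric upper tail
   P(X ≥ k) under Hypergeom(N, K, n) and per-query BH control;
5. **feed-forward loops (FFLs)** — exact enumeration of (TF, miRNA, gene)
   triples where the TF regulates both the miRNA (promoter site + DEM) and
   the gene, and the miRNA also targets the gene; exports in SIF/GraphML
   with typed nodes and edges for Cytoscape-style visualization.

Because the original sequencing libraries are not required, a first-class
synthetic-data module generates every input with recorded planted truth
(fold changes, bound miRNAs, enriched categories, contamination rates), so
each stage — and the end-to-end pipeline — is scored against known answers.
A packaged reference table ships the published 33-row DEM table (per-replicate
log₂ fold changes and p-values) as a desk-scale anchor.

## Worked example

```bash
python examples/03_published_table_filter.py
```

prints

```
selected 33 of 33 miRNAs: 12 up, 21 down
cluster/direction agreement: 33/33

strongest responders per direction:
              rep1_log2fc  rep2_log2fc        rep1_p        rep2_p direction  cluster
mirna
hsa-miR-9-5p        11.05         2.50  2.980000e-56  8.760000e-17        up        1
hsa-miR-3662        -3.22        -2.15  9.130000e-03  4.240000e-09      down      2
```

All 33 packaged miRNAs pass the robust-selection filter — 12 up- and 21
down-regulated — and Ward clustering of the per-replicate log₂ fold-change
profiles splits exactly along the up/down direction (cluster 1 = up).

The other scripts in `examples/` walk through each capability: simulating a
planted dataset, cleaning/counting/DEM selection, promoter-site discovery
(recovering 18 planted bound miRNAs, 7 with multiple sites), target
integration + enrichment (planted categories significant, background not),
FFL enumeration (count equals the set-algebra expectation), and the
end-to-end pipeline with a checksummed, seed-reproducible manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged DEM table, the selection-filter counts: the
number of up-regulated (t1), down-regulated (t2), and total (t3) miRNAs
passing the robust criteria, writing one JSON object with a `value` and
problem size `n` per quantity.

## Layout

```
src/p53mirnet/       synthetic.py  reads.py  diffexpr.py  promoters.py
                     targets.py    network.py pipeline.py io.py fixtures.py
examples/            one narrative script per capability
docs/methods.md      model, assumptions, parameter choices, limitations
tests/               pytest suite incl. acceptance criteria
```
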