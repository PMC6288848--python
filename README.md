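# uprepeats

Analysis of repetitive-element (transposable element and simple/low-complexity
repeat) **configurations in upstream promoter regions** of coding genes.

Many human promoters carry one or more RepeatMasker-annotated repeats within
the first kilobase upstream of the transcription start site (TSS). The ordered
arrangement of those repeats — not just their density — is informative:
distinct configurations recur across gene sets and associate with cellular
pathways and Gene Ontology categories. `uprepeats` implements that analysis as
a tested, reusable pipeline for anyone studying repeat architecture around
gene starts: parse standard annotation formats, extract strand-aware promoter
windows, catalog ordered repeat configurations, cluster repeat classes by
window co-occurrence with bootstrap support, and test configurations for
functional enrichment. A synthetic-data generator with planted ground truth
makes every stage verifiable without genome downloads.

## The method

For each gene, the **upstream promoter region (UPR)** is the window of
`RD = 1000` bp immediately 5' of the TSS on the gene's own strand. A repeat
overlapping the window is retained with the normalized position

```
P = d / RD,        retained iff 0 <= P < 1,
```

where `d` is the distance in bp from the TSS to the repeat's TSS-proximal
boundary (`d = 0` for repeats spanning the TSS). Reading repeats outward from
the TSS by ascending `P` gives the gene's **configuration pattern**, written
`TSS<>A<>B`; genes sharing a canonical string form that pattern's gene set.

Downstream of the catalog:

- **Structural statistics** — single vs multiple repeats per window, the
  R² of repeat count against gene length, original-vs-order-inverted
  comparison of two-repeat patterns, per-class frequencies, cumulative
  TSS-distance curves and length summaries.
- **Clustering** — repeat classes are profiled by occurrence counts across
  gene windows, compared with Pearson correlation distance `d = 1 − r`, and
  clustered agglomeratively (UPGMA or complete linkage). Cluster stability is
  the **frequency of configuration (FC)**: the fraction of gene-column
  bootstrap replicates whose recomputed dendrogram conserves a node's leaf
  set (pvclust-style); subclusters are reported at FC ≥ 0.7.
- **Functional association** — pathway membership is folded into a
  class × pathway matrix (term scores variance-normalized across terms) for
  joint clustering, and each pattern's gene set is tested for GO-term
  over-representation by the hypergeometric upper tail
  `P(X ≥ k)` with `k` of the pattern's `K` annotated genes among a term's
  `n` carriers in an `N`-gene annotated background (singular enrichment
  analysis, cutoff p ≤ 0.05; Benjamini–Hochberg optional).

## Worked example

```python
import uprepeats as up

# 500 genes on 4 chromosomes, 10 repeat classes, the configuration
# TSS<>MIR<>Alu planted into 40 genes, 20% of genes left repeat-free
ds = up.generate(up.GeneratorConfig(seed=7))
catalog = up.catalog_patterns(ds.genes, ds.repeats, rd=1000)

print(len(catalog.patterns), catalog.coverage_fraction)
print(catalog.patterns["TSS<>MIR<>Alu"].n_genes)
print(up.single_multiple_split(catalog))
print(up.length_vs_count_r2(ds.genes, catalog))
```

prints

```
218 0.8
40
(0.245, 0.755)
(0.12452999395394646, -1)
```

— 218 distinct configurations cover exactly 80% of the genes (the configured
repeat-free fraction), the planted pattern is recovered in exactly its 40
genes, 24.5% of repeat-carrying genes hold a single repeat, and repeat count
declines with gene length (negative slope; the R² reflects the generator's
noise level). Enrichment of the planted GO term then follows with

```python
results = up.enrich_patterns(catalog, ds.go_annotations)
print(results[0].pattern, results[0].term_id, results[0].p_value)
# TSS<>MIR<>Alu GO:0006412 2.8422073298304836e-21
```

The same pipeline runs from the shell on real annotation files:

```bash
uprepeats extract --genes genes.gff3 --repeats repeats.out --out-dir out/
uprepeats cluster --genes genes.gff3 --repeats repeats.out \
    --linkage upgma --n-bootstrap 100 --seed 1 --out-dir out/
uprepeats enrich  --genes genes.gff3 --repeats repeats.out \
    --go go.tsv --pathways pathways.tsv --out-dir out/
```

Every command writes a `manifest.json` (version, parameters, seeds, input
checksums) from which its outputs can be regenerated.

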