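# Methods

## Coordinates and the promoter window

All intervals are 0-based half-open internally; GFF3/GTF and RepeatMasker
`.out` readers convert from 1-based inclusive on input and writers convert
back, so the conversion is an involution. The TSS is taken as the gene
feature's 5' boundary (start for `+` genes, end for `-` genes); genes are
treated as units, with no per-transcript alternative promoters. The window of
exploration `rd` (default 1000 bp) extends upstream from the TSS on the
gene's own strand, and the minus strand is handled as an exact mirror of the
plus-strand definitions. Windows clipped at a chromosome edge are kept and
flagged `truncated`; their position scores remain normalized by the full
`rd`, so positions stay comparable across genes.

## Position score and pattern construction

A repeat is retained when it overlaps the window, with normalized position
`P = d/rd` where `d` measures from the TSS to the repeat's TSS-proximal
boundary, clipped to 0 for repeats spanning the TSS. This "any overlap,
proximal boundary" rule — rather than requiring the repeat's start coordinate
to fall inside the window — is the reading that makes the retention condition
`0 <= P < 1` hold automatically for every overlapping repeat, and it is the
one this package commits to. Nested and overlapping repeat records are each
scored; one annotation record is one placement.

Placements sort by ascending `P`; exact ties break by ascending repeat
length, then lexicographic label, making catalogs fully deterministic
(identical inputs give byte-identical catalog TSVs). Repeated classes remain
separate entries (`TSS<>Alu<>Alu`). A gene with no retained repeat joins the
repeat-free set, so pattern gene sets plus the repeat-free set always
partition the input genes — an invariant validated on every catalog
construction.

For the gene-length regression the genomic span (end − start) is used as the
gene length. The original-vs-inverted comparison covers exactly the
two-repeat patterns, pairing each `TSS<>A<>B` with `TSS<>B<>A` (palindromes
pair with themselves); its R² is the squared Pearson correlation of the two
count vectors and is undefined (NaN) below two patterns or at zero variance.

## Clustering and the frequency of configuration

Repeat classes are profiled by occurrence counts over the columns of
repeat-carrying genes. Distance is `1 − r` (Pearson over rows), in `[0, 2]`;
a zero-variance row is an error rather than a silent `r = 0`, except inside
bootstrap replicates (below). Agglomeration uses scipy's average (UPGMA) and
complete linkage. Reported heights follow a declared convention stored on
the dendrogram: UPGMA defaults to half the merge distance (the ultrametric
tree-depth convention used in phylogenetics, so two leaves at distance `d`
merge at height `d/2`), complete linkage to the full merge distance; both are
switchable, and Newick exports derive branch lengths from these heights.

The frequency of configuration (FC) of a subcluster is operationalized as
bootstrap cluster conservation: gene columns are resampled with replacement
`n_bootstrap` times (default 100; a seed is mandatory), each replicate is
reclustered, and FC(node) is the fraction of replicates containing a cluster
with exactly that node's leaf set. A replicate can flatten a profile to zero
variance; such rows get `r = 0` (distance 1) for that replicate only, keeping
the resampling well-defined. The root and singleton leaves are trivially
conserved in every replicate and are therefore excluded from FC reporting;
`filter_by_fc` returns the maximal non-root nodes at or above the threshold
(default 0.7), outermost first.

## Functional association

The class × pathway matrix sums each class's per-gene occurrence counts over
a term's genes and scales each term by a normalization score equal to the
term's gene count divided by the standard deviation of gene counts across
terms (unit-variance scaling of term sizes; all-equal sizes leave scores at
1). This is one concrete choice for a variance-based term weighting among
several defensible ones, and it is recorded in output metadata via the run
manifest.

Enrichment is singular enrichment analysis with the hypergeometric
distribution, computed through scipy's log-space implementation (stable to
`N = 1e6`). The decision p-value is the upper tail `P(X >= k)`; the point
mass `P(X = k)` is reported alongside because point-mass testing is
incoherent as an enrichment criterion but useful for auditability. The
background `N` is the set of genes carrying at least one annotation in the
supplied table — not all genes. Defaults: raw cutoff 0.05 with no
multiple-testing correction (Benjamini–Hochberg by flag), tested units are
configuration patterns with at least `min_genes = 2` annotated genes
(switchable to per-repeat-class gene unions, or to `min_genes = 1`). GO
annotations are used as given, with no ancestor propagation.

## The synthetic generator

The generator emulates the statistical structure of promoter-repeat data:
gene lengths log-uniform over 2–100 kb on both strands of several
chromosomes; ten default repeat classes whose mean lengths span ~55–300 bp
(ERV1 longest, low-complexity/simple repeats shortest) with Alu-dominated
frequency weights; TSS-distance preferences in two modes (low-complexity and
simple repeats draw from the proximal 20% of the window, all other classes
beyond it); planted configurations written verbatim into designated genes;
an exact repeat-free fraction (default 20%, giving coverage 0.8 by
construction); and pathway/GO terms enriched in planted gene sets (default
80% of the planted genes) over a 5% background base rate. Background repeat
counts are zero-truncated Poisson with rate decreasing in log gene length,
planting an inverse length–count relation with known sign. Default scale is
500 genes with `TSS<>MIR<>Alu` planted in 40.

Genes are spaced so that windows plus maximal repeat overhangs never touch a
neighboring gene's window, and a background gene whose random repeats would
spell a planted canonical string is redrawn; planted patterns are therefore
observed with exactly their configured gene counts, while background genes
may still create incidental patterns. The truth table distinguishes planted
from background assignments, so tests assert containment (planted ⊆
observed), not catalog equality. Generation is fully deterministic given the
seed (single PCG64 stream, fixed iteration order).

What the generator does **not** emulate: real repeat sequence content,
chromosomal clustering of genes, the full 47-class frequency spectrum of a
real genome, overlapping or nested gene models, and annotation noise.
Passing tests therefore demonstrate correctness of the pipeline's
computations and contracts, not biological conclusions about any genome.

## Verification scales and numerical choices

The hypergeometric implementation is checked against exact integer
combinatorics (Pascal-triangle binomials) for every valid parameter
combination with `N <= 60` at absolute tolerance 1e-12; linkage against a
from-scratch cubic greedy agglomeration on 100 random matrices with up to 12
leaves (ties broken toward the lowest index pair, a measure-zero event for
continuous distances); null calibration of enrichment over 200 random
annotation sets of 10 terms at a 25% assignment rate on a 300-gene dataset;
mirror invariance over 20 datasets of 150 genes. These sizes keep the full
suite and the acceptance script in the tens of seconds on one CPU while
leaving each check statistically meaningful.

Floating-point conventions: Pearson distances are symmetrized and clipped to
`[0, 2]`; UPGMA/complete heights agree with the naive reference to 1e-8;
degenerate hypergeometric draws (`n = 0` or `K = 0`) return pmf 1 up to
1e-12 (log-space rounding). `length_vs_count_r2` refuses zero-variance
inputs rather than returning a conventional value.

## Known limitations

- The per-gene pattern unit means alternative promoters of one gene are not
  distinguished; using transcript-level TSSs would require per-transcript
  gene models upstream.
- FC is defined relative to the reference dendrogram's nodes; clusters that
  never appear in the reference get no FC even if frequent in replicates.
- The class-label vocabulary ships as an editable two-column mapping; raw
  RepeatMasker strings missing from it pass through verbatim in lenient mode
  (logged) and fail in strict mode.
- Enrichment treats annotations as flat sets; GO graph structure and
  evidence codes are out of scope.
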