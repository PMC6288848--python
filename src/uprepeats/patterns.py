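"""Promoter-window extraction, repeat position scoring and pattern cataloging.

The analysis window (range of exploration, ``rd``, default 1000 bp) sits
immediately 5' of each gene's transcription start site on the gene's own
strand.  A repeat overlapping the window is retained with a normalized
position score

    p = d / rd,   0 <= p < 1,

where ``d`` is the distance in bp from the TSS to the repeat's TSS-proximal
boundary (0 for repeats spanning the TSS).  The ordered sequence of repeat
classes by ascending ``p`` is the gene's configuration pattern, written
``TSS<>A<>B`` reading outward from the TSS.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import (
    ConfigurationPattern,
    GeneModel,
    PatternCatalog,
    PromoterWindow,
    RepeatAnnotation,
    RepeatPlacement,
    ValidationError,
    GenomicInterval,
    invert_pattern,
)

DEFAULT_RD = 1000


def promoter_window(
    gene: GeneModel, rd: int = DEFAULT_RD, chrom_length: int | None = None
) -> PromoterWindow:
    """Strand-aware window of up to ``rd`` bp immediately upstream of the TSS."""
    if rd <= 0:
        raise ValidationError(f"rd must be positive, got {rd}")
    tss = gene.tss
    if gene.interval.strand == "+":
        start, end = tss - rd, tss
    else:
        start, end = tss, tss + rd
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if chrom_length is not None and end > chrom_length:
        end, truncated = chrom_length, True
    if start >= end:
        # TSS flush against the chromosome edge: degenerate empty window
        start, end, truncated = max(0, end - 1), max(1, end), True
    return PromoterWindow(
        gene_id=gene.gene_id,
        window=GenomicInterval(gene.interval.chrom, start, end, gene.interval.strand),
        tss=tss,
        rd=rd,
        truncated=truncated,
    )


def p_score(repeat: RepeatAnnotation, window: PromoterWindow) -> RepeatPlacement | None:
    """Score one repeat against one window; ``None`` when not retained.

    Retention requires overlap with the (possibly clipped) window and
    0 <= p < 1; p stays normalized by the full ``rd`` even for truncated
    windows so positions remain comparable across genes.
    """
    if repeat.interval.chrom != window.window.chrom:
        raise ValidationError(
            f"chromosome mismatch: repeat on {repeat.interval.chrom}, "
            f"window on {window.window.chrom}"
        )
    r, w = repeat.interval, window.window
    if r.start >= w.end or r.end <= w.start:
        return None
    if w.strand == "+":
        d = max(0, window.tss - r.end)
    else:
        d = max(0, r.start - window.tss)
    p = d / window.rd
    if not (0.0 <= p < 1.0):
        return None
    return RepeatPlacement(
        gene_id=window.gene_id,
        repeat_class=repeat.repeat_class,
        p_score=p,
        tss_distance=int(round(p * window.rd)),
        length=r.length,
    )


def build_pattern(
    gene: GeneModel, placements: list[RepeatPlacement]
) -> ConfigurationPattern | None:
    """Order placements TSS-outward into a configuration pattern.

    Ties in position break by ascending repeat length, then label.  Empty
    placement lists yield ``None`` (gene recorded as repeat-free).
    """
    if not placements:
        return None
    ordered = sorted(placements, key=lambda pl: pl.sort_key())
    labels = tuple(pl.repeat_class for pl in ordered)
    return ConfigurationPattern(labels=labels, gene_ids={gene.gene_id})


def _repeat_trees(repeats: list[RepeatAnnotation]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rep in repeats:
        trees[rep.interval.chrom].addi(rep.interval.start, rep.interval.end, rep)
    return trees


def extract_placements(
    genes: list[GeneModel],
    repeats: list[RepeatAnnotation],
    rd: int = DEFAULT_RD,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """All retained placements as a tidy frame.

    Columns: gene_id, repeat_class, p_score, tss_distance, length; ordered
    by gene then TSS-outward position (fully deterministic).
    """
    trees = _repeat_trees(repeats)
    rows = []
    for gene in genes:
        clen = None if chrom_lengths is None else chrom_lengths.get(gene.interval.chrom)
        win = promoter_window(gene, rd=rd, chrom_length=clen)
        hits = trees.get(gene.interval.chrom)
        placed: list[RepeatPlacement] = []
        if hits is not None:
            for iv in hits.overlap(win.window.start, win.window.end):
                pl = p_score(iv.data, win)
                if pl is not None:
                    placed.append(pl)
        for pl in sorted(placed, key=lambda x: x.sort_key()):
            rows.append((pl.gene_id, pl.repeat_class, pl.p_score, pl.tss_distance, pl.length))
    return pd.DataFrame(
        rows, columns=["gene_id", "repeat_class", "p_score", "tss_distance", "length"]
    )


def catalog_from_placements(
    placements: pd.DataFrame, genes: list[GeneModel]
) -> PatternCatalog:
    """Aggregate per-gene placements into a pattern catalog."""
    gene_ids = [g.gene_id for g in genes]
    by_gene: dict[str, ConfigurationPattern] = {}
    for gid, grp in placements.groupby("gene_id", sort=False):
        grp = grp.sort_values(["p_score", "length", "repeat_class"], kind="mergesort")
        by_gene[str(gid)] = ConfigurationPattern(
            labels=tuple(grp["repeat_class"]), gene_ids={str(gid)}
        )
    patterns: dict[str, ConfigurationPattern] = {}
    free: set[str] = set()
    for gid in gene_ids:
        pat = by_gene.get(gid)
        if pat is None:
            free.add(gid)
            continue
        canon = pat.canonical
        if canon in patterns:
            patterns[canon].gene_ids.add(gid)
        else:
            patterns[canon] = pat
    return PatternCatalog(
        patterns=patterns, repeat_free_gene_ids=free, n_genes_total=len(gene_ids)
    )


def catalog_patterns(
    genes: list[GeneModel],
    repeats: list[RepeatAnnotation],
    rd: int = DEFAULT_RD,
    chrom_lengths: dict[str, int] | None = None,
) -> PatternCatalog:
    """End-to-end: windows -> placements -> catalog."""
    if not genes:
        raise ValidationError("catalog_patterns requires a nonempty gene list")
    placements = extract_placements(genes, repeats, rd=rd, chrom_lengths=chrom_lengths)
    return catalog_from_placements(placements, genes)


# ---------------------------------------------------------------------------
# structural statistics


def single_multiple_split(catalog: PatternCatalog) -> tuple[float, float]:
    """Fractions of repeat-carrying genes with one vs several window repeats."""
    total = catalog.n_genes_with_repeats
    if total == 0:
        raise ValidationError("empty catalog: single/multiple split undefined")
    single = sum(p.n_genes for p in catalog.patterns.values() if p.n_repeats == 1)
    return single / total, (total - single) / total


def length_vs_count_r2(
    genes: list[GeneModel], catalog: PatternCatalog
) -> tuple[float, int]:
    """R-squared and slope sign of per-gene repeat count vs gene length."""
    counts = {
        g: p.n_repeats for p in catalog.patterns.values() for g in p.gene_ids
    }
    pairs = [(g.length, counts[g.gene_id]) for g in genes if g.gene_id in counts]
    if len(pairs) < 3:
        raise ValidationError("need >= 3 genes with patterns for the regression")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in gene length or repeat count")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), int(np.sign(fit.slope))


def inverted_comparison(catalog: PatternCatalog) -> tuple[pd.DataFrame, float]:
    """Original vs order-inverted gene counts for all 2-repeat patterns.

    Returns the per-pattern table and the R-squared between the two count
    vectors (NaN when fewer than two patterns or zero variance).
    Palindromic patterns (A = B) compare to themselves.
    """
    two = {
        canon: pat.n_genes
        for canon, pat in catalog.patterns.items()
        if pat.n_repeats == 2
    }
    rows = [
        (canon, n, two.get(invert_pattern(canon), 0))
        for canon, n in sorted(two.items())
    ]
    table = pd.DataFrame(rows, columns=["pattern", "n_genes_original", "n_genes_inverted"])
    r2 = float("nan")
    if len(table) >= 2:
        x = table["n_genes_original"].to_numpy(dtype=float)
        y = table["n_genes_inverted"].to_numpy(dtype=float)
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            r2 = float(stats.linregress(x, y).rvalue ** 2)
    return table, r2


def repeat_frequency_stats(catalog: PatternCatalog) -> pd.DataFrame:
    """Per class: genes containing it, total occurrences, gene fraction."""
    n_genes: dict[str, int] = defaultdict(int)
    n_occ: dict[str, int] = defaultdict(int)
    for pat in catalog.patterns.values():
        per_class: dict[str, int] = defaultdict(int)
        for lab in pat.labels:
            per_class[lab] += 1
        for lab, c in per_class.items():
            n_genes[lab] += pat.n_genes
            n_occ[lab] += c * pat.n_genes
    denom = catalog.n_genes_with_repeats
    rows = [
        (lab, n_genes[lab], n_occ[lab], n_genes[lab] / denom if denom else 0.0)
        for lab in sorted(n_genes)
    ]
    return pd.DataFrame(rows, columns=["repeat_class", "n_genes", "n_occurrences",
                                       "gene_fraction"])


def tss_distance_distribution(
    placements: pd.DataFrame, bins: int = 20, rd: int = DEFAULT_RD
) -> pd.DataFrame:
    """Per-class cumulative frequency of TSS distance over [0, rd).

    One row per class, columns are bin upper edges; each curve is monotone
    non-decreasing and ends at 1.0.  Classes without placements are omitted.
    """
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    edges = np.linspace(0, rd, bins + 1)
    rows = {}
    for lab, grp in placements.groupby("repeat_class"):
        if len(grp) == 0:
            continue
        hist, _ = np.histogram(grp["tss_distance"], bins=edges)
        rows[lab] = np.cumsum(hist) / len(grp)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=edges[1:])
    out.index.name = "repeat_class"
    return out.sort_index()


def length_stats(placements: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean and dispersion of repeat length (bp) inside windows."""
    if len(placements) == 0:
        raise ValidationError("no placements")
    g = placements.groupby("repeat_class")["length"]
    out = pd.DataFrame(
        {"mean_length": g.mean(), "sd_length": g.std(ddof=1).fillna(0.0), "n": g.size()}
    )
    out.index.name = "repeat_class"
    return out.sort_index()
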