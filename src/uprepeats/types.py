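"""Domain types shared across the pipeline.

All coordinates are 0-based half-open internally; only the readers and
writers in :mod:`uprepeats.annotation_io` convert to and from the 1-based
inclusive conventions of GFF3/GTF and RepeatMasker ``.out`` files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

PATTERN_SEP = "<>"
PATTERN_PREFIX = "TSS"


class ValidationError(ValueError):
    """Input violates a documented contract (bounds, strand, uniqueness)."""


class ParseError(ValueError):
    """A file could not be parsed under the declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One coding gene; its span supplies the transcription start site.

    The TSS is the gene start for ``+`` genes and the gene end for ``-``
    genes (both as half-open boundary coordinates).
    """

    gene_id: str
    interval: GenomicInterval
    name: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, "
                f"got {self.interval.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat instance (e.g. a RepeatMasker record) with its class label."""

    repeat_class: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise ValidationError("repeat_class must be non-empty")

    @property
    def length(self) -> int:
        return self.interval.length


FUNCTION_NAMESPACES = (
    "pathway_general",
    "pathway_specific",
    "GO_cellular_component",
    "GO_biological_process",
)


@dataclass(frozen=True)
class FunctionAnnotation:
    """A gene-to-term membership (pathway or GO)."""

    gene_id: str
    term_id: str
    term_name: str
    namespace: str


@dataclass(frozen=True)
class PromoterWindow:
    """The exploration window immediately 5' of a gene's TSS.

    ``rd`` is the range of exploration in bp (1000 by default across the
    package).  ``truncated`` flags windows clipped at a chromosome edge;
    position scores stay normalized by the full ``rd`` regardless.
    """

    gene_id: str
    window: GenomicInterval
    tss: int
    rd: int
    truncated: bool = False


@dataclass(frozen=True)
class RepeatPlacement:
    """A repeat retained inside a promoter window.

    ``p_score`` is the normalized distance in [0, 1) from the TSS to the
    repeat's TSS-proximal boundary; ``tss_distance`` is the same distance
    in bp.  ``length`` is the repeat's full length even when it extends
    past the window.
    """

    gene_id: str
    repeat_class: str
    p_score: float
    tss_distance: int
    length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_score < 1.0):
            raise ValidationError(
                f"p_score {self.p_score} outside [0, 1) for {self.gene_id}"
            )

    def sort_key(self) -> tuple:
        # TSS-proximal first; ties by ascending length then label
        return (self.p_score, self.length, self.repeat_class)


def canonical_pattern(labels: "list[str] | tuple[str, ...]") -> str:
    """Canonical string for an ordered label sequence: ``TSS<>A<>B``."""
    return PATTERN_SEP.join([PATTERN_PREFIX, *labels])


def pattern_labels(canonical: str) -> tuple[str, ...]:
    """Inverse of :func:`canonical_pattern`."""
    parts = canonical.split(PATTERN_SEP)
    if not parts or parts[0] != PATTERN_PREFIX or len(parts) < 2:
        raise ValidationError(f"not a canonical pattern string: {canonical!r}")
    return tuple(parts[1:])


def invert_pattern(canonical: str) -> str:
    """Reverse the repeat order of a pattern (the 'inverted distribution')."""
    return canonical_pattern(list(reversed(pattern_labels(canonical))))


@dataclass
class ConfigurationPattern:
    """An ordered repeat-class configuration and the genes exhibiting it."""

    labels: tuple[str, ...]
    gene_ids: set[str] = field(default_factory=set)

    @property
    def canonical(self) -> str:
        return canonical_pattern(self.labels)

    @property
    def n_repeats(self) -> int:
        return len(self.labels)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class PatternCatalog:
    """All configuration patterns found in one dataset.

    Gene sets of distinct patterns partition the genes that carry at least
    one window repeat; the remainder are listed in ``repeat_free_gene_ids``.
    """

    patterns: dict[str, ConfigurationPattern]
    repeat_free_gene_ids: set[str]
    n_genes_total: int

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_genes_with_repeats(self) -> int:
        return sum(p.n_genes for p in self.patterns.values())

    @property
    def coverage_fraction(self) -> float:
        if self.n_genes_total == 0:
            return 0.0
        return self.n_genes_with_repeats / self.n_genes_total

    def validate(self) -> None:
        seen: set[str] = set()
        for canon, pat in self.patterns.items():
            if canon != pat.canonical:
                raise ValidationError(f"catalog key {canon!r} != {pat.canonical!r}")
            if pat.n_genes == 0:
                raise ValidationError(f"pattern {canon!r} has no genes")
            overlap = seen & pat.gene_ids
            if overlap:
                raise ValidationError(f"genes in multiple patterns: {sorted(overlap)[:3]}")
            seen |= pat.gene_ids
        if seen & self.repeat_free_gene_ids:
            raise ValidationError("repeat-free set intersects pattern gene sets")
        if len(seen) + len(self.repeat_free_gene_ids) != self.n_genes_total:
            raise ValidationError(
                f"partition broken: {len(seen)} patterned + "
                f"{len(self.repeat_free_gene_ids)} repeat-free != {self.n_genes_total}"
            )

    def gene_to_pattern(self) -> dict[str, str]:
        return {
            g: canon for canon, pat in self.patterns.items() for g in pat.gene_ids
        }


@dataclass
class Dendrogram:
    """A binary merge tree over labelled leaves.

    ``linkage_matrix`` follows the scipy convention (rows of
    ``[left, right, merge_distance, size]``); ``height_convention`` declares
    whether reported heights are the full merge distance (``"full"``) or the
    ultrametric half-distance tree depth (``"half"``).  ``fc`` holds
    bootstrap frequency-of-configuration support per non-root internal node,
    keyed by the node's leaf set.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    height_convention: str = "full"
    fc: "dict[frozenset, float] | None" = None
    n_bootstrap: int = 0
    seed: "int | None" = None

    def __post_init__(self) -> None:
        if self.height_convention not in ("full", "half"):
            raise ValidationError(f"unknown height convention {self.height_convention!r}")
        n = len(self.labels)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValidationError("linkage matrix must have n_leaves - 1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        h = self.linkage_matrix[:, 2].astype(float)
        return h / 2.0 if self.height_convention == "half" else h

    def node_leafsets(self) -> list[frozenset]:
        """Leaf sets of internal nodes, in merge order (root last)."""
        n = self.n_leaves
        sets: list[frozenset] = [frozenset([lab]) for lab in self.labels]
        out: list[frozenset] = []
        for left, right, _, _ in self.linkage_matrix:
            merged = sets[int(left)] | sets[int(right)]
            sets.append(merged)
            out.append(merged)
        return out

    def clades(self) -> list[tuple[frozenset, float]]:
        """(leaf set, height) per internal node, heights in the declared convention."""
        return list(zip(self.node_leafsets(), self.heights))


@dataclass(frozen=True)
class FCReport:
    """Bootstrap conservation of one internal node's leaf set."""

    leafset: frozenset
    fc: float
    n_bootstrap: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fc <= 1.0):
            raise ValidationError(f"fc {self.fc} outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """One (gene set, functional term) hypergeometric test.

    ``k`` of the set's ``K`` annotated genes carry the term, against ``n``
    carriers among ``N`` background (annotated) genes.  ``p_value`` is the
    upper tail P(X >= k); ``p_point`` the point mass P(X = k).
    """

    pattern: str
    term_id: str
    term_name: str
    namespace: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_point: float
    p_adjusted: float
    significant: bool
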