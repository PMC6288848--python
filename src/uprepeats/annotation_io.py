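"""Readers and writers for gene, repeat and function annotations.

Supported inputs: GFF3/GTF or BED6 gene models, RepeatMasker ``.out`` or
BED6 repeat annotations, and 3+-column TSV gene-to-term mappings.  Outputs
are TSV (catalogs, matrices, placements, enrichment tables) and Newick
(dendrograms).  GFF3/GTF and ``.out`` coordinates (1-based inclusive) are
converted to the package-internal 0-based half-open convention on read.
"""

from __future__ import annotations

import logging
from typing import Iterable

import gffutils
import pandas as pd
import skbio

from .types import (
    ConfigurationPattern,
    Dendrogram,
    EnrichmentResult,
    FunctionAnnotation,
    GeneModel,
    GenomicInterval,
    ParseError,
    PatternCatalog,
    RepeatAnnotation,
    ValidationError,
    pattern_labels,
)

logger = logging.getLogger(__name__)

# Default RepeatMasker class/family -> pattern-vocabulary label map.  The
# controlled vocabulary follows the labels used throughout this field's
# promoter-repeat literature (SINE families by name, LINE families with
# their LINE/ prefix, LTR and DNA families by family name).  Users can
# extend or replace it with a two-column TSV via load_class_map().
DEFAULT_CLASS_MAP: dict[str, str] = {
    "SINE/Alu": "Alu",
    "SINE/MIR": "MIR",
    "SINE": "SINE",
    "SINE/Deu": "Deu",
    "SINE/tRNA": "tRNA",
    "LINE/L1": "LINE/L1",
    "LINE/L2": "LINE/L2",
    "LINE/CR1": "CR1",
    "LINE/RTE": "RTE",
    "LINE/Dong-R4": "Dong-R4",
    "LTR/ERV1": "ERV1",
    "LTR/ERVL": "ERVL",
    "LTR/ERVL-MaLR": "ERVL-MaLR",
    "LTR/ERVK": "ERVK",
    "LTR/Gypsy": "Gypsy",
    "LTR": "LTR",
    "DNA/hAT-Charlie": "hAT-Charlie",
    "DNA/hAT-Tip100": "hAT-Tip100",
    "DNA/hAT-Blackjack": "hAT-Blackjack",
    "DNA/hAT": "hAT",
    "DNA/TcMar-Tigger": "TcMar-Tigger",
    "DNA/TcMar-Mariner": "TcMar-Mariner",
    "DNA/TcMar": "TcMar",
    "DNA/PiggyBac": "PiggyBac",
    "Simple_repeat": "Simple_repeat",
    "Low_complexity": "Low_complexity",
    "Satellite": "Satellite",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "scRNA": "scRNA",
    "srpRNA": "srpRNA",
    "RC/Helitron": "Helitron",
    "Retroposon/SVA": "SVA",
}


def load_class_map(path: str) -> dict[str, str]:
    """Read a two-column TSV (raw class/family -> pattern label)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{i}: expected 2 tab-separated columns")
            out[fields[0]] = fields[1]
    return out


def normalize_repeat_class(
    raw: str, class_map: dict[str, str] | None = None, strict: bool = False
) -> str:
    """Map a raw RepeatMasker class/family string to the pattern vocabulary."""
    mapping = DEFAULT_CLASS_MAP if class_map is None else class_map
    if raw in mapping:
        return mapping[raw]
    if raw in mapping.values():  # already in the pattern vocabulary
        return raw
    # strip trailing '?' qualifiers RepeatMasker adds for uncertain calls
    stripped = raw.rstrip("?")
    if stripped in mapping:
        return mapping[stripped]
    if strict:
        raise ValidationError(f"unknown repeat class {raw!r} (strict mode)")
    logger.warning("unknown repeat class %r passed through", raw)
    return raw


# ---------------------------------------------------------------------------
# genes


def _gene_from_fields(
    gene_id: str, name: str, chrom: str, start: int, end: int, strand: str, where: str
) -> GeneModel:
    if strand not in ("+", "-"):
        raise ValidationError(f"{where}: gene {gene_id!r} has strand {strand!r}; "
                              "strandless gene records are rejected")
    try:
        return GeneModel(gene_id=gene_id, name=name,
                         interval=GenomicInterval(chrom, start, end, strand))
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from exc


def _check_unique(genes: list[GeneModel]) -> list[GeneModel]:
    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = [k for k, v in seen.items() if v > 1]
    if dups:
        raise ValidationError(f"duplicate gene_id(s): {sorted(dups)[:5]}")
    return genes


def load_genes(path: str, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3, GTF or BED6.

    GFF3/GTF 1-based inclusive coordinates are converted to 0-based
    half-open.  One :class:`GeneModel` is emitted per ``gene`` feature
    (the gene's own span, not per-transcript TSSs).
    """
    if format in ("gff3", "gtf"):
        return _load_genes_gff(path, format)
    if format == "bed":
        return _load_genes_bed(path)
    raise ValueError(f"unknown gene format {format!r}")


def _load_genes_gff(path: str, dialect: str) -> list[GeneModel]:
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted internal errors
        raise ParseError(f"{path}: failed to parse as {dialect}: {exc}") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("gene_id") or [feat.id])[0]
        name = (attrs.get("Name") or attrs.get("gene_name") or attrs.get("gene") or [""])[0]
        genes.append(
            _gene_from_fields(
                gene_id, name, feat.seqid, feat.start - 1, feat.end, feat.strand, path
            )
        )
    return _check_unique(genes)


def _load_genes_bed(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{i}: BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            strand = fields[5]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            genes.append(_gene_from_fields(name, name, chrom, s, e, strand, f"{path}:{i}"))
    return _check_unique(genes)


# ---------------------------------------------------------------------------
# repeats


def load_repeats(
    path: str,
    format: str = "rm_out",
    class_map: dict[str, str] | None = None,
    strict: bool = False,
) -> list[RepeatAnnotation]:
    """Read repeat annotations from RepeatMasker ``.out`` or BED6.

    ``.out`` begin/end are 1-based inclusive and converted on read; class
    strings pass through :func:`normalize_repeat_class`.
    """
    if format == "rm_out":
        return _load_repeats_rm_out(path, class_map, strict)
    if format == "bed":
        return _load_repeats_bed(path, class_map, strict)
    raise ValueError(f"unknown repeat format {format!r}")


def _load_repeats_rm_out(
    path: str, class_map: dict[str, str] | None, strict: bool
) -> list[RepeatAnnotation]:
    repeats: list[RepeatAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    # 3 header lines: two column-name lines and one blank
    body = lines[3:] if len(lines) >= 3 else []
    for offset, line in enumerate(body, 4):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ParseError(f"{path}:{offset}: expected >= 11 whitespace-delimited "
                             f"columns, got {len(fields)}")
        chrom, begin, end = fields[4], fields[5], fields[6]
        raw_class = fields[10]
        try:
            b, e = int(begin), int(end)
        except ValueError as exc:
            raise ParseError(f"{path}:{offset}: non-integer begin/end") from exc
        label = normalize_repeat_class(raw_class, class_map, strict)
        repeats.append(
            RepeatAnnotation(repeat_class=label,
                             interval=GenomicInterval(chrom, b - 1, e, "."))
        )
    if not repeats:
        logger.warning("%s: no repeat records parsed", path)
    return repeats


def _load_repeats_bed(
    path: str, class_map: dict[str, str] | None, strict: bool
) -> list[RepeatAnnotation]:
    repeats: list[RepeatAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{i}: repeat BED needs >= 4 columns")
            chrom, start, end, raw_class = fields[0], fields[1], fields[2], fields[3]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            label = normalize_repeat_class(raw_class, class_map, strict)
            repeats.append(
                RepeatAnnotation(repeat_class=label,
                                 interval=GenomicInterval(chrom, s, e, "."))
            )
    if not repeats:
        logger.warning("%s: no repeat records parsed", path)
    return repeats


# ---------------------------------------------------------------------------
# function annotations


def load_function_annotations(
    path: str, namespace: str, known_genes: Iterable[str] | None = None
) -> list[FunctionAnnotation]:
    """Read a gene_id / term_id / term_name TSV into deduplicated records.

    Genes absent from ``known_genes`` (when given) are retained but logged.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need >= 3 tab-separated columns "
                         f"(gene_id, term_id, term_name), got {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["gene_id", "term_id", "term_name"]
    before = len(df)
    df = df.drop_duplicates(subset=["gene_id", "term_id"])
    if len(df) < before:
        logger.info("%s: %d duplicate (gene, term) rows collapsed", path, before - len(df))
    if namespace.startswith("pathway") and df["term_id"].str.startswith("GO:").any():
        logger.warning("%s: GO-style ids under namespace %r; kept", path, namespace)
    if known_genes is not None:
        unknown = set(df["gene_id"]) - set(known_genes)
        if unknown:
            logger.info("%s: %d annotated genes not in the gene set (kept, flagged)",
                        path, len(unknown))
    return [
        FunctionAnnotation(gene_id=r.gene_id, term_id=r.term_id,
                           term_name=r.term_name, namespace=namespace)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# writers (and matching readers for round trips)


def write_pattern_catalog(catalog: PatternCatalog, path: str) -> None:
    """Write a catalog TSV; deterministic ordering (gene count desc, pattern asc).

    Catalog-level counts travel as leading ``#key=value`` metadata lines so
    the file round-trips to an identical :class:`PatternCatalog`.
    """
    rows = sorted(catalog.patterns.values(), key=lambda p: (-p.n_genes, p.canonical))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#n_genes_total={catalog.n_genes_total}\n")
        fh.write("#repeat_free_gene_ids=" +
                 ";".join(sorted(catalog.repeat_free_gene_ids)) + "\n")
        fh.write("pattern\tn_genes\tn_repeats\tgene_ids\n")
        for p in rows:
            fh.write(f"{p.canonical}\t{p.n_genes}\t{p.n_repeats}\t"
                     + ";".join(sorted(p.gene_ids)) + "\n")


def read_pattern_catalog(path: str) -> PatternCatalog:
    meta: dict[str, str] = {}
    patterns: dict[str, ConfigurationPattern] = {}
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            if not header_seen:
                if line.split("\t")[0] != "pattern":
                    raise ParseError(f"{path}:{i}: missing catalog header")
                header_seen = True
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{i}: expected 4 columns")
            canon, _n_genes, _n_repeats, gene_ids = fields
            labels = pattern_labels(canon)
            genes = set(gene_ids.split(";")) if gene_ids else set()
            patterns[canon] = ConfigurationPattern(labels=labels, gene_ids=genes)
    if "n_genes_total" not in meta:
        raise ParseError(f"{path}: missing #n_genes_total metadata line")
    free = set(x for x in meta.get("repeat_free_gene_ids", "").split(";") if x)
    return PatternCatalog(
        patterns=patterns,
        repeat_free_gene_ids=free,
        n_genes_total=int(meta["n_genes_total"]),
    )


def write_matrix(matrix: pd.DataFrame, path: str, index_label: str = "label") -> None:
    """Write a labelled matrix as a TSV with a header line."""
    matrix.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def dendrogram_to_newick(dendro: Dendrogram, include_fc: bool = True) -> str:
    """Render a dendrogram as Newick; FC support becomes internal-node labels."""
    n = dendro.n_leaves
    heights = dendro.heights
    leafsets = dendro.node_leafsets()

    def esc(label: str) -> str:
        return "'" + label.replace("'", "''") + "'" if any(
            c in label for c in " ();:,[]'") else label

    def rec(i: int) -> tuple[str, float]:
        if i < n:
            return esc(dendro.labels[i]), 0.0
        left, right, _, _ = dendro.linkage_matrix[i - n]
        h = float(heights[i - n])
        ls, lh = rec(int(left))
        rs, rh = rec(int(right))
        name = ""
        if include_fc and dendro.fc is not None:
            fc = dendro.fc.get(leafsets[i - n])
            if fc is not None:
                name = f"{fc:.3f}"
        return f"({ls}:{h - lh:.10g},{rs}:{h - rh:.10g}){name}", h

    s, _ = rec(2 * n - 2)
    return s + ";\n"


def write_dendrogram(dendro: Dendrogram, path: str, include_fc: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(dendrogram_to_newick(dendro, include_fc=include_fc))


def read_dendrogram_clades(path: str) -> dict[frozenset, float]:
    """Read a Newick file back as {leaf set: node height} (root included).

    Heights are recovered from root-to-node distances assuming an
    ultrametric tree (leaves at height 0), which both linkage conventions
    written by :func:`write_dendrogram` satisfy.
    """
    tree = skbio.TreeNode.read(path, convert_underscores=False)
    depth = max(tree.distance(t) for t in tree.tips())
    out: dict[frozenset, float] = {}
    for node in tree.non_tips(include_self=True):
        leafset = frozenset(t.name for t in node.tips())
        out[leafset] = depth - (tree.distance(node) if node.parent is not None else 0.0)
    return out


def write_placements(placements: pd.DataFrame, path: str) -> None:
    cols = ["gene_id", "repeat_class", "p_score", "tss_distance", "length"]
    placements[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_enrichment(results: list[EnrichmentResult], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "pattern": r.pattern, "term_id": r.term_id, "term_name": r.term_name,
                "namespace": r.namespace, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_value": r.p_value, "p_point": r.p_point,
                "p_adjusted": r.p_adjusted, "significant": r.significant,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def sha256_of(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
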