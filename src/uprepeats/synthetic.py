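"""Synthetic annotation generator with planted ground truth.

Emulates the statistical structure of real promoter-repeat data without any
external download: genes of log-uniform length on both strands, repeat
classes with class-specific length distributions (~50-300 bp) and
TSS-distance preferences (short simple/low-complexity repeats sit in the
proximal ~20% of the window, other classes beyond it), planted multi-repeat
configurations shared by designated gene sets, and pathway/GO terms
enriched in those sets over a background assignment rate.

Every planted assignment is recorded in a truth table, and generation is
fully deterministic given the seed.  Background repeats may create
incidental (unplanted) patterns; the guarantee is that planted patterns are
observed with exactly their configured gene counts — a background gene
whose random repeats would spell a planted configuration is redrawn.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    FunctionAnnotation,
    GeneModel,
    GenomicInterval,
    RepeatAnnotation,
    ValidationError,
    canonical_pattern,
    pattern_labels,
)

MIN_REPEAT_LEN = 10
MAX_REPEAT_LEN = 600
NEAR_FRACTION = 0.2  # proximal share of the window used by 'near' classes


@dataclass(frozen=True)
class RepeatClassSpec:
    """One repeat class: label, length distribution and TSS preference."""

    label: str
    mean_length: float
    length_sd: float
    tss_mode: str = "far"  # 'near' -> proximal 20% of the window
    weight: float = 1.0  # relative pick probability for background repeats


@dataclass(frozen=True)
class PlantedPattern:
    """A configuration planted verbatim into ``n_genes`` genes.

    ``template`` gives the TSS distances (bp) of each repeat; ``None``
    spaces them evenly through the window.
    """

    canonical: str
    n_genes: int
    template: tuple[int, ...] | None = None


@dataclass(frozen=True)
class TermSpec:
    """One functional term; optionally enriched in a planted pattern's genes."""

    term_id: str
    term_name: str
    n_genes: int = 0  # background genes to annotate when not planted
    planted_pattern: str | None = None
    enrichment_fraction: float = 0.8


# Class roster used by default: most frequent promoter-window classes with
# Alu-dominated weights, ERV1 longest (~300 bp), low-complexity shortest
# (~55-60 bp), simple/low-complexity repeats TSS-proximal.
DEFAULT_REPEAT_CLASSES: tuple[RepeatClassSpec, ...] = (
    RepeatClassSpec("Alu", 290.0, 40.0, "far", 3.0),
    RepeatClassSpec("Low_complexity", 60.0, 15.0, "near", 2.2),
    RepeatClassSpec("MIR", 180.0, 40.0, "far", 2.0),
    RepeatClassSpec("Simple_repeat", 55.0, 15.0, "near", 1.8),
    RepeatClassSpec("LINE/L2", 200.0, 50.0, "far", 1.4),
    RepeatClassSpec("LINE/L1", 250.0, 60.0, "far", 1.2),
    RepeatClassSpec("hAT-Charlie", 150.0, 40.0, "far", 0.8),
    RepeatClassSpec("ERV1", 300.0, 60.0, "far", 0.6),
    RepeatClassSpec("ERVL-MaLR", 220.0, 50.0, "far", 0.5),
    RepeatClassSpec("TcMar-Tigger", 170.0, 40.0, "far", 0.4),
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 500
    n_chromosomes: int = 4
    chrom_length: int = 8_000_000
    rd: int = 1000
    repeat_classes: tuple[RepeatClassSpec, ...] = DEFAULT_REPEAT_CLASSES
    planted_patterns: tuple[PlantedPattern, ...] = (
        PlantedPattern("TSS<>MIR<>Alu", 40),
    )
    repeat_free_fraction: float = 0.2
    gene_length_range: tuple[int, int] = (2_000, 100_000)
    background_count_mode: str = "length_linked"  # or an int-valued fixed count
    background_fixed_count: int = 1
    pathway_terms: tuple[TermSpec, ...] = (
        TermSpec("ko03050", "Proteasome", n_genes=0,
                 planted_pattern="TSS<>MIR<>Alu", enrichment_fraction=0.8),
        TermSpec("ko00010", "Glycolysis", n_genes=60),
        TermSpec("ko03010", "Ribosome", n_genes=80),
    )
    go_terms: tuple[TermSpec, ...] = (
        TermSpec("GO:0006412", "translation", n_genes=0,
                 planted_pattern="TSS<>MIR<>Alu", enrichment_fraction=0.8),
        TermSpec("GO:0005634", "nucleus", n_genes=120),
        TermSpec("GO:0016020", "membrane", n_genes=100),
    )
    term_base_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.repeat_free_fraction <= 1.0):
            raise ValidationError("repeat_free_fraction outside [0, 1]")
        labels = {c.label for c in self.repeat_classes}
        planted_total = 0
        for pp in self.planted_patterns:
            labs = pattern_labels(pp.canonical)
            missing = set(labs) - labels
            if missing:
                raise ValidationError(
                    f"planted pattern {pp.canonical!r} uses unknown classes {missing}")
            template = pp.template or default_template(len(labs), self.rd)
            if len(template) != len(labs):
                raise ValidationError(f"{pp.canonical!r}: template length mismatch")
            if any(not (0 <= d < self.rd) for d in template):
                raise ValidationError(
                    f"{pp.canonical!r}: template positions fall outside the "
                    f"{self.rd} bp window")
            planted_total += pp.n_genes
        n_free = round(self.repeat_free_fraction * self.n_genes)
        if planted_total + n_free > self.n_genes:
            raise ValidationError("planted genes + repeat-free genes exceed n_genes")
        for t in self.pathway_terms + self.go_terms:
            if not (0.0 <= t.enrichment_fraction <= 1.0):
                raise ValidationError(f"term {t.term_id}: enrichment_fraction outside [0,1]")


def default_template(n_repeats: int, rd: int) -> tuple[int, ...]:
    """Evenly spaced TSS distances for a planted configuration."""
    step = int(rd * 0.8 / max(n_repeats, 1))
    return tuple(int(rd * 0.08) + i * step for i in range(n_repeats))


@dataclass
class SyntheticDataset:
    genes: list[GeneModel]
    repeats: list[RepeatAnnotation]
    pathway_annotations: list[FunctionAnnotation]
    go_annotations: list[FunctionAnnotation]
    truth: pd.DataFrame
    chrom_lengths: dict[str, int]
    config: GeneratorConfig

    def write(self, outdir: str, gene_format: str = "gff3",
              repeat_format: str = "rm_out") -> dict[str, str]:
        """Write the dataset in the formats the readers accept; returns paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genes": os.path.join(outdir, f"genes.{ 'gff3' if gene_format == 'gff3' else 'bed' }"),
            "repeats": os.path.join(outdir, "repeats.out" if repeat_format == "rm_out"
                                    else "repeats.bed"),
            "pathways": os.path.join(outdir, "pathways.tsv"),
            "go": os.path.join(outdir, "go.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        if gene_format == "gff3":
            write_genes_gff3(self.genes, self.chrom_lengths, paths["genes"])
        elif gene_format == "bed":
            write_genes_bed(self.genes, paths["genes"])
        else:
            raise ValidationError(f"unknown gene format {gene_format!r}")
        if repeat_format == "rm_out":
            write_repeats_rm_out(self.repeats, self.chrom_lengths, paths["repeats"])
        elif repeat_format == "bed":
            write_repeats_bed(self.repeats, paths["repeats"])
        else:
            raise ValidationError(f"unknown repeat format {repeat_format!r}")
        _write_annotations(self.pathway_annotations, paths["pathways"])
        _write_annotations(self.go_annotations, paths["go"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
        return paths


def _truncnorm_int(rng: np.random.Generator, mean: float, sd: float) -> int:
    for _ in range(100):
        x = int(round(rng.normal(mean, sd)))
        if MIN_REPEAT_LEN <= x <= MAX_REPEAT_LEN:
            return x
    return int(np.clip(round(mean), MIN_REPEAT_LEN, MAX_REPEAT_LEN))


def _draw_distance(rng: np.random.Generator, mode: str, rd: int) -> int:
    near_limit = max(1, int(rd * NEAR_FRACTION))
    if mode == "near":
        return int(rng.integers(0, near_limit))
    return int(rng.integers(near_limit, rd))


def _repeat_at(gene: GeneModel, d: int, length: int, label: str) -> RepeatAnnotation:
    """Place a repeat whose TSS-proximal boundary is d bp from the TSS."""
    if gene.interval.strand == "+":
        b = gene.tss - d
        start, end = b - length, b
    else:
        b = gene.tss + d
        start, end = b, b + length
    return RepeatAnnotation(label, GenomicInterval(gene.interval.chrom, start, end, "."))


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    rd = config.rd
    gap = 2 * rd + MAX_REPEAT_LEN + 100  # keeps window+overhang regions disjoint

    # --- genes -------------------------------------------------------------
    lo, hi = config.gene_length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    lengths = lengths.astype(int)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes: list[GeneModel] = []
    cursors = {f"chr{i + 1}": gap for i in range(config.n_chromosomes)}
    chrom_names = list(cursors)
    for i in range(config.n_genes):
        chrom = chrom_names[i % config.n_chromosomes]
        start = cursors[chrom]
        end = start + int(lengths[i])
        if end + gap > config.chrom_length:
            raise ValidationError(
                f"chrom_length {config.chrom_length} too small for {config.n_genes} "
                "genes at the configured length range")
        cursors[chrom] = end + gap
        gid = f"G{i + 1:05d}"
        genes.append(GeneModel(gene_id=gid, name=gid,
                               interval=GenomicInterval(chrom, start, end, str(strands[i]))))

    # --- role assignment ---------------------------------------------------
    order = rng.permutation(config.n_genes)
    planted_assign: list[tuple[GeneModel, PlantedPattern]] = []
    pos = 0
    for pp in config.planted_patterns:
        for j in range(pp.n_genes):
            planted_assign.append((genes[order[pos + j]], pp))
        pos += pp.n_genes
    n_free = round(config.repeat_free_fraction * config.n_genes)
    free_genes = [genes[order[pos + j]] for j in range(n_free)]
    background_genes = [genes[order[j]] for j in range(pos + n_free, config.n_genes)]

    class_by_label = {c.label: c for c in config.repeat_classes}
    weights = np.array([c.weight for c in config.repeat_classes], dtype=float)
    weights /= weights.sum()
    planted_canonicals = {pp.canonical for pp in config.planted_patterns}

    repeats: list[RepeatAnnotation] = []
    truth_rows: list[tuple[str, str, str, str]] = []

    # --- planted configurations -------------------------------------------
    for gene, pp in planted_assign:
        labs = pattern_labels(pp.canonical)
        template = pp.template or default_template(len(labs), rd)
        for lab, d in zip(labs, template):
            spec = class_by_label[lab]
            length = _truncnorm_int(rng, spec.mean_length, spec.length_sd)
            repeats.append(_repeat_at(gene, d, length, lab))
        truth_rows.append(("pattern", pp.canonical, gene.gene_id, "planted"))

    # --- background repeats (zero-truncated count; rejection keeps planted
    #     canonicals exclusive to planted genes) ----------------------------
    for gene in background_genes:
        if config.background_count_mode == "length_linked":
            lam = float(np.clip(4.5 - 1.5 * np.log10(gene.length / 1000.0), 0.3, 6.0))
        else:
            lam = None
        for _attempt in range(200):
            if lam is None:
                count = config.background_fixed_count
            else:
                count = int(rng.poisson(lam))
                if count == 0:
                    count = 1  # zero-truncation: background genes carry >= 1 repeat
            drawn = []
            for _ in range(count):
                ci = int(rng.choice(len(config.repeat_classes), p=weights))
                spec = config.repeat_classes[ci]
                d = _draw_distance(rng, spec.tss_mode, rd)
                length = _truncnorm_int(rng, spec.mean_length, spec.length_sd)
                drawn.append((d, length, spec.label))
            drawn.sort(key=lambda t: (t[0] / rd, t[1], t[2]))
            canon = canonical_pattern([t[2] for t in drawn])
            if canon not in planted_canonicals:
                break
        else:
            raise ValidationError(
                f"could not draw a non-planted background pattern for {gene.gene_id}")
        for d, length, lab in drawn:
            repeats.append(_repeat_at(gene, d, length, lab))

    # --- functional terms ---------------------------------------------------
    planted_genes_by_pattern: dict[str, list[str]] = {}
    for gene, pp in planted_assign:
        planted_genes_by_pattern.setdefault(pp.canonical, []).append(gene.gene_id)
    all_gene_ids = [g.gene_id for g in genes]

    def make_annotations(terms: tuple[TermSpec, ...], namespace: str,
                         kind: str) -> list[FunctionAnnotation]:
        out: list[FunctionAnnotation] = []
        for t in terms:
            members: dict[str, str] = {}
            if t.planted_pattern is not None:
                pool = planted_genes_by_pattern.get(t.planted_pattern, [])
                n_pick = round(t.enrichment_fraction * len(pool))
                picked = rng.choice(len(pool), size=n_pick, replace=False) if pool else []
                for j in picked:
                    members[pool[int(j)]] = "planted"
                hits = rng.random(len(all_gene_ids)) < config.term_base_rate
                for gid, hit in zip(all_gene_ids, hits):
                    if hit and gid not in members:
                        members[gid] = "background"
            else:
                n_pick = min(t.n_genes, len(all_gene_ids))
                picked = rng.choice(len(all_gene_ids), size=n_pick, replace=False)
                for j in picked:
                    members[all_gene_ids[int(j)]] = "background"
            for gid in sorted(members):
                out.append(FunctionAnnotation(gene_id=gid, term_id=t.term_id,
                                              term_name=t.term_name, namespace=namespace))
                truth_rows.append((kind, t.term_id, gid, members[gid]))
        return out

    pathway_annotations = make_annotations(config.pathway_terms, "pathway_general",
                                           "pathway_term")
    go_annotations = make_annotations(config.go_terms, "GO_biological_process",
                                      "go_term")

    truth = pd.DataFrame(truth_rows, columns=["kind", "key", "gene_id", "origin"])
    return SyntheticDataset(
        genes=genes,
        repeats=repeats,
        pathway_annotations=pathway_annotations,
        go_annotations=go_annotations,
        truth=truth,
        chrom_lengths={c: config.chrom_length for c in chrom_names},
        config=config,
    )


def mirror_dataset(
    genes: list[GeneModel],
    repeats: list[RepeatAnnotation],
    chrom_lengths: dict[str, int],
) -> tuple[list[GeneModel], list[RepeatAnnotation]]:
    """Reflect every record through its chromosome midpoint and flip strands.

    Pattern catalogs are invariant under this transform; tests use it to
    check the strand-mirror contract.  Applying it twice is the identity.
    """
    flip = {"+": "-", "-": "+", ".": "."}

    def refl(iv: GenomicInterval) -> GenomicInterval:
        L = chrom_lengths[iv.chrom]
        return GenomicInterval(iv.chrom, L - iv.end, L - iv.start, flip[iv.strand])

    m_genes = [GeneModel(g.gene_id, refl(g.interval), g.name) for g in genes]
    m_repeats = [RepeatAnnotation(r.repeat_class, refl(r.interval)) for r in repeats]
    return m_genes, m_repeats


def random_function_annotations(
    gene_ids: list[str],
    n_terms: int,
    rate: float,
    seed: int,
    namespace: str = "GO_biological_process",
) -> list[FunctionAnnotation]:
    """Terms assigned to genes independently at random (null model for
    enrichment calibration); every gene gets a filler term so the whole
    gene list forms the annotated background."""
    rng = np.random.default_rng(seed)
    out = [
        FunctionAnnotation(gene_id=g, term_id="TERM:BG", term_name="background filler",
                           namespace=namespace)
        for g in gene_ids
    ]
    for t in range(n_terms):
        hits = rng.random(len(gene_ids)) < rate
        tid = f"TERM:{t + 1:04d}"
        for gid, hit in zip(gene_ids, hits):
            if hit:
                out.append(FunctionAnnotation(gene_id=gid, term_id=tid,
                                              term_name=f"random term {t + 1}",
                                              namespace=namespace))
    return out


# ---------------------------------------------------------------------------
# writers in the exact formats annotation_io reads


def write_genes_gff3(genes: list[GeneModel], chrom_lengths: dict[str, int],
                     path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tuprepeats\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};Name={g.name}\n"
            )


def write_genes_bed(genes: list[GeneModel], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n")


RM_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeats_rm_out(repeats: list[RepeatAnnotation],
                         chrom_lengths: dict[str, int], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(RM_OUT_HEADER)
        for i, r in enumerate(repeats, 1):
            iv = r.interval
            left = chrom_lengths.get(iv.chrom, iv.end) - iv.end
            fh.write(
                f"  239  1.0  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}"
                f"  ({left})  +  {r.repeat_class.replace(' ', '_')}"
                f"  {r.repeat_class}  1  {iv.length}  (0)  {i}\n"
            )


def write_repeats_bed(repeats: list[RepeatAnnotation], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_class}\t0\t.\n")


def _write_annotations(annotations: list[FunctionAnnotation], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.term_id}\t{a.term_name}\n")
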