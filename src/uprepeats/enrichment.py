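"""Functional association: pathway profile matrices and hypergeometric SEA.

Singular enrichment analysis tests each configuration pattern's gene set
against a functional term by the hypergeometric distribution: with N
background (annotated) genes of which n carry the term, drawing the
pattern's K annotated genes, the probability of observing k or more term
carriers is

    P(X >= k) = sum_{j >= k} C(n, j) C(N - n, K - j) / C(N, K).

The point mass P(X = k) is reported alongside, and the significance flag
uses the upper tail at the conventional cutoff (default 0.05, raw p;
Benjamini-Hochberg available by flag).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import hierarchical_cluster, pearson_distance
from .types import (
    Dendrogram,
    EnrichmentResult,
    FunctionAnnotation,
    PatternCatalog,
    ValidationError,
)


def _validate_counts(k, K, n, N) -> tuple:
    k, K, n, N = (np.asarray(x, dtype=np.int64) for x in (k, K, n, N))
    k, K, n, N = np.broadcast_arrays(k, K, n, N)
    if not (np.all(0 <= K) and np.all(K <= N) and np.all(0 <= n) and np.all(n <= N)):
        raise ValidationError("need 0 <= K, n <= N")
    if not (np.all(0 <= k) and np.all(k <= np.minimum(K, n))):
        raise ValidationError("need 0 <= k <= min(K, n)")
    return k, K, n, N


def hypergeom_pmf(k, K, n, N):
    """P(X = k): exactly k of the K drawn genes carry the term.

    All arguments broadcast; scalars in, float out.  Computed in log space
    by scipy, stable for N up to 1e6.
    """
    k, K, n, N = _validate_counts(k, K, n, N)
    out = stats.hypergeom.pmf(k, N, n, K)
    return float(out) if np.ndim(out) == 0 else out


def hypergeom_sf(k, K, n, N):
    """Upper tail P(X >= k); broadcasting as in :func:`hypergeom_pmf`."""
    k, K, n, N = _validate_counts(k, K, n, N)
    out = stats.hypergeom.sf(k - 1, N, n, K)
    return float(out) if np.ndim(out) == 0 else out


def _annotation_maps(
    annotations: list[FunctionAnnotation],
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[str, str], dict[str, str]]:
    term_genes: dict[str, set[str]] = defaultdict(set)
    gene_terms: dict[str, set[str]] = defaultdict(set)
    term_names: dict[str, str] = {}
    term_ns: dict[str, str] = {}
    for a in annotations:
        term_genes[a.term_id].add(a.gene_id)
        gene_terms[a.gene_id].add(a.term_id)
        term_names.setdefault(a.term_id, a.term_name)
        term_ns.setdefault(a.term_id, a.namespace)
    return term_genes, gene_terms, term_names, term_ns


def pathway_profile_matrix(
    catalog: PatternCatalog, annotations: list[FunctionAnnotation]
) -> pd.DataFrame:
    """Repeat classes x pathway terms association matrix.

    cell(class, term) = sum over the term's genes of the class's occurrence
    count in that gene's window, scaled by the term's normalization score.
    Term scores are the per-term gene counts scaled to unit variance across
    terms (score_t = |genes_t| / sd over terms of |genes|; all-equal term
    sizes leave scores at 1).  Terms with no genes are dropped.
    """
    if not annotations:
        raise ValidationError("no function annotations provided")
    term_genes, _, _, _ = _annotation_maps(annotations)
    term_genes = {t: g for t, g in term_genes.items() if g}
    gene_counts: dict[str, dict[str, int]] = {}
    for pat in catalog.patterns.values():
        per_class: dict[str, int] = defaultdict(int)
        for lab in pat.labels:
            per_class[lab] += 1
        for gid in pat.gene_ids:
            gene_counts[gid] = per_class
    classes = sorted({lab for pat in catalog.patterns.values() for lab in pat.labels})
    terms = sorted(term_genes)
    sizes = np.array([len(term_genes[t]) for t in terms], dtype=float)
    sd = sizes.std()
    scores = sizes / sd if sd > 0 else np.ones_like(sizes)
    values = np.zeros((len(classes), len(terms)))
    cidx = {c: i for i, c in enumerate(classes)}
    for j, t in enumerate(terms):
        for gid in term_genes[t]:
            counts = gene_counts.get(gid)
            if not counts:
                continue
            for lab, c in counts.items():
                values[cidx[lab], j] += c
        values[:, j] *= scores[j]
    return pd.DataFrame(values, index=classes, columns=terms)


def _unit_gene_sets(catalog: PatternCatalog, unit: str) -> dict[str, set[str]]:
    if unit == "pattern":
        return {canon: set(pat.gene_ids) for canon, pat in catalog.patterns.items()}
    if unit == "repeat":
        sets: dict[str, set[str]] = defaultdict(set)
        for pat in catalog.patterns.values():
            for lab in set(pat.labels):
                sets[lab] |= pat.gene_ids
        return dict(sets)
    raise ValidationError(f"unknown enrichment unit {unit!r}; use pattern or repeat")


def enrich_patterns(
    catalog: PatternCatalog,
    annotations: list[FunctionAnnotation],
    cutoff: float = 0.05,
    min_genes: int = 2,
    correction: str = "none",
    unit: str = "pattern",
) -> list[EnrichmentResult]:
    """Hypergeometric SEA of every (gene set, term) pair with k >= 1.

    The background N is the set of genes carrying at least one annotation.
    ``unit`` selects the tested gene sets: per configuration pattern
    (default) or per repeat class (union of genes containing the class).
    Results sort by p ascending, ties by term_id then pattern.
    """
    if correction not in ("none", "bh"):
        raise ValidationError(f"unknown correction {correction!r}")
    term_genes, gene_terms, term_names, term_ns = _annotation_maps(annotations)
    background = set(gene_terms)
    N = len(background)
    if N == 0:
        raise ValidationError("empty background: no annotated genes")
    raw: list[tuple] = []
    for set_name, genes in sorted(_unit_gene_sets(catalog, unit).items()):
        annotated = genes & background
        K = len(annotated)
        if K < min_genes:
            continue
        term_hits: dict[str, int] = defaultdict(int)
        for gid in annotated:
            for t in gene_terms[gid]:
                term_hits[t] += 1
        for t, k in sorted(term_hits.items()):
            n = len(term_genes[t] & background)
            p = hypergeom_sf(k, K, n, N)
            pp = hypergeom_pmf(k, K, n, N)
            raw.append((set_name, t, k, K, n, N, p, pp))
    if not raw:
        return []
    pvals = np.array([r[6] for r in raw])
    if correction == "bh":
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        adj = pvals
    results = [
        EnrichmentResult(
            pattern=r[0], term_id=r[1], term_name=term_names[r[1]],
            namespace=term_ns[r[1]], k=r[2], K=r[3], n=r[4], N=r[5],
            p_value=r[6], p_point=r[7], p_adjusted=float(a),
            significant=bool(a <= cutoff),
        )
        for r, a in zip(raw, adj)
    ]
    results.sort(key=lambda e: (e.p_value, e.term_id, e.pattern))
    return results


def cluster_function_heatmap(
    profile: pd.DataFrame, linkage: str = "complete"
) -> tuple[Dendrogram, pd.DataFrame]:
    """Cluster repeat classes on a class x term profile; return the ordered
    matrix for heatmap export (values untouched, rows/columns permuted)."""
    dendro = hierarchical_cluster(pearson_distance(profile), linkage=linkage)
    from scipy.cluster.hierarchy import leaves_list

    row_order = [profile.index[i] for i in leaves_list(dendro.linkage_matrix)]
    ordered = profile.loc[row_order]
    col_order = ordered.sum(axis=0).sort_values(ascending=False).index
    return dendro, ordered[col_order]
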