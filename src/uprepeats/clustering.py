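"""Repeat co-occurrence clustering with bootstrap configuration support.

Repeat classes are profiled by their occurrence counts across gene promoter
windows, compared with Pearson correlation distance d = 1 - r, and
clustered agglomeratively (UPGMA/average or complete linkage).  Cluster
stability is quantified as the frequency of configuration (FC): the
fraction of gene-column bootstrap replicates whose recomputed dendrogram
contains the same leaf set, in the style of pvclust.  The reporting
threshold used downstream is FC >= 0.7.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import Dendrogram, FCReport, PatternCatalog, ValidationError

LINKAGE_METHODS = {"upgma": "average", "complete": "complete"}

# heights reported per linkage: UPGMA as ultrametric half-distances
# (phylogenetic tree-depth convention), complete as full merge distances
DEFAULT_HEIGHT_CONVENTION = {"upgma": "half", "complete": "full"}


def cooccurrence_profiles(catalog: PatternCatalog) -> pd.DataFrame:
    """Repeat classes x genes matrix of window occurrence counts.

    Column sums equal each gene's repeat count; only classes observed at
    least once get a row.  Repeat-free genes are excluded (all-zero columns
    carry no co-occurrence information).
    """
    classes: set[str] = set()
    for pat in catalog.patterns.values():
        classes.update(pat.labels)
    class_list = sorted(classes)
    gene_list: list[str] = []
    cols: list[np.ndarray] = []
    idx = {c: i for i, c in enumerate(class_list)}
    for canon in sorted(catalog.patterns):
        pat = catalog.patterns[canon]
        vec = np.zeros(len(class_list), dtype=float)
        for lab in pat.labels:
            vec[idx[lab]] += 1
        for gid in sorted(pat.gene_ids):
            gene_list.append(gid)
            cols.append(vec)
    values = np.column_stack(cols) if cols else np.zeros((len(class_list), 0))
    return pd.DataFrame(values, index=class_list, columns=gene_list)


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson(r) over matrix rows; d in [0, 2], zero diagonal."""
    if matrix.shape[0] < 2:
        raise ValidationError("need >= 2 rows to compute pairwise distances")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    dead = [str(matrix.index[i]) for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValidationError(
            f"zero-variance profile row(s), Pearson r undefined: {dead}"
        )
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away float noise
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _linkage(dist_values: np.ndarray, linkage: str) -> np.ndarray:
    if linkage not in LINKAGE_METHODS:
        raise ValidationError(f"unknown linkage {linkage!r}; use upgma or complete")
    if np.isnan(dist_values).any():
        raise ValidationError("distance matrix contains NaN")
    condensed = squareform(dist_values, checks=False)
    return hierarchy.linkage(condensed, method=LINKAGE_METHODS[linkage])


def hierarchical_cluster(
    dist: pd.DataFrame,
    linkage: str = "upgma",
    height_convention: str | None = None,
) -> Dendrogram:
    """Agglomerative clustering of a labelled distance matrix."""
    if dist.shape[0] != dist.shape[1] or dist.shape[0] < 2:
        raise ValidationError("distance matrix must be square with n >= 2")
    Z = _linkage(dist.to_numpy(dtype=float), linkage)
    convention = height_convention or DEFAULT_HEIGHT_CONVENTION[linkage]
    return Dendrogram(
        labels=[str(x) for x in dist.index],
        linkage_matrix=Z,
        height_convention=convention,
    )


def _bootstrap_distance(values: np.ndarray) -> np.ndarray:
    """Pearson distance tolerant of zero-variance rows (bootstrap replicates
    may flatten a profile; such rows get r = 0, d = 1, rather than failing)."""
    sd = values.std(axis=1)
    safe = values.copy()
    flat = sd == 0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(safe)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def fc_support(
    matrix: pd.DataFrame,
    linkage: str = "upgma",
    n_bootstrap: int = 100,
    seed: int | None = None,
) -> tuple[Dendrogram, list[FCReport]]:
    """Reference dendrogram plus bootstrap FC per non-root internal node.

    Gene columns are resampled with replacement ``n_bootstrap`` times; each
    replicate is reclustered and FC(node) is the fraction of replicates
    containing a cluster with exactly that node's leaf set.  The root and
    singleton leaves are trivially conserved and not reported.
    """
    if n_bootstrap < 1:
        raise ValidationError("n_bootstrap must be >= 1")
    if matrix.shape[1] < 2:
        raise ValidationError("need >= 2 gene columns to bootstrap")
    if seed is None:
        raise ValidationError("fc_support requires an explicit seed")
    dendro = hierarchical_cluster(pearson_distance(matrix), linkage=linkage)
    leafsets = dendro.node_leafsets()[:-1]  # exclude root
    counts = {ls: 0 for ls in leafsets}
    values = matrix.to_numpy(dtype=float)
    labels = [str(x) for x in matrix.index]
    rng = np.random.default_rng(seed)
    n_cols = values.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_cols, size=n_cols)
        d = _bootstrap_distance(values[:, cols])
        Z = _linkage(d, linkage)
        rep = Dendrogram(labels=labels, linkage_matrix=Z)
        present = set(rep.node_leafsets()[:-1])
        for ls in counts:
            if ls in present:
                counts[ls] += 1
    fc = {ls: counts[ls] / n_bootstrap for ls in leafsets}
    dendro.fc = fc
    dendro.n_bootstrap = n_bootstrap
    dendro.seed = seed
    reports = [
        FCReport(leafset=ls, fc=fc[ls], n_bootstrap=n_bootstrap, seed=seed)
        for ls in leafsets
    ]
    return dendro, reports


def filter_by_fc(dendro: Dendrogram, threshold: float = 0.7) -> list[frozenset]:
    """Maximal non-root subclusters with FC >= threshold, outermost first."""
    if dendro.fc is None:
        raise ValidationError("FC support not computed; run fc_support first")
    n = dendro.n_leaves
    leafsets = dendro.node_leafsets()

    def node_set(i: int) -> frozenset:
        if i < n:
            return frozenset([dendro.labels[i]])
        return leafsets[i - n]

    out: list[frozenset] = []
    # walk from the root; stop descending at the first supported node
    stack = [int(dendro.linkage_matrix[-1, 0]), int(dendro.linkage_matrix[-1, 1])]
    while stack:
        i = stack.pop(0)
        if i < n:
            continue  # singletons are not subclusters
        ls = node_set(i)
        if dendro.fc.get(ls, 0.0) >= threshold:
            out.append(ls)
        else:
            stack.append(int(dendro.linkage_matrix[i - n, 0]))
            stack.append(int(dendro.linkage_matrix[i - n, 1]))
    return sorted(out, key=lambda s: (-len(s), sorted(s)))
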