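"""Independent reference implementations used only as test oracles.

These deliberately avoid scipy and the package's own code paths: exact
integer combinatorics from a Pascal triangle for the hypergeometric
distribution, a naive O(n^3) greedy agglomeration for UPGMA/complete
linkage, and textbook-formula Pearson r / R-squared.
"""

from __future__ import annotations

import math


def pascal_triangle(nmax: int) -> list[list[int]]:
    C = [[0] * (nmax + 1) for _ in range(nmax + 1)]
    for i in range(nmax + 1):
        C[i][0] = 1
        for j in range(1, i + 1):
            C[i][j] = C[i - 1][j - 1] + C[i - 1][j]
    return C


def exact_hypergeom_pmf(k: int, K: int, n: int, N: int, C: list[list[int]]) -> float:
    """C(K,k) C(N-K, n-k) / C(N,n) with exact integer arithmetic."""
    if k > K or n - k > N - K or n - k < 0:
        return 0.0
    return C[K][k] * C[N - K][n - k] / C[N][n]


def exact_hypergeom_sf(k: int, K: int, n: int, N: int, C: list[list[int]]) -> float:
    """P(X >= k) as an exact integer ratio."""
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            total += C[K][j] * C[N - K][n - j]
    return total / C[N][n]


def naive_linkage_clades(
    D: "list[list[float]]", method: str
) -> list[tuple[frozenset, float]]:
    """Greedy agglomeration: repeatedly merge the closest pair (ties by the
    lowest index pair), updating distances by the arithmetic mean weighted
    by cluster size (UPGMA) or the maximum (complete).  Returns internal
    nodes as (leaf-index set, merge distance)."""
    n = len(D)
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i][j] for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_id = n
    clades: list[tuple[frozenset, float]] = []
    while len(active) > 1:
        best = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                i, j = active[a_idx], active[b_idx]
                d = dist[(min(i, j), max(i, j))]
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = members[i] | members[j]
        clades.append((merged, d))
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            if method == "upgma":
                dn = (len(members[i]) * dik + len(members[j]) * djk) / len(merged)
            elif method == "complete":
                dn = max(dik, djk)
            else:
                raise ValueError(method)
            dist[(min(next_id, k), max(next_id, k))] = dn
        members[next_id] = merged
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return clades


def pearson_r(x: "list[float]", y: "list[float]") -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def r_squared(x: "list[float]", y: "list[float]") -> float:
    return pearson_r(x, y) ** 2
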