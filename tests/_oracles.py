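"""Independent brute-force / closed-form oracles used only by the tests.

Each oracle reimplements a quantity from first principles by a different
route than the package (triple loops, exhaustive enumeration, incomplete
beta functions) so agreement is evidence of correctness, not tautology.
"""

from itertools import combinations

import numpy as np
from scipy import special


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Topological overlap by an explicit triple loop over shared neighbors."""
    n = a.shape[0]
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(
                a[i, u] * a[u, j] for u in range(n) if u != i and u != j
            )
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def upgma_cophenetic_bruteforce(d: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix of greedy average-linkage agglomeration.

    O(n^3) list-of-clusters implementation: repeatedly merge the pair of
    clusters with the smallest average inter-point dissimilarity and
    record the merge height for every cross pair of leaves.
    """
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for ci, cj in combinations(range(len(clusters)), 2):
            avg = np.mean([d[p, q] for p in clusters[ci] for q in clusters[cj]])
            if best is None or avg < best[0]:
                best = (avg, ci, cj)
        height, ci, cj = best
        for p in clusters[ci]:
            for q in clusters[cj]:
                coph[p, q] = coph[q, p] = height
        merged = clusters[ci] + clusters[cj]
        clusters = [
            c for idx, c in enumerate(clusters) if idx not in (ci, cj)
        ] + [merged]
    return coph


def hypergeom_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P[overlap >= k] by enumerating all C(N, n) equally likely draws."""
    population = list(range(N))
    term_genes = set(range(K))
    hits = total = 0
    for draw in combinations(population, n):
        total += 1
        if len(term_genes & set(draw)) >= k:
            hits += 1
    return hits / total


def pearson_p_betainc(r: float, n: int) -> float:
    """Two-sided p for Pearson r via the regularized incomplete beta function."""
    df = n - 2
    t2 = r * r * df / (1.0 - r * r)
    return float(special.betainc(df / 2.0, 0.5, df / (df + t2)))


def anova_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA by explicit sums of squares and the F survival function."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    x = df2 / (df2 + df1 * f)
    p = float(special.betainc(df2 / 2.0, df1 / 2.0, x))
    return f, p


def wls_group_means_oracle(
    y: np.ndarray, w: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Generalized least squares on a group-indicator design via lstsq."""
    levels = sorted(set(groups))
    X = np.column_stack([(groups == g).astype(float) for g in levels])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def pearson_sum_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook sum-formula Pearson correlation."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    return (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
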