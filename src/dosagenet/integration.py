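"""Module-trait integration: trait correlations, gene significance, module membership.

All correlation tests are Pearson with two-sided p-values from the exact
t transform t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
Expression and eigengenes are averaged over clonal replicates to genotype
level before correlating against genotype-level traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationRecord",
    "CandidateScore",
    "pearson_with_p",
    "trait_correlation_table",
    "module_trait_correlations",
    "gene_significance",
    "module_membership",
    "rank_candidate_genes",
    "aggregate_to_genotype",
]


@dataclass(frozen=True)
class CorrelationRecord:
    pair: tuple[str, str]
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class CandidateScore:
    gene: str
    module: str
    trait: str
    gs: float
    mm: float
    go_terms: frozenset
    rank: int


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pearson r and two-sided t-transform p over pairwise-complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    if x.std() == 0 or y.std() == 0:
        return np.nan, n, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, n, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, n, float(min(p, 1.0))


def trait_correlation_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p for every unordered trait pair.

    Uses pairwise-complete observations; constant traits yield missing r
    with a warning. Returns columns trait_a, trait_b, r, n, p,
    significant (p < 0.05).
    """
    cols = list(traits.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            try:
                r, n, p = pearson_with_p(traits[a].to_numpy(), traits[b].to_numpy())
            except ValueError:
                warnings.warn(f"pair ({a}, {b}): fewer than 3 complete pairs",
                              stacklevel=2)
                r, n, p = np.nan, 0, np.nan
            if np.isnan(r):
                warnings.warn(f"undefined correlation for pair ({a}, {b})",
                              stacklevel=2)
            rows.append({"trait_a": a, "trait_b": b, "r": r, "n": n, "p": p})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < 0.05
    return out


def aggregate_to_genotype(
    values: pd.DataFrame, sample_to_genotype: pd.Series
) -> pd.DataFrame:
    """Average columns (samples) sharing a genotype; columns become genotypes."""
    mapping = sample_to_genotype.reindex(values.columns)
    if mapping.isna().any():
        missing = list(values.columns[mapping.isna()])
        raise ValueError(f"samples without genotype: {missing}")
    return values.T.groupby(mapping).mean().T


def module_trait_correlations(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    sample_to_genotype: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Eigengene values are averaged over clonal replicates per genotype
    before correlating; genotypes absent from the trait table are dropped
    with a warning. Returns a long frame module, trait, r, n, p,
    significant.
    """
    if sample_to_genotype is not None:
        me = aggregate_to_genotype(eigengenes, sample_to_genotype)
    else:
        me = eigengenes
    shared = me.columns.intersection(traits.index)
    dropped = me.columns.difference(traits.index)
    if len(dropped):
        warnings.warn(f"genotypes without traits dropped: {list(dropped)}",
                      stacklevel=2)
    if len(shared) < 3:
        raise ValueError("fewer than 3 genotypes shared with the trait table")
    rows = []
    for module in me.index:
        for trait in traits.columns:
            r, n, p = pearson_with_p(
                me.loc[module, shared].to_numpy(),
                traits.loc[shared, trait].to_numpy(),
            )
            rows.append({"module": module, "trait": trait, "r": r, "n": n, "p": p})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    return out


def gene_significance(
    expression: pd.DataFrame,
    trait: pd.Series,
    sample_to_genotype: pd.Series | None = None,
) -> pd.Series:
    """Correlation of each gene's (genotype-aggregated) expression with a trait."""
    if sample_to_genotype is not None:
        expr = aggregate_to_genotype(expression, sample_to_genotype)
    else:
        expr = expression
    shared = expr.columns.intersection(trait.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 genotypes shared with the trait")
    x = expr[shared].to_numpy(dtype=float)
    y = trait[shared].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        gs = (xc @ yc) / denom
    return pd.Series(gs, index=expr.index, name="GS")


def module_membership(
    expression: pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """Correlation of each gene with each module eigengene (per sample).

    Returns a genes x modules frame (kME).
    """
    shared = expression.columns.intersection(eigengenes.columns)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    x = expression[shared].to_numpy(dtype=float)
    m = eigengenes[shared].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    mc = m - m.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    mn = np.sqrt((mc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = (xc @ mc.T) / np.outer(xn, mn)
    return pd.DataFrame(mm, index=expression.index, columns=eigengenes.index)


def rank_candidate_genes(
    module: str,
    trait: str,
    labels: pd.Series,
    gs: pd.Series,
    mm: pd.DataFrame,
    enriched_terms: set,
    go_map: pd.DataFrame,
) -> list[CandidateScore]:
    """Rank a module's genes annotated with enriched terms by GS and MM.

    Only genes of the module carrying at least one enriched annotation
    term qualify. Genes are ordered by the *worse* of their two ranks on
    |GS| and module membership (both descending), so a candidate must
    score well on both; ties break by |GS| then gene id.
    """
    members = labels.index[labels == module]
    gene_terms = go_map.groupby("gene")["term"].apply(set)
    qualified = [
        g
        for g in members
        if enriched_terms & gene_terms.get(g, set())
    ]
    if not qualified:
        warnings.warn(
            f"module {module}: no member annotated with an enriched term",
            stacklevel=2,
        )
        return []
    abs_gs = gs.reindex(qualified).abs()
    kme = mm.loc[qualified, module]
    rank_gs = abs_gs.rank(ascending=False, method="min")
    rank_mm = kme.rank(ascending=False, method="min")
    worst = pd.concat([rank_gs, rank_mm], axis=1).max(axis=1)
    order = sorted(qualified, key=lambda g: (worst[g], -abs_gs[g], g))
    return [
        CandidateScore(
            gene=g,
            module=module,
            trait=trait,
            gs=float(gs[g]),
            mm=float(kme[g]),
            go_terms=frozenset(enriched_terms & gene_terms.get(g, set())),
            rank=i + 1,
        )
        for i, g in enumerate(order)
    ]
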