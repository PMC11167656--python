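"""Hypergeometric overrepresentation of annotation terms within modules.

The test asks whether a module contains more genes carrying a term than
expected when drawing the module's genes at random from the background:
p = P[X >= k] for X ~ Hypergeometric(N, K, n) with N the background size,
K the term's background count, n the module's background count and k the
observed overlap. The term mapping is flat — no propagation through the
ontology graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd
from scipy import stats

__all__ = ["EnrichmentRecord", "module_go_enrichment"]


@dataclass(frozen=True)
class EnrichmentRecord:
    module: str
    term: str
    background_size: int   # N
    term_size: int         # K
    module_size: int       # n
    overlap: int           # k
    p: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), including the observed k."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def module_go_enrichment(
    labels: pd.Series,
    go_map: pd.DataFrame,
    background: Literal["annotated", "all"] = "annotated",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test for every (module, term) with overlap.

    Parameters
    ----------
    labels
        gene -> module name ("grey" genes contribute to the background but
        are not tested as a module of interest — they are still reported).
    go_map
        Two-column frame (gene, term), one pair per row.
    background
        "annotated" (default): network genes with at least one annotation;
        "all": every network gene.
    alpha
        Raw significance cutoff for the flag column.

    Returns
    -------
    Frame with module, term, N, K, n, k, p, significant; sorted by p.
    Pairs with zero overlap are excluded.
    """
    if go_map.empty:
        raise ValueError("empty gene -> term map")
    go = go_map[go_map["gene"].isin(labels.index)].drop_duplicates()
    annotated = pd.Index(go["gene"].unique())
    if background == "annotated":
        bg = annotated
    else:
        bg = labels.index
    if len(bg) == 0:
        raise ValueError("empty background")
    N = len(bg)
    term_genes = go.groupby("term")["gene"].apply(lambda s: set(s) & set(bg))
    rows = []
    for module in sorted(labels.unique()):
        members = set(labels.index[labels == module]) & set(bg)
        n = len(members)
        if n == 0:
            continue
        for term, genes in term_genes.items():
            K = len(genes)
            if K == 0:
                continue
            k = len(members & genes)
            if k == 0:
                continue
            rows.append(
                {
                    "module": module,
                    "term": term,
                    "N": N,
                    "K": K,
                    "n": n,
                    "k": k,
                    "p": hypergeom_upper_tail(N, K, n, k),
                }
            )
    out = pd.DataFrame(rows, columns=["module", "term", "N", "K", "n", "k", "p"])
    out = out.sort_values(["p", "module", "term"], kind="mergesort").reset_index(
        drop=True
    )
    out["significant"] = out["p"] < alpha
    return out
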