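"""Dosage-response scan of dQTL regions.

Lines are grouped by relative dosage score (RDS: 0.5 deletion, 1.0 no
indel, 1.5 insertion) at a dQTL region; every expressed gene in the region
is tested for expression differences across RDS groups by one-way ANOVA,
followed by a Tukey HSD post hoc (studentized range, Tukey-Kramer standard
error for unequal group sizes) with a compact letter display, and the OLS
slope of genotype-level expression on numeric RDS quantifies the dosage
effect per gene. A cis gene responding purely proportionally to copy
number has an expected slope of about 1.585 log2 units per RDS unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import RDS_DELETION, RDS_INSERTION, RDS_NEUTRAL, DosageMap, IndelEvent

__all__ = [
    "DosageResponseRecord",
    "DosageResponseScan",
    "DosageScanResults",
    "assign_rds_groups",
    "anova_across_rds",
    "tukey_posthoc",
    "dosage_slope",
    "dqtl_region_scan",
]


@dataclass
class DosageResponseRecord:
    """Per-gene dosage-response test within one dQTL region."""

    gene: str
    region: tuple[str, int, int]
    group_means: dict[float, float]
    f_statistic: float
    p: float
    tukey: pd.DataFrame = field(repr=False)
    letters: dict[float, str] = field(default_factory=dict)
    slope: float = np.nan
    significant: bool = False


def assign_rds_groups(
    region: tuple[str, int, int],
    indels: list[IndelEvent],
    lines: list[str],
    non_lesion_pool: list[str] | None = None,
    k_controls: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Group lines by RDS at a region: deletion 0.5, control 1.0, insertion 1.5.

    A line is assigned 0.5 / 1.5 when one of its deletion / insertion
    events spans (overlaps) the region. Control lines get 1.0: either all
    lesion-free lines in ``lines``, or ``k_controls`` lines drawn seeded
    from ``non_lesion_pool`` (the randomly selected non-lesion controls).

    Raises if any of the three groups ends up empty (the ANOVA across RDS
    categories would be undefined).
    """
    chrom, start, end = region
    if start > end:
        raise ValueError("malformed region: start > end")
    rds: dict[str, float] = {}
    for event in indels:
        if event.line not in lines:
            continue
        if event.overlaps(chrom, start, end):
            value = RDS_DELETION if event.type == "deletion" else RDS_INSERTION
            if event.line in rds and rds[event.line] != value:
                raise ValueError(
                    f"line {event.line} has both event types at the region"
                )
            rds[event.line] = value
    lesion_free = [ln for ln in lines if ln not in rds]
    if non_lesion_pool is not None:
        pool = [ln for ln in non_lesion_pool if ln in lesion_free]
        if k_controls is not None:
            if k_controls > len(pool):
                raise ValueError("k_controls exceeds the non-lesion pool")
            rng = np.random.default_rng(seed)
            pool = sorted(rng.choice(pool, size=k_controls, replace=False))
        controls = pool
    else:
        controls = lesion_free
    for ln in controls:
        rds[ln] = RDS_NEUTRAL
    groups = pd.Series(rds, name="rds")
    for level in (RDS_DELETION, RDS_NEUTRAL, RDS_INSERTION):
        if (groups == level).sum() == 0:
            raise ValueError(f"empty RDS group {level}: ANOVA undefined")
    return groups.sort_index()


def anova_across_rds(values_by_group: dict[float, np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F and upper-tail p across RDS groups."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([g.size for g in groups])
    n = sizes.sum()
    df_between = len(groups) - 1
    df_within = n - len(groups)
    if df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("all observations identical: F undefined")
        warnings.warn("zero within-group variance; p reported as 0", stacklevel=2)
        return np.inf, 0.0
    f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def _compact_letters(
    levels: list[float], distinct: set[tuple[float, float]]
) -> dict[float, str]:
    """Insert-and-absorb compact letter display.

    Means sharing a letter are not significantly different; every
    significantly different pair must carry disjoint letter sets.
    """
    letter_sets: list[set[float]] = [set(levels)]
    for a, b in distinct:
        new_sets: list[set[float]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s <= t for t in letter_sets):
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(levels.index(x) for x in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[float, str] = {lv: "" for lv in levels}
    for i, s in enumerate(letter_sets):
        for lv in s:
            out[lv] += alphabet[i]
    return {lv: "".join(sorted(out[lv])) for lv in levels}


def tukey_posthoc(
    values_by_group: dict[float, np.ndarray], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[float, str]]:
    """Tukey HSD pairwise comparisons plus a compact letter display.

    Pairwise p-values come from the studentized range distribution with
    q = |mean_i - mean_j| / sqrt(s2_pooled/2 * (1/n_i + 1/n_j)) (the
    Tukey-Kramer standard error for unequal group sizes).
    """
    levels = list(values_by_group.keys())
    groups = {lv: np.asarray(v, dtype=float) for lv, v in values_by_group.items()}
    k = len(levels)
    n = sum(g.size for g in groups.values())
    df = n - k
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    s2 = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / df
    rows = []
    distinct: set[tuple[float, float]] = set()
    for a, b in combinations(levels, 2):
        ga, gb = groups[a], groups[b]
        diff = ga.mean() - gb.mean()
        if s2 == 0:
            p = 1.0 if diff == 0 else 0.0
            q = np.inf if diff != 0 else 0.0
        else:
            se = np.sqrt(s2 / 2.0 * (1.0 / ga.size + 1.0 / gb.size))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {"group_a": a, "group_b": b, "diff": diff, "q": q, "p": p}
        )
        if p < alpha:
            distinct.add((a, b))
    table = pd.DataFrame(rows)
    letters = _compact_letters(levels, distinct)
    return table, letters


def dosage_slope(expression: pd.Series, rds: pd.Series) -> float:
    """OLS slope of genotype-level expression on numeric RDS."""
    shared = expression.index.intersection(rds.index)
    x = rds[shared].to_numpy(dtype=float)
    y = expression[shared].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct RDS values for a slope")
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def dqtl_region_scan(
    region: tuple[str, int, int],
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> list[DosageResponseRecord]:
    """Test every expressed gene in a dQTL region for dosage response.

    Parameters
    ----------
    region
        (chromosome, start, end), 1-based inclusive.
    expression
        Genes x lines genotype-level expression (post filtering); only
        genes present here are tested, so upstream low-expression
        filtering propagates.
    annotation
        Gene coordinates (chromosome, start, end).
    groups
        line -> RDS from :func:`assign_rds_groups`.
    """
    chrom, start, end = region
    in_region = annotation[
        (annotation["chromosome"] == chrom)
        & (annotation["start"] <= end)
        & (annotation["end"] >= start)
    ].index
    genes = expression.index.intersection(in_region)
    if len(genes) == 0:
        warnings.warn(f"no expressed genes in region {region}", stacklevel=2)
        return []
    lines = [ln for ln in groups.index if ln in expression.columns]
    groups = groups[lines]
    records = []
    for gene in genes:
        values = expression.loc[gene, lines]
        by_group = {
            lv: values[groups.index[groups == lv]].to_numpy(dtype=float)
            for lv in sorted(groups.unique())
        }
        f, p = anova_across_rds(by_group)
        tukey, letters = tukey_posthoc(by_group, alpha=alpha)
        slope = dosage_slope(values, groups)
        records.append(
            DosageResponseRecord(
                gene=gene,
                region=region,
                group_means={lv: float(v.mean()) for lv, v in by_group.items()},
                f_statistic=f,
                p=p,
                tukey=tukey,
                letters=letters,
                slope=slope,
                significant=p < alpha,
            )
        )
    return records


@dataclass
class DosageScanResults:
    """Fitted dosage-response scan over one dQTL region."""

    region: tuple[str, int, int]
    records: list[DosageResponseRecord]
    groups: pd.Series
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        """Per-gene table in the shape of the study's dQTL result tables."""
        rows = []
        for r in self.records:
            row = {
                "gene": r.gene,
                "F": r.f_statistic,
                "p": r.p,
                "slope": r.slope,
                "significant": r.significant,
            }
            for lv, m in r.group_means.items():
                row[f"mean_rds_{lv}"] = m
            row["letters"] = "/".join(
                r.letters.get(lv, "") for lv in sorted(r.letters)
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.records)


class DosageResponseScan:
    """Model object for the dQTL dosage-response analysis of one region.

    Built from genotype-level expression, gene annotation and either a
    precomputed line -> RDS grouping or the raw indel events from which to
    derive one. ``fit()`` runs ANOVA, Tukey HSD and the dosage slope for
    every expressed gene in the region.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        annotation: pd.DataFrame,
        region: tuple[str, int, int],
        groups: pd.Series | None = None,
        indels: list[IndelEvent] | None = None,
        non_lesion_pool: list[str] | None = None,
        k_controls: int | None = None,
        seed: int = 0,
        alpha: float = 0.05,
    ):
        self.expression = expression
        self.annotation = annotation
        self.region = region
        self.alpha = alpha
        if groups is None:
            if indels is None:
                raise ValueError("provide either groups or indels")
            groups = assign_rds_groups(
                region,
                indels,
                [c for c in expression.columns],
                non_lesion_pool=non_lesion_pool,
                k_controls=k_controls,
                seed=seed,
            )
        self.groups = groups

    def fit(self) -> DosageScanResults:
        records = dqtl_region_scan(
            self.region,
            self.expression,
            self.annotation,
            self.groups,
            alpha=self.alpha,
        )
        return DosageScanResults(
            region=self.region,
            records=records,
            groups=self.groups,
            alpha=self.alpha,
        )
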