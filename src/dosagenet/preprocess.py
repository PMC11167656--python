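"""Count preprocessing: filtering, TMM normalization, log2 CPM, precision weights.

Implements the standard 3'-tag RNA-seq preprocessing chain for a clonally
replicated population: genes whose maximum count over all libraries falls
below a threshold are dropped; between-library composition bias is corrected
with trimmed-mean-of-M-values (TMM) scaling factors; counts become
log2 counts-per-million with a small prior; a mean-variance trend supplies
per-observation precision weights; and a weighted least-squares fit of
genotype indicators collapses replicate libraries into per-genotype
expression coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "PreprocessParams",
    "NormalizedExpression",
    "GenotypeExpression",
    "filter_low_expressed",
    "tmm_norm_factors",
    "log2_cpm",
    "mean_variance_weights",
    "genotype_coefficients",
    "preprocess_counts",
]


@dataclass
class PreprocessParams:
    """Tuning knobs of the preprocessing chain.

    min_max_count
        A gene is kept only if its maximum raw count over all libraries is
        at least this value (default 10).
    prior_count
        Pseudo-count added before the log2 CPM transform (default 0.5).
    logratio_trim, abundance_trim
        Two-sided trim fractions applied to the M (log ratio) and A
        (log abundance) statistics inside TMM (defaults 0.30 / 0.05, the
        original method's values).
    lowess_span
        Span of the lowess smoother for the mean-variance trend.
    """

    min_max_count: int = 10
    prior_count: float = 0.5
    logratio_trim: float = 0.30
    abundance_trim: float = 0.05
    lowess_span: float = 0.5

    def __post_init__(self) -> None:
        if self.min_max_count < 0:
            raise ValueError("min_max_count must be >= 0")
        for name in ("logratio_trim", "abundance_trim"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")
        if not 0.0 < self.lowess_span <= 1.0:
            raise ValueError("lowess_span must be in (0, 1]")


@dataclass
class NormalizedExpression:
    """log2 CPM values with matching precision weights and scaling factors."""

    values: pd.DataFrame
    weights: pd.DataFrame
    norm_factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must share a shape")
        log_gm = np.log(self.norm_factors.to_numpy()).mean()
        if abs(log_gm) > 1e-9:
            raise ValueError("norm factors must have geometric mean 1")
        if (self.weights.to_numpy() <= 0).any():
            raise ValueError("weights must be strictly positive")


@dataclass
class GenotypeExpression:
    """Per-genotype expression coefficients from the replicate-level WLS fit."""

    coefficients: pd.DataFrame
    design: pd.Series = field(repr=False)


def filter_low_expressed(
    counts: pd.DataFrame, params: PreprocessParams | None = None
) -> pd.DataFrame:
    """Drop genes whose maximum count over all libraries is below threshold.

    Retains exactly the genes with max count >= ``params.min_max_count``;
    gene order is preserved. Idempotent.
    """
    params = params or PreprocessParams()
    if counts.empty:
        raise ValueError("empty count matrix")
    keep = counts.max(axis=1) >= params.min_max_count
    return counts.loc[keep]


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abundance_trim: float,
) -> float:
    """TMM factor of one library against the reference.

    M = log2 count-fraction ratio, A = mean log2 abundance, computed over
    genes nonzero in both libraries; both statistics are two-sided
    rank-trimmed and the factor is 2^(delta-method weighted mean of M).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a = m[finite], a[finite]
    obs_f, ref_f = obs[finite], ref[finite]
    if m.size == 0:
        raise ValueError("library shares no nonzero gene with the reference")
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    # delta-method (binomial) variance of M
    var = (lib_obs - obs_f) / (lib_obs * obs_f) + (lib_ref - ref_f) / (
        lib_ref * ref_f
    )
    w = 1.0 / var[keep]
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


def tmm_norm_factors(
    counts: pd.DataFrame, params: PreprocessParams | None = None
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference library is the one whose 75th-percentile count fraction
    is closest to the mean of those fractions across libraries.
    """
    params = params or PreprocessParams()
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two libraries")
    lib_sizes = counts.sum(axis=0).astype(float)
    if (lib_sizes == 0).any():
        raise ValueError("library with zero total count")
    mat = counts.to_numpy(dtype=float)
    q75 = np.array(
        [
            np.quantile(mat[:, j], 0.75) / lib_sizes.iloc[j]
            for j in range(mat.shape[1])
        ]
    )
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        factors[j] = _tmm_pair_factor(
            mat[:, j],
            mat[:, ref_idx],
            float(lib_sizes.iloc[j]),
            float(lib_sizes.iloc[ref_idx]),
            params.logratio_trim,
            params.abundance_trim,
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def log2_cpm(
    counts: pd.DataFrame,
    norm_factors: pd.Series,
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """log2 counts-per-million on effective (TMM-scaled) library sizes.

    value = log2((count + prior) / (lib_size * factor + 1) * 1e6)
    """
    params = params or PreprocessParams()
    factors = norm_factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("norm factors must be positive and cover all libraries")
    lib_sizes = counts.sum(axis=0).astype(float)
    eff = lib_sizes * factors + 1.0
    values = np.log2(
        (counts.to_numpy(dtype=float) + params.prior_count)
        / eff.to_numpy()[None, :]
        * 1e6
    )
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def _genotype_fit_residual_sd(
    values: np.ndarray, groups: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene residual sd around genotype means, plus the fitted values."""
    n_genes, n_libs = values.shape
    fitted = np.empty_like(values)
    for g in range(n_groups):
        cols = groups == g
        fitted[:, cols] = values[:, cols].mean(axis=1, keepdims=True)
    df_resid = n_libs - n_groups
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the variance trend")
    resid = values - fitted
    sd = np.sqrt((resid**2).sum(axis=1) / df_resid)
    return sd, fitted

def mean_variance_weights(
    log2cpm: pd.DataFrame,
    design: pd.Series,
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Precision weights from a lowess mean-variance trend.

    Per gene, the residual standard deviation of the genotype-means fit is
    square-rooted and smoothed against average log2 CPM with lowess; each
    observation's weight is the interpolated trend at its fitted value,
    raised to the -4th power (i.e. inverse predicted variance).
    """
    params = params or PreprocessParams()
    design = design.reindex(log2cpm.columns)
    if design.isna().any():
        raise ValueError("design must map every library to a genotype")
    codes, uniques = pd.factorize(design)
    if len(uniques) < 2:
        raise ValueError("need at least two genotypes for the variance trend")
    values = log2cpm.to_numpy(dtype=float)
    sd, fitted = _genotype_fit_residual_sd(values, codes, len(uniques))
    sqrt_sd = np.sqrt(sd)
    mean_log = values.mean(axis=1)
    trend = lowess(
        sqrt_sd, mean_log, frac=params.lowess_span, it=3, return_sorted=True
    )
    tx, ty = trend[:, 0], trend[:, 1]
    # collapse duplicate x for interpolation; clamp the trend away from zero
    tx, idx = np.unique(tx, return_index=True)
    ty = ty[idx]
    floor = max(1e-4, float(np.min(sqrt_sd[sqrt_sd > 0], initial=1e-4)) * 1e-2)
    predicted = np.interp(fitted, tx, np.maximum(ty, floor))
    weights = np.maximum(predicted, floor) ** (-4)
    return pd.DataFrame(weights, index=log2cpm.index, columns=log2cpm.columns)


def genotype_coefficients(
    log2cpm: pd.DataFrame,
    weights: pd.DataFrame,
    design: pd.Series,
) -> GenotypeExpression:
    """Weighted least-squares genotype means per gene.

    With a genotype-indicator design (no intercept), the WLS coefficient of
    genotype g is the weighted mean sum(w*y)/sum(w) over its libraries.
    """
    design = design.reindex(log2cpm.columns)
    known = design.notna()
    if not known.all():
        warnings.warn(
            f"libraries without genotype dropped: {list(log2cpm.columns[~known])}",
            stacklevel=2,
        )
    y = log2cpm.loc[:, known]
    w = weights.loc[:, known]
    design = design[known]
    genotypes = design.unique()
    coefs = {}
    for g in genotypes:
        cols = design.index[design == g]
        wg = w[cols].to_numpy()
        yg = y[cols].to_numpy()
        coefs[g] = (wg * yg).sum(axis=1) / wg.sum(axis=1)
    coefficients = pd.DataFrame(coefs, index=log2cpm.index)
    return GenotypeExpression(coefficients=coefficients, design=design)


def preprocess_counts(
    counts: pd.DataFrame,
    design: pd.Series,
    params: PreprocessParams | None = None,
) -> tuple[NormalizedExpression, GenotypeExpression]:
    """Run the full chain: filter -> TMM -> log2 CPM -> weights -> coefficients."""
    params = params or PreprocessParams()
    filtered = filter_low_expressed(counts, params)
    factors = tmm_norm_factors(filtered, params)
    values = log2_cpm(filtered, factors, params)
    weights = mean_variance_weights(values, design, params)
    norm = NormalizedExpression(
        values=values,
        weights=weights,
        norm_factors=factors,
        library_sizes=filtered.sum(axis=0),
    )
    geno = genotype_coefficients(values, weights, design)
    return norm, geno
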