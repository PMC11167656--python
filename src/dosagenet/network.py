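"""Weighted gene co-expression network construction and module detection.

The network is built from Pearson correlations between gene expression
profiles, raised to a soft-thresholding power chosen to approximate
scale-free topology. Topological overlap converts adjacency into a
similarity that rewards shared neighborhoods; average-linkage clustering
of the topological overlap dissimilarity yields a dendrogram that is cut
at a fixed height into color-named modules. Each module is summarized by
its eigengene (first principal component of member expression), modules
with highly correlated eigengenes are merged, and module robustness is
estimated by re-detecting modules on library subsamples.

The `CoexpressionNetwork` model class orchestrates these steps; its
`fit()` returns a `NetworkResults` with labels, eigengenes, the dendrogram
and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkParams",
    "StabilityParams",
    "ScaleFreeFit",
    "CoexpressionNetwork",
    "NetworkResults",
    "MODULE_COLORS",
    "gene_correlation_matrix",
    "soft_adjacency",
    "scale_free_fit_index",
    "choose_soft_power",
    "tom_matrix",
    "average_linkage_dendrogram",
    "cut_modules",
    "module_eigengenes",
    "merge_close_modules",
    "module_stability",
]

# canonical color order for naming modules by decreasing size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)
GREY = "grey"


@dataclass
class NetworkParams:
    """Network construction parameters.

    soft_power
        Exponent applied to the correlation-based adjacency (default 12).
    signed
        Unsigned adjacency |r|^beta (default) or signed ((1+r)/2)^beta.
    cut_height
        Static dendrogram cut height on topological overlap dissimilarity
        (default 0.99).
    min_module_size
        Clusters smaller than this are left unassigned ("grey"; default 30).
    merge_threshold
        Modules whose eigengenes correlate at or above this are merged
        (default 0.75).
    scale_free_target
        Minimum signed scale-free fit index when choosing the soft power
        (default 0.80).
    n_bins
        Connectivity bins for the scale-free fit (default 10).
    """

    soft_power: int = 12
    signed: bool = False
    cut_height: float = 0.99
    min_module_size: int = 30
    merge_threshold: float = 0.75
    scale_free_target: float = 0.80
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        for name in ("cut_height", "merge_threshold", "scale_free_target"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


@dataclass
class StabilityParams:
    """Resampling scheme for module stability (63% of libraries, 49 draws)."""

    subsample_fraction: float = 0.63
    n_iterations: int = 49
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ScaleFreeFit:
    """Connectivity distribution and its signed power-law fit."""

    connectivity: pd.Series
    fit_r2: float
    slope: float


def gene_correlation_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all gene pairs across samples.

    Constant genes are dropped with a warning (their correlation is
    undefined). Requires at least 3 samples.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    # fixed memory layout so BLAS summation order is reproducible
    values = np.ascontiguousarray(expression.to_numpy(dtype=float))
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s)", stacklevel=2
        )
        expression = expression.loc[~constant]
        values = values[~constant]
    cor = np.atleast_2d(np.corrcoef(values))
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=expression.index, columns=expression.index)


def soft_adjacency(
    cor_matrix: pd.DataFrame, params: NetworkParams | None = None
) -> pd.DataFrame:
    """Soft-thresholded adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta."""
    params = params or NetworkParams()
    r = cor_matrix.to_numpy(dtype=float)
    if np.abs(r).max() > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    if params.signed:
        a = ((1.0 + r) / 2.0) ** params.soft_power
    else:
        a = np.abs(r) ** params.soft_power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor_matrix.index, columns=cor_matrix.columns)


def scale_free_fit_index(
    adjacency: pd.DataFrame, params: NetworkParams | None = None
) -> ScaleFreeFit:
    """Signed R^2 of the log-log connectivity-frequency regression.

    Connectivity k_i is the off-diagonal row sum of the adjacency. Genes
    are binned into equal-width connectivity bins; log10 frequency is
    regressed on log10 mean connectivity over nonempty bins. The index is
    R^2 times the negated sign of the slope, so power-law *decay* scores
    positive.
    """
    params = params or NetworkParams()
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    if np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: all genes identical")
    edges = np.linspace(k.min(), k.max(), params.n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, params.n_bins - 1)
    mean_k, freq = [], []
    for b in range(params.n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k.append(k[mask].mean())
        freq.append(mask.mean())
    x = np.log10(np.asarray(mean_k))
    y = np.log10(np.asarray(freq))
    if len(x) < 2:
        raise ValueError("fewer than 2 nonempty connectivity bins")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    signed_r2 = r2 * (-np.sign(slope)) if slope != 0 else 0.0
    return ScaleFreeFit(
        connectivity=pd.Series(k, index=adjacency.index, name="k"),
        fit_r2=float(signed_r2),
        slope=float(slope),
    )


def choose_soft_power(
    cor_matrix: pd.DataFrame,
    candidates: list[int],
    params: NetworkParams | None = None,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power reaching the scale-free fit target.

    Returns (beta, diagnostics). If no candidate reaches the target, the
    candidate with the highest fit index is returned with a warning.
    """
    params = params or NetworkParams()
    if not candidates:
        raise ValueError("empty candidate power list")
    rows = []
    for beta in candidates:
        trial = NetworkParams(
            soft_power=beta, signed=params.signed, n_bins=params.n_bins
        )
        fit = scale_free_fit_index(soft_adjacency(cor_matrix, trial), trial)
        rows.append(
            {"power": beta, "fit_r2": fit.fit_r2, "slope": fit.slope,
             "mean_k": float(fit.connectivity.mean())}
        )
        if fit.fit_r2 >= params.scale_free_target:
            return beta, pd.DataFrame(rows)
    diag = pd.DataFrame(rows)
    best = int(diag.loc[diag["fit_r2"].idxmax(), "power"])
    warnings.warn(
        f"no candidate power reached fit {params.scale_free_target}; "
        f"using argmax power {best}",
        stacklevel=2,
    )
    return best, diag


def tom_matrix(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k excluding the diagonal; TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    # (A @ A)_ij counts u=i and u=j: a_ii*a_ij + a_ij*a_jj = 2*a_ij with unit diag
    shared = a @ a - 2.0 * a
    k = a.sum(axis=1) - np.diag(a)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def average_linkage_dendrogram(dissimilarity: pd.DataFrame) -> np.ndarray:
    """UPGMA (average-linkage) merge tree of a dissimilarity matrix.

    Returns a scipy linkage matrix over the rows of ``dissimilarity``.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(d, d.T, atol=1e-12) or np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    return linkage(squareform(d, checks=False), method="average")


def _name_modules(labels: pd.Series) -> pd.Series:
    """Rename integer cluster ids to canonical colors by decreasing size."""
    sizes = labels[labels != GREY].value_counts()
    # stable order: size descending, then original id for determinism
    order = sorted(sizes.index, key=lambda c: (-sizes[c], str(c)))
    mapping = {}
    for i, cid in enumerate(order):
        mapping[cid] = (
            MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        )
    return labels.map(lambda c: GREY if c == GREY else mapping[c])


def cut_modules(
    dendrogram: np.ndarray,
    gene_index: pd.Index,
    params: NetworkParams | None = None,
) -> pd.Series:
    """Static height cut of the dendrogram into color-named modules.

    Clusters are the connected components below ``cut_height``; clusters
    smaller than ``min_module_size`` become "grey" (unassigned); the rest
    are named by canonical color order by decreasing size.
    """
    params = params or NetworkParams()
    if not 0.0 < params.cut_height <= 1.0:
        raise ValueError("cut_height must be in (0, 1]")
    assignments = fcluster(dendrogram, t=params.cut_height, criterion="distance")
    labels = pd.Series(assignments, index=gene_index, name="module")
    sizes = labels.value_counts()
    small = sizes.index[sizes < params.min_module_size]
    labels = labels.map(lambda c: GREY if c in set(small) else c)
    return _name_modules(labels)


def module_eigengenes(
    expression: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """First principal component summary profile per module.

    Member genes are standardized across samples; the eigengene is the
    leading right singular vector (sample-space PC1), rescaled to unit
    variance and sign-oriented so its mean correlation with member genes
    is nonnegative. Returns a modules x samples frame.
    """
    labels = labels.reindex(expression.index)
    rows = {}
    for module in sorted(set(labels) - {GREY}):
        members = expression.loc[labels == module].to_numpy(dtype=float)
        mean = members.mean(axis=1, keepdims=True)
        sd = members.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"module {module} contains constant gene(s)")
        z = (members - mean) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        member_cor = np.array([np.corrcoef(row, me)[0, 1] for row in z])
        if member_cor.mean() < 0:
            me = -me
        rows[module] = me
    return pd.DataFrame(rows, index=expression.columns).T


def merge_close_modules(
    expression: pd.DataFrame,
    labels: pd.Series,
    params: NetworkParams | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge modules whose eigengenes correlate at or above the threshold.

    Iteratively merges the most correlated pair (if >= threshold) into one
    module named after the larger member, recomputing eigengenes each
    round. Returns (labels, eigengenes).
    """
    params = params or NetworkParams()
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {GREY})
        if len(modules) < 2:
            break
        me = module_eigengenes(expression, labels)
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] < params.merge_threshold:
            break
        a, b = me.index[i], me.index[j]
        sizes = labels.value_counts()
        keep, drop = (a, b) if sizes[a] >= sizes[b] else (b, a)
        labels = labels.replace({drop: keep})
    me = module_eigengenes(expression, labels)
    return labels, me


def _detect_labels(
    expression: pd.DataFrame, params: NetworkParams
) -> pd.Series:
    """Correlation -> adjacency -> TOM -> dendrogram -> cut -> merge."""
    cor = gene_correlation_matrix(expression)
    adj = soft_adjacency(cor, params)
    tom = tom_matrix(adj)
    dendro = average_linkage_dendrogram(1.0 - tom)
    labels = cut_modules(dendro, cor.index, params)
    if (labels != GREY).any():
        labels, _ = merge_close_modules(expression.loc[cor.index], labels, params)
    return labels.reindex(expression.index, fill_value=GREY)


def _best_jaccard(reference: set, candidates: list[set]) -> float:
    best = 0.0
    for c in candidates:
        inter = len(reference & c)
        union = len(reference | c)
        if union:
            best = max(best, inter / union)
    return best


def module_stability(
    expression: pd.DataFrame,
    labels: pd.Series,
    params: NetworkParams | None = None,
    stability: StabilityParams | None = None,
) -> pd.Series:
    """Median best-Jaccard module overlap over library subsamples.

    For each of ``n_iterations`` seeded draws of
    ceil(fraction * n_libraries) libraries, modules are re-detected and
    each original module is scored by its best Jaccard overlap with any
    re-detected module; stability is the median over iterations.
    """
    params = params or NetworkParams()
    stability = stability or StabilityParams()
    n = expression.shape[1]
    size = int(np.ceil(stability.subsample_fraction * n))
    if size < 3:
        raise ValueError("subsample would have fewer than 3 libraries")
    rng = np.random.default_rng(stability.seed)
    modules = sorted(set(labels) - {GREY})
    scores: dict[str, list[float]] = {m: [] for m in modules}
    original = {m: set(labels.index[labels == m]) for m in modules}
    for _ in range(stability.n_iterations):
        cols = rng.choice(n, size=size, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub_labels = _detect_labels(expression.iloc[:, np.sort(cols)], params)
        candidates = [
            set(sub_labels.index[sub_labels == m])
            for m in set(sub_labels) - {GREY}
        ]
        for m in modules:
            scores[m].append(_best_jaccard(original[m], candidates))
    return pd.Series(
        {m: float(np.median(scores[m])) for m in modules}, name="stability"
    )


@dataclass
class NetworkResults:
    """Fitted co-expression network: module labels and diagnostics."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    dendrogram: np.ndarray = field(repr=False)
    tom: pd.DataFrame | None = field(repr=False, default=None)
    scale_free: ScaleFreeFit | None = None
    stability: pd.Series | None = None
    params: NetworkParams | None = None

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def summary(self) -> pd.DataFrame:
        """Per-module size, mean intramodular eigengene variance share, stability."""
        sizes = self.module_sizes()
        rows = []
        for m in self.modules:
            row = {"module": m, "n_genes": int(sizes.get(m, 0))}
            if self.stability is not None:
                row["stability"] = float(self.stability.get(m, np.nan))
            rows.append(row)
        out = pd.DataFrame(rows).set_index("module")
        if GREY in sizes.index:
            out.loc[GREY, "n_genes"] = int(sizes[GREY])
        return out


class CoexpressionNetwork:
    """Weighted co-expression network model over an expression matrix.

    Parameters
    ----------
    expression
        Genes x samples matrix of normalized expression (log2 CPM or
        per-genotype coefficients).
    params
        Network construction parameters.

    Examples
    --------
    >>> net = CoexpressionNetwork(expr, NetworkParams(soft_power=12))
    >>> result = net.fit()
    >>> result.labels.value_counts()
    """

    def __init__(
        self, expression: pd.DataFrame, params: NetworkParams | None = None
    ):
        self.expression = expression
        self.params = params or NetworkParams()

    @classmethod
    def from_dataframe(
        cls, expression: pd.DataFrame, **param_kwargs
    ) -> "CoexpressionNetwork":
        return cls(expression, NetworkParams(**param_kwargs))

    def pick_soft_power(
        self, candidates: list[int] | None = None
    ) -> tuple[int, pd.DataFrame]:
        """Choose and adopt the smallest power meeting the scale-free target."""
        candidates = candidates or [1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20]
        cor = gene_correlation_matrix(self.expression)
        beta, diag = choose_soft_power(cor, candidates, self.params)
        self.params.soft_power = beta
        return beta, diag

    def fit(
        self,
        compute_stability: bool = False,
        stability_params: StabilityParams | None = None,
        keep_tom: bool = False,
    ) -> NetworkResults:
        cor = gene_correlation_matrix(self.expression)
        expr = self.expression.loc[cor.index]
        adj = soft_adjacency(cor, self.params)
        fit = scale_free_fit_index(adj, self.params)
        tom = tom_matrix(adj)
        dendro = average_linkage_dendrogram(1.0 - tom)
        labels = cut_modules(dendro, cor.index, self.params)
        if (labels != GREY).any():
            labels, me = merge_close_modules(expr, labels, self.params)
        else:
            me = pd.DataFrame(columns=expr.columns)
        labels = labels.reindex(self.expression.index, fill_value=GREY)
        stab = None
        if compute_stability:
            stab = module_stability(
                expr, labels, self.params, stability_params
            )
        return NetworkResults(
            labels=labels,
            eigengenes=me,
            dendrogram=dendro,
            tom=tom if keep_tom else None,
            scale_free=fit,
            stability=stab,
            params=self.params,
        )
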