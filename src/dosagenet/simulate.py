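"""Synthetic indel-population transcriptome generator with known ground truth.

Emulates a 3'-tag RNA-seq study of a clonally replicated poplar indel
population: ~33 genotypes with 2-3 clonal replicates each, a handful of
large chromosomal deletions/insertions confined to designated dQTL
regions, planted co-expression modules driven by genotype-level latent
factors, cis-dosage effects on genes inside indel regions, and
quantitative traits loading on module factors. Counts are drawn from a
negative-binomial model (variance = mean + phi * mean^2) on
compositionally normalized per-genotype expected expression, so library
size — not content — sets sequencing depth.

Every stochastic choice derives from the config seed, so identical
configs produce byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .dosage import DosageMap, IndelEvent, compute_gene_dosage

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "GeneAnnotation",
    "SimulatedDataset",
    "make_annotation",
    "make_indel_population",
    "simulate_counts",
    "simulate_traits",
    "simulate_dataset",
    "write_dataset",
    "DEFAULT_TRAIT_LOADINGS",
]

BACKGROUND = -1

# trait abbreviations used throughout: tree height (TH), vessel frequency
# (VF) and its height-corrected form (cVF), mean vessel diameter (MVD) and
# its corrected form (cMVD), mean vessel circularity (MVC), vessel grouping
# index (VGI), non-lumen fraction (NF), bark thickness (BT)
DEFAULT_TRAIT_LOADINGS: dict[str, tuple[int, float, float]] = {
    "TH": (0, 1.0, 0.5),
    "VF": (1, -1.0, 0.5),
    "MVD": (2, 1.0, 0.5),
    "BT": (3, 1.0, 0.5),
    "cVF": (1, 0.0, 1.0),
    "cMVD": (2, 0.0, 1.0),
    "MVC": (0, 0.0, 1.0),
    "VGI": (0, 0.0, 1.0),
    "NF": (0, 0.0, 1.0),
}


def _default_reps() -> tuple[int, ...]:
    # 25 genotypes x 3 replicates + 8 x 2 = 91 libraries
    return (3,) * 25 + (2,) * 8


@dataclass
class SimulationConfig:
    """Design of one synthetic indel-population dataset.

    The defaults emulate the study design the generator stands in for:
    33 genotypes with 2-3 clonal replicates (91 libraries), two dQTL
    regions (chromosome 9 at 6.3-6.8 Mb with 3 deletion and 2 insertion
    lines; chromosome 16 at 0-0.5 Mb with 4 and 2), four planted
    co-expression modules of 50 genes, cis-dosage effect gamma = 1 (log2
    fold per log2 dosage unit) and negative-binomial dispersion phi = 0.1.
    """

    n_genotypes: int = 33
    reps_per_genotype: int | tuple[int, ...] = field(default_factory=_default_reps)
    n_genes: int = 2000
    n_chromosomes: int = 19
    genes_per_chromosome: int | None = None
    chromosome_length: int = 10_000_000
    module_sizes: tuple[int, ...] = (50, 50, 50, 50)
    module_factor_sd: float = 2.0
    noise_dispersion: float = 0.1
    base_log2_mean_range: tuple[float, float] = (3.0, 8.0)
    library_size_range: tuple[int, int] = (1_000_000, 3_000_000)
    indel_regions: tuple[tuple[str, int, int], ...] = (
        ("Chr09", 6_300_000, 6_800_000),
        ("Chr16", 1, 500_000),
    )
    lines_with_deletion: tuple[int, ...] = (3, 4)
    lines_with_insertion: tuple[int, ...] = (2, 2)
    cis_effect: float = 1.0
    go_enrichment_fraction: float = 0.5
    n_background_terms: int = 20
    background_term_fraction: float = 0.05
    trait_loadings: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_LOADINGS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.reps_per_genotype, int):
            self.reps_per_genotype = (self.reps_per_genotype,) * self.n_genotypes
        else:
            self.reps_per_genotype = tuple(self.reps_per_genotype)
        if len(self.reps_per_genotype) != self.n_genotypes:
            raise ValueError("reps_per_genotype length must equal n_genotypes")
        if min(self.n_genotypes, self.n_genes, self.n_chromosomes) < 1:
            raise ValueError("counts must be >= 1")
        if any(r < 1 for r in self.reps_per_genotype):
            raise ValueError("each genotype needs >= 1 replicate")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes sum exceeds n_genes")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion (phi) must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("empty or invalid library_size_range")
        if self.genes_per_chromosome is None:
            self.genes_per_chromosome = math.ceil(self.n_genes / self.n_chromosomes)
        if self.genes_per_chromosome * self.n_chromosomes < self.n_genes:
            raise ValueError(
                "genes_per_chromosome x n_chromosomes smaller than n_genes"
            )
        if len(self.lines_with_deletion) != len(self.indel_regions) or len(
            self.lines_with_insertion
        ) != len(self.indel_regions):
            raise ValueError("per-region line counts must match indel_regions")
        for chrom, start, end in self.indel_regions:
            if not (1 <= start <= end <= self.chromosome_length):
                raise ValueError(
                    f"indel region {chrom}:{start}-{end} outside chromosome bounds"
                )
        n_modules = len(self.module_sizes)
        for trait, (m, _loading, _sd) in self.trait_loadings.items():
            if not 0 <= m < n_modules:
                raise ValueError(
                    f"trait {trait} references nonexistent module {m}"
                )

    @property
    def genotypes(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"L{i + 1:0{width}d}" for i in range(self.n_genotypes)]

    def chromosome_names(self) -> list[str]:
        return [f"Chr{c + 1:02d}" for c in range(self.n_chromosomes)]

    _STREAMS = {"annotation": 1, "indels": 2, "counts": 3, "traits": 4}

    def _rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, self._STREAMS[stage]])


@dataclass
class GeneAnnotation:
    """Gene coordinates, module labels and gene -> GO term map."""

    genes: pd.DataFrame            # index gene; chromosome, start, end
    go_map: pd.DataFrame           # columns gene, term
    module_labels: pd.Series       # gene -> module index (BACKGROUND = none)


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests."""

    module_label_per_gene: pd.Series
    cis_genes: set[str]
    dosage: DosageMap
    factors: pd.DataFrame          # modules x genotypes latent factors
    trait_loadings: dict[str, tuple[int, float, float]]
    seed: int

    def to_json_dict(self) -> dict:
        nonneutral = {}
        affected = self.dosage.affected_genes()
        for gene in affected:
            row = self.dosage.rds.loc[gene]
            nonneutral[gene] = {
                line: float(v) for line, v in row.items() if v != 1.0
            }
        return {
            "module_label_per_gene": {
                g: int(m) for g, m in self.module_label_per_gene.items()
            },
            "cis_genes": sorted(self.cis_genes),
            "rds_nonneutral": nonneutral,
            "lines": list(self.dosage.lines),
            "factors": {
                "index": [int(i) for i in self.factors.index],
                "columns": list(self.factors.columns),
                "values": self.factors.to_numpy().tolist(),
            },
            "trait_loadings": {
                t: [int(m), float(lo), float(sd)]
                for t, (m, lo, sd) in self.trait_loadings.items()
            },
            "seed": int(self.seed),
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "SimulationTruth":
        labels = pd.Series(data["module_label_per_gene"], name="module")
        lines = data["lines"]
        rds = pd.DataFrame(1.0, index=labels.index, columns=pd.Index(lines, name="line"))
        for gene, per_line in data["rds_nonneutral"].items():
            for line, v in per_line.items():
                rds.at[gene, line] = v
        factors = pd.DataFrame(
            data["factors"]["values"],
            index=data["factors"]["index"],
            columns=data["factors"]["columns"],
        )
        return cls(
            module_label_per_gene=labels,
            cis_genes=set(data["cis_genes"]),
            dosage=DosageMap(rds),
            factors=factors,
            trait_loadings={
                t: (int(v[0]), float(v[1]), float(v[2]))
                for t, v in data["trait_loadings"].items()
            },
            seed=int(data["seed"]),
        )


@dataclass
class SimulatedDataset:
    """One generated dataset plus the model means used to draw it."""

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    annotation: GeneAnnotation
    indels: list[IndelEvent]
    traits: pd.DataFrame
    truth: SimulationTruth
    means: pd.DataFrame = field(repr=False, default=None)


def make_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Lay out genes on chromosomes and assign module labels and GO terms.

    Genes are evenly spaced, non-overlapping, 1-based inclusive. Module
    members are drawn (seeded) from genes outside every configured indel
    region so planted trans modules stay distinct from cis-dosage genes.
    Each module gets one synthetic GO term shared by
    ``go_enrichment_fraction`` of its members; background terms annotate
    random genes.
    """
    width = len(str(config.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    chroms = config.chromosome_names()
    spacing = config.chromosome_length // config.genes_per_chromosome
    if spacing < 1:
        raise ValueError("too many genes per chromosome for chromosome_length")
    gene_length = min(3000, spacing)
    rows = []
    for i, gene in enumerate(gene_ids):
        c = i // config.genes_per_chromosome
        idx = i % config.genes_per_chromosome
        start = 1 + idx * spacing
        rows.append(
            {
                "gene": gene,
                "chromosome": chroms[c],
                "start": start,
                "end": start + gene_length - 1,
            }
        )
    genes = pd.DataFrame(rows).set_index("gene")

    in_region = pd.Series(False, index=genes.index)
    for chrom, start, end in config.indel_regions:
        hit = (
            (genes["chromosome"] == chrom)
            & (genes["start"] <= end)
            & (genes["end"] >= start)
        )
        in_region |= hit

    rng = config._rng("annotation")
    eligible = np.array(genes.index[~in_region])
    needed = sum(config.module_sizes)
    if needed > eligible.size:
        raise ValueError("not enough genes outside indel regions for modules")
    chosen = rng.choice(eligible, size=needed, replace=False)
    labels = pd.Series(BACKGROUND, index=genes.index, name="module")
    pos = 0
    for m, size in enumerate(config.module_sizes):
        labels.loc[chosen[pos:pos + size]] = m
        pos += size

    go_rows = []
    for m, size in enumerate(config.module_sizes):
        members = labels.index[labels == m]
        n_term = math.ceil(config.go_enrichment_fraction * size)
        tagged = rng.choice(np.array(members), size=n_term, replace=False)
        term = f"GO:SIM{m + 1:04d}"
        go_rows.extend({"gene": g, "term": term} for g in sorted(tagged))
    n_bg = max(1, int(round(config.background_term_fraction * config.n_genes)))
    for b in range(config.n_background_terms):
        tagged = rng.choice(np.array(genes.index), size=n_bg, replace=False)
        term = f"GO:BG{b + 1:04d}"
        go_rows.extend({"gene": g, "term": term} for g in sorted(tagged))
    go_map = pd.DataFrame(go_rows, columns=["gene", "term"])
    return GeneAnnotation(genes=genes, go_map=go_map, module_labels=labels)


def make_indel_population(
    config: SimulationConfig, annotation: GeneAnnotation
) -> tuple[list[IndelEvent], SimulationTruth]:
    """Assign indel events to lines and build the full ground truth.

    Designated lines are drawn seeded and without replacement across all
    regions, so each line carries at most one event and deletion /
    insertion sets are disjoint per region. Genotype-level module factors
    are realized here so counts and traits share them.
    """
    rng = config._rng("indels")
    genotypes = config.genotypes
    total = sum(config.lines_with_deletion) + sum(config.lines_with_insertion)
    if total > config.n_genotypes:
        raise ValueError("more designated indel lines than genotypes")
    designated = list(rng.choice(genotypes, size=total, replace=False))
    events: list[IndelEvent] = []
    pos = 0
    for r, (chrom, start, end) in enumerate(config.indel_regions):
        for _ in range(config.lines_with_deletion[r]):
            events.append(IndelEvent(designated[pos], chrom, start, end, "deletion"))
            pos += 1
        for _ in range(config.lines_with_insertion[r]):
            events.append(IndelEvent(designated[pos], chrom, start, end, "insertion"))
            pos += 1
    dosage = compute_gene_dosage(annotation.genes, events, lines=genotypes)
    cis = set(dosage.affected_genes())
    factors = pd.DataFrame(
        rng.normal(0.0, config.module_factor_sd,
                   size=(len(config.module_sizes), config.n_genotypes)),
        index=range(len(config.module_sizes)),
        columns=genotypes,
    )
    truth = SimulationTruth(
        module_label_per_gene=annotation.module_labels.copy(),
        cis_genes=cis,
        dosage=dosage,
        factors=factors,
        trait_loadings=dict(config.trait_loadings),
        seed=config.seed,
    )
    return events, truth


def simulate_counts(
    config: SimulationConfig,
    annotation: GeneAnnotation,
    indels: list[IndelEvent],
    truth: SimulationTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the genes x libraries count matrix.

    Per genotype g the log2 relative expression of gene i is
    x_ig = base_i + f_{m(i),g} + gamma * log2(RDS_ig) (the cis term only
    for genes inside indel regions). Counts for library s of genotype g
    are NegativeBinomial(mean = L_s * 2^x_ig / sum_j 2^x_jg, dispersion
    phi); clonal replicates share x and differ only by sampling noise and
    library size.

    Returns (counts, sample_sheet, means).
    """
    rng = config._rng("counts")
    genotypes = config.genotypes
    labels = truth.module_label_per_gene
    base = rng.uniform(*config.base_log2_mean_range, size=config.n_genes)
    x = np.tile(base[:, None], (1, config.n_genotypes))
    lab = labels.to_numpy()
    for m in range(len(config.module_sizes)):
        members = lab == m
        x[members, :] += truth.factors.loc[m].to_numpy()[None, :]
    gamma = config.cis_effect
    rds = truth.dosage.rds.reindex(index=labels.index, columns=genotypes)
    x += gamma * np.log2(rds.to_numpy())

    libraries, lib_geno, lib_rep = [], [], []
    for g, geno in enumerate(genotypes):
        for r in range(config.reps_per_genotype[g]):
            libraries.append(f"{geno}_r{r + 1}")
            lib_geno.append(geno)
            lib_rep.append(r + 1)
    lo, hi = config.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=len(libraries))

    rel = 2.0 ** x
    frac = rel / rel.sum(axis=0, keepdims=True)
    geno_idx = {g: i for i, g in enumerate(genotypes)}
    phi = config.noise_dispersion
    counts = np.empty((config.n_genes, len(libraries)), dtype=np.int64)
    means = np.empty_like(counts, dtype=float)
    for s, lib in enumerate(libraries):
        mu = lib_sizes[s] * frac[:, geno_idx[lib_geno[s]]]
        means[:, s] = mu
        if phi > 1e-8:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
            counts[:, s] = rng.poisson(lam)
        else:
            counts[:, s] = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=labels.index, columns=libraries)
    sheet = pd.DataFrame(
        {"genotype": lib_geno, "replicate": lib_rep},
        index=pd.Index(libraries, name="library"),
    )
    means_df = pd.DataFrame(means, index=labels.index, columns=libraries)
    return counts_df, sheet, means_df


def simulate_traits(
    config: SimulationConfig, truth: SimulationTruth
) -> pd.DataFrame:
    """Genotype-level trait values from module factors plus Gaussian noise.

    trait_t(g) = loading * f_{m,g} + Normal(0, noise_sd).
    """
    rng = config._rng("traits")
    genotypes = config.genotypes
    data = {}
    for trait, (m, loading, noise_sd) in config.trait_loadings.items():
        if m >= len(config.module_sizes):
            raise ValueError(f"trait {trait} references nonexistent module {m}")
        signal = loading * truth.factors.loc[m].to_numpy()
        noise = rng.normal(0.0, noise_sd, size=config.n_genotypes)
        data[trait] = signal + noise
    return pd.DataFrame(data, index=pd.Index(genotypes, name="genotype"))


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a complete dataset: annotation, indels, counts, traits, truth."""
    config = config or SimulationConfig()
    annotation = make_annotation(config)
    indels, truth = make_indel_population(config, annotation)
    counts, sheet, means = simulate_counts(config, annotation, indels, truth)
    traits = simulate_traits(config, truth)
    return SimulatedDataset(
        counts=counts,
        sample_sheet=sheet,
        annotation=annotation,
        indels=indels,
        traits=traits,
        truth=truth,
        means=means,
    )


def write_dataset(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write all dataset files; round-trips losslessly through the readers."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"directory does not exist: {directory}")
    paths = {
        "counts": directory / "counts.tsv",
        "sample_sheet": directory / "sample_sheet.csv",
        "annotation": directory / "annotation.tsv",
        "go_map": directory / "go_map.tsv",
        "indels": directory / "indels.tsv",
        "traits": directory / "traits.csv",
        "truth": directory / "truth.json",
    }
    io.write_counts(dataset.counts, paths["counts"])
    io.write_sample_sheet(dataset.sample_sheet, paths["sample_sheet"])
    io.write_annotation(dataset.annotation.genes, paths["annotation"])
    io.write_go_map(dataset.annotation.go_map, paths["go_map"])
    io.write_indels(dataset.indels, paths["indels"])
    io.write_traits(dataset.traits, paths["traits"])
    io.write_truth_json(dataset.truth.to_json_dict(), paths["truth"])
    return paths
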