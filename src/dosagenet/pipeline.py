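"""End-to-end pipeline: config validation, orchestration and run manifests.

A run executes filter -> TMM -> log2 CPM -> precision weights -> genotype
coefficients -> (optional indel normalization) -> network construction ->
module-trait integration -> GO enrichment -> dQTL dosage scans, writing
every stage's table plus a JSON manifest with parameters, seed and
checksums of all inputs and outputs, sufficient to reproduce the run
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .dosage import compute_gene_dosage, indel_normalize_expression
from .dosage_response import DosageResponseScan, assign_rds_groups
from .enrichment import module_go_enrichment
from .integration import (
    gene_significance,
    module_membership,
    module_trait_correlations,
    trait_correlation_table,
)
from .network import CoexpressionNetwork, NetworkParams, StabilityParams
from .preprocess import PreprocessParams, genotype_coefficients, preprocess_counts

__all__ = ["PipelineConfig", "load_config", "run_full_pipeline"]

logger = logging.getLogger("dosagenet")

_PATH_KEYS = ("counts", "sample_sheet", "annotation", "go_map", "indels", "traits")


@dataclass
class PipelineConfig:
    """Validated configuration of one full pipeline run."""

    counts: Path
    sample_sheet: Path
    annotation: Path
    go_map: Path
    indels: Path
    traits: Path
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    stability: StabilityParams = field(default_factory=StabilityParams)
    enrichment_background: str = "annotated"
    dqtl_regions: list[tuple[str, int, int]] = field(default_factory=list)
    k_controls: int | None = None
    alpha: float = 0.05
    indel_normalize: bool = False
    compute_stability: bool = False
    network_input: str = "libraries"  # or "coefficients"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.network_input not in ("libraries", "coefficients"):
            raise ValueError("network_input must be 'libraries' or 'coefficients'")
        if self.enrichment_background not in ("annotated", "all"):
            raise ValueError("enrichment_background must be 'annotated' or 'all'")
        for key in _PATH_KEYS:
            p = Path(getattr(self, key))
            setattr(self, key, p)
            if not p.is_file():
                raise FileNotFoundError(f"{key} file does not exist: {p}")


def _build_section(cls, data: dict, section: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {section}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are rejected."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file does not exist: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    base = path.parent
    for key in _PATH_KEYS:
        if key not in kwargs:
            raise ValueError(f"missing required path: {key}")
        p = Path(kwargs[key])
        kwargs[key] = p if p.is_absolute() else base / p
    if "preprocess" in kwargs:
        kwargs["preprocess"] = _build_section(
            PreprocessParams, kwargs["preprocess"], "preprocess"
        )
    if "network" in kwargs:
        kwargs["network"] = _build_section(NetworkParams, kwargs["network"], "network")
    if "stability" in kwargs:
        kwargs["stability"] = _build_section(
            StabilityParams, kwargs["stability"], "stability"
        )
    if "dqtl_regions" in kwargs:
        kwargs["dqtl_regions"] = [
            (str(c), int(s), int(e)) for c, s, e in kwargs["dqtl_regions"]
        ]
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    for key in _PATH_KEYS:
        d[key] = str(d[key])
    return d


def run_full_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and write tables plus a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    current_stage = "init"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage: %s", name)

    def save(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)
        outputs[name] = path

    try:
        stage("load")
        counts = io.read_counts(config.counts)
        sheet = io.read_sample_sheet(config.sample_sheet)
        annotation = io.read_annotation(config.annotation)
        go_map = io.read_go_map(config.go_map)
        indels = io.read_indels(config.indels)
        traits = io.read_traits(config.traits)
        design = sheet["genotype"]

        stage("preprocess")
        norm, geno = preprocess_counts(counts, design, config.preprocess)
        save("log2_cpm", norm.values)
        save("weights", norm.weights)
        save("genotype_coefficients", geno.coefficients)
        with open(outdir / "norm_factors.json", "w") as fh:
            json.dump(
                {
                    "norm_factors": norm.norm_factors.round(10).to_dict(),
                    "library_sizes": norm.library_sizes.astype(int).to_dict(),
                    "params": asdict(config.preprocess),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        outputs["norm_factors"] = outdir / "norm_factors.json"

        lines = sorted(design.unique())
        dosage = compute_gene_dosage(
            annotation.loc[annotation.index.intersection(norm.values.index)],
            indels,
            lines=lines,
        )
        expression = norm.values
        if config.indel_normalize:
            stage("indel_normalize")
            expression, replacement_log = indel_normalize_expression(
                expression, dosage, library_to_line=design
            )
            save("indel_replacement_log", replacement_log, index=False)
            # coefficients refit on normalized values
            geno = genotype_coefficients(expression, norm.weights, design)
            save("genotype_coefficients_indel_normalized", geno.coefficients)

        stage("network")
        net_input = (
            expression if config.network_input == "libraries" else geno.coefficients
        )
        net = CoexpressionNetwork(net_input, config.network)
        result = net.fit(
            compute_stability=config.compute_stability,
            stability_params=config.stability,
        )
        save("module_labels", result.labels.to_frame())
        save("eigengenes", result.eigengenes)
        if result.stability is not None:
            save("module_stability", result.stability.to_frame())

        stage("integration")
        save("trait_correlations", trait_correlation_table(traits), index=False)
        sample_to_geno = (
            design if config.network_input == "libraries" else None
        )
        mt = module_trait_correlations(
            result.eigengenes, traits, sample_to_genotype=sample_to_geno,
            alpha=config.alpha,
        )
        save("module_trait_correlations", mt, index=False)
        gs_frames = {}
        for trait in traits.columns:
            gs_frames[trait] = gene_significance(
                net_input, traits[trait], sample_to_genotype=sample_to_geno
            )
        save("gene_significance", pd.DataFrame(gs_frames))
        mm = module_membership(net_input, result.eigengenes)
        save("module_membership", mm)

        stage("enrichment")
        enr = module_go_enrichment(
            result.labels, go_map, background=config.enrichment_background,
            alpha=config.alpha,
        )
        save("go_enrichment", enr, index=False)

        stage("dosage_scan")
        scan_rows = []
        for region in config.dqtl_regions:
            groups = assign_rds_groups(
                region,
                indels,
                lines,
                non_lesion_pool=lines,
                k_controls=config.k_controls,
                seed=config.seed,
            )
            scan = DosageResponseScan(
                geno.coefficients,
                annotation,
                region,
                groups=groups,
                alpha=config.alpha,
            ).fit()
            table = scan.summary()
            if not table.empty:
                table.insert(0, "region", f"{region[0]}:{region[1]}-{region[2]}")
                scan_rows.append(table)
        if scan_rows:
            save("dosage_response", pd.concat(scan_rows))

        stage("manifest")
        manifest = {
            "params": _params_dict(config),
            "seed": config.seed,
            "inputs": {k: _sha256(getattr(config, k)) for k in _PATH_KEYS},
            "outputs": {k: _sha256(p) for k, p in sorted(outputs.items())},
        }
        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        for name, p in outputs.items():
            if not p.is_file() or p.stat().st_size == 0:
                raise RuntimeError(f"declared output missing or empty: {name}")
        return manifest_path
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{current_stage}': {exc}"
        ) from exc
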