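"""Plain-text readers and writers for the pipeline's tabular formats.

All coordinates are 1-based inclusive in memory (GFF convention); the
indel reader can convert from 0-based half-open on request. Writers are
byte-stable for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dosage import IndelEvent

__all__ = [
    "read_counts", "write_counts",
    "read_sample_sheet", "write_sample_sheet",
    "read_annotation", "write_annotation",
    "read_go_map", "write_go_map",
    "read_indels", "write_indels",
    "read_traits", "write_traits",
    "read_truth_json", "write_truth_json",
]


def _check_parent(path: Path) -> None:
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    _check_parent(path)
    out = counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"library", "genotype", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must contain columns {sorted(required)}")
    return df.set_index("library")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    _check_parent(path)
    sheet.reset_index().to_csv(path, index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    _check_parent(path)
    annotation.to_csv(path, sep="\t")


def read_go_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene", "term"]:
        raise ValueError("GO map must have exactly the columns gene, term")
    return df


def write_go_map(go_map: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    _check_parent(path)
    go_map[["gene", "term"]].to_csv(path, sep="\t", index=False)


def read_indels(path: str | Path, zero_based_half_open: bool = False) -> list[IndelEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "chromosome": str})
    events = []
    for _, row in df.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if zero_based_half_open:
            start, end = start + 1, end
        events.append(
            IndelEvent(
                line=row["line"],
                chromosome=row["chromosome"],
                start=start,
                end=end,
                type=row["type"],
            )
        )
    return events


def write_indels(events: list[IndelEvent], path: str | Path) -> None:
    path = Path(path)
    _check_parent(path)
    df = pd.DataFrame(
        [
            {
                "line": e.line,
                "chromosome": e.chromosome,
                "start": e.start,
                "end": e.end,
                "type": e.type,
            }
            for e in events
        ],
        columns=["line", "chromosome", "start", "end", "type"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "genotype"
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    _check_parent(path)
    out = traits.copy()
    out.index.name = "genotype"
    out.to_csv(path)


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth_json(truth: dict, path: str | Path) -> None:
    path = Path(path)
    _check_parent(path)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
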