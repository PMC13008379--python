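"""Delimited-text I/O for feature tables, networks, and run artifacts.

The feature table is the pipeline's universal currency: one row per subject
with metadata columns (subject_id, site, group, age, sex, icv, severity)
followed by one numeric column per region volume. Schema validation
enumerates every violation rather than stopping at the first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CovarianceNetwork

__all__ = [
    "METADATA_COLUMNS",
    "SchemaError",
    "read_feature_table",
    "write_feature_table",
    "write_network",
    "write_json",
]

METADATA_COLUMNS = ["subject_id", "site", "group", "age", "sex", "icv", "severity"]

REQUIRED_COLUMNS = ["subject_id", "site", "group", "age", "sex", "icv"]

FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """Raised with the full list of feature-table schema violations."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("feature table schema violations:\n  - " + "\n  - ".join(problems))


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_feature_table(
    path: str | Path,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a feature table from CSV/TSV.

    ``regions`` restricts the required region columns; by default every
    non-metadata column is treated as a region and must be numeric and
    finite. All schema violations are collected and raised together.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    problems: list[str] = []
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            problems.append(f"missing required column {col!r}")
    region_cols = regions if regions is not None else [
        c for c in table.columns if c not in METADATA_COLUMNS
    ]
    for col in region_cols:
        if col not in table.columns:
            problems.append(f"missing region column {col!r}")
            continue
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        for row in table.index[bad]:
            problems.append(f"malformed numeric cell at row {row}, column {col!r}: {table.loc[row, col]!r}")
        table[col] = numeric
    if "subject_id" in table.columns and table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        problems.append(f"duplicate subject_id values: {dups}")
    for col in ("age", "icv"):
        if col in table.columns:
            numeric = pd.to_numeric(table[col], errors="coerce")
            bad = numeric.isna() & table[col].notna()
            for row in table.index[bad]:
                problems.append(f"malformed numeric cell at row {row}, column {col!r}: {table.loc[row, col]!r}")
            table[col] = numeric
    if problems:
        raise SchemaError(problems)
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FORMAT)


def write_network(net: CovarianceNetwork, out_dir: str | Path, name: str) -> dict[str, Path]:
    """Write a network as square adjacency CSV and long-format edge list TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adj = out_dir / f"{name}_adjacency.csv"
    net.to_dataframe().to_csv(adj, float_format=FLOAT_FORMAT)
    edges = out_dir / f"{name}_edges.tsv"
    net.to_edge_list().to_csv(edges, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return {"adjacency": adj, "edges": edges}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
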