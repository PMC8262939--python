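"""Table schemas, validated readers/writers, and experiment configuration.

All tables are UTF-8 CSV/TSV with a header row and '.' decimal separator;
scientific notation is accepted on read.  Schemas declare per-column
semantic types and validation rules so malformed inputs fail with the row
numbers that violate them (strict mode) or are dropped with warnings
(lenient mode).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rmeco")

__all__ = [
    "ColumnSpec",
    "TableSchema",
    "SchemaError",
    "PROTEIN_SCHEMA",
    "DOMHIT_SCHEMA",
    "ALIHIT_SCHEMA",
    "ISOLATE_SCHEMA",
    "GENUS_SCHEMA",
    "read_validated",
    "write_table",
    "load_experiment_config",
    "write_manifest",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str  # "str" | "int" | "float"
    required: bool = True
    unit: str | None = None
    min_value: float | None = None
    min_exclusive: bool = False
    allowed: tuple[str, ...] | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]
    sep: str = "\t"

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(names) != len(set(names)):
            raise ValueError(f"schema {self.name}: duplicate column names")

    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]


PROTEIN_SCHEMA = TableSchema(
    "proteins",
    (
        ColumnSpec("protein_id", "str"),
        ColumnSpec("genome_id", "str"),
        ColumnSpec("contig_id", "str"),
        ColumnSpec("gene_start", "int", unit="bp", min_value=1),
        ColumnSpec("gene_end", "int", unit="bp", min_value=1),
        ColumnSpec("strand", "str", allowed=("+", "-")),
        ColumnSpec("length", "int", unit="aa", min_value=0, min_exclusive=True),
    ),
)

DOMHIT_SCHEMA = TableSchema(
    "domain_hits",
    (
        ColumnSpec("protein_id", "str"),
        ColumnSpec("profile_id", "str"),
        ColumnSpec("env_start", "int", unit="residue", min_value=1),
        ColumnSpec("env_end", "int", unit="residue", min_value=1),
        ColumnSpec("evalue", "float", min_value=0),
        ColumnSpec(
            "role", "str",
            allowed=("MTase", "REase", "specificity", "ResIII", "FP-covariate"),
        ),
    ),
)

ALIHIT_SCHEMA = TableSchema(
    "alignment_hits",
    (
        ColumnSpec("protein_id", "str"),
        ColumnSpec("query_id", "str"),
        ColumnSpec("query_length", "int", unit="aa", min_value=0, min_exclusive=True),
        ColumnSpec("align_length", "int", unit="aa", min_value=0, min_exclusive=True),
        ColumnSpec("evalue", "float", min_value=0),
        ColumnSpec("role", "str", allowed=("MTase", "REase")),
    ),
)

ISOLATE_SCHEMA = TableSchema(
    "isolates",
    (
        ColumnSpec("assembly_id", "str"),
        ColumnSpec("genus", "str"),
        ColumnSpec("phylum", "str", required=False),
        ColumnSpec("genome_size", "float", unit="bp", min_value=0, min_exclusive=True),
        ColumnSpec("rm_total", "float", min_value=0),
        ColumnSpec("rm_total_no_iig", "float", required=False, min_value=0),
        ColumnSpec("habitat", "str", required=False),
    ),
    sep=",",
)

GENUS_SCHEMA = TableSchema(
    "genus",
    (
        ColumnSpec("genus", "str"),
        ColumnSpec("n_isolates", "int", min_value=1),
        ColumnSpec("mean_rmpg", "float", min_value=0),
        ColumnSpec("std_rmpg", "float", required=False, min_value=0),
        ColumnSpec("mean_bp", "float", unit="bp", min_value=0, min_exclusive=True),
        ColumnSpec("phylum", "str", required=False),
    ),
    sep=",",
)


def read_validated(path: str | Path, schema: TableSchema, strict: bool = True) -> pd.DataFrame:
    """Read and validate a table against its schema.

    Missing required columns raise :class:`SchemaError`.  Rows violating a
    column rule are reported with their (0-based) row numbers; strict mode
    raises, lenient mode drops them with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=schema.sep)
    missing = [c for c in schema.required_names() if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    bad = np.zeros(len(df), dtype=bool)
    messages: list[str] = []
    for col in schema.columns:
        if col.name not in df.columns:
            continue
        s = df[col.name]
        if col.dtype in ("int", "float"):
            coerced = pd.to_numeric(s, errors="coerce")
            nan_rows = coerced.isna() & s.notna()
            if nan_rows.any():
                messages.append(
                    f"column {col.name}: non-numeric at rows {[int(i) for i in np.flatnonzero(nan_rows)[:10]]}"
                )
                bad |= nan_rows.to_numpy()
            df[col.name] = coerced if col.dtype == "float" else coerced
            if col.min_value is not None:
                viol = (
                    (coerced <= col.min_value) if col.min_exclusive else (coerced < col.min_value)
                ) & coerced.notna()
                if viol.any():
                    messages.append(
                        f"column {col.name}: value below minimum at rows "
                        f"{[int(i) for i in np.flatnonzero(viol)[:10]]}"
                    )
                    bad |= viol.to_numpy()
        else:
            df[col.name] = s.astype(str)
            if col.allowed is not None:
                viol = ~df[col.name].isin(col.allowed) & s.notna()
                if viol.any():
                    messages.append(
                        f"column {col.name}: disallowed value at rows "
                        f"{[int(i) for i in np.flatnonzero(viol)[:10]]}"
                    )
                    bad |= viol.to_numpy()
    if bad.any():
        detail = "; ".join(messages)
        if strict:
            raise SchemaError(f"{path.name}: {int(bad.sum())} invalid row(s): {detail}")
        logger.warning("%s: dropping %d invalid row(s): %s", path.name, int(bad.sum()), detail)
        df = df.loc[~bad].reset_index(drop=True)
    # integer columns coerced after row filtering so NaNs never block the cast
    for col in schema.columns:
        if col.dtype == "int" and col.name in df.columns:
            df[col.name] = df[col.name].astype(np.int64)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> None:
    """Write a table in the dialect its schema declares (TSV or CSV)."""
    sep = schema.sep if schema is not None else ","
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


@dataclass
class ExperimentConfig:
    """YAML-backed experiment description for the simulation CLI."""

    model: str = "general"
    arrangement: str = "subset"
    n_levels: int = 2
    m_v: float = 0.99
    seed: int = 0
    s_min: float = 1e3
    s_max: float = 1e9
    n_supply: int = 30
    n_draws: int = 1000
    params: dict = field(default_factory=dict)
    lhs_ranges: dict = field(default_factory=dict)
    include_zero_level: bool = False


def load_experiment_config(path: str | Path | None) -> ExperimentConfig:
    if path is None:
        return ExperimentConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    return ExperimentConfig(**raw)


def write_manifest(out_dir: str | Path, command: str, seed: int, config: dict) -> Path:
    """Drop a reproducibility manifest next to a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
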