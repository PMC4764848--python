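"""CSV readers and writers for the pipeline's interchange schemas.

All files are comma-separated UTF-8 with a mandatory header row and "."
decimal separator.

Schemas
-------
metabolite CSV : ``parent_id, replicate, internal_standard_area, <analyte>...``
    Raw peak areas, one row per (parent, replicate).
metadata CSV : ``parent_id, group, f_i, origin``
trait CSV : ``id, YPP, MSPH, HD``
    Replicate-mean trait values for lines or hybrids.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel, ParentLine, SchemaError, validate_trait_table
from .preprocess import MetaboliteMatrix

logger = logging.getLogger("hybridmet")

_META_COLS = ("parent_id", "group", "f_i", "origin")
_MET_FIXED = ("parent_id", "replicate", "internal_standard_area")


def _read_csv(path: str | Path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} file not found: {path}")
    try:
        # round_trip parsing so write -> read reproduces floats exactly
        return pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:
        raise SchemaError(f"{name}: could not parse {path}: {exc}") from exc


def read_metadata(path: str | Path) -> Panel:
    df = _read_csv(path, "metadata")
    missing = [c for c in _META_COLS[:2] if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata: missing column(s) {missing}")
    lines = []
    for _, row in df.iterrows():
        f_i = row.get("f_i")
        origin = row.get("origin")
        lines.append(
            ParentLine(
                id=str(row["parent_id"]),
                group=str(row["group"]),
                f_i=None if pd.isna(f_i) else float(f_i),
                origin=None if pd.isna(origin) else str(origin),
            )
        )
    return Panel(lines)


def read_metabolites(path: str | Path) -> MetaboliteMatrix:
    """Raw peak-area matrix at stage='raw' with internal-standard areas."""
    df = _read_csv(path, "metabolite")
    missing = [c for c in _MET_FIXED if c not in df.columns]
    if missing:
        raise SchemaError(f"metabolite: missing column(s) {missing}")
    analytes = [c for c in df.columns if c not in _MET_FIXED]
    if not analytes:
        raise SchemaError("metabolite: no analyte columns")
    for col in analytes + ["internal_standard_area"]:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise SchemaError(f"metabolite: non-numeric cell at row {bad[0]}, column {col!r}")
    idx = pd.MultiIndex.from_frame(df[["parent_id", "replicate"]])
    if idx.duplicated().any():
        dup = idx[idx.duplicated()][0]
        raise SchemaError(f"metabolite: duplicated (parent, replicate) row {dup}")
    values = df[analytes].astype(float).set_axis(idx, axis=0)
    std = df["internal_standard_area"].astype(float).set_axis(idx, axis=0)
    return MetaboliteMatrix(values=values, stage="raw", internal_standard=std)


def read_trait_table(path: str | Path, name: str = "trait table") -> pd.DataFrame:
    df = _read_csv(path, name)
    if "id" not in df.columns:
        raise SchemaError(f"{name}: missing 'id' column")
    df = df.set_index("id")
    return validate_trait_table(df, name=name)


def read_panel(
    metabolite_csv: str | Path,
    metadata_csv: str | Path,
    trait_csv: str | Path,
) -> tuple[Panel, MetaboliteMatrix, pd.DataFrame]:
    """Read and cross-reference the three parental input files.

    Every metabolite and trait row id must appear in the metadata; ids in
    the metadata without measurements are a hard error too (no silent
    drops).
    """
    panel = read_metadata(metadata_csv)
    raw = read_metabolites(metabolite_csv)
    traits = read_trait_table(trait_csv, name="parent trait table")

    meta_ids = set(panel.ids)
    met_ids = set(raw.parent_ids)
    trait_ids = set(traits.index.astype(str))
    for label, ids in (("metabolite", met_ids), ("trait", trait_ids)):
        orphan = sorted(ids - meta_ids)
        if orphan:
            raise SchemaError(f"{label} row id(s) absent from metadata: {orphan[:5]}")
        absent = sorted(meta_ids - ids)
        if absent:
            raise SchemaError(f"parent(s) without {label} rows: {absent[:5]}")
    logger.info(
        "panel read: %d parents, %d analytes, %d replicate rows",
        len(panel), raw.n_analytes, raw.values.shape[0],
    )
    return panel, raw, traits


def write_matrix(matrix: MetaboliteMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path)


def write_report(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write one CSV per table; returns a manifest of (file, n_rows).

    Column order is whatever the table carries — construction sites keep
    it deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=not isinstance(table.index, pd.RangeIndex))
        records.append({"file": path.name, "n_rows": int(table.shape[0])})
        logger.info("wrote %s (%d rows)", path, table.shape[0])
    manifest = pd.DataFrame(records, columns=["file", "n_rows"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
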