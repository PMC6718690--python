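"""Readers and writers for the package's plain-text table formats.

The cell-table dialect mirrors the raw per-cell export of a supervised
image-analysis system: one CSV row per segmented cell with nucleus
coordinates in µm (per-image frame, origin at the tile corner, y increasing
downward), identifiers, tissue labels, and per-marker mean intensities.

Required columns::

    cell_id, patient_id, image_id, roi, x_um, y_um, compartment,
    CD68, CD163, CD206, IRF8, PDL1, AE1AE3

Optional columns: ``exposure_<marker>`` (per-marker exposure times),
``phenotype`` (gate output), ``signed_distance_um``. ROI and compartment
vocabularies are closed; single-letter aliases (C/E/M/N, T/S) are accepted
on read and normalized.

Expression matrices are dense TSV with genes in rows and samples in
columns; survival records are CSV (patient_id, time, event).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .phenotype import MARKERS

REQUIRED_COLUMNS: tuple[str, ...] = (
    "cell_id",
    "patient_id",
    "image_id",
    "roi",
    "x_um",
    "y_um",
    "compartment",
) + MARKERS

ROI_VOCAB: tuple[str, ...] = ("core", "edge", "margin", "normal")
ROI_ALIASES: dict[str, str] = {"C": "core", "E": "edge", "M": "margin", "N": "normal"}
COMPARTMENT_VOCAB: tuple[str, ...] = ("tumor_nest", "stroma")
COMPARTMENT_ALIASES: dict[str, str] = {"T": "tumor_nest", "S": "stroma"}

_NUMERIC = ("x_um", "y_um") + MARKERS


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell-table CSV.

    Raises :class:`SchemaError` naming missing required columns, rows with
    non-finite numbers (by line number), or unknown ROI / compartment
    tokens.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    numeric = list(_NUMERIC) + [c for c in df.columns if c.startswith("exposure_")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise SchemaError(f"{path.name}: non-numeric value in column {col!r} at line {line}")
        df[col] = vals
    df["roi"] = df["roi"].replace(ROI_ALIASES)
    bad_roi = set(df["roi"].unique()) - set(ROI_VOCAB)
    if bad_roi:
        raise SchemaError(f"{path.name}: unknown roi token(s): {sorted(bad_roi)}")
    df["compartment"] = df["compartment"].replace(COMPARTMENT_ALIASES)
    bad_comp = set(df["compartment"].unique()) - set(COMPARTMENT_VOCAB)
    if bad_comp:
        raise SchemaError(f"{path.name}: unknown compartment token(s): {sorted(bad_comp)}")
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table in the dialect; round-trips through
    :func:`read_cell_table`."""
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cannot write cell table; missing column(s): {missing}")
    ordered = list(REQUIRED_COLUMNS) + [c for c in cells.columns if c not in REQUIRED_COLUMNS]
    cells[ordered].to_csv(path, index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix from dense TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise SchemaError(f"{Path(path).name}: duplicate gene identifiers")
    if df.columns.has_duplicates:
        raise SchemaError(f"{Path(path).name}: duplicate sample identifiers")
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise SchemaError(f"{Path(path).name}: non-finite expression values")
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "time", "event") if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing column(s): {missing}")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    if (df["time"] < 0).any():
        raise SchemaError(f"{Path(path).name}: negative survival times")
    df["event"] = df["event"].astype(bool)
    return df


def write_survival(records: pd.DataFrame, path: str | Path) -> None:
    records[["patient_id", "time", "event"]].to_csv(path, index=False)
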