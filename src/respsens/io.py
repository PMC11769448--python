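"""CSV/YAML/JSON readers and writers for the pipeline's file surface.

Dialect: comma-separated UTF-8 with a mandatory header row; doses always in
µg/cm². Readers validate schema and units row by row and raise
:class:`~respsens.errors.SchemaError` naming the file, row and column of the
first malformed cell (rows are numbered as in the file, header = row 1).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List

import pandas as pd
import yaml

from .errors import SchemaError
from .types import COMPARTMENTS, MARKERS, ROLES, WellReading

WELL_COLUMNS = ("compartment", "role", "dose_ug_cm2", "replicate", "fluorescence")
EVENT_COLUMNS = ("condition_id", "tube", "marker", "fluorescence")
MFI_COLUMNS = (
    "chemical", "dose_tier", "marker", "mfi_sample", "mfi_isotype_sample",
    "mfi_vehicle", "mfi_isotype_vehicle", "viable_fraction",
)


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError("no records (empty file)", path=path) from None
    if len(df) == 0:
        raise SchemaError("no records", path=path)
    return df


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s) {missing}", path=path)


def read_wells(path) -> pd.DataFrame:
    """Load and validate a viability-plate table (`wells.csv`)."""
    df = _read_csv(path)
    _require_columns(df, WELL_COLUMNS, path)
    if "chemical" not in df.columns:
        df = df.assign(chemical="sample")
    for i, row in df.iterrows():
        rownum = i + 2
        if row["compartment"] not in COMPARTMENTS:
            raise SchemaError(
                f"unknown compartment {row['compartment']!r}",
                path=path, row=rownum, column="compartment",
            )
        if row["role"] not in ROLES:
            raise SchemaError(
                f"unknown role {row['role']!r}", path=path, row=rownum, column="role"
            )
        dose = row["dose_ug_cm2"]
        has_dose = not (dose is None or (isinstance(dose, str) and dose == "")
                        or (isinstance(dose, float) and math.isnan(dose)))
        if row["role"] == "sample":
            if not has_dose or float(dose) <= 0:
                raise SchemaError(
                    "sample wells need a positive dose (µg/cm²)",
                    path=path, row=rownum, column="dose_ug_cm2",
                )
        elif has_dose:
            raise SchemaError(
                f"{row['role']} wells must not carry a dose",
                path=path, row=rownum, column="dose_ug_cm2",
            )
        try:
            f = float(row["fluorescence"])
        except (TypeError, ValueError):
            f = float("nan")
        if not math.isfinite(f):
            raise SchemaError(
                f"fluorescence {row['fluorescence']!r} is not a finite number",
                path=path, row=rownum, column="fluorescence",
            )
    return df


def wells_from_frame(df: pd.DataFrame) -> Dict[str, List[WellReading]]:
    """Convert a validated wells table into per-chemical WellReading lists."""
    out: Dict[str, List[WellReading]] = {}
    for _, row in df.iterrows():
        dose = row["dose_ug_cm2"]
        has_dose = not (dose is None or (isinstance(dose, str) and dose == "")
                        or (isinstance(dose, float) and math.isnan(dose)))
        out.setdefault(str(row.get("chemical", "sample")), []).append(WellReading(
            compartment=row["compartment"],
            role=row["role"],
            raw_fluorescence=float(row["fluorescence"]),
            dose=float(dose) if has_dose else None,
            replicate_id=str(row["replicate"]),
            chemical=str(row.get("chemical", "sample")),
        ))
    return out


def read_events(path) -> pd.DataFrame:
    """Load and validate an event-level flow table (`events.csv`)."""
    df = _read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    if "dead" not in df.columns and "dead_stain" not in df.columns:
        raise SchemaError(
            "need either a 'dead' flag or a 'dead_stain' intensity column", path=path
        )
    bad_tube = ~df["tube"].isin(["stained", "isotype"])
    if bad_tube.any():
        i = int(df.index[bad_tube][0])
        raise SchemaError(
            f"unknown tube {df.loc[i, 'tube']!r}", path=path, row=i + 2, column="tube"
        )
    bad_marker = ~df["marker"].isin(MARKERS)
    if bad_marker.any():
        i = int(df.index[bad_marker][0])
        raise SchemaError(
            f"unknown marker {df.loc[i, 'marker']!r}", path=path, row=i + 2, column="marker"
        )
    fl = pd.to_numeric(df["fluorescence"], errors="coerce")
    if not fl.map(math.isfinite).all():
        i = int(df.index[~fl.map(math.isfinite)][0])
        raise SchemaError("non-finite fluorescence", path=path, row=i + 2, column="fluorescence")
    return df


def read_mfi_summary(path) -> pd.DataFrame:
    """Load a pre-summarized MFI table (`mfi_summary.csv`)."""
    df = _read_csv(path)
    _require_columns(df, MFI_COLUMNS, path)
    return df


def read_panel(path) -> List[dict]:
    """Load panel metadata (`panel.yaml`): chemicals, classes, condition ids."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not doc or "chemicals" not in doc or not doc["chemicals"]:
        raise SchemaError("panel metadata lists no chemicals", path=path)
    return doc["chemicals"]


def write_panel(panel: List[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"chemicals": panel}, fh, sort_keys=True)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_bundle(bundle, outdir) -> Dict[str, Path]:
    """Write a simulated panel bundle to the CSV/YAML/JSON files the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wells": outdir / "wells.csv",
        "events": outdir / "events.csv",
        "panel": outdir / "panel.yaml",
        "truth": outdir / "truth.json",
    }
    bundle.wells.to_csv(paths["wells"], index=False)
    bundle.events.to_csv(paths["events"], index=False)
    write_panel(bundle.panel, paths["panel"])
    write_json({"seed": bundle.seed, "chemicals": bundle.truth}, paths["truth"])
    return paths
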