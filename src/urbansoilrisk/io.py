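"""File I/O: survey CSV ingestion with unit harmonization, GeoJSON
point output, ESRI ASCII grids, and the scenario/toxicity config
readers."""
from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .risk import ExposureScenario, ToxRecord
from .spatial import Grid, GridSpec
from .types import (DEFAULT_PTES, DEFAULT_UNITS, SampleTable, UnitSpec,
                    ValidationError, harmonize)

__all__ = [
    "read_samples", "write_samples_csv",
    "write_point_results", "read_point_results",
    "write_grid", "read_grid",
    "read_units_yaml", "read_scenarios_yaml", "read_toxicity_tsv",
    "default_scenarios", "default_toxicity", "default_organ_map",
]

NODATA = -9999.0


# ---------------------------------------------------------------------------
# Survey CSV
# ---------------------------------------------------------------------------

def read_samples(path, units: UnitSpec = DEFAULT_UNITS,
                 elements: list[str] | None = None,
                 detection_limits: dict[str, float] | None = None,
                 ) -> SampleTable:
    """Read a point survey CSV (comma separator, '.' decimal, UTF-8)
    and harmonize every element column to mg/kg.

    The header must contain ``sample_id``, ``x``, ``y``; element columns
    default to the 15 tracked PTEs plus Fe where present.
    """
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    for col in ("sample_id", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"samples CSV missing required column {col!r}")
    if elements is None:
        elements = [e for e in [*DEFAULT_PTES, "Fe"] if e in df.columns]
        if not elements:
            raise ValidationError("no recognized element columns in CSV")
    df = harmonize(df, elements, units, detection_limits)
    return SampleTable(df, list(elements))


def write_samples_csv(table: SampleTable, path,
                      raw_units: bool = False) -> None:
    """Write a survey CSV; with ``raw_units`` Hg goes out in μg/kg and
    Fe in %, mirroring field-report conventions."""
    df = table.data
    if raw_units:
        from .synthetic import survey_to_raw_csv_frame
        df = survey_to_raw_csv_frame(table)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON points
# ---------------------------------------------------------------------------

def write_point_results(table: SampleTable, values: dict[str, np.ndarray],
                        path) -> None:
    """One GeoJSON point feature per sample carrying the given value
    columns as properties."""
    n = len(table)
    for name, v in values.items():
        if len(v) != n:
            raise ValidationError(
                f"value column {name!r} has {len(v)} entries for {n} samples")
    feats = []
    xy = table.coords
    for i, sid in enumerate(table.sample_ids):
        props = {"sample_id": str(sid)}
        props.update({name: float(np.asarray(v)[i]) for name, v in values.items()})
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(xy[i, 0]), float(xy[i, 1])]},
            "properties": props,
        })
    fc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(fc, indent=1), encoding="utf-8")


def read_point_results(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_point_results`."""
    fc = json.loads(Path(path).read_text(encoding="utf-8"))
    rows = []
    for f in fc.get("features", []):
        row = dict(f["properties"])
        row["x"], row["y"] = f["geometry"]["coordinates"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

def write_grid(grid: Grid, path, fmt: str = "%.6g") -> None:
    """ESRI ASCII grid: standard 6-line header then rows north→south;
    masked cells carry the NODATA token."""
    if grid.values.size == 0:
        raise ValidationError("cannot write an empty grid")
    s = grid.spec
    lines = [
        f"ncols {s.ncols}",
        f"nrows {s.nrows}",
        f"xllcorner {s.xll:.6f}",
        f"yllcorner {s.yll:.6f}",
        f"cellsize {s.cell_size:.6f}",
        f"NODATA_value {NODATA:g}",
    ]
    vals = np.where(grid.mask, grid.values, NODATA)
    for row in vals:
        lines.append(" ".join(fmt % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_grid(path) -> Grid:
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    hdr = {}
    for line in text[:6]:
        k, v = line.split()
        hdr[k.lower()] = float(v)
    spec = GridSpec(hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"],
                    int(hdr["ncols"]), int(hdr["nrows"]))
    vals = np.loadtxt(text[6:], dtype=float).reshape(spec.nrows, spec.ncols)
    nodata = hdr.get("nodata_value", NODATA)
    mask = vals != nodata
    vals = np.where(mask, vals, np.nan)
    return Grid(spec, vals, mask)


# ---------------------------------------------------------------------------
# Config: units, scenarios, toxicity
# ---------------------------------------------------------------------------

def read_units_yaml(path) -> UnitSpec:
    """YAML mapping element → unit string (mg/kg | ug/kg | %)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return UnitSpec({str(k): str(v) for k, v in data.items()})


def read_scenarios_yaml(path) -> list[ExposureScenario]:
    """YAML list of scenario mappings (receptor, pathway, rates...)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return [ExposureScenario(**entry) for entry in data["scenarios"]]


def read_toxicity_tsv(path) -> dict[str, ToxRecord]:
    """TSV with columns element, RfD, RfC, SF, IUR, organs (semicolon
    separated); empty cells mean the value is unavailable."""
    df = pd.read_csv(path, sep="\t")
    recs = {}
    for _, row in df.iterrows():
        def _opt(col):
            v = row.get(col)
            return None if pd.isna(v) else float(v)
        organs = row.get("organs")
        organs = ([] if pd.isna(organs) or not str(organs).strip()
                  else [o.strip() for o in str(organs).split(";") if o.strip()])
        recs[row["element"]] = ToxRecord(
            element=row["element"], rfd=_opt("RfD"), rfc=_opt("RfC"),
            sf=_opt("SF"), iur=_opt("IUR"), target_organs=organs)
    return recs


def _data_path(name: str):
    return resources.files("urbansoilrisk").joinpath("data", name)


def default_toxicity() -> dict[str, ToxRecord]:
    """The packaged residential-screening toxicity table (replaceable)."""
    with resources.as_file(_data_path("toxicity_defaults.tsv")) as p:
        return read_toxicity_tsv(p)


def default_scenarios() -> list[ExposureScenario]:
    with resources.as_file(_data_path("scenarios_default.yaml")) as p:
        return read_scenarios_yaml(p)


def default_organ_map() -> dict[str, list[str]]:
    """Target-organ grouping used for the hazard index."""
    tox = default_toxicity()
    organ_map: dict[str, list[str]] = {}
    for el, rec in tox.items():
        for organ in rec.target_organs:
            organ_map.setdefault(organ, []).append(el)
    return organ_map
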