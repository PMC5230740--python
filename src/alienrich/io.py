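"""Readers, writers and external-data validation.

Formats: introduction records as CSV; range maps as a GeoJSON
FeatureCollection (cell-set ranges keep their explicit cell ids in a
``cells`` property, with the cell centroids as a MultiPoint geometry so the
file remains valid GeoJSON); grid tables as CSV; weights as sparse triplet
CSV.  ``ingest_external`` validates user-supplied files row by row and
reports every violation rather than silently coercing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape, MultiPoint

from .core import IntroductionRecord, RangeMap, VALID_STATUSES
from .grid import EqualAreaGrid, behrmann_inverse

RECORD_COLUMNS = ["species_id", "family_id", "country_id", "year", "status",
                  "provenance"]


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in RECORD_COLUMNS}
                         for r in records], columns=RECORD_COLUMNS)


def write_records_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        year = None if pd.isna(row.year) else int(row.year)
        out.append(IntroductionRecord(
            species_id=str(row.species_id), family_id=str(row.family_id),
            country_id=str(row.country_id), year=year,
            status=int(row.status),
            provenance=str(getattr(row, "provenance", "introduction"))))
    return out


# ---------------------------------------------------------------------------
# ranges
# ---------------------------------------------------------------------------

def write_ranges_geojson(ranges, path, grid: EqualAreaGrid | None = None
                         ) -> None:
    features = []
    for rm in ranges:
        props = {"species_id": rm.species_id, "role": rm.role,
                 "date": rm.date}
        if rm.cells is not None:
            cells = sorted(rm.cells)
            props["cells"] = cells
            if grid is not None:
                rows, cols = grid.rowcol(np.array(cells))
                x = grid.x_min + (cols + 0.5) * grid.cell_km
                y = grid.y_max - (rows + 0.5) * grid.cell_km
                lon, lat = behrmann_inverse(x, y)
                geom = MultiPoint(list(zip(lon, lat)))
            else:
                geom = MultiPoint([(float(c), 0.0) for c in cells])
            features.append({"type": "Feature", "geometry": mapping(geom),
                             "properties": props})
        else:
            features.append({"type": "Feature",
                             "geometry": mapping(rm.geometry),
                             "properties": props})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=None,
        sort_keys=True))


def read_ranges_geojson(path) -> list:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        props = feat["properties"]
        cells = props.get("cells")
        date = props.get("date")
        out.append(RangeMap(
            species_id=props["species_id"], role=props["role"],
            cells=frozenset(cells) if cells is not None else None,
            geometry=None if cells is not None else shape(feat["geometry"]),
            date=None if date is None else int(date)))
    return out


def write_realms_geojson(realms: dict, path) -> None:
    features = [{"type": "Feature", "geometry": mapping(geom),
                 "properties": {"realm": label}}
                for label, geom in sorted(realms.items())]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, sort_keys=True))


def read_realms_geojson(path) -> dict:
    data = json.loads(Path(path).read_text())
    return {f["properties"]["realm"]: shape(f["geometry"])
            for f in data["features"]}


# ---------------------------------------------------------------------------
# grid tables and avifauna
# ---------------------------------------------------------------------------

def write_grid_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_grid_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_avifauna_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"species", "family"} <= set(df.columns):
        raise ValueError("avifauna CSV needs 'species' and 'family' columns")
    return df[["species", "family"]]


# ---------------------------------------------------------------------------
# external ingestion with itemized validation
# ---------------------------------------------------------------------------

@dataclass
class IngestReport:
    records: list = field(default_factory=list)
    ranges: list = field(default_factory=list)
    covariates: pd.DataFrame | None = None
    rejected: list = field(default_factory=list)  # (source, row, message)

    @property
    def ok(self) -> bool:
        return not self.rejected


def _parse_year(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None, None
    if isinstance(value, (int, np.integer)):
        return int(value), None
    if isinstance(value, float) and float(value).is_integer():
        return int(value), None
    s = str(value).strip()
    if s.isdigit() or (s.startswith("-") and s[1:].isdigit()):
        return int(s), None
    return None, f"unparseable year {value!r} (no silent coercion)"


def ingest_external(records_csv=None, ranges_geojson=None,
                    covariates_csv=None) -> IngestReport:
    """Validate user-supplied inputs against the documented schemas.

    Rows violating the schema (status outside 1-6, non-integer years,
    missing required fields) are rejected and itemized in the report; valid
    rows become typed records usable in place of synthetic data.
    """
    report = IngestReport()
    if records_csv is not None:
        df = pd.read_csv(records_csv)
        missing = set(RECORD_COLUMNS[:5]) - set(df.columns)
        if missing:
            raise ValueError(f"records CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(df.to_dict("records")):
            year, err = _parse_year(row.get("year"))
            if err:
                report.rejected.append(("records", i, err))
                continue
            try:
                status = int(row["status"])
            except (TypeError, ValueError):
                report.rejected.append(
                    ("records", i, f"non-integer status {row['status']!r}"))
                continue
            if status not in VALID_STATUSES:
                report.rejected.append(
                    ("records", i, f"status {status} outside 1-6"))
                continue
            report.records.append(IntroductionRecord(
                species_id=str(row["species_id"]),
                family_id=str(row["family_id"]),
                country_id=str(row["country_id"]), year=year, status=status,
                provenance=str(row.get("provenance", "introduction"))))
    if ranges_geojson is not None:
        data = json.loads(Path(ranges_geojson).read_text())
        for i, feat in enumerate(data.get("features", [])):
            props = feat.get("properties", {})
            role = props.get("role")
            if role not in ("native", "introduction", "established"):
                report.rejected.append(
                    ("ranges", i, f"unknown role {role!r}"))
                continue
            cells = props.get("cells")
            try:
                geom = None if cells is not None else shape(feat["geometry"])
            except Exception as exc:  # malformed geometry
                report.rejected.append(("ranges", i, f"bad geometry: {exc}"))
                continue
            if geom is not None and not geom.is_valid:
                report.rejected.append(
                    ("ranges", i,
                     f"invalid geometry for {props.get('species_id')}"))
                continue
            date = props.get("date")
            report.ranges.append(RangeMap(
                species_id=str(props.get("species_id")), role=role,
                cells=frozenset(cells) if cells is not None else None,
                geometry=geom, date=None if date is None else int(date)))
    if covariates_csv is not None:
        df = pd.read_csv(covariates_csv)
        for col in ("cell_id", "row", "col"):
            if col not in df.columns:
                raise ValueError(f"covariates CSV missing column {col!r}")
        report.covariates = df
    return report
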