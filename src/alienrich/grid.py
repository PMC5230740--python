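"""Equal-area analysis grid and rasterization of species ranges.

The analysis grid is a cylindrical equal-area (Behrmann, standard parallel
30 degrees) grid of 96.486-km cells: 360 columns by 152 rows once the partial
cells poleward of the latitude cutoff are dropped, i.e. 54,720 cells in
total.  One column spans exactly 1 degree of longitude; a row spans roughly
1 degree of latitude at the equator.  Cells are indexed (row, col) from the
north-west corner, 0-based, and cell extents are half-open,
[x_min, x_max) x (y_min, y_max], so every projected point maps to exactly
one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

COS_STANDARD_PARALLEL = np.sqrt(3.0) / 2.0  # cos(30 deg)
CELL_KM = 96.486
N_COLS_GLOBAL = 360
N_ROWS_GLOBAL = 152
LATITUDE_CUTOFF = 87.13
# Sphere radius consistent with 360 cells of 96.486 km spanning the full
# 360 degrees of longitude at the standard parallel.
EARTH_RADIUS_KM = N_COLS_GLOBAL * CELL_KM / (2.0 * np.pi * COS_STANDARD_PARALLEL)


def behrmann_forward(lon, lat):
    """Project geographic coordinates (degrees) to Behrmann x, y in km."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_KM * np.radians(lon) * COS_STANDARD_PARALLEL
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat)) / COS_STANDARD_PARALLEL
    return x, y


def behrmann_inverse(x, y):
    """Inverse projection from Behrmann x, y (km) to lon, lat in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / (EARTH_RADIUS_KM * COS_STANDARD_PARALLEL))
    s = np.clip(y * COS_STANDARD_PARALLEL / EARTH_RADIUS_KM, -1.0, 1.0)
    lat = np.degrees(np.arcsin(s))
    return lon, lat


@dataclass(frozen=True)
class EqualAreaGrid:
    """A rectangular block of equal-area cells centred on (lon=0, equator).

    All cells share the same projected area (``cell_km ** 2``), which is what
    makes per-cell species counts comparable across latitudes.
    """

    n_rows: int = N_ROWS_GLOBAL
    n_cols: int = N_COLS_GLOBAL
    cell_km: float = CELL_KM

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    # -- geometry ----------------------------------------------------------
    @property
    def x_min(self) -> float:
        return -0.5 * self.n_cols * self.cell_km

    @property
    def y_max(self) -> float:
        return 0.5 * self.n_rows * self.cell_km

    def cell_id(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_bounds(self, cell_id):
        """(x_min, y_min, x_max, y_max) of a cell in projected km."""
        row, col = self.rowcol(cell_id)
        x0 = self.x_min + col * self.cell_km
        y1 = self.y_max - row * self.cell_km
        return x0, y1 - self.cell_km, x0 + self.cell_km, y1

    def cell_polygon(self, cell_id) -> BaseGeometry:
        return box(*self.cell_bounds(int(cell_id)))

    def point_to_cell(self, x: float, y: float) -> int | None:
        """Map a projected point to its unique cell (half-open extents)."""
        col = int(np.floor((x - self.x_min) / self.cell_km))
        row = int(np.floor((self.y_max - y) / self.cell_km))
        # top edge of row 0 belongs to row 0
        if y == self.y_max:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            return None
        return int(self.cell_id(row, col))

    def centroids_xy(self):
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = self.x_min + (cols + 0.5) * self.cell_km
        y = self.y_max - (rows + 0.5) * self.cell_km
        return x, y

    def centroids_lonlat(self):
        x, y = self.centroids_xy()
        return behrmann_inverse(x, y)

    def to_frame(self) -> pd.DataFrame:
        """Per-cell table with ids, indices and centroid coordinates."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x, y = self.centroids_xy()
        lon, lat = self.centroids_lonlat()
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "row": rows,
                "col": cols,
                "x_km": x,
                "y_km": y,
                "centroid_lon": lon,
                "centroid_lat": lat,
            }
        )


def build_grid(n_rows: int = N_ROWS_GLOBAL, n_cols: int = N_COLS_GLOBAL,
               cell_km: float = CELL_KM) -> EqualAreaGrid:
    """Build the analysis grid (defaults give the 54,720-cell global grid)."""
    grid = EqualAreaGrid(n_rows=n_rows, n_cols=n_cols, cell_km=cell_km)
    # The global grid must not reach poleward of the latitude cutoff.
    _, lat_top = behrmann_inverse(0.0, grid.y_max - 0.5 * cell_km)
    if abs(float(lat_top)) > LATITUDE_CUTOFF:
        raise ValueError(
            f"grid extends poleward of the {LATITUDE_CUTOFF} degree cutoff"
        )
    return grid


def _project_geometry(geom: BaseGeometry) -> BaseGeometry:
    return shapely.transform(
        geom, lambda pts: np.column_stack(behrmann_forward(pts[:, 0], pts[:, 1]))
    )


def rasterize(range_map, grid: EqualAreaGrid) -> set[int]:
    """Cells touched by a species range.

    A species is scored present in a cell if any positive-area part of its
    range overlaps the cell; this deliberately counts even tiny island
    ranges.  Explicit cell sets pass through unchanged.  Degenerate point
    geometries falling exactly on a shared cell corner are assigned to the
    lowest cell id among the touching cells, which keeps the assignment
    deterministic.
    """
    if getattr(range_map, "cells", None) is not None:
        cells = {int(c) for c in range_map.cells}
        bad = [c for c in cells if not (0 <= c < grid.n_cells)]
        if bad:
            raise ValueError(
                f"range of {range_map.species_id} references cells outside "
                f"the grid: {sorted(bad)[:5]}"
            )
        return cells

    geom = range_map.geometry
    if geom is None or geom.is_empty:
        raise ValueError(f"range of {range_map.species_id} has empty geometry")
    if not geom.is_valid:
        raise ValueError(
            f"range of {range_map.species_id} has invalid geometry"
        )
    if getattr(range_map, "crs", "lonlat") == "lonlat":
        geom = _project_geometry(geom)

    out: set[int] = set()
    if geom.area > 0:
        x0, y0, x1, y1 = geom.bounds
        c0 = max(0, int(np.floor((x0 - grid.x_min) / grid.cell_km)))
        c1 = min(grid.n_cols - 1, int(np.floor((x1 - grid.x_min) / grid.cell_km)))
        r0 = max(0, int(np.floor((grid.y_max - y1) / grid.cell_km)))
        r1 = min(grid.n_rows - 1, int(np.floor((grid.y_max - y0) / grid.cell_km)))
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                cid = int(grid.cell_id(r, c))
                if grid.cell_polygon(cid).intersection(geom).area > 0:
                    out.add(cid)
        return out

    # degenerate geometry: points and lines
    parts = getattr(geom, "geoms", [geom])
    for part in parts:
        if part.geom_type == "Point":
            touching = []
            px, py = part.x, part.y
            col0 = int(np.floor((px - grid.x_min) / grid.cell_km))
            row0 = int(np.floor((grid.y_max - py) / grid.cell_km))
            for r in (row0 - 1, row0, row0 + 1):
                for c in (col0 - 1, col0, col0 + 1):
                    if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols:
                        cid = int(grid.cell_id(r, c))
                        bx0, by0, bx1, by1 = grid.cell_bounds(cid)
                        if bx0 <= px <= bx1 and by0 <= py <= by1:
                            touching.append(cid)
            if not touching:
                continue
            out.add(min(touching))
        else:  # line-like
            x0, y0, x1, y1 = part.bounds
            c0 = max(0, int(np.floor((x0 - grid.x_min) / grid.cell_km)))
            c1 = min(grid.n_cols - 1,
                     int(np.floor((x1 - grid.x_min) / grid.cell_km)))
            r0 = max(0, int(np.floor((grid.y_max - y1) / grid.cell_km)))
            r1 = min(grid.n_rows - 1,
                     int(np.floor((grid.y_max - y0) / grid.cell_km)))
            for r in range(r0, r1 + 1):
                for c in range(c0, c1 + 1):
                    cid = int(grid.cell_id(r, c))
                    if grid.cell_polygon(cid).intersects(part):
                        out.add(cid)
    return out


def richness_layers(ranges, grid: EqualAreaGrid) -> pd.DataFrame:
    """Per-cell alien species richness, colonisation pressure and first date.

    ASR counts distinct species with an established range (each species
    contributes its most recently dated established map); CP counts distinct
    species over their introduction-location maps regardless of outcome.
    The first-record year per cell is the minimum over all alien maps
    (introduction or established) touching the cell.
    """
    asr = np.zeros(grid.n_cells, dtype=int)
    cp = np.zeros(grid.n_cells, dtype=int)
    earliest = np.full(grid.n_cells, np.nan)

    established: dict[object, object] = {}
    for rm in ranges:
        if rm.role == "established":
            prev = established.get(rm.species_id)
            # ties on date resolve to the later-listed map (cumulative
            # snapshots list the larger range last)
            if prev is None or (rm.date or -np.inf) >= (prev.date or -np.inf):
                established[rm.species_id] = rm

    asr_seen: dict[int, set] = {}
    cp_seen: dict[int, set] = {}
    for rm in ranges:
        if rm.role == "native":
            continue
        if rm.role == "established" and established.get(rm.species_id) is not rm:
            continue
        cells = rasterize(rm, grid)
        for cid in cells:
            if rm.role == "established":
                asr_seen.setdefault(cid, set()).add(rm.species_id)
            elif rm.role == "introduction":
                cp_seen.setdefault(cid, set()).add(rm.species_id)
            if rm.date is not None:
                if np.isnan(earliest[cid]) or rm.date < earliest[cid]:
                    earliest[cid] = rm.date
    for cid, sp in asr_seen.items():
        asr[cid] = len(sp)
    for cid, sp in cp_seen.items():
        cp[cid] = len(sp)

    return pd.DataFrame(
        {"cell_id": np.arange(grid.n_cells), "ASR": asr, "CP": cp,
         "earliest_intro_year": earliest}
    )


# ----------------------------------------------------------------------------
# predictor table: transformations, filtering, collinearity screen
# ----------------------------------------------------------------------------

#: transform applied to each raw column -> (new name, function, domain check)
_TRANSFORMS = {
    "ASR": ("log1p_ASR", np.log1p, None),
    "CP": ("log1p_CP", np.log1p, None),
    "time_since_first_intro": ("log_time_since", np.log, "positive"),
    "dist_historic_port_m": (
        "sqrt_dist_port", lambda v: np.sqrt(v / 1000.0), "nonnegative"),
    "NSR": ("sqrt_NSR", np.sqrt, "nonnegative"),
    "elev_median": ("log_elev_median", lambda v: np.log(v + 30.0), "elev"),
    "elev_range": ("sqrt_elev_range", np.sqrt, "nonnegative"),
    "temp_range": ("sqrt_temp_range", np.sqrt, "nonnegative"),
    "precip_median": ("sqrt_precip", np.sqrt, "nonnegative"),
}

#: the nine predictors retained for model building after the a-priori screen
MODEL_PREDICTORS = [
    "log1p_CP",
    "log_time_since",
    "sqrt_dist_port",
    "human_footprint",
    "sqrt_NSR",
    "sqrt_elev_range",
    "temp_median",
    "sqrt_precip",
    "habitat_complexity_8",
]

#: predictors excluded a priori on collinearity / redundancy grounds
APRIORI_EXCLUDED = {
    "temp_min", "temp_max", "temp_range", "sqrt_temp_range",
    "elev_median", "log_elev_median",
    "habitat_complexity_24",
    "pop_density_mean", "pop_density_median", "log1p_pop_density_mean",
    "log1p_pop_density_median", "dist_city", "log_dist_city",
}

#: candidates allowed a quadratic term during model building
QUADRATIC_CANDIDATES = [
    "log1p_CP", "log_time_since", "sqrt_NSR", "sqrt_elev_range",
    "temp_median", "sqrt_precip",
]


def transform_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Add the analysis-scale columns to a raw per-cell table.

    Each transform is fixed by the analysis design: counts are natural
    log(1+x); time since first introduction natural log; port distance is
    converted to km and square-rooted; native richness, elevational range,
    temperature range and precipitation are square-rooted; median elevation
    has 30 m added before the natural log (the most negative median
    elevation in the source data is -29.7 m).  Raw columns are retained.
    Re-application is refused.
    """
    done = [new for new, _, _ in _TRANSFORMS.values() if new in raw.columns]
    if done:
        raise ValueError(
            f"table already transformed (found {done[0]}); refusing to re-apply"
        )
    out = raw.copy()
    for src, (new, func, domain) in _TRANSFORMS.items():
        if src not in out.columns:
            continue
        v = out[src].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if domain == "nonnegative" and np.any(v[ok] < 0):
            raise ValueError(f"{src} has negative values; transform undefined")
        if domain == "positive" and np.any(v[ok] <= 0):
            raise ValueError(f"{src} has non-positive values; log undefined")
        if domain == "elev" and np.any(v[ok] < -30):
            raise ValueError(
                f"{src} below -30 m; log(x + 30) transform undefined")
        out[new] = func(v)
    return out


def filter_cells(table: pd.DataFrame, required=None):
    """Drop double-zero cells and cells with missing covariates.

    Cells where both colonisation pressure and alien species richness are
    zero carry no information about establishment and would inflate
    covariation measures (the double-zero problem), so they are excluded.
    Returns the retained table and a removal ledger
    ``{"double_zero": k1, "missing": k2}``.
    """
    if required is None:
        required = [c for c in table.columns
                    if c not in ("cell_id", "row", "col", "realm", "country_id")]
    keep_dz = (table["CP"] > 0) | (table["ASR"] > 0)
    n_dz = int((~keep_dz).sum())
    sub = table.loc[keep_dz]
    complete = sub[required].notna().all(axis=1)
    n_missing = int((~complete).sum())
    out = sub.loc[complete].reset_index(drop=True)
    return out, {"double_zero": n_dz, "missing": n_missing}


def collinearity_screen(table: pd.DataFrame, predictors, threshold: float = 0.7):
    """Pairwise Pearson correlations plus the fixed a-priori exclusion list.

    Returns ``(corr, excluded, retained, high_pairs)``. Constant columns have
    undefined correlations and are excluded with a flag; pairs among the
    retained predictors with |r| above ``threshold`` are reported as
    warnings only (the a-priori list is what actually removes variables).
    """
    predictors = list(predictors)
    corr = table[predictors].corr()
    excluded = [p for p in predictors if p in APRIORI_EXCLUDED]
    constant = [p for p in predictors
                if p not in excluded and table[p].nunique(dropna=True) <= 1]
    excluded += constant
    retained = [p for p in predictors if p not in excluded]
    high_pairs = []
    for i, a in enumerate(retained):
        for b in retained[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                high_pairs.append((a, b, float(r)))
    return corr, excluded, retained, high_pairs
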