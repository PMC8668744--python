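"""Occurrence reading, cleaning, and cumulative temporal windows.

Records enter as tabular text with longitude, latitude, year and source
columns. Cleaning applies, in order: drop undated records, drop records
without coordinates, drop records before a minimum year, drop records
outside the study region; each removal is attributed to the first rule a
record fails and tallied in a :class:`FilterReport`. The cleaned table is
then split into cumulative windows (all records up to each end year), the
unit of the decade-effect analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .raster import RasterStack

__all__ = [
    "FilterReport",
    "TemporalWindow",
    "read_occurrences",
    "filter_records",
    "build_windows",
    "thin_to_cells",
    "DEFAULT_END_YEARS",
]

DEFAULT_END_YEARS = [1950, 1960, 1970, 1980, 1990, 2000, 2010, 2020]


@dataclass
class FilterReport:
    """Per-rule removal tallies; counts always balance to the input size."""

    n_input: int
    n_undated: int
    n_no_coordinates: int
    n_pre_min_year: int
    n_outside_region: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_undated
            + self.n_no_coordinates
            + self.n_pre_min_year
            + self.n_outside_region
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("FilterReport does not balance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "input",
                    "undated",
                    "no_coordinates",
                    "pre_min_year",
                    "outside_region",
                    "retained",
                ],
                "count": [
                    self.n_input,
                    self.n_undated,
                    self.n_no_coordinates,
                    self.n_pre_min_year,
                    self.n_outside_region,
                    self.n_retained,
                ],
            }
        )


@dataclass
class TemporalWindow:
    """A cumulative record window: everything dated up to ``end_year``."""

    label: str
    end_year: int
    records: pd.DataFrame


def read_occurrences(
    path: str | Path,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    year_col: str = "year",
    source_col: str = "source",
) -> pd.DataFrame:
    """Read an occurrence CSV into the canonical column layout.

    Missing or unparseable longitude/latitude/year entries are kept as
    NaN — records are not dropped here; that is the filter's job.
    """
    df = pd.read_csv(path)
    missing = [c for c in (lon_col, lat_col, year_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    out = pd.DataFrame(
        {
            "longitude": pd.to_numeric(df[lon_col], errors="coerce"),
            "latitude": pd.to_numeric(df[lat_col], errors="coerce"),
            "year": pd.to_numeric(df[year_col], errors="coerce"),
            "source": df[source_col] if source_col in df.columns else "unknown",
        }
    )
    return out


def _as_geometry(region) -> BaseGeometry:
    if isinstance(region, BaseGeometry):
        return region
    xmin, ymin, xmax, ymax = region
    return box(xmin, ymin, xmax, ymax)


def filter_records(
    occ: pd.DataFrame,
    region,
    min_year: int = 1900,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cleaning rules in order and return the survivors.

    Rules, in order of attribution: (1) undated; (2) missing coordinates;
    (3) year earlier than ``min_year``; (4) outside ``region`` (a shapely
    geometry or an (xmin, ymin, xmax, ymax) rectangle). Boundary points
    count as inside.
    """
    geom = _as_geometry(region)
    if geom.is_empty:
        raise ValueError("region is empty")

    n_input = len(occ)
    undated = occ["year"].isna()
    no_coords = ~undated & (occ["longitude"].isna() | occ["latitude"].isna())
    pre = ~undated & ~no_coords & (occ["year"] < min_year)
    candidate = ~(undated | no_coords | pre)
    inside = np.zeros(n_input, dtype=bool)
    if candidate.any():
        lon = occ.loc[candidate, "longitude"].to_numpy(dtype=float)
        lat = occ.loc[candidate, "latitude"].to_numpy(dtype=float)
        # intersects (not contains) so boundary points count as inside
        inside_c = shapely.intersects_xy(geom, lon, lat)
        inside[np.flatnonzero(candidate.to_numpy())] = inside_c
    outside = candidate & ~inside
    retained = candidate & inside

    report = FilterReport(
        n_input=n_input,
        n_undated=int(undated.sum()),
        n_no_coordinates=int(no_coords.sum()),
        n_pre_min_year=int(pre.sum()),
        n_outside_region=int(outside.sum()),
        n_retained=int(retained.sum()),
    )
    kept = occ.loc[retained].reset_index(drop=True)
    kept["year"] = kept["year"].astype(int)
    return kept, report


def build_windows(
    occ: pd.DataFrame,
    end_years: Sequence[int] = tuple(DEFAULT_END_YEARS),
    start_year: int = 1900,
) -> list[TemporalWindow]:
    """Split filtered records into cumulative windows.

    Window *k* holds every record with ``year <= end_years[k]`` (right
    boundary inclusive), so window record sets are nested.
    """
    end_years = list(end_years)
    if any(nxt <= cur for cur, nxt in zip(end_years, end_years[1:])):
        raise ValueError("end_years must be strictly increasing")
    if occ["year"].isna().any():
        raise ValueError("records must be filtered (no missing years) first")
    windows = []
    for ey in end_years:
        sub = occ.loc[occ["year"] <= ey]
        windows.append(
            TemporalWindow(label=f"{start_year}–{ey}", end_year=ey, records=sub)
        )
    return windows


def thin_to_cells(occ: pd.DataFrame, grid: RasterStack) -> pd.DataFrame:
    """Keep at most one record per raster cell (earliest year wins).

    Ties on year keep the first record in table order. Used before model
    fitting so duplicated localities do not dominate the likelihood; the
    distance-to-center analysis uses the unthinned table.
    """
    if occ.empty:
        return occ.copy()
    row, col = grid.index_of(
        occ["longitude"].to_numpy(float), occ["latitude"].to_numpy(float)
    )
    cell = row * grid.n_cols + col
    order = np.lexsort((np.arange(len(occ)), occ["year"].to_numpy(), cell))
    cell_sorted = cell[order]
    first = np.ones(len(occ), dtype=bool)
    first[1:] = cell_sorted[1:] != cell_sorted[:-1]
    keep = np.sort(order[first])
    return occ.iloc[keep].reset_index(drop=True)
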