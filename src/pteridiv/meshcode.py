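"""Secondary standard-area-mesh grid codes (JIS X 0410).

Japan's standard area mesh tiles the country into a hierarchy of
latitude/longitude rectangles.  All occurrence records in this package are
georeferenced to the 6-digit *secondary* mesh, whose cells span 5' of
latitude by 7.5' of longitude — roughly 10 km x 10 km at Japanese latitudes.

A 6-digit code ``PPQQRC`` decomposes positionally:

* ``PP`` — primary-mesh latitude index: SW latitude of the primary cell is
  ``PP / 1.5`` degrees (each primary cell is 40' tall),
* ``QQ`` — primary-mesh longitude index: SW longitude is ``100 + QQ`` degrees
  (each primary cell is 1 degree wide),
* ``R``  — secondary row (0–7 in real data), each step 1/12 degree north,
* ``C``  — secondary column (0–7 in real data), each step 1/8 degree east.

Codes are handled as strings throughout so leading zeros survive; only the
6-digit secondary level is accepted, because that is the resolution of the
occurrence dataset.  Parsing does not range-check the row/column digits —
observed data governs.  Cell *centroids* are the canonical per-cell
coordinate for all latitude statistics: latitudinal breadth (max − min) is
identical whether computed from centroids or SW corners, since the half-cell
offset cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

from .errors import MeshCodeError, MeshDomainError

__all__ = [
    "MeshCell",
    "parse_mesh",
    "format_mesh",
    "cell_bounds",
    "cell_centroid",
    "encode_mesh",
    "centroid_arrays",
    "LAT_CELL_DEG",
    "LON_CELL_DEG",
    "LON_ORIGIN_DEG",
]

#: Height of a secondary cell in degrees of latitude (5 minutes).
LAT_CELL_DEG = 1.0 / 12.0
#: Width of a secondary cell in degrees of longitude (7.5 minutes).
LON_CELL_DEG = 1.0 / 8.0
#: Longitude of the mesh system's western origin.
LON_ORIGIN_DEG = 100.0

# Guard against float representation error in floor arithmetic; far smaller
# than any quantity the 1/12-degree grid can distinguish.
_EPS = 1e-9


@dataclass(frozen=True)
class MeshCell:
    """A decoded 6-digit secondary standard-area-mesh cell."""

    code: str
    lat_index: int
    lon_index: int
    row: int
    col: int


def parse_mesh(code: str) -> MeshCell:
    """Decode a 6-digit secondary mesh code into its positional fields.

    Raises
    ------
    MeshCodeError
        If *code* is not a string of exactly six decimal digits.
    """
    if not isinstance(code, str) or len(code) != 6 or not code.isdigit():
        raise MeshCodeError(
            f"malformed secondary mesh code {code!r}: expected exactly "
            "6 decimal digits"
        )
    return MeshCell(
        code=code,
        lat_index=int(code[0:2]),
        lon_index=int(code[2:4]),
        row=int(code[4]),
        col=int(code[5]),
    )


def format_mesh(lat_index: int, lon_index: int, row: int, col: int) -> str:
    """Assemble a 6-digit code from positional indices."""
    if not (0 <= lat_index <= 99 and 0 <= lon_index <= 99
            and 0 <= row <= 9 and 0 <= col <= 9):
        raise MeshCodeError(
            f"mesh indices out of digit range: "
            f"({lat_index}, {lon_index}, {row}, {col})"
        )
    return f"{lat_index:02d}{lon_index:02d}{row}{col}"


def cell_bounds(cell: MeshCell) -> Tuple[float, float, float, float]:
    """SW/NE corners ``(lat_sw, lon_sw, lat_ne, lon_ne)`` in degrees."""
    lat_sw = cell.lat_index / 1.5 + cell.row * LAT_CELL_DEG
    lon_sw = LON_ORIGIN_DEG + cell.lon_index + cell.col * LON_CELL_DEG
    return (lat_sw, lon_sw, lat_sw + LAT_CELL_DEG, lon_sw + LON_CELL_DEG)


def cell_centroid(cell: MeshCell) -> Tuple[float, float]:
    """Cell midpoint ``(lat, lon)`` in degrees."""
    lat_sw, lon_sw, lat_ne, lon_ne = cell_bounds(cell)
    return ((lat_sw + lat_ne) / 2.0, (lon_sw + lon_ne) / 2.0)


def encode_mesh(lat: float, lon: float) -> str:
    """Code of the secondary mesh cell containing the point ``(lat, lon)``.

    Floor arithmetic inverse of :func:`cell_bounds`:
    ``encode_mesh(*cell_centroid(c)) == c.code`` for every valid cell.

    Raises
    ------
    MeshDomainError
        If the point lies outside the mesh system's domain
        (``0 <= lat < 200/3`` and ``100 <= lon < 200``).
    """
    if not (0.0 <= lat and LON_ORIGIN_DEG <= lon < 200.0):
        raise MeshDomainError(
            f"point ({lat}, {lon}) outside mesh domain "
            "(lat >= 0, 100 <= lon < 200)"
        )
    lat_units = math.floor(lat * 12.0 + _EPS)   # count of 1/12-degree rows
    lon_units = math.floor((lon - LON_ORIGIN_DEG) * 8.0 + _EPS)
    lat_index, row = divmod(lat_units, 8)       # 8 rows per 40' primary cell
    lon_index, col = divmod(lon_units, 8)
    if lat_index > 99:
        raise MeshDomainError(
            f"latitude {lat} exceeds the 2-digit primary mesh range"
        )
    return format_mesh(lat_index, lon_index, row, col)


def centroid_arrays(codes: Iterable[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised centroids for an iterable of codes → ``(lats, lons)``.

    Convenience for range statistics over many cells; each code is validated
    through :func:`parse_mesh`.
    """
    lats, lons = [], []
    for code in codes:
        lat, lon = cell_centroid(parse_mesh(code))
        lats.append(lat)
        lons.append(lon)
    return np.asarray(lats, dtype=float), np.asarray(lons, dtype=float)
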