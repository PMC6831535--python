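"""Per-cell map layers: richness, subset richness, proportions, exports.

A :class:`GridMap` is one scalar per secondary mesh cell — a taxon count, a
Faith's-PD value, or a proportion — with explicit undefined-cell semantics
(NaN).  Counts are always defined; PD is undefined where fewer than two
tree tips are present; proportions are undefined where the denominator
count is zero.

Exports carry raw values (colour ramps are a rendering concern, out of
scope here): CSV as ``mesh_code,value,defined`` and GeoJSON as one
axis-aligned rectangular polygon feature per cell in (lon, lat) coordinate
order.  Cells of a configured study frame that carry no data can be padded
in (zero for counts, undefined otherwise) so exported layers share a frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import meshcode
from .checklist import TaxonTable
from .errors import GridMapError
from .occurrences import OccurrenceMatrix, filter_matrix

__all__ = [
    "GridMap",
    "richness_map",
    "subset_richness_map",
    "proportion_map",
    "top_cells",
    "pad_to_frame",
    "export_layer",
    "read_layer_csv",
]


@dataclass
class GridMap:
    """One scalar value per mesh cell; NaN marks an undefined cell."""

    values: pd.Series          # float, index = mesh codes
    name: str = "layer"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        s = pd.Series(self.values, dtype=float)
        for code in s.index:
            meshcode.parse_mesh(code)
        self.values = s

    @property
    def defined(self) -> pd.Series:
        return self.values.notna()

    def __getitem__(self, code: str) -> float:
        return float(self.values[code])

    def __len__(self) -> int:
        return len(self.values)

    def equals(self, other: "GridMap") -> bool:
        a = self.values.sort_index()
        b = other.values.sort_index()
        return a.index.equals(b.index) and np.allclose(
            a.to_numpy(), b.to_numpy(), equal_nan=True, rtol=0, atol=0)


def richness_map(m: OccurrenceMatrix, table: TaxonTable, *,
                 include_hybrids: bool = False) -> GridMap:
    """Per-cell count of present taxa (hybrids excluded by default)."""
    fm = filter_matrix(m, table, include_hybrids=include_hybrids)
    counts = fm.presence.to_numpy().sum(axis=0)
    values = pd.Series(counts.astype(float), index=fm.presence.columns)
    return GridMap(values, name="richness",
                   provenance={"include_hybrids": include_hybrids})


def subset_richness_map(m: OccurrenceMatrix, table: TaxonTable,
                        predicate: str, *, include_both: bool = True
                        ) -> GridMap:
    """Richness restricted to a checklist predicate.

    ``"apomictic"``: apomictic fern taxa, hybrids excluded (dual-mode taxa
    counted when *include_both*).  ``"redlisted"``: nationally red-listed
    taxa, hybrids included.
    """
    if predicate == "apomictic":
        fm = filter_matrix(m, table, include_hybrids=False, lineage="ferns",
                           subset="apomictic", include_both=include_both)
    elif predicate == "redlisted":
        fm = filter_matrix(m, table, include_hybrids=True,
                           subset="redlisted")
    else:
        raise GridMapError(f"unknown richness predicate {predicate!r}")
    counts = fm.presence.to_numpy().sum(axis=0)
    values = pd.Series(counts.astype(float), index=fm.presence.columns)
    return GridMap(values, name=f"richness_{predicate}",
                   provenance={"predicate": predicate,
                               "include_both": include_both})


def proportion_map(numerator: GridMap, denominator: GridMap) -> GridMap:
    """Cellwise ratio of two count layers; undefined where denominator is 0.

    Raises
    ------
    GridMapError
        If the layers cover different cells or the numerator exceeds the
        denominator anywhere.
    """
    num = numerator.values.sort_index()
    den = denominator.values.sort_index()
    if not num.index.equals(den.index):
        raise GridMapError("proportion layers must share identical cells")
    if bool((num > den).any()):
        offender = num.index[(num > den).argmax()]
        raise GridMapError(
            f"numerator exceeds denominator at cell {offender}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num.to_numpy() / den.to_numpy()
    ratio[den.to_numpy() == 0] = np.nan
    return GridMap(pd.Series(ratio, index=num.index),
                   name=f"{numerator.name}_over_{denominator.name}")


def top_cells(g: GridMap, k: int) -> List[Tuple[str, float]]:
    """The *k* largest defined cells, ties broken by ascending mesh code."""
    s = g.values.dropna()
    if s.empty:
        raise GridMapError(f"layer {g.name!r} has no defined cells")
    order = sorted(s.items(), key=lambda item: (-item[1], item[0]))
    return order[:k]


def pad_to_frame(g: GridMap, frame: Iterable[str], *,
                 fill: float = math.nan) -> GridMap:
    """Extend a layer to a full study frame.

    Frame cells missing from the layer get *fill* (0 for count layers,
    NaN/undefined for PD or proportion layers).
    """
    frame = list(frame)
    values = g.values.reindex(frame)
    if not math.isnan(fill):
        missing = ~pd.Index(frame).isin(g.values.index)
        values[missing] = fill
    return GridMap(values, name=g.name, provenance=dict(g.provenance))


def export_layer(g: GridMap, path, format: str = "csv") -> None:
    """Write a layer to disk as CSV or GeoJSON.

    CSV columns are ``mesh_code,value,defined``; undefined cells have an
    empty value field.  GeoJSON features are cell rectangles from the mesh
    arithmetic, coordinates in (lon, lat) order, with ``mesh_code``,
    ``value`` (null when undefined) and ``defined`` properties.
    """
    if format == "csv":
        out = pd.DataFrame({
            "mesh_code": g.values.index,
            "value": g.values.to_numpy(),
            "defined": g.defined.to_numpy(),
        })
        out.to_csv(path, index=False)
    elif format == "geojson":
        features = []
        for code, value in g.values.items():
            cell = meshcode.parse_mesh(code)
            lat_sw, lon_sw, lat_ne, lon_ne = meshcode.cell_bounds(cell)
            ring = [[lon_sw, lat_sw], [lon_ne, lat_sw], [lon_ne, lat_ne],
                    [lon_sw, lat_ne], [lon_sw, lat_sw]]
            defined = not (isinstance(value, float) and math.isnan(value))
            features.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "mesh_code": code,
                    "value": float(value) if defined else None,
                    "defined": defined,
                },
            })
        doc = {"type": "FeatureCollection", "name": g.name,
               "features": features}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        raise GridMapError(f"unknown export format {format!r}")


def read_layer_csv(path, name: str = "layer") -> GridMap:
    """Inverse of the CSV export; round-trips a layer exactly."""
    df = pd.read_csv(path, dtype={"mesh_code": str})
    values = pd.Series(df["value"].to_numpy(dtype=float),
                       index=df["mesh_code"])
    defined = df["defined"].astype(bool).to_numpy()
    arr = values.to_numpy()
    arr[~defined] = np.nan
    return GridMap(pd.Series(arr, index=values.index), name=name)
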