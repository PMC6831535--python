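"""Presence records and the deduplicated taxon x grid-cell matrix.

Occurrence data arrive as presence-only records, one (taxon, 10-km mesh
code) pair per row; a taxon may be recorded for the same cell many times
(once per specimen).  Loading collapses those duplicates into a boolean
presence matrix while keeping the raw record count as provenance, so both
the pre- and post-deduplication sizes of a dataset can be reported.

Filtered views restrict the *taxa* (hybrids in or out, ferns only,
apomictic or red-listed subsets) but always retain every cell column, so
denominators over "all grid cells" stay fixed under filtering.  Absence is
never inferred: a cell missing from the record file is simply absent from
the matrix, and the study-frame total (4852 cells in the motivating
dataset) is supplied as configuration where needed.
"""

from __future__ import annotations

import io
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import meshcode
from .checklist import TaxonTable, percent
from .errors import OccurrenceError

__all__ = ["OccurrenceMatrix", "load_occurrences", "filter_matrix",
           "occupancy_summary"]


class OccurrenceMatrix:
    """Deduplicated boolean presence of taxa over secondary mesh cells.

    Parameters
    ----------
    presence:
        Boolean frame, index = taxon_ids (checklist order of appearance),
        columns = mesh codes (sorted ascending).
    provenance:
        Number of raw records before deduplication.
    """

    def __init__(self, presence: pd.DataFrame, provenance: int):
        if presence.dtypes.ne(bool).any():
            raise OccurrenceError("presence matrix must be boolean")
        self.presence = presence
        self.provenance = int(provenance)

    @property
    def taxa(self) -> list:
        return list(self.presence.index)

    @property
    def cells(self) -> list:
        return list(self.presence.columns)

    @property
    def n_presences(self) -> int:
        """Distinct (taxon, cell) pairs."""
        return int(self.presence.to_numpy().sum())

    def cells_of(self, taxon_id: str) -> list:
        """Mesh codes occupied by one taxon."""
        row = self.presence.loc[taxon_id]
        return list(row.index[row])

    def to_records(self) -> pd.DataFrame:
        """Long form ``(taxon_id, mesh_code)`` of the deduplicated matrix."""
        ti, ci = np.nonzero(self.presence.to_numpy())
        idx = self.presence.index.to_numpy()
        cols = self.presence.columns.to_numpy()
        return pd.DataFrame({"taxon_id": idx[ti], "mesh_code": cols[ci]})

    def to_csv(self, path) -> None:
        self.to_records().to_csv(path, index=False)

    def __eq__(self, other) -> bool:  # provenance deliberately excluded
        return (isinstance(other, OccurrenceMatrix)
                and self.presence.equals(other.presence))


def load_occurrences(path, table: TaxonTable) -> OccurrenceMatrix:
    """Read a two-column ``taxon_id, mesh_code`` CSV into a presence matrix.

    Duplicated (taxon, cell) pairs are collapsed; the raw row count is kept
    as ``provenance``.  Every taxon_id must exist in the checklist and every
    mesh code must parse as a 6-digit secondary code; offenders are listed,
    never silently dropped.
    """
    if isinstance(path, str) and "\n" in path:
        path = io.StringIO(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["taxon_id", "mesh_code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise OccurrenceError(
            f"occurrence file missing column(s): {', '.join(missing)}"
        )
    return matrix_from_records(df[required], table)


def matrix_from_records(df: pd.DataFrame, table: TaxonTable
                        ) -> OccurrenceMatrix:
    """Build a deduplicated matrix from an in-memory record frame."""
    provenance = len(df)
    known = set(table.df["taxon_id"])
    unknown = sorted(set(df["taxon_id"]) - known)
    if unknown:
        shown = ", ".join(unknown[:10])
        more = "" if len(unknown) <= 10 else f" (+{len(unknown) - 10} more)"
        raise OccurrenceError(
            f"occurrence records reference taxa absent from the checklist: "
            f"{shown}{more}"
        )
    # Validate codes once per distinct value, not per record.
    for code in pd.unique(df["mesh_code"]):
        meshcode.parse_mesh(code)

    dedup = df.drop_duplicates()
    observed = set(dedup["taxon_id"])
    taxa = [t for t in table.df["taxon_id"] if t in observed]
    cells = sorted(pd.unique(dedup["mesh_code"]))
    t_pos = {t: i for i, t in enumerate(taxa)}
    c_pos = {c: j for j, c in enumerate(cells)}
    mat = np.zeros((len(taxa), len(cells)), dtype=bool)
    if len(dedup):
        rows = dedup["taxon_id"].map(t_pos).to_numpy()
        cols = dedup["mesh_code"].map(c_pos).to_numpy()
        mat[rows, cols] = True
    presence = pd.DataFrame(mat, index=pd.Index(taxa, name="taxon_id"),
                            columns=pd.Index(cells, name="mesh_code"))
    return OccurrenceMatrix(presence, provenance)


def filter_matrix(m: OccurrenceMatrix, table: TaxonTable, *,
                  include_hybrids: bool = True, lineage: str = "all",
                  subset: str = "all", include_both: bool = True
                  ) -> OccurrenceMatrix:
    """Restrict matrix rows by checklist predicates; cell columns are kept.

    Parameters
    ----------
    include_hybrids:
        Keep nothotaxa rows (richness-style maps may include them; all
        phylogenetic and range analyses exclude them).
    lineage:
        ``"all"`` or ``"ferns"`` (drops lycophytes).
    subset:
        ``"all"``, ``"apomictic"`` (reproductive mode apomictic, plus
        dual-mode taxa when *include_both*), or ``"redlisted"`` (any of the
        seven threat categories).
    """
    if lineage not in ("all", "ferns"):
        raise OccurrenceError(f"unknown lineage filter {lineage!r}")
    if subset not in ("all", "apomictic", "redlisted"):
        raise OccurrenceError(f"unknown subset filter {subset!r}")
    tdf = table.df.set_index("taxon_id")
    keep = pd.Series(True, index=tdf.index)
    if not include_hybrids:
        keep &= ~tdf["is_hybrid"]
    if lineage == "ferns":
        keep &= tdf["lineage"] == "fern"
    if subset == "apomictic":
        modes = ("apomictic", "both") if include_both else ("apomictic",)
        keep &= tdf["reproductive_mode"].isin(modes)
    elif subset == "redlisted":
        keep &= tdf["redlist"] != "none"
    kept = [t for t in m.taxa if bool(keep.get(t, False))]
    return OccurrenceMatrix(m.presence.loc[kept], m.provenance)


def occupancy_summary(m: OccurrenceMatrix, total_cells: Optional[int] = None
                      ) -> Tuple[int, int, float]:
    """``(occupied_cells, total_cells, percent_occupied)``.

    *total_cells* is the study frame size (e.g. the 4852-cell national
    frame); presence-only data cannot reveal empty frame cells, so the
    frame is configuration.  Defaults to the number of cells in the matrix.
    """
    occupied = int(m.presence.to_numpy().any(axis=0).sum()) \
        if len(m.taxa) else 0
    total = int(total_cells) if total_cells is not None else len(m.cells)
    if total < occupied:
        raise OccurrenceError(
            f"frame of {total} cells smaller than {occupied} occupied cells"
        )
    pct = percent(occupied, total) if total else 0.0
    return occupied, total, pct
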