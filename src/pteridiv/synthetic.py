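"""Synthetic checklist / occurrence / phylogeny triples.

The generator emulates the statistical structure of the archipelago
dataset the pipeline targets, so every stage is testable without the
deposited files: a rectangular band of secondary mesh cells spanning the
archipelago's latitudes (24–46°N), taxa with group-specific latitudinal
range centres and breadths (apomicts shifted south and narrower;
seasonally green taxa shifted north), a random Yule tree over the
non-hybrid taxa with a small fraction of tips withheld to emulate
incomplete rbcL sampling, and optional duplicate occurrence records to
exercise deduplication.

Defaults reproduce the study's regime: 721 native taxa plus 371 hybrids;
11% of natives apomictic (≈79, the published group size), 1.1% capable of
both modes (≈8) and ~31% of unknown mode (leaving ≈413 known-mode sexual
taxa); breadth distributions Normal(7.62, 5.02) for sexual and
Normal(5.93, 3.77) degrees for apomictic taxa; 2.1% of taxa missing from
the tree (97.9% coverage).  Occupancy is sampled independently per cell
within each taxon's latitudinal band — a deliberate simplification with no
spatial autocorrelation and no coastline mask.

All three generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import meshcode
from .checklist import TaxonTable
from .errors import PteridivError
from .phylodiv import Phylogeny, parse_newick

__all__ = ["SimConfig", "Frame", "gen_checklist", "gen_tree",
           "gen_occurrences", "gen_dataset"]


@dataclass(frozen=True)
class Frame:
    """Rectangular band of secondary mesh cells (the synthetic study area).

    Bounds are degrees; cells whose SW corner lies in
    ``[lat_min, lat_max) x [lon_min, lon_max)`` belong to the frame.
    """

    lat_min: float = 24.0
    lat_max: float = 46.0
    lon_min: float = 123.0
    lon_max: float = 146.0

    def grid(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(codes 2-d, row centroid lats, col centroid lons)``.

        ``codes`` has shape (n_rows, n_cols), rows ordered south to north.
        """
        lat_units = np.arange(int(round(self.lat_min * 12)),
                              int(round(self.lat_max * 12)))
        lon_units = np.arange(
            int(round((self.lon_min - meshcode.LON_ORIGIN_DEG) * 8)),
            int(round((self.lon_max - meshcode.LON_ORIGIN_DEG) * 8)))
        if len(lat_units) == 0 or len(lon_units) == 0:
            raise PteridivError("empty synthetic frame")
        lat_idx, row = np.divmod(lat_units, 8)
        lon_idx, col = np.divmod(lon_units, 8)
        codes = np.empty((len(lat_units), len(lon_units)), dtype=object)
        for i in range(len(lat_units)):
            prefix = f"{lat_idx[i]:02d}"
            r = str(row[i])
            for j in range(len(lon_units)):
                codes[i, j] = f"{prefix}{lon_idx[j]:02d}{r}{col[j]}"
        row_lats = (lat_units + 0.5) / 12.0
        col_lons = meshcode.LON_ORIGIN_DEG + (lon_units + 0.5) / 8.0
        return codes, row_lats, col_lons

    @property
    def n_cells(self) -> int:
        n_rows = int(round(self.lat_max * 12)) - int(round(self.lat_min * 12))
        n_cols = int(round((self.lon_max - meshcode.LON_ORIGIN_DEG) * 8)) \
            - int(round((self.lon_min - meshcode.LON_ORIGIN_DEG) * 8))
        return n_rows * n_cols


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic archipelago.

    Fractions are probabilities applied per taxon (realised counts vary
    binomially).  ``hybrid_fraction`` is hybrids per native taxon, so the
    default yields ≈371 hybrids alongside 721 natives.  Breadths are
    degrees of latitude, truncated below at one cell height.
    """

    seed: int = 0
    n_taxa: int = 721                    # native (non-hybrid) taxa
    hybrid_fraction: float = 371 / 721   # hybrids per native taxon
    lycophyte_fraction: float = 0.07
    infraspecific_fraction: float = 0.047  # subspecies/variety ranks
    apomict_fraction: float = 0.11       # of native taxa
    both_fraction: float = 0.011         # capable of either mode
    mode_unknown_fraction: float = 0.306
    polyploid_fraction: float = 0.452    # among known-ploidy sexual taxa
    ploidy_unknown_fraction: float = 0.0
    evergreen_fraction: float = 0.745    # among known-phenology natives
    phenology_unknown_fraction: float = 0.0
    endemic_fraction: float = 125 / 721
    redlist_fraction: float = 255 / 721
    missing_tip_fraction: float = 0.021  # taxa without an rbcL tip
    tree_birth_rate: float = 100.0       # edge lengths ~ Exp(rate)
    frame: Frame = field(default_factory=Frame)
    center_lat_mean: float = 35.0
    center_lat_sd: float = 3.0
    apomict_center_shift: float = -2.5   # southward
    seasonal_center_shift: float = 2.5   # northward
    breadth_sexual: Tuple[float, float] = (7.62, 5.02)    # (mean, sd)
    breadth_apomictic: Tuple[float, float] = (5.93, 3.77)
    occupancy_density: float = 0.02      # per-cell Bernoulli within band
    duplicate_rate: float = 0.0          # extra duplicated records

    def __post_init__(self):
        for name in ("lycophyte_fraction", "infraspecific_fraction",
                     "apomict_fraction", "both_fraction",
                     "mode_unknown_fraction", "polyploid_fraction",
                     "ploidy_unknown_fraction", "evergreen_fraction",
                     "phenology_unknown_fraction", "endemic_fraction",
                     "redlist_fraction", "missing_tip_fraction",
                     "occupancy_density", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PteridivError(f"{name}={v} outside [0, 1]")
        if (self.apomict_fraction + self.both_fraction
                + self.mode_unknown_fraction) > 1.0:
            raise PteridivError("reproductive-mode fractions exceed 1")
        if self.n_taxa < 1:
            raise PteridivError("n_taxa must be positive")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


_REDLIST_WEIGHTS = {"EX": 7, "EW": 2, "CR": 82, "EN": 59, "VU": 67,
                    "NT": 37, "DD": 1}


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # Independent, reproducible stream per generator stage (stable hash:
    # Python's str hash is salted per process).
    tag = zlib.crc32(stream.encode("utf-8")) % (2 ** 31)
    return np.random.default_rng([cfg.seed, tag])


def gen_checklist(cfg: SimConfig) -> TaxonTable:
    """Generate a trait-annotated checklist: natives first, then hybrids."""
    rng = _rng(cfg, "checklist")
    n_nat = cfg.n_taxa
    n_hyb = int(round(cfg.n_taxa * cfg.hybrid_fraction))

    ids = [f"t{i:04d}" for i in range(1, n_nat + 1)] \
        + [f"h{i:04d}" for i in range(1, n_hyb + 1)]
    names = [f"Taxon {i}" for i in range(1, n_nat + 1)] \
        + [f"Taxon x-{i}" for i in range(1, n_hyb + 1)]
    is_hybrid = np.r_[np.zeros(n_nat, bool), np.ones(n_hyb, bool)]
    n = n_nat + n_hyb

    rank = np.where(rng.random(n) < cfg.infraspecific_fraction,
                    np.where(rng.random(n) < 0.5, "subspecies", "variety"),
                    "species")
    rank[is_hybrid] = "species"
    lineage = np.where(rng.random(n) < cfg.lycophyte_fraction,
                       "lycophyte", "fern")

    p_apo = cfg.apomict_fraction
    p_both = cfg.both_fraction
    p_unk = cfg.mode_unknown_fraction
    u = rng.random(n)
    mode = np.full(n, "sexual", dtype=object)
    mode[u < p_apo] = "apomictic"
    mode[(u >= p_apo) & (u < p_apo + p_both)] = "both"
    mode[(u >= p_apo + p_both) & (u < p_apo + p_both + p_unk)] = "unknown"
    mode[is_hybrid] = "unknown"     # hybrid modes are not analysed

    ploidy = np.full(n, "unknown", dtype=object)
    sexual = (mode == "sexual") & ~is_hybrid
    known_ploidy = sexual & (rng.random(n) >= cfg.ploidy_unknown_fraction)
    ploidy[known_ploidy] = np.where(
        rng.random(int(known_ploidy.sum())) < cfg.polyploid_fraction,
        "polyploid", "diploid")

    phenology = np.full(n, "unknown", dtype=object)
    known_phen = rng.random(n) >= cfg.phenology_unknown_fraction
    phenology[known_phen] = np.where(
        rng.random(int(known_phen.sum())) < cfg.evergreen_fraction,
        "evergreen", "seasonal_green")

    endemic = (rng.random(n) < cfg.endemic_fraction) & ~is_hybrid
    redlist = np.full(n, "none", dtype=object)
    listed = (rng.random(n) < cfg.redlist_fraction) & ~is_hybrid
    cats = list(_REDLIST_WEIGHTS)
    weights = np.array(list(_REDLIST_WEIGHTS.values()), dtype=float)
    weights /= weights.sum()
    redlist[listed] = rng.choice(cats, size=int(listed.sum()), p=weights)

    df = pd.DataFrame({
        "taxon_id": ids, "name": names, "rank": rank,
        "is_hybrid": is_hybrid, "lineage": lineage,
        "reproductive_mode": mode, "ploidy_class": ploidy,
        "phenology": phenology, "endemic": endemic, "redlist": redlist,
        "in_tree": np.zeros(n, bool),   # set by gen_tree
    })
    return TaxonTable(df)


def gen_tree(cfg: SimConfig, table: TaxonTable
             ) -> Tuple[str, Phylogeny, TaxonTable]:
    """Yule tree over non-hybrid taxa with exponential branch lengths.

    A ``missing_tip_fraction`` Bernoulli draw withholds taxa from the tree
    (emulating incomplete rbcL sampling); the returned table carries
    updated ``in_tree`` flags.  Returns ``(newick, Phylogeny, table)``.
    """
    rng = _rng(cfg, "tree")
    native_ids = list(table.native["taxon_id"])
    keep = rng.random(len(native_ids)) >= cfg.missing_tip_fraction
    tips = [t for t, k in zip(native_ids, keep) if k]
    if len(tips) < 2:
        raise PteridivError("fewer than two tips for the synthetic tree")

    # Yule topology by uniform random joins; each join assigns exponential
    # lengths to the two child edges.
    scale = 1.0 / cfg.tree_birth_rate
    parts = list(tips)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        li, lj = (float(x) for x in rng.exponential(scale, size=2))
        merged = f"({parts[i]}:{li!r},{parts[j]}:{lj!r})"
        parts[i] = merged
        parts.pop(j)
    newick = parts[0] + ";"

    df = table.df.copy()
    df["in_tree"] = df["taxon_id"].isin(set(tips))
    return newick, parse_newick(newick), TaxonTable(df)


def _taxon_centers_breadths(cfg: SimConfig, table: TaxonTable,
                            rng: np.random.Generator
                            ) -> Tuple[np.ndarray, np.ndarray]:
    df = table.df
    n = len(df)
    centers = rng.normal(cfg.center_lat_mean, cfg.center_lat_sd, size=n)
    apo = (df["reproductive_mode"] == "apomictic").to_numpy()
    seasonal = (df["phenology"] == "seasonal_green").to_numpy()
    centers = centers + np.where(apo, cfg.apomict_center_shift, 0.0) \
        + np.where(seasonal, cfg.seasonal_center_shift, 0.0)

    mean_s, sd_s = cfg.breadth_sexual
    mean_a, sd_a = cfg.breadth_apomictic
    breadths = np.where(apo, rng.normal(mean_a, sd_a, size=n),
                        rng.normal(mean_s, sd_s, size=n))
    span = cfg.frame.lat_max - cfg.frame.lat_min
    breadths = np.clip(breadths, meshcode.LAT_CELL_DEG, span)
    # Keep the whole band inside the frame: clipping bands at the frame
    # edge would shrink realised breadths below their drawn values, so
    # group breadth means would not converge to the configured ones.
    centers = np.clip(centers, cfg.frame.lat_min + breadths / 2.0,
                      cfg.frame.lat_max - breadths / 2.0)
    return centers, breadths


def gen_occurrences(cfg: SimConfig, table: TaxonTable) -> pd.DataFrame:
    """Presence records ``(taxon_id, mesh_code)``, duplicates included.

    Each taxon receives a latitudinal centre and breadth from its group's
    distributions; within the resulting band every frame cell is occupied
    independently with probability ``occupancy_density``.  A
    ``duplicate_rate`` fraction of records is re-appended afterwards to
    exercise deduplication downstream.
    """
    rng = _rng(cfg, "occurrences")
    codes, row_lats, _ = cfg.frame.grid()
    n_cols = codes.shape[1]
    centers, breadths = _taxon_centers_breadths(cfg, table, rng)

    taxon_col, code_col = [], []
    for t_idx, taxon_id in enumerate(table.df["taxon_id"]):
        lo = centers[t_idx] - breadths[t_idx] / 2.0
        hi = centers[t_idx] + breadths[t_idx] / 2.0
        rows = np.nonzero((row_lats >= lo) & (row_lats <= hi))[0]
        if len(rows) == 0:
            continue
        draws = rng.random((len(rows), n_cols)) < cfg.occupancy_density
        ri, ci = np.nonzero(draws)
        if len(ri) == 0:
            continue
        picked = codes[rows[ri], ci]
        taxon_col.extend([taxon_id] * len(picked))
        code_col.extend(picked.tolist())

    records = pd.DataFrame({"taxon_id": taxon_col, "mesh_code": code_col})
    n_dup = int(round(cfg.duplicate_rate * len(records)))
    if n_dup:
        dup_idx = rng.choice(len(records), size=n_dup, replace=True)
        records = pd.concat([records, records.iloc[dup_idx]],
                            ignore_index=True)
    return records


def gen_dataset(cfg: SimConfig, outdir: Optional[str] = None):
    """Generate the full triple; optionally write the loader dialects.

    Returns ``(table, newick, tree, records)`` where *table* carries the
    ``in_tree`` flags.  With *outdir*, writes ``checklist.csv``,
    ``occurrences.csv`` and ``tree.nwk`` in exactly the dialects the
    loaders read.
    """
    table = gen_checklist(cfg)
    newick, tree, table = gen_tree(cfg, table)
    records = gen_occurrences(cfg, table)
    if outdir is not None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "checklist.csv")
        records.to_csv(out / "occurrences.csv", index=False)
        (out / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
    return table, newick, tree, records
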