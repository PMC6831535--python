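"""Trait-annotated taxon checklist and flora-level summary proportions.

The checklist is the unit of every denominator in the analysis.  Each row is
one taxon (species, subspecies or variety) of the fern/lycophyte flora,
annotated with the traits the downstream comparisons stratify on:
nothotaxon (hybrid) status, fern vs lycophyte lineage, reproductive mode
(sexual, apomictic, or capable of both), ploidy class among sexual taxa,
phenology (evergreen vs seasonally green), endemism, national red-list
category, and whether the taxon has a tip in the reference rbcL phylogeny.

Two denominators matter and are deliberately kept distinct: "native taxa"
means the non-hybrid rows (the flora's 721 in the motivating dataset), while
interspecific hybrids (371 there) are excluded from every diversity and
range analysis unless explicitly included.  Trait values recorded as
``unknown`` are excluded from any denominator described as "whose ... are
known" and are never imputed.

Percentages follow the convention of the source tables: one decimal place,
round-half-away-from-zero (so 17.25 -> 17.3).
"""

from __future__ import annotations

import io
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import pandas as pd

from .errors import ChecklistError, UndefinedProportionError

__all__ = [
    "TaxonTable",
    "load_checklist",
    "percent",
    "redlist_total",
    "apomixis_rate",
    "flora_summary",
    "COLUMNS",
    "CATEGORICAL_LEVELS",
    "REDLIST_CATEGORIES",
]

#: Checklist CSV columns, in canonical order.
COLUMNS = [
    "taxon_id",
    "name",
    "rank",
    "is_hybrid",
    "lineage",
    "reproductive_mode",
    "ploidy_class",
    "phenology",
    "endemic",
    "redlist",
    "in_tree",
]

#: Allowed levels for each categorical column.
CATEGORICAL_LEVELS = {
    "rank": ("species", "subspecies", "variety"),
    "lineage": ("fern", "lycophyte"),
    "reproductive_mode": ("sexual", "apomictic", "both", "unknown"),
    "ploidy_class": ("diploid", "polyploid", "unknown"),
    "phenology": ("evergreen", "seasonal_green", "unknown"),
    "redlist": ("EX", "EW", "CR", "EN", "VU", "NT", "DD", "none"),
}

_BOOL_COLUMNS = ("is_hybrid", "endemic", "in_tree")

#: The seven national red-list threat categories (``none`` is not one).
REDLIST_CATEGORIES = ("EX", "EW", "CR", "EN", "VU", "NT", "DD")


def percent(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` at one decimal, half away from zero.

    Reproduces the printed flora proportions exactly, e.g.
    ``percent(487, 721) == 67.5`` and ``percent(34, 199) == 17.1``.

    Raises
    ------
    UndefinedProportionError
        If *denominator* is zero.
    """
    if denominator == 0:
        raise UndefinedProportionError(
            f"proportion {numerator}/0 is undefined (zero denominator)"
        )
    # Exact rational arithmetic, then quantize: Decimal's ROUND_HALF_UP is
    # round-half-away-from-zero.
    value = (Decimal(numerator) * 100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class TaxonTable:
    """Validated, ordered collection of checklist taxa.

    Thin wrapper over a :class:`pandas.DataFrame` with the schema in
    :data:`COLUMNS`; all flora summaries are pure functions of the table.
    """

    def __init__(self, df: pd.DataFrame):
        self._df = _validate(df.reset_index(drop=True))

    # -- container basics -------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying frame (treat as read-only)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in set(self._df["taxon_id"])

    # -- masks and counts --------------------------------------------------

    @property
    def native(self) -> pd.DataFrame:
        """Non-hybrid rows: the 'native taxa' denominator."""
        return self._df[~self._df["is_hybrid"]]

    @property
    def hybrids(self) -> pd.DataFrame:
        return self._df[self._df["is_hybrid"]]

    @property
    def n_total(self) -> int:
        return len(self._df)

    @property
    def n_native(self) -> int:
        return int((~self._df["is_hybrid"]).sum())

    @property
    def n_hybrid(self) -> int:
        return int(self._df["is_hybrid"].sum())

    @property
    def n_species(self) -> int:
        """Native taxa at species rank (the narrower '687' style count)."""
        nat = self.native
        return int((nat["rank"] == "species").sum())

    def redlist_counts(self, native_only: bool = True) -> dict:
        """Count of taxa per threat category (``none`` excluded)."""
        rows = self.native if native_only else self._df
        vc = rows["redlist"].value_counts()
        return {cat: int(vc.get(cat, 0)) for cat in REDLIST_CATEGORIES}

    def trait_levels(self, trait: str) -> tuple:
        return CATEGORICAL_LEVELS[trait]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the checklist in the canonical CSV dialect (UTF-8, header,
        booleans as lowercase ``true``/``false``)."""
        out = self._df.copy()
        for col in _BOOL_COLUMNS:
            out[col] = out[col].map({True: "true", False: "false"})
        out.to_csv(path, index=False, columns=COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "TaxonTable":
        return load_checklist(path)


def load_checklist(path) -> TaxonTable:
    """Read and validate a checklist CSV.

    The file must be UTF-8 with a header row carrying exactly the columns in
    :data:`COLUMNS`.  Validation errors name the offending row (1-based file
    line, header = line 1) and column.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "read"):
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(str(path), dtype=str, keep_default_na=False)
    return TaxonTable(_coerce_strings(df))


def loads_checklist(text: str) -> TaxonTable:
    """Parse a checklist from an in-memory CSV string (testing aid)."""
    return load_checklist(io.StringIO(text))


def _coerce_strings(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ChecklistError(
            f"checklist is missing required column(s): {', '.join(missing)}"
        )
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise ChecklistError(
            f"checklist has unrecognised column(s): {', '.join(extra)}"
        )
    df = df[COLUMNS].copy()
    for col in _BOOL_COLUMNS:
        lowered = df[col].astype(str).str.strip().str.lower()
        bad = ~lowered.isin(("true", "false"))
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ChecklistError(
                f"column {col!r}, row {row}: expected true/false, "
                f"got {df[col][bad.idxmax()]!r}"
            )
        df[col] = lowered == "true"
    return df


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ChecklistError(
            f"checklist is missing required column(s): {', '.join(missing)}"
        )
    dup = df["taxon_id"].duplicated()
    if dup.any():
        offenders = sorted(df.loc[dup, "taxon_id"].unique())
        raise ChecklistError(
            f"duplicate taxon_id value(s): {', '.join(map(str, offenders))}"
        )
    if (df["taxon_id"].astype(str).str.strip() == "").any():
        raise ChecklistError("empty taxon_id value(s) present")
    for col, levels in CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise ChecklistError(
                f"column {col!r}, row {row}: value "
                f"{df.loc[bad.idxmax(), col]!r} not in {levels}"
            )
    for col in _BOOL_COLUMNS:
        if df[col].dtype != bool:
            raise ChecklistError(f"column {col!r} must be boolean")
    return df


def redlist_total(counts: Mapping[str, int]) -> int:
    """Sum of taxa over the seven threat categories.

    Keys other than the seven categories (e.g. ``none``) are ignored;
    negative counts are rejected.
    """
    total = 0
    for cat in REDLIST_CATEGORIES:
        n = int(counts.get(cat, 0))
        if n < 0:
            raise ChecklistError(f"negative red-list count for {cat}: {n}")
        total += n
    return total


def apomixis_rate(table: TaxonTable, include_both: bool = True) -> float:
    """Percentage of known-mode native taxa that reproduce apomictically.

    Denominator: native (non-hybrid) taxa whose reproductive mode is known
    (not ``unknown``).  Numerator: mode ``apomictic``, plus mode ``both``
    (capable of either) when *include_both* is true.  Both numerator
    conventions are exposed because published rates do not state whether
    dual-mode taxa were counted as apomictic.
    """
    nat = table.native
    known = nat[nat["reproductive_mode"] != "unknown"]
    if len(known) == 0:
        raise UndefinedProportionError(
            "no native taxa with known reproductive mode"
        )
    modes = ("apomictic", "both") if include_both else ("apomictic",)
    num = int(known["reproductive_mode"].isin(modes).sum())
    return percent(num, len(known))


def flora_summary(table: TaxonTable) -> dict:
    """Flora-level report: counts, proportions, red-list totals.

    Pure function of the table; keys are stable for machine consumption.
    """
    nat = table.native
    n_native = len(nat)
    rl = table.redlist_counts(native_only=True)
    known_mode = nat[nat["reproductive_mode"] != "unknown"]
    summary = {
        "n_total": table.n_total,
        "n_native": n_native,
        "n_hybrid": table.n_hybrid,
        "n_species_rank": table.n_species,
        "n_endemic": int(nat["endemic"].sum()),
        "pct_endemic": percent(int(nat["endemic"].sum()), n_native)
        if n_native else None,
        "n_known_mode": len(known_mode),
        "n_apomictic": int((nat["reproductive_mode"] == "apomictic").sum()),
        "n_both_modes": int((nat["reproductive_mode"] == "both").sum()),
        "pct_apomictic_incl_both": apomixis_rate(table, include_both=True)
        if len(known_mode) else None,
        "pct_apomictic_excl_both": apomixis_rate(table, include_both=False)
        if len(known_mode) else None,
        "redlist_counts": rl,
        "n_redlisted": redlist_total(rl),
        "n_in_tree": int(nat["in_tree"].sum()),
        "pct_in_tree": percent(int(nat["in_tree"].sum()), n_native)
        if n_native else None,
    }
    return summary
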