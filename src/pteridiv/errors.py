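"""Exception hierarchy shared across the package."""


class PteridivError(Exception):
    """Base class for all errors raised by this package."""


class MeshCodeError(PteridivError):
    """A grid code is not a well-formed 6-digit secondary mesh code."""


class MeshDomainError(PteridivError):
    """A coordinate lies outside the domain of the standard area mesh."""


class ChecklistError(PteridivError):
    """Checklist table failed validation (duplicate id, bad category, ...)."""


class UndefinedProportionError(PteridivError):
    """A percentage was requested with a zero denominator."""


class OccurrenceError(PteridivError):
    """Occurrence records failed referential or structural validation."""


class PhylogenyError(PteridivError):
    """A Newick tree could not be parsed or violates tree invariants."""


class AbsentTaxonError(PteridivError):
    """A per-taxon range summary was requested for a taxon with no cells."""


class DegenerateGroupError(PteridivError):
    """A statistical test received a group too small to analyse (n < 2)."""


class GridMapError(PteridivError):
    """A grid-map operation received inconsistent layers or an empty map."""
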