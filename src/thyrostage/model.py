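"""Domain model for the gross-invasion anatomic checklist.

Grossly invasive thyroid cancer is staged from what the surgeon sees in the
operating room, not only from specimen histology.  The checklist records, per
anatomic structure, whether the tumor was dissected off the structure in a
tissue-sparing plane (degree 0: subepineural, subperichondrial, subperiosteal,
subadventitial, or muscularis-only for the pharyngoesophagus) or whether the
structure had to be resected through-and-through (degree 1).  Muscle
involvement is binary and carries no degree.  This module defines the
controlled vocabulary of sites and subsites, the AJCC T/N/M category sets,
residual-disease codes, the checklist record itself, and the validation and
ordering primitives every other module builds on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


# ---------------------------------------------------------------------------
# Site / subsite vocabulary
# ---------------------------------------------------------------------------

class Ordering(enum.Enum):
    """Outcome of comparing two T categories."""

    LESS = "less"
    EQUAL = "equal"
    GREATER = "greater"
    INCOMPARABLE = "incomparable"


@dataclass(frozen=True)
class SiteCategory:
    """One of the six anatomic site categories of the checklist."""

    code: str
    label: str


@dataclass(frozen=True)
class Subsite:
    """An anatomic subsite within a site category.

    ``takes_degree`` is False exactly for muscle subsites (muscle invasion is
    a binary determination); ``takes_ring_count`` is True only for the
    trachea, whose subscript counts involved tracheal rings.
    """

    category: str
    code: str
    label: str
    takes_degree: bool = True
    takes_ring_count: bool = False


CATEGORIES: tuple[SiteCategory, ...] = (
    SiteCategory("LT", "laryngotracheal complex"),
    SiteCategory("B", "bone"),
    SiteCategory("N", "nerves"),
    SiteCategory("PE", "pharyngoesophagus"),
    SiteCategory("Vas", "arteries and veins"),
    SiteCategory("M", "muscle"),
)

CATEGORY_ORDER: tuple[str, ...] = tuple(c.code for c in CATEGORIES)
CATEGORY_BY_CODE: dict[str, SiteCategory] = {c.code.upper(): c for c in CATEGORIES}

SUBSITES: tuple[Subsite, ...] = (
    Subsite("LT", "Th", "thyroid ala"),
    Subsite("LT", "Cr", "cricoid cartilage"),
    Subsite("LT", "T", "trachea", takes_ring_count=True),
    Subsite("B", "Clav", "clavicular head"),
    Subsite("B", "St", "sternum"),
    Subsite("N", "RLN", "recurrent laryngeal nerve"),
    Subsite("N", "SLN", "superior laryngeal nerve"),
    Subsite("N", "Vag", "vagus nerve"),
    Subsite("PE", "Ph", "pharynx"),
    Subsite("PE", "E", "esophagus"),
    Subsite("Vas", "A_CC", "common carotid artery"),
    Subsite("Vas", "A_INN", "innominate artery"),
    Subsite("Vas", "V_IJ", "internal jugular vein"),
    Subsite("Vas", "V_INN", "innominate vein"),
    Subsite("M", "SM", "strap muscles", takes_degree=False),
    Subsite("M", "SCM", "sternocleidomastoid muscle", takes_degree=False),
    Subsite("M", "CT", "cricothyroid muscle", takes_degree=False),
)

SUBSITE_BY_KEY: dict[tuple[str, str], Subsite] = {
    (s.category.upper(), s.code.upper()): s for s in SUBSITES
}

SUBSITE_CODES: dict[str, tuple[str, ...]] = {
    c.code: tuple(s.code for s in SUBSITES if s.category == c.code) for c in CATEGORIES
}


def find_category(code: str) -> SiteCategory | None:
    """Case-insensitive category lookup ('VAS' and 'Vas' both resolve)."""
    return CATEGORY_BY_CODE.get(code.upper())


def find_subsite(category: str, code: str) -> Subsite | None:
    """Case-insensitive subsite lookup within a category."""
    return SUBSITE_BY_KEY.get((category.upper(), code.upper()))


# ---------------------------------------------------------------------------
# Involvement
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Involvement:
    """One anatomic structure involved by tumor.

    ``degree`` is the extent-of-surgery superscript (0 = tissue-sparing
    plane, 1 = structure resected); it is None exactly for muscle subsites.
    ``ring_count`` is the tracheal-ring subscript, present only for LT-T.
    """

    category: str
    subsite: str
    degree: int | None = None
    ring_count: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.category, self.subsite)

    @property
    def sort_key(self) -> tuple[int, int]:
        cat = CATEGORY_ORDER.index(self.category)
        return (cat, SUBSITE_CODES[self.category].index(self.subsite))

    def token(self) -> str:
        """Canonical ASCII token, e.g. ``LT-T_2^0`` or ``M-SCM``."""
        out = f"{self.category}-{self.subsite}"
        if self.ring_count is not None:
            out += f"_{self.ring_count}"
        if self.degree is not None:
            out += f"^{self.degree}"
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def sorted_involvements(involvements) -> tuple[Involvement, ...]:
    """Canonical ordering: categories LT, B, N, PE, Vas, M; subsites in
    vocabulary order within each category."""
    return tuple(sorted(involvements, key=lambda i: i.sort_key))


# ---------------------------------------------------------------------------
# AJCC categories (8th edition, thyroid)
# ---------------------------------------------------------------------------

class TCategory(enum.Enum):
    TX = "TX"
    T0 = "T0"
    T1A = "T1a"
    T1B = "T1b"
    T2 = "T2"
    T3A = "T3a"
    T3B = "T3b"
    T4A = "T4a"
    T4B = "T4b"


# Strict total order over the non-X categories; TX is incomparable.
_T_RANK: dict[TCategory, int] = {
    t: i
    for i, t in enumerate(
        (
            TCategory.T0,
            TCategory.T1A,
            TCategory.T1B,
            TCategory.T2,
            TCategory.T3A,
            TCategory.T3B,
            TCategory.T4A,
            TCategory.T4B,
        )
    )
}


def t_order(a: TCategory, b: TCategory) -> Ordering:
    """Compare two AJCC T categories; TX compares incomparable to everything
    (including itself) because an unassessable primary cannot be ranked."""
    if a not in _T_RANK or b not in _T_RANK:
        return Ordering.INCOMPARABLE
    ra, rb = _T_RANK[a], _T_RANK[b]
    if ra < rb:
        return Ordering.LESS
    if ra > rb:
        return Ordering.GREATER
    return Ordering.EQUAL


def t_max(a: TCategory | None, b: TCategory | None) -> TCategory | None:
    """Maximum of two T categories under t_order; None and TX never win over
    an ordered category."""
    ordered = [t for t in (a, b) if t is not None and t in _T_RANK]
    if not ordered:
        return a if a is not None else b
    return max(ordered, key=_T_RANK.get)


class NCategory(enum.Enum):
    NX = "NX"
    N0 = "N0"
    N0A = "N0a"
    N0B = "N0b"
    N1 = "N1"
    N1A = "N1a"
    N1B = "N1b"


class MCategory(enum.Enum):
    MX = "MX"
    M0 = "M0"
    M1 = "M1"


def _display(code: str) -> str:
    return code.replace("X", "x")


@dataclass(frozen=True)
class TNMCategory:
    """Ordered T/N/M triple, e.g. pT4a N1b Mx."""

    t: TCategory
    n: NCategory = NCategory.NX
    m: MCategory = MCategory.MX

    def display(self) -> str:
        return f"p{_display(self.t.value)} {_display(self.n.value)} {_display(self.m.value)}"


class ResidualCode(enum.Enum):
    """Residual-disease code: R0 none, R1 microscopic, R2 gross tumor left."""

    R0 = "R0"
    R1 = "R1"
    R2 = "R2"


# ---------------------------------------------------------------------------
# Minimum data set & checklist record
# ---------------------------------------------------------------------------

class DiseaseStatus(enum.Enum):
    PRIMARY = "primary"
    RECURRENT = "recurrent"
    PERSISTENT = "persistent"


class Presence(enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class VocalCordFunction(enum.Enum):
    MOBILE = "mobile"
    PARETIC = "paretic"
    PARALYZED = "paralyzed"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MinimumDataSet:
    """Preoperative/operative context required for staging and risk-of-
    recurrence classification; every field has an explicit unknown state."""

    molecular_testing: str = "unknown"
    vocal_cord_right: VocalCordFunction = VocalCordFunction.UNKNOWN
    vocal_cord_left: VocalCordFunction = VocalCordFunction.UNKNOWN
    distant_mets: Presence = Presence.UNKNOWN
    residual: ResidualCode = ResidualCode.R0
    disease_status: DiseaseStatus = DiseaseStatus.PRIMARY


@dataclass(frozen=True)
class ChecklistRecord:
    """One surgical case as captured by the anatomic checklist.

    ``pathology_t`` is the T category justified by tumor size/extent alone
    (what the pathology report would assign without intraoperative anatomic
    information); it is optional, and not applicable to recurrent disease.
    """

    case_id: str
    surgeon: str = ""
    histology: str = ""
    mds: MinimumDataSet = field(default_factory=MinimumDataSet)
    involvements: frozenset[Involvement] = frozenset()
    pathology_t: TCategory | None = None
    pathology_n: NCategory | None = None
    pathology_m: MCategory | None = None
    checklist_submitted: bool = False


def validate_involvement(inv: Involvement) -> list[str]:
    """Invariant checks for a single involvement; violations are data."""
    out: list[str] = []
    sub = find_subsite(inv.category, inv.subsite)
    if sub is None or sub.category != inv.category or sub.code != inv.subsite:
        out.append(f"unknown_subsite:{inv.category}-{inv.subsite}")
        return out
    if not sub.takes_degree and inv.degree is not None:
        out.append(f"muscle_degree_forbidden:{inv.token()}")
    if sub.takes_degree and inv.degree is None:
        out.append(f"degree_missing:{inv.token()}")
    if inv.degree is not None and inv.degree not in (0, 1):
        out.append(f"degree_invalid:{inv.token()}")
    if inv.ring_count is not None:
        if not sub.takes_ring_count:
            out.append(f"ring_count_misplaced:{inv.token()}")
        elif inv.ring_count < 1:
            out.append(f"ring_count_invalid:{inv.token()}")
    return out


def validate_record(record: ChecklistRecord) -> list[str]:
    """Return all invariant violations of a checklist record.

    An empty list means the record is well formed.  Violations are returned
    as coded strings naming the offending field, never raised.
    """
    out: list[str] = []
    seen: set[tuple[str, str]] = set()
    # plain lexicographic order: unknown subsites must not crash the sort
    for inv in sorted(record.involvements, key=lambda i: (i.category, i.subsite)):
        out.extend(validate_involvement(inv))
        if inv.key in seen:
            out.append(f"duplicate_subsite:{inv.category}-{inv.subsite}")
        seen.add(inv.key)
    # A pathology_t on a recurrent/persistent record is not a violation:
    # AJCC staging is simply suppressed downstream, with a warning.
    return out
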