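"""Parser and canonical formatter for the shorthand classification string.

The shorthand appends an anatomic suffix to the familiar TNM triple, e.g.::

    pT4a N1b Mx PE-E^0 Vas-V_IJ^1 LT-T_2^0 N-RLN^1

Each suffix token is ``CATEGORY-SUBSITE`` with an optional ``_`` subscript
(tracheal ring count) and a ``^`` superscript (degree of invasion: 0 =
structure preserved by dissection in a tissue-sparing plane, 1 = structure
resected).  Muscle tokens carry no superscript.  Recurrent/persistent disease
is prefixed ``Rec`` and carries no TNM; gross or microscopic residual disease
is prefixed ``R2``/``R1``.

This is the ASCII interchange dialect: ``^`` stands for the typographic
superscript and ``_`` for the subscript.  The parser is deliberately liberal
(case-insensitive category/subsite codes, chained subsite groups that inherit
the category, ``/`` compression distributing a shared degree, either order of
``^``/``_`` suffixes, parenthesized English glosses ignored); the formatter
emits exactly one canonical spelling, so ``format(parse(s))`` normalizes any
accepted spelling and round-trips canonical strings unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import (
    CATEGORY_BY_CODE,
    SUBSITE_CODES,
    Involvement,
    MCategory,
    NCategory,
    ResidualCode,
    TCategory,
    TNMCategory,
    find_subsite,
    sorted_involvements,
    validate_involvement,
)


class ParseError(ValueError):
    """A classification string failed to parse.

    ``code`` is a stable machine-readable reason; ``position`` is the
    0-based character offset into the original string.
    """

    def __init__(self, code: str, position: int, message: str):
        super().__init__(f"{message} (at offset {position})")
        self.code = code
        self.position = position


@dataclass(frozen=True)
class ParsedClassification:
    """Structured content of one classification string."""

    rec_prefix: bool = False
    residual: ResidualCode = ResidualCode.R0
    tnm: TNMCategory | None = None
    involvements: frozenset[Involvement] = frozenset()


_T_RE = re.compile(r"^p?T(X|0|1a|1b|2|3a|3b|4a|4b)$", re.IGNORECASE)
_N_RE = re.compile(r"^N(X|0a|0b|0|1a|1b|1)$", re.IGNORECASE)
_M_RE = re.compile(r"^M(X|0|1)$", re.IGNORECASE)
_R_RE = re.compile(r"^R([012])$", re.IGNORECASE)
_REC_RE = re.compile(r"^Rec(-|$)", re.IGNORECASE)

# Bare vessel names allowed after "/" in a Vas chain; they inherit the
# artery/vein letter of the preceding vessel (VAS-V_IJ/INN^1 -> V_IJ, V_INN).
_BARE_VESSELS = ("INN", "CC", "IJ")


def _canon_t(group: str) -> TCategory:
    return TCategory.TX if group.upper() == "X" else TCategory("T" + group.lower())


def _canon_n(group: str) -> NCategory:
    return NCategory.NX if group.upper() == "X" else NCategory("N" + group.lower())


def _canon_m(group: str) -> MCategory:
    return MCategory("M" + group.upper()) if group.upper() in ("0", "1") else (
        MCategory.MX if group.upper() == "X" else MCategory("M" + group)
    )


def _strip_glosses(text: str) -> str:
    """Blank out parenthesized English glosses, preserving offsets."""
    out = text
    while True:
        new = re.sub(r"\([^()]*\)", lambda m: " " * len(m.group()), out)
        if new == out:
            return out
        out = new


def _match_subsite(category: str, text: str, prev_vessel: str | None) -> tuple[str, int] | None:
    """Longest case-insensitive subsite match at the start of ``text``.

    Returns (canonical subsite code, chars consumed).  For the Vas category a
    bare vessel name (after ``/``) resolves against the preceding vessel's
    A/V letter.
    """
    upper = text.upper()
    codes = sorted(SUBSITE_CODES[category], key=len, reverse=True)
    for code in codes:
        if upper.startswith(code.upper()):
            return code, len(code)
    if category == "Vas" and prev_vessel is not None:
        letter = prev_vessel.split("_", 1)[0]
        for bare in _BARE_VESSELS:
            if upper.startswith(bare):
                full = f"{letter}_{bare}"
                if find_subsite("Vas", full) is not None:
                    return find_subsite("Vas", full).code, len(bare)
    return None


def _parse_groups(
    chunk: str,
    category: str,
    base: int,
    involvements: dict[tuple[str, str], Involvement],
) -> None:
    """Parse one whitespace token's worth of subsite groups for ``category``.

    Groups may be concatenated (``T_2^0Cr^0``) or ``/``-compressed
    (``SM/CT``, ``V_IJ/INN^1``); a trailing shared degree distributes over
    all ``/`` alternatives that lack their own.
    """
    i = 0
    while i < len(chunk):
        alternatives: list[tuple[str, int | None, int | None, int]] = []
        prev_vessel: str | None = None
        while True:
            pos = base + i
            matched = _match_subsite(category, chunk[i:], prev_vessel)
            if matched is None:
                raise ParseError(
                    "unknown_subsite",
                    pos,
                    f"unknown subsite {chunk[i:]!r} for category {category}",
                )
            code, used = matched
            i += used
            prev_vessel = code if category == "Vas" else None
            rings: int | None = None
            degree: int | None = None
            # suffixes in either order, at most one of each
            while i < len(chunk) and chunk[i] in "_^":
                if chunk[i] == "_":
                    m = re.match(r"_(\d+)", chunk[i:])
                    if m is None or rings is not None:
                        raise ParseError(
                            "malformed_subscript", base + i, "malformed subscript"
                        )
                    rings = int(m.group(1))
                    i += m.end()
                else:
                    m = re.match(r"\^(\d)", chunk[i:])
                    if m is None or degree is not None:
                        raise ParseError(
                            "malformed_superscript", base + i, "malformed superscript"
                        )
                    degree = int(m.group(1))
                    i += m.end()
            alternatives.append((code, rings, degree, pos))
            if i < len(chunk) and chunk[i] == "/":
                i += 1
                continue
            break
        # a shared trailing degree distributes across "/" alternatives
        shared = alternatives[-1][2]
        for code, rings, degree, pos in alternatives:
            if degree is None and len(alternatives) > 1:
                degree = shared
            _add_involvement(category, code, degree, rings, pos, involvements)


def _add_involvement(
    category: str,
    code: str,
    degree: int | None,
    rings: int | None,
    pos: int,
    involvements: dict[tuple[str, str], Involvement],
) -> None:
    inv = Involvement(category=category, subsite=code, degree=degree, ring_count=rings)
    for violation in validate_involvement(inv):
        raise ParseError(violation.split(":", 1)[0], pos, violation)
    if inv.key in involvements:
        raise ParseError(
            "duplicate_subsite", pos, f"duplicate_subsite:{category}-{code}"
        )
    involvements[inv.key] = inv


def parse_classification(text: str) -> ParsedClassification:
    """Parse a shorthand classification string.

    Raises :class:`ParseError` (with character offset) on the first
    violation: unknown category/subsite, a degree on a muscle token, a
    subscript anywhere but the trachea, duplicate subsites, a malformed TNM,
    or a ``Rec`` prefix combined with a pT token.
    """
    if not text or not text.strip():
        raise ParseError("empty", 0, "empty classification string")
    stripped = _strip_glosses(text)
    tokens = [(m.group(), m.start()) for m in re.finditer(r"\S+", stripped)]

    rec = False
    residual = ResidualCode.R0
    tnm: TNMCategory | None = None
    involvements: dict[tuple[str, str], Involvement] = {}

    idx = 0
    # --- optional Rec prefix ------------------------------------------------
    if idx < len(tokens):
        tok, pos = tokens[idx]
        m = _REC_RE.match(tok)
        if m:
            rec = True
            rest = tok[m.end():]
            if rest:
                tokens[idx] = (rest, pos + m.end())
            else:
                idx += 1
    # --- optional residual code --------------------------------------------
    if idx < len(tokens):
        tok, pos = tokens[idx]
        m = _R_RE.match(tok)
        if m:
            residual = ResidualCode("R" + m.group(1))
            idx += 1
    # --- optional TNM -------------------------------------------------------
    if idx < len(tokens):
        tok, pos = tokens[idx]
        m = _T_RE.match(tok)
        if m:
            if rec:
                raise ParseError(
                    "rec_with_tnm", pos, "Rec classification cannot carry a pT category"
                )
            t = _canon_t(m.group(1))
            n, mm = NCategory.NX, MCategory.MX
            idx += 1
            if idx < len(tokens):
                mn = _N_RE.match(tokens[idx][0])
                if mn:
                    n = _canon_n(mn.group(1))
                    idx += 1
            if idx < len(tokens):
                mm_match = _M_RE.match(tokens[idx][0])
                if mm_match:
                    mm = _canon_m(mm_match.group(1))
                    idx += 1
            tnm = TNMCategory(t, n, mm)

    # --- anatomic suffix ----------------------------------------------------
    current: str | None = None
    for tok, pos in tokens[idx:]:
        m = re.match(r"^([A-Za-z]+)-(.+)$", tok)
        if m and m.group(1).upper() in CATEGORY_BY_CODE:
            current = CATEGORY_BY_CODE[m.group(1).upper()].code
            _parse_groups(m.group(2), current, pos + m.end(1) + 1, involvements)
        elif current is not None:
            _parse_groups(tok, current, pos, involvements)
        else:
            raise ParseError("unknown_token", pos, f"unrecognized token {tok!r}")

    return ParsedClassification(
        rec_prefix=rec,
        residual=residual,
        tnm=tnm,
        involvements=frozenset(involvements.values()),
    )


def format_classification(parsed: ParsedClassification) -> str:
    """Emit the canonical spelling of a parsed classification.

    Canonical order: ``Rec`` prefix, residual code (if R1/R2), TNM, then one
    full token per subsite with categories in the order LT, B, N, PE, Vas, M
    and subsites in vocabulary order; no ``/`` compression; single spaces.
    A ``Rec`` classification never carries a TNM.
    """
    if parsed.rec_prefix and parsed.tnm is not None:
        raise ValueError("a Rec classification cannot carry a TNM category")
    for inv in parsed.involvements:
        violations = validate_involvement(inv)
        if violations:
            raise ValueError("; ".join(violations))
    keys = [inv.key for inv in parsed.involvements]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate subsite in involvement set")
    parts: list[str] = []
    if parsed.rec_prefix:
        parts.append("Rec")
    if parsed.residual is not ResidualCode.R0:
        parts.append(parsed.residual.value)
    if parsed.tnm is not None:
        parts.append(parsed.tnm.display())
    parts.extend(inv.token() for inv in sorted_involvements(parsed.involvements))
    return " ".join(parts)


def canonicalize(text: str) -> str:
    """Parse then format: normalize any accepted spelling to canonical form."""
    return format_classification(parse_classification(text))
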