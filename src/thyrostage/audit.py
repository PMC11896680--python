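"""Cohort audit: per-case staging accuracy, structure-omission tallies and
a first-principles two-tailed Fisher exact test.

The audit replays the staging engine over a cohort, compares each case's
reported classification with the recommendation, stratifies accuracy by
checklist use and surgeon, and tests the checklist/accuracy association on
the resulting 2x2 table.  Recurrent cases carry no AJCC category and are
summarized separately as missing-item reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .model import ChecklistRecord, DiseaseStatus, Involvement
from .notation import ParsedClassification, format_classification, parse_classification
from .staging import (
    DEFAULT_RULES,
    RuleTable,
    StagedResult,
    compare_stages,
    derive_stage,
)
from . import schema as _schema


# ---------------------------------------------------------------------------
# Fisher exact test (two-tailed, hypergeometric enumeration)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contingency2x2:
    """Counts with rows = checklist yes/no, columns = accurate/discrepant."""

    a: int  # checklist, accurate
    b: int  # checklist, discrepant
    c: int  # no checklist, accurate
    d: int  # no checklist, discrepant

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency grand total must be positive")


_TIE_TOLERANCE = 1e-7


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_two_tailed(table: Contingency2x2) -> float:
    """Exact two-tailed p for a 2x2 table by hypergeometric enumeration.

    With all margins fixed, every admissible table is indexed by its
    top-left count x; the two-tailed p is the sum of the probabilities of
    all tables no more probable than the observed one (a relative tolerance
    of 1e-7 counts ties), computed with log-factorials for overflow safety.
    A degenerate margin (an empty row or column) returns p = 1 by
    convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        return 1.0
    denom = _log_comb(n, c1)

    def log_p(x: int) -> float:
        return _log_comb(r1, x) + _log_comb(r2, c1 - x) - denom

    observed = log_p(a)
    cutoff = observed + math.log1p(_TIE_TOLERANCE)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    qualifying = [x for x in range(lo, hi + 1) if log_p(x) <= cutoff]
    if len(qualifying) == hi - lo + 1:
        return 1.0  # every admissible table qualifies; the sum is exactly 1
    return min(1.0, sum(math.exp(log_p(x)) for x in qualifying))


# ---------------------------------------------------------------------------
# Cohort cases and audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCase:
    """One audited case: the checklist record, what the final pathology
    report actually said, and the audit metadata."""

    record: ChecklistRecord
    reported: ParsedClassification | None
    checklist_submitted: bool
    surgeon: str = ""
    accuracy_override: bool = False
    annotations: dict = field(default_factory=dict)

    @property
    def is_primary(self) -> bool:
        return self.record.mds.disease_status is DiseaseStatus.PRIMARY


@dataclass(frozen=True)
class CaseVerdict:
    case_id: str
    surgeon: str
    checklist_submitted: bool
    verdict: str  # "accurate" | "discrepant" | "recurrent"
    codes: tuple[str, ...]
    staged: StagedResult


@dataclass(frozen=True)
class AuditReport:
    verdicts: tuple[CaseVerdict, ...]
    arm_counts: dict
    surgeon_counts: dict
    contingency: Contingency2x2 | None
    fisher_p: float | None
    recurrent_missing: dict

    def to_dict(self) -> dict:
        return {
            "verdicts": [
                {
                    "case_id": v.case_id,
                    "surgeon": v.surgeon,
                    "checklist_submitted": v.checklist_submitted,
                    "verdict": v.verdict,
                    "codes": list(v.codes),
                    "recommended_classification": v.staged.classification,
                }
                for v in self.verdicts
            ],
            "arm_counts": self.arm_counts,
            "surgeon_counts": self.surgeon_counts,
            "contingency": (
                None
                if self.contingency is None
                else {
                    "checklist_accurate": self.contingency.a,
                    "checklist_discrepant": self.contingency.b,
                    "no_checklist_accurate": self.contingency.c,
                    "no_checklist_discrepant": self.contingency.d,
                }
            ),
            "fisher_p": self.fisher_p,
            "recurrent_missing": self.recurrent_missing,
        }


def _missing_items(case: CohortCase, staged: StagedResult) -> list[str]:
    reported = case.reported.involvements if case.reported is not None else frozenset()
    reported_by_key = {inv.key: inv for inv in reported}
    out = []
    for inv in staged.anatomic_suffix:
        got = reported_by_key.get(inv.key)
        if got is None or got.degree != inv.degree:
            out.append(inv.token())
    return out


def audit_cohort(cases: list[CohortCase], rules: RuleTable = DEFAULT_RULES) -> AuditReport:
    """Audit a cohort: per-case verdicts plus stratified summary counts.

    Primary cases are accurate iff the accuracy override is set (used when a
    correctly worded operative report conveyed the finding) or the reported
    classification matches the engine recommendation; recurrent cases get no
    AJCC accuracy verdict and are summarized by their unreported items.  The
    checklist/accuracy 2x2 table and its Fisher p cover primary cases only.
    """
    if not cases:
        raise ValueError("cohort is empty")
    verdicts: list[CaseVerdict] = []
    arm = {
        "checklist": {"n": 0, "accurate": 0, "discrepant": 0},
        "no_checklist": {"n": 0, "accurate": 0, "discrepant": 0},
    }
    surgeons: dict[str, dict] = {}
    recurrent_missing: dict[str, list[str]] = {}
    for case in cases:
        staged = derive_stage(case.record, rules)
        if not case.is_primary:
            missing = _missing_items(case, staged)
            recurrent_missing[case.record.case_id] = missing
            verdicts.append(
                CaseVerdict(
                    case_id=case.record.case_id,
                    surgeon=case.surgeon,
                    checklist_submitted=case.checklist_submitted,
                    verdict="recurrent",
                    codes=tuple(f"missing_involvement:{t}" for t in missing),
                    staged=staged,
                )
            )
            continue
        cmp = compare_stages(case.reported, staged)
        accurate = case.accuracy_override or cmp.accurate
        verdict = "accurate" if accurate else "discrepant"
        codes = () if case.accuracy_override else cmp.codes
        verdicts.append(
            CaseVerdict(
                case_id=case.record.case_id,
                surgeon=case.surgeon,
                checklist_submitted=case.checklist_submitted,
                verdict=verdict,
                codes=codes,
                staged=staged,
            )
        )
        key = "checklist" if case.checklist_submitted else "no_checklist"
        arm[key]["n"] += 1
        arm[key][verdict] += 1
        s = surgeons.setdefault(
            case.surgeon,
            {
                "checklist": {"n": 0, "accurate": 0, "discrepant": 0},
                "no_checklist": {"n": 0, "accurate": 0, "discrepant": 0},
            },
        )
        s[key]["n"] += 1
        s[key][verdict] += 1

    contingency = None
    fisher_p = None
    if arm["checklist"]["n"] + arm["no_checklist"]["n"] > 0:
        contingency = Contingency2x2(
            a=arm["checklist"]["accurate"],
            b=arm["checklist"]["discrepant"],
            c=arm["no_checklist"]["accurate"],
            d=arm["no_checklist"]["discrepant"],
        )
        fisher_p = fisher_exact_two_tailed(contingency)
    return AuditReport(
        verdicts=tuple(verdicts),
        arm_counts=arm,
        surgeon_counts=surgeons,
        contingency=contingency,
        fisher_p=fisher_p,
        recurrent_missing=recurrent_missing,
    )


# ---------------------------------------------------------------------------
# Structure-omission tallies
# ---------------------------------------------------------------------------

STRUCTURE_CLASSES = (
    "SM",
    "CT",
    "SCM",
    "RLN_sacrifice",
    "RLN_epineurium",
    "PE",
    "LT",
    "B",
    "Vas",
    "SLN_Vag",
)


def structure_class(inv: Involvement) -> str:
    """Map an involvement to its tally class."""
    if inv.category == "M":
        return inv.subsite  # SM / SCM / CT
    if inv.category == "N":
        if inv.subsite == "RLN":
            return "RLN_sacrifice" if inv.degree == 1 else "RLN_epineurium"
        return "SLN_Vag"
    return inv.category  # PE / LT / B / Vas


def tally_missing_structures(
    cases: list[CohortCase],
    scope: str = "discrepant_no_checklist",
    rules: RuleTable = DEFAULT_RULES,
) -> dict:
    """Count, per structure class, the cases whose recommended classification
    contains the structure but whose reported classification does not.

    ``scope`` selects the audited subset: ``discrepant_no_checklist``
    (primary cases without a checklist whose verdict is discrepant — the
    understaged reports), ``recurrent``, or ``all``.  Counts are case-level
    (a case missing two pharyngoesophageal tokens counts once under ``PE``);
    the token-level pharyngoesophageal count is reported alongside as
    ``PE_tokens`` because the two conventions genuinely differ, and a
    ``nerve_sacrifice`` aggregate (any degree-1 nerve) is included for the
    recurrent summaries.
    """
    counts: dict[str, int] = {cls: 0 for cls in STRUCTURE_CLASSES}
    counts["PE_tokens"] = 0
    counts["nerve_sacrifice"] = 0
    for case in cases:
        staged = derive_stage(case.record, rules)
        if scope == "discrepant_no_checklist":
            if not case.is_primary or case.checklist_submitted:
                continue
            cmp = compare_stages(case.reported, staged)
            if case.accuracy_override or cmp.accurate:
                continue
        elif scope == "recurrent":
            if case.is_primary:
                continue
        elif scope != "all":
            raise ValueError(f"unknown scope {scope!r}")
        missing = []
        reported = case.reported.involvements if case.reported is not None else frozenset()
        reported_by_key = {inv.key: inv for inv in reported}
        for inv in staged.anatomic_suffix:
            got = reported_by_key.get(inv.key)
            if got is None or got.degree != inv.degree:
                missing.append(inv)
        classes = {structure_class(inv) for inv in missing}
        for cls in classes:
            counts[cls] += 1
        counts["PE_tokens"] += sum(1 for inv in missing if inv.category == "PE")
        if any(inv.category == "N" and inv.degree == 1 for inv in missing):
            counts["nerve_sacrifice"] += 1
    return counts


# ---------------------------------------------------------------------------
# Cohort CSV dialect
# ---------------------------------------------------------------------------

_CSV_COLUMNS = (
    "case_id",
    "surgeon",
    "checklist_submitted",
    "reported_classification",
    "recommended_inputs",
    "accuracy_override",
)


def cohort_to_frame(cases: list[CohortCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        reported = (
            format_classification(case.reported) if case.reported is not None else ""
        )
        rows.append(
            {
                "case_id": case.record.case_id,
                "surgeon": case.surgeon,
                "checklist_submitted": case.checklist_submitted,
                "reported_classification": reported,
                "recommended_inputs": json.dumps(
                    _schema.record_to_dict(case.record), sort_keys=True
                ),
                "accuracy_override": case.accuracy_override,
            }
        )
    return pd.DataFrame(rows, columns=list(_CSV_COLUMNS))


def write_cohort_csv(cases: list[CohortCase], path) -> None:
    cohort_to_frame(cases).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortCase]:
    df = pd.read_csv(path, dtype={"case_id": str}, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    cases = []
    for row in df.itertuples(index=False):
        record = _schema.record_from_dict(json.loads(row.recommended_inputs))
        reported_text = str(row.reported_classification).strip()
        reported = parse_classification(reported_text) if reported_text else None
        cases.append(
            CohortCase(
                record=record,
                reported=reported,
                checklist_submitted=_as_bool(row.checklist_submitted),
                surgeon=str(row.surgeon),
                accuracy_override=_as_bool(row.accuracy_override),
            )
        )
    return cases


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")
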