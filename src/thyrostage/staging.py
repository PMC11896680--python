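"""AJCC T-category floors, stage derivation and risk-of-recurrence tiers.

Intraoperative gross invasion raises the AJCC (8th edition) T category
irrespective of tumor size: gross strap-muscle invasion defines T3b;
invasion of the laryngotracheal complex, pharyngoesophagus, recurrent
laryngeal nerve or bone defines T4a; arterial encasement/transection defines
T4b.  The rule engine expresses these as *floors*: the recommended T is the
maximum of the size-based pathology T and the highest floor fired by any
recorded involvement.  Venous involvement carries no floor (a case with
isolated jugular/innominate vein resection stays at its size-based T);
subadventitial arterial dissection and superior-laryngeal/vagus involvement
fire review warnings instead of floors.  Recurrent or persistent disease is
never assigned an AJCC category: its classification is the ``Rec`` prefix
plus the anatomic suffix.

The default rule table can be exported to, and overridden from, a YAML file
so institutions can adjust floors without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .model import (
    ChecklistRecord,
    DiseaseStatus,
    Involvement,
    MCategory,
    NCategory,
    Ordering,
    Presence,
    ResidualCode,
    TCategory,
    TNMCategory,
    sorted_involvements,
    t_max,
    t_order,
    validate_record,
)
from .notation import ParsedClassification, format_classification


# ---------------------------------------------------------------------------
# Rule table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selector:
    """Predicate over involvements: category, optional subsite and degree sets."""

    category: str
    subsites: tuple[str, ...] | None = None
    degrees: tuple[int, ...] | None = None

    def matches(self, inv: Involvement) -> bool:
        if inv.category != self.category:
            return False
        if self.subsites is not None and inv.subsite not in self.subsites:
            return False
        if self.degrees is not None and inv.degree not in self.degrees:
            return False
        return True


@dataclass(frozen=True)
class TFloorRule:
    """One side-effect-free floor rule; at most one floor per rule."""

    id: str
    description: str
    selectors: tuple[Selector, ...]
    floor: TCategory | None = None
    warning: str | None = None

    def matches(self, inv: Involvement) -> bool:
        return any(sel.matches(inv) for sel in self.selectors)


@dataclass(frozen=True)
class RuleTable:
    rules: tuple[TFloorRule, ...]

    def t_floor(
        self, involvements
    ) -> tuple[TCategory | None, list[tuple[str, Involvement]], list[str]]:
        """Maximum floor over fired rules, with a full trace.

        Returns ``(floor or None, [(rule id, firing involvement), ...],
        warnings)``.  The trace lists every (rule, involvement) pair that
        fired, including no-floor rules, and is permutation-invariant in the
        input set because involvements are visited in canonical order.
        """
        floor: TCategory | None = None
        trace: list[tuple[str, Involvement]] = []
        warnings: list[str] = []
        for rule in self.rules:
            for inv in sorted_involvements(involvements):
                if rule.matches(inv):
                    trace.append((rule.id, inv))
                    if rule.floor is not None:
                        floor = t_max(floor, rule.floor)
                    if rule.warning is not None and rule.warning not in warnings:
                        warnings.append(rule.warning)
        return floor, trace, warnings

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "id": r.id,
                    "description": r.description,
                    "floor": r.floor.value if r.floor else None,
                    "warning": r.warning,
                    "match": [
                        {
                            "category": s.category,
                            **({"subsites": list(s.subsites)} if s.subsites else {}),
                            **({"degrees": list(s.degrees)} if s.degrees is not None else {}),
                        }
                        for s in r.selectors
                    ],
                }
                for r in self.rules
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RuleTable":
        rules = []
        for rd in data["rules"]:
            selectors = tuple(
                Selector(
                    category=sd["category"],
                    subsites=tuple(sd["subsites"]) if "subsites" in sd else None,
                    degrees=tuple(sd["degrees"]) if "degrees" in sd else None,
                )
                for sd in rd["match"]
            )
            rules.append(
                TFloorRule(
                    id=rd["id"],
                    description=rd.get("description", ""),
                    selectors=selectors,
                    floor=TCategory(rd["floor"]) if rd.get("floor") else None,
                    warning=rd.get("warning"),
                )
            )
        return cls(rules=tuple(rules))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RuleTable":
        return cls.from_dict(yaml.safe_load(text))


DEFAULT_RULES = RuleTable(
    rules=(
        TFloorRule(
            id="R1",
            description="gross muscle invasion (strap, SCM or cricothyroid) floors T3b",
            selectors=(Selector("M"),),
            floor=TCategory.T3B,
        ),
        TFloorRule(
            id="R2",
            description=(
                "laryngotracheal, pharyngoesophageal, recurrent-laryngeal-nerve "
                "or bone involvement (any degree) floors T4a"
            ),
            selectors=(
                Selector("LT"),
                Selector("PE"),
                Selector("B"),
                Selector("N", subsites=("RLN",)),
            ),
            floor=TCategory.T4A,
        ),
        TFloorRule(
            id="R3",
            description="arterial encasement/transection (carotid or innominate) floors T4b",
            selectors=(Selector("Vas", subsites=("A_CC", "A_INN"), degrees=(1,)),),
            floor=TCategory.T4B,
        ),
        TFloorRule(
            id="R4",
            description=(
                "subadventitial arterial dissection: no automatic floor, "
                "flagged for review"
            ),
            selectors=(Selector("Vas", subsites=("A_CC", "A_INN"), degrees=(0,)),),
            warning="arterial_involvement_review",
        ),
        TFloorRule(
            id="R5",
            description="venous involvement never modifies T",
            selectors=(Selector("Vas", subsites=("V_IJ", "V_INN")),),
        ),
        TFloorRule(
            id="R6",
            description="superior laryngeal / vagus nerve: outside the floor table, review",
            selectors=(Selector("N", subsites=("SLN", "Vag")),),
            warning="nerve_outside_rule_table",
        ),
    )
)


def t_floor(involvements, rules: RuleTable = DEFAULT_RULES):
    """Module-level convenience over :meth:`RuleTable.t_floor`."""
    return rules.t_floor(involvements)


# ---------------------------------------------------------------------------
# Stage derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StagedResult:
    """Engine output: recommended TNM (absent for recurrent disease),
    residual code, canonically ordered anatomic suffix, risk-of-recurrence
    tier, warnings and the floor-rule trace."""

    tnm: TNMCategory | None
    residual: ResidualCode
    anatomic_suffix: tuple[Involvement, ...]
    ror: str
    warnings: tuple[str, ...]
    rule_trace: tuple[tuple[str, Involvement], ...]
    classification: str = field(default="")


ROR_HIGH = "high"
ROR_LOW = "low"
ROR_NOT_APPLICABLE = "not_applicable"


def classify_ror(record: ChecklistRecord) -> tuple[str, list[str], list[str]]:
    """ATA risk-of-recurrence tier to the resolution the checklist feeds.

    Returns ``(tier, fired rule ids, warnings)``.  Any recorded gross
    invasion, an R1/R2 residual code, or known distant metastasis puts the
    case in the high tier.  When no high rule fires, the checklist alone
    cannot separate low from intermediate (that needs histologic vascular
    invasion, nodal burden and mutational data), so the tier degrades to
    ``low`` with a ``ror_incomplete_inputs`` warning.  Recurrent disease is
    ``not_applicable``.
    """
    if record.mds.disease_status is not DiseaseStatus.PRIMARY:
        return ROR_NOT_APPLICABLE, [], []
    fired: list[str] = []
    if record.involvements:
        fired.append("ror_high_gross_invasion")
    if record.mds.residual in (ResidualCode.R1, ResidualCode.R2):
        fired.append("ror_high_residual_disease")
    if record.mds.distant_mets is Presence.PRESENT:
        fired.append("ror_high_distant_metastasis")
    if fired:
        return ROR_HIGH, fired, []
    return ROR_LOW, [], ["ror_incomplete_inputs"]


def derive_stage(record: ChecklistRecord, rules: RuleTable = DEFAULT_RULES) -> StagedResult:
    """Derive the recommended stage and classification for one record.

    Primary disease: recommended T is the maximum of the size-based
    pathology T and the anatomic floor (pathology T absent -> the floor
    alone; both absent -> TX with a warning); N passes through; M passes
    through except that known distant metastasis forces M1.  Recurrent or
    persistent disease: no TNM, classification is ``Rec`` + suffix, ROR not
    applicable.
    """
    violations = validate_record(record)
    if violations:
        raise ValueError("invalid record: " + "; ".join(violations))

    floor, trace, warnings = rules.t_floor(record.involvements)
    suffix = sorted_involvements(record.involvements)
    ror, ror_trace, ror_warnings = classify_ror(record)
    warnings = list(warnings) + list(ror_warnings)
    residual = record.mds.residual

    if record.mds.disease_status is not DiseaseStatus.PRIMARY:
        if record.pathology_t is not None:
            warnings.append("ajcc_not_applicable_for_recurrent")
        parsed = ParsedClassification(
            rec_prefix=True,
            residual=residual,
            tnm=None,
            involvements=frozenset(suffix),
        )
        return StagedResult(
            tnm=None,
            residual=residual,
            anatomic_suffix=suffix,
            ror=ror,
            warnings=tuple(warnings),
            rule_trace=tuple(trace),
            classification=format_classification(parsed),
        )

    if record.pathology_t is None or record.pathology_t is TCategory.TX:
        t = floor if floor is not None else TCategory.TX
        if floor is None:
            warnings.append("t_category_unassessable")
    else:
        t = t_max(record.pathology_t, floor)
    n = record.pathology_n if record.pathology_n is not None else NCategory.NX
    if record.mds.distant_mets is Presence.PRESENT:
        m = MCategory.M1
    else:
        m = record.pathology_m if record.pathology_m is not None else MCategory.MX
    tnm = TNMCategory(t=t, n=n, m=m)
    parsed = ParsedClassification(
        rec_prefix=False, residual=residual, tnm=tnm, involvements=frozenset(suffix)
    )
    return StagedResult(
        tnm=tnm,
        residual=residual,
        anatomic_suffix=suffix,
        ror=ror,
        warnings=tuple(warnings),
        rule_trace=tuple(trace),
        classification=format_classification(parsed),
    )


# ---------------------------------------------------------------------------
# Reported-vs-recommended comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageComparison:
    accurate: bool
    codes: tuple[str, ...]


def compare_stages(
    reported: ParsedClassification | None, recommended: StagedResult
) -> StageComparison:
    """Compare a reported classification against the engine recommendation.

    Discrepant iff the reported T is below the recommended T, the reported
    string omits a recommended R1/R2 residual code, or the reported
    involvement set lacks a recommended involvement (subsite-level match; a
    degree mismatch is also discrepant).  A reported T *above* the
    recommendation is not an understaging discrepancy by itself (the
    in-scope failure mode is understaging), but such cases are typically
    caught through the missing residual/involvement codes.
    """
    codes: list[str] = []
    rep = reported if reported is not None else ParsedClassification()

    if recommended.tnm is not None:
        if rep.tnm is None:
            codes.append("t_unreported")
        elif t_order(rep.tnm.t, recommended.tnm.t) is Ordering.LESS:
            codes.append("t_understaged")
    if recommended.residual in (ResidualCode.R1, ResidualCode.R2):
        if rep.residual is not recommended.residual:
            codes.append(f"residual_unreported:{recommended.residual.value}")
    reported_by_key = {inv.key: inv for inv in rep.involvements}
    for inv in recommended.anatomic_suffix:
        got = reported_by_key.get(inv.key)
        if got is None:
            codes.append(f"missing_involvement:{inv.token()}")
        elif got.degree != inv.degree:
            codes.append(f"degree_mismatch:{inv.token()}")
    return StageComparison(accurate=not codes, codes=tuple(codes))
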