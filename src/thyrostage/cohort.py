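"""Packaged study cohort and seeded synthetic-cohort generation.

``load_paper_cohort`` returns the 35 consecutive grossly invasive cases of
the two-surgeon study (29 primary resections requiring AJCC staging, 6
recurrent) as fully structured :class:`~thyrostage.audit.CohortCase`
objects, rebuilt from the packaged classification strings.

``generate_cohort`` emulates the study's omission mechanism: each synthetic
case draws anatomic involvements by prevalence, derives its true
recommended stage through the rule engine, and then constructs the reported
classification — identical to the recommendation when a checklist is used,
or with each involvement independently dropped (and T re-derived from the
survivors) when it is not.  The defaults mirror the study cohort: subsite
prevalences and the checklist rate are the Table frequencies of the 29
primary cases, and the omission probability is high because essentially no
involved structure reached the final report without a checklist.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .audit import CohortCase
from .model import (
    ChecklistRecord,
    DiseaseStatus,
    MCategory,
    MinimumDataSet,
    NCategory,
    Presence,
    ResidualCode,
    TCategory,
    find_subsite,
    t_max,
    _T_RANK,
)
from .notation import ParsedClassification, TNMCategory, parse_classification
from .staging import DEFAULT_RULES, RuleTable, derive_stage


class FixtureCorruptionError(RuntimeError):
    """The packaged cohort file does not match its recorded checksum."""


def _data_text(name: str) -> str:
    return resources.files("thyrostage.data").joinpath(name).read_text()


def load_paper_cohort() -> list[CohortCase]:
    """Load the packaged 35-case study cohort (29 primary + 6 recurrent).

    The size-based pathology T of each primary case is reconstructed as the
    minimum of the printed reported T and the recommended T (the recommended
    classification proves the size-based T cannot exceed it, and where no
    anatomic floor bound the stage the two coincide).  For
    checklist-submitted cases the transmitted checklist accompanied the
    final report, so the effective reported classification equals the
    recommended one; the bare printed TNM is kept under
    ``annotations['reported_stage']``.
    """
    raw = _data_text("paper_cohort.json")
    digest = hashlib.sha256(raw.encode()).hexdigest()
    expected = _data_text("paper_cohort.sha256").strip()
    if digest != expected:
        raise FixtureCorruptionError(
            f"paper_cohort.json checksum mismatch: {digest} != {expected}"
        )
    data = json.loads(raw)
    cases: list[CohortCase] = []
    for entry in data["primary"]:
        recommended = parse_classification(entry["recommended"])
        reported_parsed = parse_classification(entry["reported_stage"])
        size_t = _ordered_min(reported_parsed.tnm.t, recommended.tnm.t)
        record = ChecklistRecord(
            case_id=str(entry["id"]),
            surgeon=entry["surgeon"],
            histology=entry["diagnosis"],
            mds=MinimumDataSet(
                distant_mets=(
                    Presence.PRESENT
                    if recommended.tnm.m is MCategory.M1
                    else Presence.UNKNOWN
                ),
                residual=recommended.residual,
                disease_status=DiseaseStatus.PRIMARY,
            ),
            involvements=recommended.involvements,
            pathology_t=size_t,
            pathology_n=recommended.tnm.n,
            pathology_m=recommended.tnm.m,
            checklist_submitted=entry["checklist"],
        )
        reported = (
            recommended if entry["checklist"] else reported_parsed
        )
        cases.append(
            CohortCase(
                record=record,
                reported=reported,
                checklist_submitted=entry["checklist"],
                surgeon=entry["surgeon"],
                accuracy_override=entry.get("accuracy_override", False),
                annotations={
                    "reported_stage": entry["reported_stage"],
                    "items_not_reported": entry["items_not_reported"],
                    "result": entry["result"],
                },
            )
        )
    for entry in data["recurrent"]:
        recommended = parse_classification(entry["recommended"])
        record = ChecklistRecord(
            case_id=str(entry["id"]),
            surgeon=entry["surgeon"],
            histology=entry["diagnosis"],
            mds=MinimumDataSet(
                residual=recommended.residual,
                disease_status=DiseaseStatus.RECURRENT,
            ),
            involvements=recommended.involvements,
            checklist_submitted=entry["checklist"],
        )
        cases.append(
            CohortCase(
                record=record,
                reported=None,
                checklist_submitted=entry["checklist"],
                surgeon=entry["surgeon"],
                annotations={"items_not_reported": entry["items_not_reported"]},
            )
        )
    return cases


def _ordered_min(a: TCategory, b: TCategory) -> TCategory:
    if a not in _T_RANK:
        return b
    if b not in _T_RANK:
        return a
    return min(a, b, key=_T_RANK.get)


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

# Subsite prevalences: Table frequencies over the 29 primary study cases.
_DEFAULT_PREVALENCE: dict[str, float] = {
    "LT-Th": 0.01,
    "LT-Cr": 1 / 29,
    "LT-T": 5 / 29,
    "B-Clav": 1 / 29,
    "B-St": 1 / 29,
    "N-RLN": 13 / 29,
    "N-SLN": 0.01,
    "N-Vag": 0.01,
    "PE-Ph": 6 / 29,
    "PE-E": 11 / 29,
    "Vas-A_CC": 0.01,
    "Vas-A_INN": 0.01,
    "Vas-V_IJ": 1 / 29,
    "Vas-V_INN": 1 / 29,
    "M-SM": 11 / 29,
    "M-SCM": 1 / 29,
    "M-CT": 4 / 29,
}

# Probability that an involved degree-taking structure required resection
# (degree 1) rather than a tissue-sparing plane; study-cohort frequencies,
# rounded (nerves were nearly always sacrificed; laryngotracheal and
# pharyngoesophageal resections were nearly always plane-sparing).
_DEFAULT_DEGREE1: dict[str, float] = {
    "LT": 0.05,
    "B": 0.5,
    "N": 0.9,
    "PE": 0.1,
    "Vas": 0.8,
}

# Size-based T distribution, a rounded fit to the no-checklist reported Ts.
_DEFAULT_SIZE_T: dict[str, float] = {
    "T1a": 0.1,
    "T1b": 0.2,
    "T2": 0.4,
    "T3a": 0.3,
}


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic cohort generator.

    ``prevalence`` maps subsite tokens (``"N-RLN"``) to the probability that
    a case involves the structure; ``p_omit`` maps the same keys to the
    probability that an involved structure is dropped from the reported
    classification when no checklist was submitted (a float applies to all
    structures); ``p_size_t`` is the distribution of the size-based T
    category.  Defaults reproduce the study conditions.
    """

    n_cases: int = 29
    seed: int = 0
    prevalence: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    p_checklist: float = 15 / 29
    p_omit: dict | float = 0.9
    p_size_t: dict = field(default_factory=lambda: dict(_DEFAULT_SIZE_T))

    def omit_probability(self, key: str) -> float:
        if isinstance(self.p_omit, dict):
            return float(self.p_omit.get(key, 0.0))
        return float(self.p_omit)

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        for key, p in self.prevalence.items():
            cat, _, sub = key.partition("-")
            if find_subsite(cat, sub) is None:
                raise ValueError(f"prevalence key {key!r} is not a known subsite")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{key!r}] outside [0, 1]")
        if not 0.0 <= self.p_checklist <= 1.0:
            raise ValueError("p_checklist outside [0, 1]")
        omit_values = (
            self.p_omit.values() if isinstance(self.p_omit, dict) else [self.p_omit]
        )
        if any(not 0.0 <= float(p) <= 1.0 for p in omit_values):
            raise ValueError("p_omit outside [0, 1]")
        total = sum(self.p_size_t.values())
        if not np.isclose(total, 1.0):
            raise ValueError("p_size_t probabilities must sum to 1")


def generate_cohort(params: SynthParams, rules: RuleTable = DEFAULT_RULES) -> list[CohortCase]:
    """Generate a reproducible synthetic cohort.

    Each case uses its own counter-derived substream of the seeded
    pseudo-random stream, so cohorts are order-independent and two calls
    with the same parameters are identical.  Omission acts on whole
    involvements: when a structure is dropped from a no-checklist report,
    the reported T is re-derived from the surviving set, reproducing the
    understaging mechanism.
    """
    params.validate()
    from .model import Involvement  # local import keeps module top uncluttered

    size_ts = sorted(params.p_size_t)
    size_ps = np.array([params.p_size_t[t] for t in size_ts])
    size_ps = size_ps / size_ps.sum()
    cases: list[CohortCase] = []
    for i in range(params.n_cases):
        rng = np.random.default_rng([params.seed, i])
        involvements = set()
        for key in sorted(params.prevalence):
            if rng.random() >= params.prevalence[key]:
                continue
            cat, _, sub = key.partition("-")
            subsite = find_subsite(cat, sub)
            degree = None
            rings = None
            if subsite.takes_degree:
                degree = int(rng.random() < _DEFAULT_DEGREE1[subsite.category])
            if subsite.takes_ring_count:
                rings = int(rng.integers(1, 4))
            involvements.add(
                Involvement(subsite.category, subsite.code, degree, rings)
            )
        size_t = TCategory(size_ts[int(rng.choice(len(size_ts), p=size_ps))])
        record = ChecklistRecord(
            case_id=f"S{i:05d}",
            surgeon="synthetic",
            histology="synthetic",
            mds=MinimumDataSet(disease_status=DiseaseStatus.PRIMARY),
            involvements=frozenset(involvements),
            pathology_t=size_t,
            pathology_n=NCategory.N0,
            pathology_m=MCategory.MX,
            checklist_submitted=False,
        )
        staged = derive_stage(record, rules)
        use_checklist = bool(rng.random() < params.p_checklist)
        if use_checklist:
            record = ChecklistRecord(
                **{**record.__dict__, "checklist_submitted": True}
            )
            reported = ParsedClassification(
                residual=record.mds.residual,
                tnm=staged.tnm,
                involvements=frozenset(staged.anatomic_suffix),
            )
        else:
            surviving = frozenset(
                inv
                for inv in sorted(involvements, key=lambda v: v.sort_key)
                if rng.random() >= params.omit_probability(f"{inv.category}-{inv.subsite}")
            )
            floor, _, _ = rules.t_floor(surviving)
            reported_t = t_max(size_t, floor)
            reported = ParsedClassification(
                residual=ResidualCode.R0,
                tnm=TNMCategory(reported_t, NCategory.N0, MCategory.MX),
                involvements=surviving,
            )
        cases.append(
            CohortCase(
                record=record,
                reported=reported,
                checklist_submitted=use_checklist,
                surgeon="synthetic",
            )
        )
    return cases


def expected_no_checklist_discrepancy(params: SynthParams) -> float:
    """Analytic per-case discrepancy probability in the no-checklist arm.

    A no-checklist case is discrepant iff at least one involvement is
    omitted (an omission always leaves a missing token, whether or not it
    moves T), so with independent structures the probability is
    ``1 - prod_s (1 - prevalence_s * p_omit_s)``.
    """
    p_accurate = 1.0
    for key, prev in params.prevalence.items():
        p_accurate *= 1.0 - prev * params.omit_probability(key)
    return 1.0 - p_accurate
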