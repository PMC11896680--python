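"""JSON interchange for checklist records.

Publishes the record schema (JSON-Schema draft 2020-12 document), converts
records to/from plain dicts, and performs structural validation of incoming
JSON with coded violation strings (the same convention as
:func:`thyrostage.model.validate_record`).
"""

from __future__ import annotations

from .model import (
    ChecklistRecord,
    DiseaseStatus,
    Involvement,
    MCategory,
    MinimumDataSet,
    NCategory,
    Presence,
    ResidualCode,
    TCategory,
    VocalCordFunction,
    sorted_involvements,
)

_T_VALUES = [t.value for t in TCategory]
_N_VALUES = [n.value for n in NCategory]
_M_VALUES = [m.value for m in MCategory]

RECORD_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "$id": "https://example.org/thyrostage/checklist-record.schema.json",
    "title": "ChecklistRecord",
    "type": "object",
    "required": ["case_id", "mds", "involvements"],
    "additionalProperties": False,
    "properties": {
        "case_id": {"type": "string"},
        "surgeon": {"type": "string"},
        "histology": {"type": "string"},
        "checklist_submitted": {"type": "boolean"},
        "pathology_t": {"enum": _T_VALUES + [None]},
        "pathology_n": {"enum": _N_VALUES + [None]},
        "pathology_m": {"enum": _M_VALUES + [None]},
        "mds": {
            "type": "object",
            "required": [
                "molecular_testing",
                "vocal_cord_function",
                "distant_mets",
                "residual",
                "disease_status",
            ],
            "additionalProperties": False,
            "properties": {
                "molecular_testing": {"type": "string"},
                "vocal_cord_function": {
                    "type": "object",
                    "required": ["right", "left"],
                    "additionalProperties": False,
                    "properties": {
                        "right": {"enum": [v.value for v in VocalCordFunction]},
                        "left": {"enum": [v.value for v in VocalCordFunction]},
                    },
                },
                "distant_mets": {"enum": [p.value for p in Presence]},
                "residual": {"enum": [r.value for r in ResidualCode]},
                "disease_status": {"enum": [d.value for d in DiseaseStatus]},
            },
        },
        "involvements": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["category", "subsite"],
                "additionalProperties": False,
                "properties": {
                    "category": {"enum": ["LT", "B", "N", "PE", "Vas", "M"]},
                    "subsite": {"type": "string"},
                    "degree": {"enum": [0, 1, None]},
                    "ring_count": {"type": ["integer", "null"], "minimum": 1},
                },
            },
        },
    },
}


def record_to_dict(record: ChecklistRecord) -> dict:
    return {
        "case_id": record.case_id,
        "surgeon": record.surgeon,
        "histology": record.histology,
        "checklist_submitted": record.checklist_submitted,
        "pathology_t": record.pathology_t.value if record.pathology_t else None,
        "pathology_n": record.pathology_n.value if record.pathology_n else None,
        "pathology_m": record.pathology_m.value if record.pathology_m else None,
        "mds": {
            "molecular_testing": record.mds.molecular_testing,
            "vocal_cord_function": {
                "right": record.mds.vocal_cord_right.value,
                "left": record.mds.vocal_cord_left.value,
            },
            "distant_mets": record.mds.distant_mets.value,
            "residual": record.mds.residual.value,
            "disease_status": record.mds.disease_status.value,
        },
        "involvements": [
            {
                "category": inv.category,
                "subsite": inv.subsite,
                "degree": inv.degree,
                "ring_count": inv.ring_count,
            }
            for inv in sorted_involvements(record.involvements)
        ],
    }


def record_from_dict(data: dict) -> ChecklistRecord:
    violations = validate_record_dict(data)
    if violations:
        raise ValueError("invalid record JSON: " + "; ".join(violations))
    mds_data = data["mds"]
    vcf = mds_data.get("vocal_cord_function", {})
    mds = MinimumDataSet(
        molecular_testing=mds_data.get("molecular_testing", "unknown"),
        vocal_cord_right=VocalCordFunction(vcf.get("right", "unknown")),
        vocal_cord_left=VocalCordFunction(vcf.get("left", "unknown")),
        distant_mets=Presence(mds_data.get("distant_mets", "unknown")),
        residual=ResidualCode(mds_data.get("residual", "R0")),
        disease_status=DiseaseStatus(mds_data.get("disease_status", "primary")),
    )
    involvements = frozenset(
        Involvement(
            category=i["category"],
            subsite=i["subsite"],
            degree=i.get("degree"),
            ring_count=i.get("ring_count"),
        )
        for i in data.get("involvements", [])
    )
    return ChecklistRecord(
        case_id=data["case_id"],
        surgeon=data.get("surgeon", ""),
        histology=data.get("histology", ""),
        mds=mds,
        involvements=involvements,
        pathology_t=TCategory(data["pathology_t"]) if data.get("pathology_t") else None,
        pathology_n=NCategory(data["pathology_n"]) if data.get("pathology_n") else None,
        pathology_m=MCategory(data["pathology_m"]) if data.get("pathology_m") else None,
        checklist_submitted=bool(data.get("checklist_submitted", False)),
    )


def validate_record_dict(data: dict) -> list[str]:
    """Structural validation of a record dict against the published schema.

    Minimal by design (types, required fields, enum membership); semantic
    invariants are checked by :func:`thyrostage.model.validate_record` after
    conversion.
    """
    out: list[str] = []
    if not isinstance(data, dict):
        return ["record_not_object"]
    if not isinstance(data.get("case_id"), str) or not data.get("case_id"):
        out.append("case_id_missing")
    mds = data.get("mds")
    if not isinstance(mds, dict):
        out.append("mds_missing")
        mds = {}
    for fld, enum_cls in (
        ("distant_mets", Presence),
        ("residual", ResidualCode),
        ("disease_status", DiseaseStatus),
    ):
        value = mds.get(fld)
        if value is not None and value not in {e.value for e in enum_cls}:
            out.append(f"mds_{fld}_invalid")
    vcf = mds.get("vocal_cord_function", {})
    if not isinstance(vcf, dict):
        out.append("mds_vocal_cord_function_invalid")
    else:
        for side in ("right", "left"):
            value = vcf.get(side)
            if value is not None and value not in {v.value for v in VocalCordFunction}:
                out.append(f"mds_vocal_cord_{side}_invalid")
    invs = data.get("involvements", [])
    if not isinstance(invs, list):
        out.append("involvements_not_array")
        invs = []
    for i, inv in enumerate(invs):
        if not isinstance(inv, dict) or "category" not in inv or "subsite" not in inv:
            out.append(f"involvement_{i}_malformed")
    for fld, values in (
        ("pathology_t", _T_VALUES),
        ("pathology_n", _N_VALUES),
        ("pathology_m", _M_VALUES),
    ):
        value = data.get(fld)
        if value is not None and value not in values:
            out.append(f"{fld}_invalid")
    return out
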