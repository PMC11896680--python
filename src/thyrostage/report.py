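"""Plain-text summary report for a staged checklist record.

The report mirrors the electronically generated checklist output a surgeon
forwards to the pathologist: the minimum data set, the intraoperative
findings with English glosses, the canonical classification string, and —
for primary disease — the AJCC category and ATA risk-of-recurrence tables.
ASCII-only so it can be pasted into an electronic health record; it carries
no patient identifiers beyond the opaque case id.
"""

from __future__ import annotations

from .model import (
    CATEGORY_BY_CODE,
    ChecklistRecord,
    DiseaseStatus,
    Involvement,
    find_subsite,
)
from .staging import StagedResult

_DEGREE0_VERB = {
    "LT": "subperichondrial dissection of the",
    "B": "subperiosteal dissection of the",
    "N": "epineural dissection of the",
    "PE": "resection of the muscularis of the",
    "Vas": "subadventitial dissection of the",
}

_DEGREE1_VERB = {
    "LT": "full-thickness resection of the",
    "B": "resection of the",
    "N": "sacrifice of the",
    "PE": "full-thickness resection of the",
    "Vas": "resection of the",
}


def gloss(inv: Involvement) -> str:
    """English gloss for one involvement, e.g. ``sacrifice of the recurrent
    laryngeal nerve`` for ``N-RLN^1``."""
    subsite = find_subsite(inv.category, inv.subsite)
    label = subsite.label if subsite is not None else inv.subsite
    if inv.category == "M":
        text = f"resection of the {label}"
    elif inv.degree == 1:
        text = f"{_DEGREE1_VERB[inv.category]} {label}"
    else:
        text = f"{_DEGREE0_VERB[inv.category]} {label}"
    if inv.ring_count is not None:
        rings = "ring" if inv.ring_count == 1 else "rings"
        text += f" ({inv.ring_count} tracheal {rings})"
    return text


def render_report(record: ChecklistRecord, staged: StagedResult) -> str:
    """Render the deterministic plain-text report for a staged record."""
    mds = record.mds
    lines: list[str] = []
    lines.append("GROSS EXTRATHYROIDAL/EXTRANODAL DISEASE CHECKLIST SUMMARY")
    lines.append(f"Case: {record.case_id}    Surgeon: {record.surgeon or '-'}")
    if record.histology:
        lines.append(f"Histology: {record.histology}")
    lines.append("")
    lines.append("== Minimum data set ==")
    lines.append(f"Disease status: {mds.disease_status.value}")
    lines.append(f"Molecular testing: {mds.molecular_testing}")
    lines.append(
        "Vocal cord function (right/left): "
        f"{mds.vocal_cord_right.value}/{mds.vocal_cord_left.value}"
    )
    lines.append(f"Distant metastasis: {mds.distant_mets.value}")
    lines.append(f"Residual disease: {mds.residual.value}")
    lines.append("")
    lines.append("== Intraoperative findings ==")
    if staged.anatomic_suffix:
        width = max(len(inv.token()) for inv in staged.anatomic_suffix)
        for inv in staged.anatomic_suffix:
            category = CATEGORY_BY_CODE[inv.category.upper()].label
            lines.append(f"{inv.token():<{width}}  {gloss(inv)} [{category}]")
    else:
        lines.append("No gross extrathyroidal or extranodal invasion recorded.")
    lines.append("")
    lines.append("== Anatomic classification ==")
    lines.append(staged.classification)
    lines.append("")
    if staged.tnm is not None:
        lines.append("== AJCC category (8th edition) ==")
        t, n, m = (
            staged.tnm.t.value,
            staged.tnm.n.value.replace("X", "x"),
            staged.tnm.m.value.replace("X", "x"),
        )
        lines.append(f"T: {t}   N: {n}   M: {m}   Residual: {staged.residual.value}")
        lines.append("")
    else:
        lines.append("== AJCC category ==")
        lines.append(
            "Not applicable: AJCC staging is not defined for "
            f"{mds.disease_status.value} surgical disease."
        )
        lines.append("")
    lines.append("== ATA risk of recurrence ==")
    lines.append(staged.ror.replace("_", " "))
    lines.append("")
    warnings = list(staged.warnings)
    if not staged.anatomic_suffix and record.mds.disease_status is DiseaseStatus.PRIMARY:
        warnings.append("no_gross_invasion_recorded")
    if warnings:
        lines.append("== Warnings ==")
        for w in warnings:
            lines.append(f"- {w}")
        lines.append("")
    return "\n".join(lines)
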