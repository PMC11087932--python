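"""WHO-CNS5-style composite interpretation of the marker table.

The engine encodes the CNV-level diagnostic logic for adult diffuse glioma:
a complete 1p/19q codeletion is the signature of oligodendroglioma; diffuse
gliomas without the codeletion (IDH-mutant or IDH-unknown) read as
astrocytoma; the +7/−10 signature or EGFR amplification in an IDH-wildtype
(or unknown) tumor supports the molecular diagnosis of glioblastoma; and a
homozygous CDKN2A/B deletion supports WHO grade 4 regardless of lineage.

CNV data alone cannot determine IDH status, so the clinical-context record
is advisory: rules degrade gracefully when it is absent, and every output
is phrased as CNV-consistent decision support, never a diagnosis. The rule
engine is total and deterministic over every combination of marker statuses
and IDH states; each suggestion cites the rules that fired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .marker_calls import (AMPLIFICATION, GAIN, HOMOZYGOUS_LOSS, INDETERMINATE,
                           LOSSES, MarkerTable, NEUTRAL)

OLIGODENDROGLIOMA = "oligodendroglioma"
ASTROCYTOMA = "astrocytoma"
GLIOBLASTOMA_MOLECULAR = "glioblastoma_molecular"
UNCLASSIFIED = "unclassified_by_cnv"

GRADE4_SUPPORTED = "grade_4_supported"
NO_GRADE4_EVIDENCE = "no_grade4_cnv_evidence"
GRADE_INDETERMINATE = "indeterminate"

IDH_STATES = ("mutant", "wildtype", "unknown")

DISCLAIMER = (
    "CNV-based decision support only: suggestions describe copy-number "
    "patterns consistent with WHO CNS5 entities and are not a diagnosis. "
    "Integrate with histology and sequence-level markers (IDH, ATRX, TERT)."
)


@dataclass
class ClinicalContext:
    """Optional sample metadata; all fields default to unknown/empty."""

    idh_status: str = "unknown"
    histology_note: str = ""
    sample_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.idh_status not in IDH_STATES:
            raise ValueError(f"idh_status must be one of {IDH_STATES}")


@dataclass
class ClassificationResult:
    suggestion: str
    grade_hint: str
    rules_fired: list
    disclaimer: str = DISCLAIMER

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def classify_glioma(table: MarkerTable,
                    context: ClinicalContext | None = None
                    ) -> ClassificationResult:
    """Apply the composite CNV rules to a marker table.

    Rule order: R1 codeletion → oligodendroglioma; R2 no codeletion +
    IDH mutant/unknown + any diffuse-glioma CNV evidence → astrocytoma;
    R3 (+7/−10 or EGFR amplification) + IDH wildtype/unknown →
    glioblastoma (molecular), overriding R2; R4 CDKN2A/B homozygous loss →
    grade-4 support, independent of lineage.
    """
    context = context or ClinicalContext()
    idh = context.idh_status
    rules: list[dict] = []

    cdkn = table.calls["CDKN2AB"].status
    egfr = table.calls["EGFR"].status
    codel = table.codeletion_1p19q
    p7m10 = table.plus7_minus10

    altered = [mid for mid in ("ARM_1P", "ARM_19Q", "CHR7", "CHR10")
               if table.calls[mid].status not in (NEUTRAL, INDETERMINATE)]
    any_evidence = (codel is True or p7m10 is True or cdkn in LOSSES or
                    egfr in (GAIN, AMPLIFICATION) or bool(altered))

    suggestion = UNCLASSIFIED
    if codel is True:
        rules.append({"id": "R1", "evidence":
                      "complete 1p/19q codeletion present"})
        suggestion = OLIGODENDROGLIOMA
    else:
        r3_fires = (p7m10 is True or egfr == AMPLIFICATION) and \
            idh in ("wildtype", "unknown")
        r2_fires = codel is False and idh in ("mutant", "unknown") and any_evidence
        if r2_fires:
            rules.append({"id": "R2", "evidence":
                          "no 1p/19q codeletion; diffuse-glioma CNV evidence "
                          f"present (IDH {idh})"})
            suggestion = ASTROCYTOMA
        if r3_fires:
            ev = []
            if p7m10 is True:
                ev.append("+7/-10 signature")
            if egfr == AMPLIFICATION:
                ev.append("EGFR amplification")
            note = " and ".join(ev) + f" (IDH {idh})"
            if r2_fires:
                note += "; overrides R2 astrocytoma reading"
            rules.append({"id": "R3", "evidence": note})
            suggestion = GLIOBLASTOMA_MOLECULAR
        if suggestion == UNCLASSIFIED:
            if codel is None and p7m10 is None:
                rules.append({"id": "R0", "evidence":
                              "composite markers indeterminate"})
            else:
                rules.append({"id": "R0", "evidence":
                              "no diagnostic CNV evidence"})

    if cdkn == HOMOZYGOUS_LOSS:
        rules.append({"id": "R4", "evidence":
                      "CDKN2A/B homozygous_loss supports WHO grade 4"})
        grade = GRADE4_SUPPORTED
    elif cdkn == INDETERMINATE:
        grade = GRADE_INDETERMINATE
    else:
        grade = NO_GRADE4_EVIDENCE

    return ClassificationResult(suggestion=suggestion, grade_hint=grade,
                                rules_fired=rules)
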