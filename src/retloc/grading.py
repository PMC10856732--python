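"""ICDR severity rules and the annotation/grade consistency audit.

The International Clinical Diabetic Retinopathy (ICDR) scale orders
severity as none < mild NPDR < moderate NPDR < severe NPDR < PDR, each
grade defined by the presence and extent of retinal features:

* PDR: any neovascularization (at the disc, NVD, or elsewhere, NVE);
* severe NPDR: IRMA, or venous beading in at least two quadrants (the
  "4-2-1" rule's 2-quadrant criterion);
* moderate NPDR: intraretinal hemorrhages, exudates, cotton wool spots,
  or venous beading in a single quadrant;
* mild NPDR: microaneurysms only;
* none: no features.

The full 4-2-1 rule also grants severe NPDR for extensive hemorrhages in
all four quadrants; presence flags alone cannot capture "extensive", so
an optional ``severe_hemorrhage_quadrants`` count is accepted and
hemorrhages otherwise cap at moderate.

:func:`min_consistent_grade` returns the least severe grade consistent
with a feature set; :func:`audit` flags images whose nominated grade is
below that minimum and raises them (audits only ever upgrade).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GRADE_ORDER",
    "grade_rank",
    "FeatureFindings",
    "GradeAudit",
    "min_consistent_grade",
    "audit",
]

#: ICDR grades from least to most severe.
GRADE_ORDER: tuple[str, ...] = ("none", "mild", "moderate", "severe", "pdr")

_GRADE_RANK = {g: i for i, g in enumerate(GRADE_ORDER)}


def grade_rank(grade: str) -> int:
    """Position of a grade in the severity order (0 = no retinopathy)."""
    try:
        return _GRADE_RANK[grade]
    except KeyError:
        raise ValueError(f"unknown ICDR grade {grade!r}") from None


@dataclass(frozen=True)
class FeatureFindings:
    """Presence flags (and venous-beading quadrant count) for one image."""

    microaneurysms: bool = False
    hemorrhages: bool = False
    exudates: bool = False
    cotton_wool_spots: bool = False
    irma: bool = False
    nvd: bool = False
    nve: bool = False
    vb_quadrants: int = 0
    severe_hemorrhage_quadrants: int = 0

    def __post_init__(self) -> None:
        for name in ("vb_quadrants", "severe_hemorrhage_quadrants"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3, 4):
                raise ValueError(f"{name} must be in 0..4, got {v}")


@dataclass(frozen=True)
class GradeAudit:
    """Outcome of checking one image's grade against its annotations."""

    image_id: str
    assigned_grade: str
    minimum_consistent_grade: str
    changed: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def effective_grade(self) -> str:
        """Post-audit grade: raised to the minimum consistent when needed."""
        return self.minimum_consistent_grade if self.changed else self.assigned_grade


def min_consistent_grade(f: FeatureFindings) -> str:
    """Least severe ICDR grade consistent with the findings."""
    if f.nvd or f.nve:
        return "pdr"
    if f.irma or f.vb_quadrants >= 2 or f.severe_hemorrhage_quadrants >= 4:
        return "severe"
    if f.hemorrhages or f.exudates or f.cotton_wool_spots or f.vb_quadrants == 1:
        return "moderate"
    if f.microaneurysms:
        return "mild"
    return "none"


def _reasons(f: FeatureFindings, minimum: str) -> list[str]:
    """Human-readable justification for the minimum grade."""
    out: list[str] = []
    if minimum == "pdr":
        if f.nvd:
            out.append("NVD present")
        if f.nve:
            out.append("NVE present")
    elif minimum == "severe":
        if f.irma:
            out.append("IRMA present")
        if f.vb_quadrants >= 2:
            out.append(f"Venous beading in {f.vb_quadrants} quadrants")
        if f.severe_hemorrhage_quadrants >= 4:
            out.append("Severe hemorrhages in four quadrants")
        if f.hemorrhages:
            out.append("Hemorrhages present")
    elif minimum == "moderate":
        if f.hemorrhages:
            out.append("Hemorrhages present")
        if f.exudates:
            out.append("Exudates present")
        if f.cotton_wool_spots:
            out.append("Cotton wool spots present")
        if f.vb_quadrants == 1:
            out.append("Venous beading in one quadrant")
    elif minimum == "mild":
        out.append("Microaneurysms present")
    return out


def audit(
    records: Iterable[tuple[str, str, FeatureFindings]]
) -> list[GradeAudit]:
    """Check nominated grades against annotations; flag and raise conflicts.

    Each record is ``(image_id, assigned_grade, findings)``.  A record is
    *changed* when the least grade consistent with its annotations is
    strictly more severe than the nominated grade; grades are never
    lowered (images may legitimately carry features below their grade's
    ceiling).  Ungraded images are passed through unchanged.
    """
    audits: list[GradeAudit] = []
    for image_id, assigned, findings in records:
        assigned = assigned.strip().lower()
        if assigned == "ungraded":
            minimum = min_consistent_grade(findings)
            audits.append(
                GradeAudit(image_id, assigned, minimum, changed=False, reasons=[])
            )
            continue
        rank = grade_rank(assigned)  # validates the vocabulary
        minimum = min_consistent_grade(findings)
        changed = grade_rank(minimum) > rank
        audits.append(
            GradeAudit(
                image_id=image_id,
                assigned_grade=assigned,
                minimum_consistent_grade=minimum,
                changed=changed,
                reasons=_reasons(findings, minimum) if changed else [],
            )
        )
    return audits
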