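"""Classical vs heterogeneous strain-pattern classification (Risum criteria).

A view fulfils the LBBB-related "classical" pattern when all three criteria
hold: (1) early contraction of a basal/mid segment of the early-activated
wall together with early stretching of the opposing wall; (2) the early peak
contraction within the first 70 % of the ejection phase; (3) peak contraction
of the stretching wall after aortic valve closure.  In component terms
criterion 1 is c1 AND c2, criterion 2 is c3, criterion 3 is c4.  A patient is
"classical" when at least one apical view fulfils all three, otherwise
"heterogeneous".

The source criteria name the septal/anteroseptal wall as the early-activated
wall; this is the anatomic early wall of the 4- and 3-chamber views.  The
2-chamber view has no septal wall, so its fixed early wall (anterior) is used
as the minimal consistent extension; set ``include_two_chamber=False`` to
restrict the classical label to the septum-bearing views.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import InputError, PatientRecord, VIEWS
from .scoring import ComponentVector, ScoringConfig, compute_rspi

CLASSICAL = "classical"
HETEROGENEOUS = "heterogeneous"


@dataclass(frozen=True)
class PatternResult:
    """Per-view criterion fulfilment and the binary pattern label."""

    per_view: dict[str, bool]
    label: str
    views_considered: tuple[str, ...]

    def __post_init__(self) -> None:
        fulfilled = any(self.per_view[v] for v in self.views_considered)
        if (self.label == CLASSICAL) != fulfilled:
            raise InputError("label inconsistent with per-view criteria")


def criteria_from_components(cv: ComponentVector) -> tuple[bool, bool, bool]:
    """Map a view's component bits onto the three classical-pattern criteria."""
    c1, c2, c3, c4 = cv.bits
    return (bool(c1 and c2), bool(c3), bool(c4))


def classify_pattern(patient: PatientRecord,
                     config: ScoringConfig = ScoringConfig(),
                     include_two_chamber: bool = True) -> PatternResult:
    """Label a patient classical or heterogeneous from the strain views."""
    result = compute_rspi(patient, config)
    considered = tuple(v for v in VIEWS
                       if include_two_chamber or v != "2CH")
    per_view = {
        view: all(criteria_from_components(result.per_view[view]))
        for view in VIEWS
    }
    label = CLASSICAL if any(per_view[v] for v in considered) else HETEROGENEOUS
    return PatternResult(per_view=per_view, label=label,
                         views_considered=considered)
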