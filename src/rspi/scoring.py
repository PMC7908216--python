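"""Regional Strain Pattern Index (RSPI) scoring.

Each apical view contributes up to four points, one per dyssynchrony
component of the LBBB-type contraction sequence:

1. *Early contraction* of the early-activated wall — a distinct shortening
   peak with a rebound during the ejection phase.
2. *Prestretch* of the opposing late-activated wall — early-systolic positive
   strain above threshold.
3. The early-wall peak contraction falls within the *first 70 %* of the
   systolic ejection phase (scored only when component 1 is present).
4. The late wall's *peak contraction occurs after aortic valve closure*.

Components are assessed per wall over its basal and mid segments
(existential: one qualifying segment sets the bit) and independently of each
other, so e.g. a view may score component 4 without component 2.  Summing
over the three apical views gives the 0–12 RSPI; scores at or above the
cutoff (default 7) define the high-RSPI class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import (
    InputError,
    PatientRecord,
    StrainTrace,
    ViewStrainSet,
    VIEWS,
    find_shortening_peak,
    find_stretch_max,
    global_peak_shortening_time,
)

_EPS = 1e-9

DEFAULT_CUTOFF = 7


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds operationalising the visual criteria of RSPI scoring.

    contraction_prominence
        Minimum two-sided prominence (% strain) for an "evident" early
        shortening peak.  The source criteria are visual; 2 % is a
        conservative default well above trace noise.
    prestretch_threshold
        Minimum positive strain (%) counting as prestretch.
    prestretch_window_fraction
        Fraction of the ejection phase in which prestretch is sought
        (early systole).
    early_fraction
        The fixed 0.70 fraction of the ejection phase for component 3.
    require_rebound
        If True (default) component 1 requires an interior local minimum
        with two-sided prominence; if False, a monotone shortening reaching
        the prominence depth also qualifies (its argmin supplies the peak
        time for component 3).
    late_peak_search_end_fraction
        How far past AVC, as a fraction of the ejection length, the
        late-wall global peak search extends.
    smoothing_ms
        Width of the moving-average filter applied to strain samples before
        detection, emulating the temporal filtering of speckle-tracking
        software; 0 disables.
    wall_assignment
        "anatomic" keeps the fixed early/late wall roles of the view;
        "data_driven" swaps the roles when the nominal late wall shows the
        earlier qualifying peak.
    """

    contraction_prominence: float = 2.0
    prestretch_threshold: float = 1.0
    prestretch_window_fraction: float = 0.5
    early_fraction: float = 0.70
    require_rebound: bool = True
    late_peak_search_end_fraction: float = 0.4
    smoothing_ms: float = 25.0
    wall_assignment: str = "anatomic"

    def __post_init__(self) -> None:
        for name in ("contraction_prominence", "prestretch_threshold",
                     "smoothing_ms"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if abs(self.early_fraction - 0.70) > 1e-12:
            raise InputError("early_fraction is fixed at 0.70")
        if not 0 < self.prestretch_window_fraction <= 1:
            raise InputError("prestretch_window_fraction must be in (0, 1]")
        if not 0 <= self.late_peak_search_end_fraction <= 1:
            raise InputError("late_peak_search_end_fraction must be in [0, 1]")
        if self.wall_assignment not in ("anatomic", "data_driven"):
            raise InputError("wall_assignment must be anatomic or data_driven")


@dataclass(frozen=True)
class ComponentVector:
    """The four component bits of one apical view (plus assessability)."""

    c1_early_contraction: int
    c2_prestretch: int
    c3_within_70pct: int
    c4_late_peak_after_avc: int
    view: str
    assessable: bool = True

    def __post_init__(self) -> None:
        for name in ("c1_early_contraction", "c2_prestretch",
                     "c3_within_70pct", "c4_late_peak_after_avc"):
            if getattr(self, name) not in (0, 1):
                raise InputError(f"{name} must be 0 or 1")
        if self.c3_within_70pct > self.c1_early_contraction:
            raise InputError("component 3 requires component 1")

    @property
    def bits(self) -> tuple[int, int, int, int]:
        return (self.c1_early_contraction, self.c2_prestretch,
                self.c3_within_70pct, self.c4_late_peak_after_avc)

    @property
    def points(self) -> int:
        return sum(self.bits)


@dataclass(frozen=True)
class RSPIResult:
    """Per-view component vectors, the 0–12 total and the cutoff class."""

    per_view: dict[str, ComponentVector]
    total: int
    high: bool
    cutoff: int = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        expected = sum(cv.points for cv in self.per_view.values())
        if self.total != expected or not 0 <= self.total <= 12:
            raise InputError("total must equal the sum of component bits")
        if self.high != (self.total >= self.cutoff):
            raise InputError("high flag inconsistent with cutoff")


def _smooth(trace: StrainTrace, smoothing_ms: float) -> StrainTrace:
    """Centered moving average over ~smoothing_ms, reflect-padded at the ends."""
    if smoothing_ms <= 0 or trace.times.size < 3:
        return trace
    dt = float(np.median(np.diff(trace.times)))
    half = int(round(smoothing_ms / (2.0 * dt)))
    if half < 1:
        return trace
    k = 2 * half + 1
    padded = np.pad(trace.values, half, mode="reflect")
    smoothed = np.convolve(padded, np.ones(k) / k, mode="valid")
    return replace(trace, values=smoothed)


def _early_peak_times(traces, avc, config: ScoringConfig) -> list[float]:
    """Qualifying early-contraction peak times over a wall's segments."""
    times = []
    for tr in traces:
        if config.require_rebound:
            pk = find_shortening_peak(tr, (0.0, avc),
                                      config.contraction_prominence)
            if pk is not None:
                times.append(pk.time)
        else:
            t, v = tr.window(0.0, avc)
            i = int(np.argmin(v))
            depth = float(np.max(v[:i + 1]) - v[i])
            if depth >= config.contraction_prominence - _EPS:
                times.append(float(t[i]))
    return times


def score_view(view_set: ViewStrainSet,
               config: ScoringConfig = ScoringConfig()) -> ComponentVector:
    """Assess the four RSPI components in one apical view.

    Returns a :class:`ComponentVector`; a view missing traces on either wall
    is returned all-zero with ``assessable=False`` (it contributes 0 points,
    consistent with the convention that absent contraction scores nothing).
    """
    if not view_set.early_wall or not view_set.late_wall:
        return ComponentVector(0, 0, 0, 0, view=view_set.view, assessable=False)

    timing = view_set.timing
    avc = timing.avc
    E = timing.ejection_time
    early = [_smooth(tr, config.smoothing_ms) for tr in view_set.early_wall]
    late = [_smooth(tr, config.smoothing_ms) for tr in view_set.late_wall]

    if config.wall_assignment == "data_driven":
        t_early = _early_peak_times(early, avc, config)
        t_late = _early_peak_times(late, avc, config)
        if t_late and (not t_early or min(t_late) < min(t_early)):
            early, late = late, early

    peak_times = _early_peak_times(early, avc, config)
    c1 = int(bool(peak_times))
    c3 = int(c1 and min(peak_times) <= config.early_fraction * E + _EPS)

    c2 = 0
    stretch_end = config.prestretch_window_fraction * E
    for tr in late:
        value, _ = find_stretch_max(tr, (0.0, stretch_end))
        if value >= config.prestretch_threshold - _EPS:
            c2 = 1
            break

    c4 = 0
    search_end = avc + config.late_peak_search_end_fraction * E
    for tr in late:
        t_peak = global_peak_shortening_time(tr, search_end)
        if t_peak > avc + _EPS:
            c4 = 1
            break

    return ComponentVector(c1, c2, c3, c4, view=view_set.view)


def compute_rspi(patient: PatientRecord,
                 config: ScoringConfig = ScoringConfig(),
                 cutoff: int = DEFAULT_CUTOFF) -> RSPIResult:
    """Sum the component bits over the three apical views into the RSPI.

    A missing view contributes 0 points and is flagged not assessable; a
    patient with no view at all is an error.
    """
    if not any(patient.views.get(v) is not None for v in VIEWS):
        raise InputError(f"patient {patient.id!r} has no assessable view")
    per_view: dict[str, ComponentVector] = {}
    for view in VIEWS:
        vs = patient.views.get(view)
        if vs is None:
            per_view[view] = ComponentVector(0, 0, 0, 0, view=view,
                                             assessable=False)
        else:
            per_view[view] = score_view(vs, config)
    total = sum(cv.points for cv in per_view.values())
    return RSPIResult(per_view=per_view, total=total,
                      high=classify_high_rspi(total, cutoff), cutoff=cutoff)


def classify_high_rspi(total: int, cutoff: int = DEFAULT_CUTOFF) -> bool:
    """True iff ``total >= cutoff`` (boundary inclusive)."""
    if not 0 <= total <= 12:
        raise InputError("RSPI total must be in 0..12")
    return total >= cutoff
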