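"""Comparison dyssynchrony indexes and the volumetric responder definition.

These are the classical timing-based dyssynchrony measures against which the
RSPI is benchmarked: atrioventricular (diastolic filling fraction of the
cycle), interventricular (aortic minus pulmonary pre-ejection delay) and
intraventricular measures derived from the 12 basal/mid time-to-peak
systolic velocities (per-view maximum delay, maximum time delay over all
segments, maximal opposing-wall delay, and the Yu index — the SD of the 12
times).  Response to resynchronization is a >=15 % reduction of LV
end-systolic volume at follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    CardiacTiming,
    InputError,
    PatientRecord,
    VelocityTrace,
    VIEWS,
    time_to_peak_velocity,
)

RESPONDER_THRESHOLD_PCT = 15.0


@dataclass(frozen=True)
class IndexPanel:
    """The full comparison-index panel of one patient."""

    lvdft_rr: float                       # % of cycle spent in LV filling
    ivmd: float                           # ms, signed
    view_max_delay: dict[str, float]      # ms per apical view
    max_time_delay: float                 # ms over all 12 segments
    opposing_wall_delay: float            # ms, level-matched wall pairs
    yu_index: float                       # ms
    septal_flash: int                     # expert-annotated input bit
    spwmd: Optional[float] = None         # ms, signed; None if unavailable


def lvdft_rr(timing: CardiacTiming) -> float:
    """LV diastolic filling time as a percentage of the RR interval."""
    return 100.0 * timing.lv_filling_time / timing.rr


def ivmd(timing: CardiacTiming) -> float:
    """Interventricular mechanical delay: aortic minus pulmonary pre-ejection (ms)."""
    return timing.aortic_preejection - timing.pulmonary_preejection


def spwmd(septal_motion, posterior_motion) -> Optional[float]:
    """Septal-to-posterior wall motion delay from M-mode style motion traces.

    Each trace is ``(times_ms, displacement)`` with inward motion positive;
    the delay is the posterior peak-inward time minus the septal one
    (negative when the posterior wall moves first).  A flat trace has no
    inward peak and yields ``None`` (not assessable).
    """
    t_peaks = []
    for times, values in (septal_motion, posterior_motion):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.size == 0 or t.shape != v.shape:
            raise InputError("motion trace times/values mismatch")
        if np.ptp(v) == 0:
            return None
        t_peaks.append(float(t[int(np.argmax(v))]))
    return t_peaks[1] - t_peaks[0]


def timing_panel(velocities: list[VelocityTrace],
                 timing: CardiacTiming,
                 ddof: int = 1) -> dict:
    """Intraventricular timing statistics from the 12 basal/mid velocity traces.

    Expects 4 traces per apical view (two walls x basal/mid).  Returns the
    per-view maximum delay, the overall maximum time delay, the maximal
    level-matched opposing-wall delay and the Yu index (SD of the 12
    time-to-peaks, sample SD by default).
    """
    if len(velocities) != 12:
        raise InputError(f"expected 12 velocity traces, got {len(velocities)}")
    by_view: dict[str, list[VelocityTrace]] = {v: [] for v in VIEWS}
    for tr in velocities:
        if tr.level not in ("basal", "mid"):
            raise InputError("timing panel uses basal and mid segments only")
        by_view[tr.view].append(tr)
    if any(len(trs) != 4 for trs in by_view.values()):
        counts = {v: len(trs) for v, trs in by_view.items()}
        raise InputError(f"expected 4 traces per view, got {counts}")

    ttp = {(tr.view, tr.wall, tr.level): time_to_peak_velocity(tr, timing)
           for tr in velocities}
    if len(ttp) != 12:
        raise InputError("duplicate (view, wall, level) among velocity traces")

    view_max_delay = {}
    opposing = 0.0
    for view, trs in by_view.items():
        times = [ttp[(view, tr.wall, tr.level)] for tr in trs]
        view_max_delay[view] = max(times) - min(times)
        walls = sorted({tr.wall for tr in trs})
        if len(walls) != 2:
            raise InputError(f"view {view} must hold two opposing walls")
        for level in ("basal", "mid"):
            a = ttp.get((view, walls[0], level))
            b = ttp.get((view, walls[1], level))
            if a is None or b is None:
                raise InputError(f"view {view} missing a {level} trace")
            opposing = max(opposing, abs(a - b))

    all_times = np.array(list(ttp.values()), dtype=float)
    return {
        "view_max_delay": view_max_delay,
        "max_time_delay": float(all_times.max() - all_times.min()),
        "opposing_wall_delay": float(opposing),
        "yu_index": float(np.std(all_times, ddof=ddof)),
    }


def classify_responder(lvesv_base: float,
                       lvesv_fu: float) -> tuple[bool, float]:
    """Volumetric CRT response: ``(responder, delta_lvesv_pct)``.

    ``delta_lvesv_pct`` is the percent reduction of end-systolic volume
    (negative when the ventricle dilated); responders reduce by >=15 %.
    """
    if not lvesv_base > 0:
        raise InputError("baseline LVESV must be positive")
    delta_pct = 100.0 * (lvesv_base - lvesv_fu) / lvesv_base
    return delta_pct >= RESPONDER_THRESHOLD_PCT, delta_pct


def compute_index_panel(patient: PatientRecord, ddof: int = 1) -> IndexPanel:
    """Assemble the comparison-index panel for one patient."""
    panel = timing_panel(list(patient.velocity_traces), patient.timing,
                         ddof=ddof) if len(patient.velocity_traces) == 12 \
        else {"view_max_delay": {v: float("nan") for v in VIEWS},
              "max_time_delay": float("nan"),
              "opposing_wall_delay": float("nan"),
              "yu_index": float("nan")}
    return IndexPanel(
        lvdft_rr=lvdft_rr(patient.timing),
        ivmd=ivmd(patient.timing),
        view_max_delay=panel["view_max_delay"],
        max_time_delay=panel["max_time_delay"],
        opposing_wall_delay=panel["opposing_wall_delay"],
        yu_index=panel["yu_index"],
        septal_flash=int(patient.septal_flash),
    )
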