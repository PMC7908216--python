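"""Domain types for segmental strain/velocity traces and curve primitives.

The time axis of every trace is milliseconds from QRS onset, the standard
reference point for speckle-tracking strain analysis.  Longitudinal strain is
expressed in percent with negative values meaning shortening (contraction),
positive values lengthening (stretch).  Every dyssynchrony index in this
package is built on the four primitives at the bottom of this module:
shortening-peak detection with two-sided prominence, stretch maximum,
time-to-peak systolic velocity, and global peak-shortening time.

Traces are treated as piecewise-linear samples; extrema are located on the
sample grid, without sub-sample interpolation, because the source data are
frame-rate limited.  All tie-breaks resolve to the earliest time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_prominences

VIEWS = ("4CH", "2CH", "3CH")
LEVELS = ("basal", "mid", "apical")

#: Anatomically early-activated wall per apical view (LBBB activation order).
EARLY_WALL = {"4CH": "septal", "2CH": "anterior", "3CH": "anteroseptal"}
#: Opposing, late-activated wall per apical view.
LATE_WALL = {"4CH": "lateral", "2CH": "inferior", "3CH": "posterior"}

_EPS = 1e-9


class InputError(ValueError):
    """Raised when an input violates a documented precondition."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InputError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class CardiacTiming:
    """Timing annotations of one beat, all in ms from QRS onset.

    ``avc`` is aortic valve closure; the systolic ejection phase is
    ``[qrs_onset, avc]`` and its length is :attr:`ejection_time`.
    """

    avc: float
    aortic_preejection: float
    pulmonary_preejection: float
    lv_filling_time: float
    rr: float
    qrs_onset: float = 0.0

    def __post_init__(self) -> None:
        if not self.avc > self.qrs_onset:
            raise InputError("avc must lie after QRS onset")
        for name in ("aortic_preejection", "pulmonary_preejection",
                     "lv_filling_time", "rr"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")
        if not self.lv_filling_time < self.rr:
            raise InputError("lv_filling_time must be shorter than RR")

    @property
    def ejection_time(self) -> float:
        return self.avc - self.qrs_onset


@dataclass(frozen=True)
class _Trace:
    times: np.ndarray
    values: np.ndarray
    view: str
    wall: str
    level: str
    segment_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.times.shape != self.values.shape:
            raise InputError(
                f"times/values length mismatch in segment {self.segment_id!r}")
        if not np.all(np.diff(self.times) > 0):
            raise InputError(
                f"times must be strictly increasing in segment {self.segment_id!r}")
        if self.view not in VIEWS:
            raise InputError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.level not in LEVELS:
            raise InputError(f"level must be one of {LEVELS}, got {self.level!r}")

    def window(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """Samples with ``t0 <= t <= t1``; errors if the window is unsupported."""
        if t1 < t0:
            raise InputError(f"empty window [{t0}, {t1}]")
        if t0 < self.times[0] - _EPS or t1 > self.times[-1] + _EPS:
            raise InputError(
                f"window [{t0}, {t1}] outside trace support "
                f"[{self.times[0]}, {self.times[-1]}] (segment {self.segment_id!r})")
        mask = (self.times >= t0 - _EPS) & (self.times <= t1 + _EPS)
        if not mask.any():
            raise InputError(f"window [{t0}, {t1}] contains no samples")
        return self.times[mask], self.values[mask]


@dataclass(frozen=True)
class StrainTrace(_Trace):
    """One segment's longitudinal strain curve (%, negative = shortening)."""


@dataclass(frozen=True)
class VelocityTrace(_Trace):
    """One segment's myocardial velocity curve (positive = systolic motion)."""


@dataclass(frozen=True)
class ViewStrainSet:
    """Basal/mid strain traces of one apical view, split by activation order.

    ``early_wall`` holds the early-activated wall (septal, anteroseptal or
    anterior depending on view), ``late_wall`` the opposing wall.
    """

    view: str
    early_wall: tuple[StrainTrace, ...]
    late_wall: tuple[StrainTrace, ...]
    timing: CardiacTiming

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise InputError(f"view must be one of {VIEWS}")
        object.__setattr__(self, "early_wall", tuple(self.early_wall))
        object.__setattr__(self, "late_wall", tuple(self.late_wall))
        for tr in self.early_wall + self.late_wall:
            if tr.view != self.view:
                raise InputError(
                    f"trace {tr.segment_id!r} tagged {tr.view}, expected {self.view}")
            if tr.level not in ("basal", "mid"):
                raise InputError("scoring uses basal and mid segments only")
        for wall in (self.early_wall, self.late_wall):
            if len(wall) > 2:
                raise InputError("at most one basal and one mid trace per wall")


@dataclass
class PatientRecord:
    """One patient: three view strain sets, optional velocities, clinical data."""

    id: str
    views: dict[str, Optional[ViewStrainSet]]
    timing: CardiacTiming
    lvesv_base: float
    lvesv_fu: float
    lvedv_base: float
    lvedv_fu: float
    lvef_base: float
    lvef_fu: float
    nyha_base: int
    nyha_fu: int
    septal_flash: bool = False
    qrs_ms: float = 150.0
    lbbb: bool = True
    upgrade: bool = False
    velocity_traces: tuple[VelocityTrace, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("lvesv_base", "lvesv_fu", "lvedv_base", "lvedv_fu"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")
        for name in ("lvef_base", "lvef_fu"):
            if not 0 < getattr(self, name) < 100:
                raise InputError(f"{name} must be in (0, 100)")
        for name in ("nyha_base", "nyha_fu"):
            if getattr(self, name) not in (1, 2, 3, 4):
                raise InputError(f"{name} must be in 1..4")
        unknown = set(self.views) - set(VIEWS)
        if unknown:
            raise InputError(f"unknown views {sorted(unknown)}")
        self.velocity_traces = tuple(self.velocity_traces)


@dataclass(frozen=True)
class Peak:
    """A detected shortening peak: its time, strain value and prominence."""

    time: float
    value: float
    prominence: float


def find_shortening_peak(trace: StrainTrace,
                         window: tuple[float, float],
                         min_prominence: float) -> Optional[Peak]:
    """Most negative interior shortening peak with two-sided prominence.

    Scans the samples inside ``window`` for local minima of strain and keeps
    those whose prominence (rise on both sides, or to the window edge) is at
    least ``min_prominence`` percent.  A minimum sitting exactly on a window
    edge never qualifies: the detector encodes a distinct early peak with a
    rebound, not end-systolic shortening.  Among qualifying peaks the most
    negative wins; ties resolve to the earliest.

    Returns ``None`` when no peak qualifies.
    """
    if min_prominence < 0:
        raise InputError("min_prominence must be >= 0")
    t, v = trace.window(*window)
    if t.size < 3:
        return None
    idx, _ = find_peaks(-v)
    if idx.size == 0:
        return None
    prom = peak_prominences(-v, idx)[0]
    keep = idx[prom >= min_prominence - _EPS]
    if keep.size == 0:
        return None
    best = keep[np.argmin(v[keep])]  # argmin keeps the earliest on ties
    best_prom = float(prom[np.flatnonzero(idx == best)[0]])
    return Peak(time=float(t[best]), value=float(v[best]), prominence=best_prom)


def find_stretch_max(trace: StrainTrace,
                     window: tuple[float, float]) -> tuple[float, float]:
    """``(value, time)`` of the most positive strain inside ``window``.

    On an all-negative trace this is simply the least negative sample; the
    caller applies any stretch threshold.  Ties resolve to the earliest time.
    """
    t, v = trace.window(*window)
    i = int(np.argmax(v))
    return float(v[i]), float(t[i])


def time_to_peak_velocity(trace: VelocityTrace, timing: CardiacTiming) -> float:
    """Time of maximum positive velocity within the ejection phase [0, AVC]."""
    t, v = trace.window(timing.qrs_onset, timing.avc)
    return float(t[int(np.argmax(v))])


def global_peak_shortening_time(trace: StrainTrace, search_end: float) -> float:
    """Time of the global strain minimum over ``[0, search_end]``.

    Unlike :func:`find_shortening_peak` this accepts a minimum at the window
    edge — it locates the overall peak contraction, which may fall after
    aortic valve closure in a late-activated wall.
    """
    t, v = trace.window(0.0, search_end)
    return float(t[int(np.argmin(v))])
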