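"""Synthetic strain/velocity waveforms and cohorts with known dyssynchrony.

No clinical strain recordings are distributed with this package, so every
module is exercised against synthetic beats whose dyssynchrony components
are prescribed exactly.  Waveforms are sums of Gaussian bumps on a uniform
5 ms grid spanning 1.5x the ejection phase: an early-activated wall either
contracts synchronously into end-systole or shows a distinct early
shortening peak with a rebound (placed inside or beyond 70 % of ejection to
toggle the timing component), while the opposing late-activated wall may be
prestretched in early systole and may reach its peak shortening after
aortic valve closure.  Additive white Gaussian noise with a fixed seed
models frame-to-frame measurement error.

Cohort generation assigns each synthetic patient a target RSPI total and a
responder label (with LV volumes drawn consistently with that label), either
with exact group counts — reproducing a prescribed 2x2 table without
sampling — or stochastically from group-specific score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    CardiacTiming,
    EARLY_WALL,
    InputError,
    LATE_WALL,
    PatientRecord,
    StrainTrace,
    VelocityTrace,
    ViewStrainSet,
    VIEWS,
)

#: Representative beat timing: 60 bpm, ejection 300 ms, IVMD 40 ms,
#: diastolic filling 40 % of the cycle.
DEFAULT_TIMING = CardiacTiming(avc=300.0, aortic_preejection=140.0,
                               pulmonary_preejection=100.0,
                               lv_filling_time=400.0, rr=1000.0)

PATTERN_BITS = {
    "classical": (1, 1, 1, 1),
    "heterogeneous": (1, 1, 0, 1),
    "synchronized": (0, 0, 0, 0),
}

#: Canonical component assignment used when a view must contribute a given
#: number of points (component 3 requires component 1 throughout).
BITS_FOR_POINTS = {
    0: (0, 0, 0, 0),
    1: (1, 0, 0, 0),
    2: (1, 0, 1, 0),
    3: (1, 1, 1, 0),
    4: (1, 1, 1, 1),
}


@dataclass(frozen=True)
class WaveformSpec:
    """Prescription for one view's pair of wall strain morphologies.

    ``components`` are the target bits (c1, c2, c3, c4).  The early peak is
    placed at ``early_peak_fraction`` of the ejection phase (default 0.45,
    or 0.75 when the spec demands a peak beyond the 70 % window); the late
    wall's peak shortening falls ``late_peak_delay`` ms after AVC when c4 is
    set.  ``early_feature_level``/``late_feature_level`` restrict the
    dyssynchronous morphology to one segment level, the other level
    receiving the synchronous shape.
    """

    components: tuple[int, int, int, int] = (1, 1, 1, 1)
    peak_strain: float = -15.0
    prestretch_amp: float = 3.0
    early_peak_fraction: Optional[float] = None
    late_peak_delay: float = 60.0
    noise_sd: float = 0.0
    seed: int = 0
    dt: float = 5.0
    timing: CardiacTiming = DEFAULT_TIMING
    early_feature_level: Optional[str] = None
    late_feature_level: Optional[str] = None

    def __post_init__(self) -> None:
        c1, c2, c3, c4 = self.components
        if any(b not in (0, 1) for b in self.components):
            raise InputError("components must be 0/1 bits")
        if c3 > c1:
            raise InputError("component 3 requires component 1 (c3 <= c1)")
        if not 0 < abs(self.peak_strain) <= 30:
            raise InputError("|peak_strain| must be in (0, 30] %")
        if not 0 <= self.prestretch_amp <= 30:
            raise InputError("prestretch_amp must be in [0, 30] %")
        if self.early_peak_fraction is not None and \
                not 0 < self.early_peak_fraction < 1.5:
            raise InputError("early_peak_fraction must be in (0, 1.5)")
        if self.noise_sd < 0 or self.dt <= 0:
            raise InputError("noise_sd must be >= 0 and dt > 0")
        for lv in (self.early_feature_level, self.late_feature_level):
            if lv not in (None, "basal", "mid"):
                raise InputError("feature level must be basal, mid or None")

    @classmethod
    def from_pattern(cls, pattern: str, **kwargs) -> "WaveformSpec":
        if pattern not in PATTERN_BITS:
            raise InputError(f"unknown pattern {pattern!r}")
        return cls(components=PATTERN_BITS[pattern], **kwargs)

    @property
    def resolved_early_peak_fraction(self) -> float:
        if self.early_peak_fraction is not None:
            return self.early_peak_fraction
        return 0.45 if self.components[2] else 0.75


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _time_grid(timing: CardiacTiming, dt: float) -> np.ndarray:
    E = timing.ejection_time
    return np.arange(0.0, 1.5 * E + dt / 2, dt)


def early_wall_values(t: np.ndarray, spec: WaveformSpec,
                      dyssynchronous: bool) -> np.ndarray:
    """Early-activated wall morphology.

    Dyssynchronous: a deep early shortening peak followed by a rebound and
    mild late-systolic stretch (the wall is pulled while the opposite wall
    contracts).  Synchronous: smooth shortening into a single end-systolic
    peak at AVC.
    """
    timing, E = spec.timing, spec.timing.ejection_time
    depth = 0.8 * abs(spec.peak_strain)
    if dyssynchronous:
        t_peak = spec.resolved_early_peak_fraction * E
        v = -depth * _gauss(t, t_peak, 0.10 * E)
        v += 2.0 * _gauss(t, timing.avc + 0.25 * E, 0.15 * E)
        return v
    return -abs(spec.peak_strain) * _gauss(t, timing.avc, 0.35 * E)


def late_wall_values(t: np.ndarray, spec: WaveformSpec,
                     prestretch: bool, late_peak: bool) -> np.ndarray:
    """Late-activated wall morphology: optional early-systolic prestretch
    bump and a main shortening peak either before or after AVC."""
    timing, E = spec.timing, spec.timing.ejection_time
    t_min = timing.avc + spec.late_peak_delay if late_peak else 0.85 * E
    v = -abs(spec.peak_strain) * _gauss(t, t_min, 0.25 * E)
    if prestretch:
        v += spec.prestretch_amp * _gauss(t, 0.20 * E, 0.10 * E)
    return v


def make_view(spec: WaveformSpec, view: str) -> ViewStrainSet:
    """Synthesize the basal+mid strain traces of one apical view."""
    if view not in VIEWS:
        raise InputError(f"view must be one of {VIEWS}")
    c1, c2, c3, c4 = spec.components
    t = _time_grid(spec.timing, spec.dt)
    rng = np.random.default_rng(spec.seed)

    def build(wall: str, level: str, values: np.ndarray) -> StrainTrace:
        noisy = values if spec.noise_sd == 0 else \
            values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        return StrainTrace(times=t.copy(), values=noisy, view=view,
                           wall=wall, level=level,
                           segment_id=f"{view}-{wall}-{level}")

    early, late = [], []
    for level, scale in (("basal", 1.0), ("mid", 0.95)):
        carries_early = bool(c1) and spec.early_feature_level in (None, level)
        v_early = scale * early_wall_values(t, spec, dyssynchronous=carries_early)
        early.append(build(EARLY_WALL[view], level, v_early))

        carries_late = spec.late_feature_level in (None, level)
        v_late = scale * late_wall_values(
            t, spec,
            prestretch=bool(c2) and carries_late,
            late_peak=bool(c4) and carries_late)
        late.append(build(LATE_WALL[view], level, v_late))

    return ViewStrainSet(view=view, early_wall=tuple(early),
                         late_wall=tuple(late), timing=spec.timing)


def distribute_points(total: int) -> dict[str, tuple[int, int, int, int]]:
    """Split an RSPI total of 0..12 into canonical per-view component bits."""
    if not 0 <= total <= 12:
        raise InputError("RSPI total must be in 0..12")
    out, remaining = {}, total
    for view in VIEWS:
        pts = min(4, remaining)
        out[view] = BITS_FOR_POINTS[pts]
        remaining -= pts
    return out


def make_patient(patient_id: str,
                 per_view_bits: dict[str, tuple[int, int, int, int]],
                 responder: bool,
                 delta_lvesv_pct: float,
                 seed: int = 0,
                 noise_sd: float = 0.0,
                 timing: CardiacTiming = DEFAULT_TIMING,
                 rng: Optional[np.random.Generator] = None) -> PatientRecord:
    """One synthetic patient with waveforms realizing the given bits and
    volumes consistent with the responder label."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    views = {}
    for i, view in enumerate(VIEWS):
        spec = WaveformSpec(components=per_view_bits[view],
                            noise_sd=noise_sd, timing=timing,
                            seed=int(rng.integers(0, 2**31 - 1)))
        views[view] = make_view(spec, view)

    lvesv_base = float(np.clip(rng.normal(218.0, 109.0), 80.0, 520.0))
    lvesv_fu = lvesv_base * (1.0 - delta_lvesv_pct / 100.0)
    lvef_base = float(np.clip(rng.normal(25.0, 6.0), 12.0, 45.0))
    lvef_fu = float(np.clip(
        lvef_base + (rng.normal(9.0, 3.0) if responder else rng.normal(0.0, 2.0)),
        12.0, 55.0))
    lvedv_base = lvesv_base / (1.0 - lvef_base / 100.0)
    lvedv_fu = lvesv_fu / (1.0 - lvef_fu / 100.0)
    nyha_base = int(rng.choice([2, 3, 4], p=[0.30, 0.65, 0.05]))
    nyha_fu = max(1, nyha_base - (1 if responder or rng.random() < 0.5 else 0))

    total_points = sum(sum(b) for b in per_view_bits.values())
    velocities = make_velocity_traces(
        timing, dyssynchrony_sd=20.0 + 8.0 * total_points, rng=rng)

    return PatientRecord(
        id=patient_id, views=views, timing=timing,
        lvesv_base=lvesv_base, lvesv_fu=lvesv_fu,
        lvedv_base=lvedv_base, lvedv_fu=lvedv_fu,
        lvef_base=lvef_base, lvef_fu=lvef_fu,
        nyha_base=nyha_base, nyha_fu=nyha_fu,
        septal_flash=bool(rng.random() < 0.31),
        qrs_ms=float(np.clip(rng.normal(173.0, 19.0), 140.0, 220.0)),
        lbbb=bool(rng.random() < 0.71),
        upgrade=bool(rng.random() < 0.41),
        velocity_traces=velocities,
    )


def make_velocity_traces(timing: CardiacTiming,
                         dyssynchrony_sd: float,
                         rng: np.random.Generator,
                         dt: float = 5.0) -> tuple[VelocityTrace, ...]:
    """Twelve basal/mid systolic velocity bumps with spread peak times."""
    t = _time_grid(timing, dt)
    E = timing.ejection_time
    traces = []
    for view in VIEWS:
        for wall in (EARLY_WALL[view], LATE_WALL[view]):
            for level in ("basal", "mid"):
                ttp = float(np.clip(rng.normal(0.5 * E, dyssynchrony_sd),
                                    0.1 * E, timing.avc - dt))
                ttp = round(ttp / dt) * dt  # land on the grid
                v = 6.0 * _gauss(t, ttp, 0.15 * E)
                traces.append(VelocityTrace(
                    times=t.copy(), values=v, view=view, wall=wall,
                    level=level, segment_id=f"{view}-{wall}-{level}-vel"))
    return tuple(traces)


@dataclass(frozen=True)
class CohortSpec:
    """Prescription for a synthetic cohort.

    With ``n_high_responders``/``n_high_nonresponders`` set, the cohort
    reproduces that exact responder x high-RSPI 2x2 (scores are assigned,
    not sampled).  Otherwise scores are drawn uniformly from
    ``responder_scores``/``nonresponder_scores``.
    """

    n_responders: int
    n_nonresponders: int
    n_high_responders: Optional[int] = None
    n_high_nonresponders: Optional[int] = None
    responder_scores: Sequence[int] = tuple(range(0, 13))
    nonresponder_scores: Sequence[int] = tuple(range(0, 10))
    cutoff: int = 7
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise InputError("group sizes must be non-negative")
        for n_high, n_group, name in (
                (self.n_high_responders, self.n_responders, "responders"),
                (self.n_high_nonresponders, self.n_nonresponders,
                 "non-responders")):
            if n_high is not None and not 0 <= n_high <= n_group:
                raise InputError(f"high-RSPI count exceeds {name} group size")


def make_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a synthetic cohort of patient records (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    high_pool = [s for s in range(7, 13)]
    low_pool = [s for s in range(0, spec.cutoff)]
    patients: list[PatientRecord] = []
    idx = 0
    for responder, n_group, n_high, pool in (
            (True, spec.n_responders, spec.n_high_responders,
             spec.responder_scores),
            (False, spec.n_nonresponders, spec.n_high_nonresponders,
             spec.nonresponder_scores)):
        for i in range(n_group):
            if n_high is not None:
                score_pool = high_pool if i < n_high else low_pool
                score = int(score_pool[int(rng.integers(len(score_pool)))])
            else:
                score = int(pool[int(rng.integers(len(pool)))])
            delta = float(rng.uniform(15.0, 72.0)) if responder \
                else float(rng.uniform(-22.0, 14.0))
            patients.append(make_patient(
                patient_id=f"P{idx:03d}",
                per_view_bits=distribute_points(score),
                responder=responder, delta_lvesv_pct=delta,
                noise_sd=spec.noise_sd, rng=rng))
            idx += 1
    return patients
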