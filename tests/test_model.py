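"""Curve primitives against exhaustive-scan oracles and edge rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rspi.model import (
    CardiacTiming,
    InputError,
    StrainTrace,
    VelocityTrace,
    find_shortening_peak,
    find_stretch_max,
    global_peak_shortening_time,
    time_to_peak_velocity,
)


def strain(times, values, **kw):
    kw.setdefault("view", "4CH")
    kw.setdefault("wall", "septal")
    kw.setdefault("level", "basal")
    kw.setdefault("segment_id", "test")
    return StrainTrace(times=np.asarray(times, float),
                       values=np.asarray(values, float), **kw)


def bump_trace(centers, depths, t_end=500.0, dt=5.0, width=30.0):
    """Sum of Gaussian dips — smooth curves where peak definitions agree."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.zeros_like(t)
    for c, d in zip(centers, depths):
        v -= d * np.exp(-0.5 * ((t - c) / width) ** 2)
    return strain(t, v)


def oracle_interior_minima(t, v):
    """Brute-force interior local minima with two-sided prominence."""
    out = []
    for i in range(1, len(v) - 1):
        if not (v[i] < v[i - 1] and v[i] < v[i + 1]):
            continue
        left = v[:i][::-1]
        right = v[i + 1:]
        rise_l = rise_r = 0.0
        for side, store in ((left, "l"), (right, "r")):
            best = -np.inf
            for x in side:
                if x < v[i]:
                    break
                best = max(best, x)
            rise = best - v[i] if np.isfinite(best) else 0.0
            if store == "l":
                rise_l = rise
            else:
                rise_r = rise
        out.append((t[i], v[i], min(rise_l, rise_r)))
    return out


class TestFindShorteningPeak:
    def test_monotone_ramp_has_no_interior_peak(self):
        t = np.arange(0.0, 301.0, 5.0)
        tr = strain(t, -15.0 * t / 300.0)
        assert find_shortening_peak(tr, (0, 300), 1.0) is None

    def test_flat_trace_has_no_peak(self):
        t = np.arange(0.0, 301.0, 5.0)
        assert find_shortening_peak(strain(t, np.zeros_like(t)), (0, 300), 0.0) is None

    def test_two_dip_curve_returns_deepest(self):
        # dips to -8% at t=100 (rebound to about -2%) and -10% at t=350
        tr = bump_trace([100.0, 350.0], [8.0, 10.0])
        pk = find_shortening_peak(tr, (0, 400), 1.0)
        assert pk is not None
        assert pk.time == pytest.approx(350.0, abs=5.0)
        assert pk.value == pytest.approx(-10.0, abs=0.1)

    def test_edge_minimum_never_counts(self):
        # single dip centered on the window edge
        tr = bump_trace([300.0], [12.0])
        assert find_shortening_peak(tr, (0, 300), 1.0) is None
        # but a wider window exposes it as interior
        assert find_shortening_peak(tr, (0, 400), 1.0) is not None

    def test_matches_bruteforce_on_random_smooth_curves(self, rng):
        for _ in range(200):
            k = rng.integers(1, 4)
            centers = rng.uniform(60, 440, size=k)
            depths = rng.uniform(2.5, 15, size=k)
            tr = bump_trace(centers, depths)
            thresh = float(rng.uniform(0.0, 3.0))
            pk = find_shortening_peak(tr, (0, 500), thresh)
            t, v = tr.window(0, 500)
            qual = [m for m in oracle_interior_minima(t, v)
                    if m[2] >= thresh - 1e-9]
            if pk is None:
                assert not qual
            else:
                best = min(qual, key=lambda m: (m[1], m[0]))
                assert pk.time == best[0] and pk.value == best[1]

    def test_raising_threshold_never_resurrects_a_peak(self, rng):
        for _ in range(50):
            tr = bump_trace(rng.uniform(50, 450, size=2),
                            rng.uniform(1, 10, size=2))
            lo = find_shortening_peak(tr, (0, 500), 1.0)
            hi = find_shortening_peak(tr, (0, 500), 4.0)
            if lo is None:
                assert hi is None

    def test_window_outside_support_is_an_error(self):
        tr = bump_trace([100.0], [5.0], t_end=300.0)
        with pytest.raises(InputError):
            find_shortening_peak(tr, (0, 400), 1.0)


class TestFindStretchMax:
    def test_all_negative_trace_returns_least_negative(self):
        tr = bump_trace([250.0], [10.0])
        value, _ = find_stretch_max(tr, (0, 500))
        assert value <= 0 and value == pytest.approx(tr.values.max())

    def test_positive_bump_located(self):
        t = np.arange(0.0, 301.0, 5.0)
        v = 3.0 * np.exp(-0.5 * ((t - 60.0) / 20.0) ** 2)
        value, time = find_stretch_max(strain(t, v), (0, 300))
        assert value == pytest.approx(3.0, abs=0.01)
        assert time == 60.0

    def test_constant_trace_ties_to_earliest(self):
        t = np.arange(0.0, 301.0, 5.0)
        value, time = find_stretch_max(strain(t, np.zeros_like(t)), (10, 300))
        assert (value, time) == (0.0, 10.0)


class TestTimeToPeakVelocity:
    timing = CardiacTiming(avc=300, aortic_preejection=140,
                           pulmonary_preejection=100, lv_filling_time=400,
                           rr=1000)

    def velocity(self, t, v):
        return VelocityTrace(times=t, values=v, view="4CH", wall="septal",
                             level="basal", segment_id="v")

    def test_single_bump(self):
        t = np.arange(0.0, 501.0, 5.0)
        v = np.exp(-0.5 * ((t - 120.0) / 30.0) ** 2)
        assert time_to_peak_velocity(self.velocity(t, v), self.timing) == 120.0

    def test_equal_bumps_tie_to_earliest(self):
        t = np.arange(0.0, 501.0, 5.0)
        v = (np.exp(-0.5 * ((t - 100.0) / 20.0) ** 2)
             + np.exp(-0.5 * ((t - 200.0) / 20.0) ** 2))
        assert time_to_peak_velocity(self.velocity(t, v), self.timing) == 100.0

    def test_matches_exhaustive_scan(self, rng):
        t = np.arange(0.0, 501.0, 5.0)
        for _ in range(100):
            v = rng.normal(size=t.shape)
            got = time_to_peak_velocity(self.velocity(t, v), self.timing)
            mask = t <= 300.0
            best_i = max(range(mask.sum()),
                         key=lambda i: (v[mask][i], -t[mask][i]))
            assert got == t[mask][best_i]

    def test_trace_not_covering_ejection_errors(self):
        t = np.arange(0.0, 201.0, 5.0)
        with pytest.raises(InputError):
            time_to_peak_velocity(self.velocity(t, np.ones_like(t)),
                                  self.timing)


class TestGlobalPeakShorteningTime:
    def test_post_avc_minimum(self):
        tr = bump_trace([380.0], [18.0])
        assert global_peak_shortening_time(tr, 500.0) == 380.0

    def test_plateau_ties_to_earliest(self):
        t = np.arange(0.0, 501.0, 5.0)
        v = np.where((t >= 250) & (t <= 300), -10.0, 0.0)
        assert global_peak_shortening_time(strain(t, v), 500.0) == 250.0

    def test_matches_exhaustive_scan(self, rng):
        t = np.arange(0.0, 501.0, 5.0)
        for _ in range(100):
            v = rng.normal(size=t.shape)
            got = global_peak_shortening_time(strain(t, v), 500.0)
            assert got == t[int(np.argmin(v))]

    def test_empty_window_errors(self):
        tr = bump_trace([100.0], [5.0])
        with pytest.raises(InputError):
            global_peak_shortening_time(tr, -10.0)


@given(st.integers(20, 100), st.integers(2, 5))
def test_resampling_finer_grid_moves_extrema_at_most_one_interval(center_i, factor):
    """Piecewise-linear refinement cannot move a sampled extremum further
    than one coarse sample interval."""
    dt = 5.0
    t = np.arange(0.0, 501.0, dt)
    v = -10.0 * np.exp(-0.5 * ((t - t[center_i]) / 30.0) ** 2)
    fine_t = np.arange(0.0, 500.0 + 1e-9, dt / factor)
    fine_v = np.interp(fine_t, t, v)
    coarse = global_peak_shortening_time(strain(t, v), 500.0)
    fine = global_peak_shortening_time(strain(fine_t, fine_v), 500.0)
    assert abs(coarse - fine) <= dt


def test_trace_validation_rejects_bad_times():
    with pytest.raises(InputError):
        strain([0.0, 10.0, 10.0], [0.0, -1.0, -2.0])
    with pytest.raises(InputError):
        strain([0.0, 10.0], [0.0, np.nan])


def test_timing_invariants():
    with pytest.raises(InputError):
        CardiacTiming(avc=-5, aortic_preejection=140,
                      pulmonary_preejection=100, lv_filling_time=400, rr=1000)
    with pytest.raises(InputError):
        CardiacTiming(avc=300, aortic_preejection=140,
                      pulmonary_preejection=100, lv_filling_time=1000, rr=1000)
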