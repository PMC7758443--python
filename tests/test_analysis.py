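"""Analysis suite: APD90, event detection, wave metrics, dyssynchrony, stats."""

import numpy as np
import pytest
from itertools import combinations

from mecsim.analysis import (
    EventThresholds,
    apd90,
    detect_events,
    dyssynchrony,
    group_stats,
    wave_amplitude,
    wave_velocity,
)
from mecsim.engine.run import SimulationResult


# ----------------------------------------------------------------------
# fixtures: synthetic trace containers
# ----------------------------------------------------------------------
def make_result(t, ca, vm, spacing=1.89, obs_start=0.0):
    """SimulationResult with a single synthetic cell."""
    n = ca.shape[1]
    pos = (np.arange(n) + 0.5) * spacing
    z = np.zeros_like(ca)
    return SimulationResult(
        time=np.asarray(t, dtype=float),
        traces={"Ca_cyto": ca, "Vm": vm, "Ca_SR": z, "Ca_SS": z, "SL": z, "force": z},
        vf=np.zeros((len(t), 0)),
        positions=pos,
        cell_bounds=[(0, n)],
        metadata={"observation_start": obs_start},
    )


def trapezoid_ap(dt=1.0):
    """Rest -85 mV, instant rise to +35, linear fall over 300 ms."""
    t = np.arange(0.0, 500.0, dt)
    vm = np.full_like(t, -85.0)
    k0 = 100
    vm[k0:] = 35.0
    fall = 120.0 / 300.0  # mV per ms
    for k in range(k0, t.size):
        vm[k] = max(35.0 - fall * (t[k] - t[k0]), -85.0)
    vm[k0] = 35.0
    return t, vm


# ----------------------------------------------------------------------
# APD90
# ----------------------------------------------------------------------
class TestApd90:
    def test_trapezoid_gives_270ms(self):
        t, vm = trapezoid_ap()
        apds = apd90(vm, t)
        assert apds.size == 1
        assert apds[0] == pytest.approx(270.0, abs=2.0)

    def test_offset_invariance(self):
        t, vm = trapezoid_ap()
        a = apd90(vm, t)
        b = apd90(vm + 5.0, t)
        assert a[0] == pytest.approx(b[0], abs=1e-9)

    def test_flat_trace_yields_no_aps(self):
        t = np.arange(0.0, 1000.0)
        assert apd90(np.full_like(t, -85.0), t).size == 0

    def test_refinement_invariance(self):
        t1, v1 = trapezoid_ap(dt=1.0)
        t2, v2 = trapezoid_ap(dt=0.5)
        a1 = apd90(v1, t1)[0]
        a2 = apd90(v2, t2)[0]
        assert abs(a1 - a2) / a1 < 0.01


# ----------------------------------------------------------------------
# wave velocity / amplitude
# ----------------------------------------------------------------------
class TestWaveVelocity:
    @pytest.mark.parametrize("speed", [50.0, 100.0, 1000.0, 5000.0])
    def test_recovers_synthetic_speeds(self, speed):
        n, spacing = 50, 1.89
        pos = (np.arange(n) + 0.5) * spacing
        at = pos / speed * 1000.0  # ms
        v, flag = wave_velocity(at, pos)
        assert flag == "propagating"
        assert v == pytest.approx(speed, rel=0.02)

    @pytest.mark.parametrize("speed", [50.0, 100.0, 1000.0, 5000.0])
    def test_robust_to_timing_noise(self, speed):
        rng = np.random.default_rng(1234)
        n, spacing = 50, 1.89
        pos = (np.arange(n) + 0.5) * spacing
        at = pos / speed * 1000.0
        # 10% of the total crossing time as gaussian jitter
        at = at + rng.normal(0.0, 0.1 * np.ptp(at) / n, n)
        v, _ = wave_velocity(at, pos)
        assert v == pytest.approx(speed, rel=0.02)

    def test_direction_invariance(self):
        pos = (np.arange(20) + 0.5) * 2.0
        at = pos / 100.0 * 1000.0
        v_fwd, _ = wave_velocity(at, pos)
        v_bwd, _ = wave_velocity(at[::-1], pos)
        assert v_fwd == pytest.approx(v_bwd)

    def test_simultaneous_flagged_synchronous(self):
        pos = (np.arange(10) + 0.5) * 1.89
        v, flag = wave_velocity(np.full(10, 1000.0), pos)
        assert flag == "synchronous" and np.isnan(v)

    def test_too_few_activations_non_propagating(self):
        at = np.full(10, np.nan)
        at[3] = 100.0
        v, flag = wave_velocity(at, np.arange(10.0))
        assert flag == "non_propagating" and np.isnan(v)


class TestWaveAmplitude:
    def test_flat_traces_zero(self):
        assert wave_amplitude(np.full(5, 1e-4), np.full(5, 1e-4)) == 0.0

    def test_known_peak_recovered_in_micromolar(self):
        dia = np.full(5, 1e-4)
        peak = dia.copy()
        peak[2] += 5e-4  # +0.5 uM in one CRU
        assert wave_amplitude(peak, dia) == pytest.approx(0.5)

    def test_invariant_to_common_offset(self):
        dia = np.full(5, 1e-4)
        peak = dia + 3e-4
        assert wave_amplitude(peak + 1e-3, dia + 1e-3) == pytest.approx(
            wave_amplitude(peak, dia)
        )


# ----------------------------------------------------------------------
# detect_events on constructed fixtures
# ----------------------------------------------------------------------
class TestDetectEvents:
    def test_quiescent_decay_yields_no_events(self):
        t = np.arange(0.0, 3000.0, 0.5)
        n = 20
        decay = 1e-4 + 4e-4 * np.exp(-t / 300.0)
        ca = np.tile(decay[:, None], (1, n))
        vm = np.full_like(ca, -85.0)
        assert detect_events(make_result(t, ca, vm)) == []

    def test_translating_pulse_detected_as_slow_wave(self):
        """A gaussian calcium pulse moving at 100 um/s with no membrane
        response is one slow, propagating, electrically silent event."""
        t = np.arange(0.0, 2500.0, 0.5)
        n, spacing, speed = 30, 1.89, 100.0  # um, um/s
        pos = (np.arange(n) + 0.5) * spacing
        ca = np.full((t.size, n), 1e-4)
        for i in range(n):
            t_arr = 500.0 + pos[i] / speed * 1000.0
            ca[:, i] += 8e-4 * np.exp(-((t - t_arr) / 40.0) ** 2)
        vm = np.full_like(ca, -85.0)
        events = detect_events(make_result(t, ca, vm))
        assert len(events) == 1
        ev = events[0]
        assert ev.wave_class == "slow"
        assert ev.event_class == "none"
        assert ev.velocity == pytest.approx(speed, rel=0.05)
        assert ev.amplitude == pytest.approx(0.8, rel=0.05)
        assert ev.n_activated == n

    def test_whole_cell_release_with_ap_is_triggered_beat(self):
        t = np.arange(0.0, 2000.0, 0.5)
        n = 20
        ca = np.full((t.size, n), 1e-4)
        vm = np.full_like(ca, -85.0)
        burst = 1e-3 * np.exp(-((t - 800.0) / 60.0) ** 2)
        ca += burst[:, None]
        ap = np.where((t > 805) & (t < 1000), 20.0, -85.0)  # regenerative AP
        vm[:] = ap[:, None]
        events = detect_events(make_result(t, ca, vm))
        assert len(events) == 1
        assert events[0].event_class == "triggered_beat"
        assert events[0].wave_class == "synchronous"

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            EventThresholds(ca_event=0.0)


# ----------------------------------------------------------------------
# dyssynchrony
# ----------------------------------------------------------------------
class TestDyssynchrony:
    def test_identical_cells_zero(self):
        assert dyssynchrony([10.0, 10.0, 10.0]) == 0.0

    def test_hand_computed_sample_std(self):
        assert dyssynchrony([10.0, 20.0, 30.0]) == pytest.approx(10.0)

    def test_permutation_invariance(self):
        a = dyssynchrony([5.0, 17.0, 11.0, 2.0])
        b = dyssynchrony([17.0, 2.0, 5.0, 11.0])
        assert a == pytest.approx(b)

    def test_per_cru_arrays_are_averaged_first(self):
        cells = [np.array([8.0, 12.0]), np.array([19.0, 21.0]), np.array([30.0, 30.0])]
        assert dyssynchrony(cells) == pytest.approx(10.0)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            dyssynchrony([10.0])


# ----------------------------------------------------------------------
# group statistics
# ----------------------------------------------------------------------
class TestGroupStats:
    def test_identical_groups_not_significant(self):
        g = [1.0, 1.1, 0.9, 1.05]
        rep = group_stats([g, list(g)])
        assert all(row[3] > 0.1 for row in rep.pairwise)

    def test_far_outlier_removed_by_three_sigma_rule(self):
        rng = np.random.default_rng(2)
        clean = rng.normal(10.0, 0.2, 24)
        g = np.concatenate([clean, [10.0 + 4.0 * 1.0]])  # ~4 sigma of the pooled spread
        rep = group_stats([g, clean + 0.05], labels=["a", "b"])
        assert rep.outliers_removed["a"] == [24]
        assert rep.outliers_removed["b"] == []

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.01, 6)
        b = rng.normal(10.0, 0.01, 6)
        rep = group_stats([a, b])
        _, _, _, p_adj, tier = rep.pairwise[0]
        assert p_adj < 0.01 and tier == "***"

    def test_bonferroni_equals_m_times_raw(self):
        """Adjusted p = min(1, m * p_raw) for all m pairwise tests, checked
        against a brute-force recomputation with scipy on the raw groups."""
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        groups = [rng.normal(loc, 1.0, 8) for loc in (0.0, 0.4, 1.0, 5.0)]
        rep = group_stats(groups)
        m = len(list(combinations(range(4), 2)))
        for (i, j), row in zip(combinations(range(4), 2), rep.pairwise):
            p_raw = sps.ttest_ind(groups[i], groups[j]).pvalue
            assert row[2] == pytest.approx(p_raw)
            assert row[3] == pytest.approx(min(1.0, m * p_raw))
            assert row[3] >= row[2]

    def test_significance_tiers(self):
        from mecsim.analysis import _tier

        assert _tier(0.005) == "***"
        assert _tier(0.03) == "**"
        assert _tier(0.07) == "*"
        assert _tier(0.5) == ""

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            group_stats([[1.0], [2.0, 3.0]])
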