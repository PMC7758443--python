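"""Measurement machinery: APD90, spontaneous-event detection and
classification, calcium-wave velocity and amplitude, inter-cellular
dyssynchrony, and group statistics.

Spontaneous events are scored in the quiescent observation window after
pacing and stretching stop.  A spontaneous event is a cytosolic-calcium
excursion above the per-CRU diastolic baseline by more than a threshold
(default 0.05 uM) in at least one CRU; the per-CRU activation time is the
crossing of 50% of that CRU's event amplitude.  The event's class is read
off the simultaneous membrane-potential trace: no deflection beyond
threshold -> "none"; a deflection without a regenerative upstroke ->
subthreshold DAD; a regenerative upstroke that stays below 0 mV ->
suprathreshold DAD; a full overshooting action potential -> triggered beat.
Propagating events are co-classified fast/slow by a velocity cutoff
(default 1000 um/s, between the slow ~100 um/s diffusion-limited waves and
the ~4000+ um/s electrotonically driven fast waves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "EventThresholds",
    "WaveEvent",
    "StatsReport",
    "apd90",
    "detect_events",
    "wave_velocity",
    "wave_amplitude",
    "dyssynchrony",
    "dyssynchrony_from_result",
    "dyssynchrony_across_results",
    "cell_mean_ttp",
    "group_stats",
    "events_table",
]


# ----------------------------------------------------------------------
# action potential duration
# ----------------------------------------------------------------------
def apd90(
    vm_trace,
    time,
    dvdt_threshold: float = 5.0,
    min_separation: float = 80.0,
    repol_frac: float = 0.9,
):
    """APD90 (ms) of every action potential in a voltage trace.

    An upstroke is a crossing of ``dvdt_threshold`` (mV/ms); each AP is
    measured from its maximum-upstroke time to ``repol_frac`` (90%)
    repolarization toward the pre-upstroke diastolic potential, with linear
    interpolation at the crossing.  A trace with no AP returns an empty
    array (not an error); the measure is invariant to a constant offset.
    """
    vm = np.asarray(vm_trace, dtype=float)
    t = np.asarray(time, dtype=float)
    if vm.size < 3:
        return np.array([])
    dvdt = np.diff(vm) / np.diff(t)
    above = dvdt > dvdt_threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    # merge onsets closer than min_separation
    keep = []
    for i in onsets:
        if not keep or t[i] - t[keep[-1]] >= min_separation:
            keep.append(i)
    out = []
    for n, i in enumerate(keep):
        j_end = keep[n + 1] if n + 1 < len(keep) else len(vm) - 1
        # maximum-upstroke sample within this AP's rising phase
        hi = max(i + 1, min(i + 50, j_end))
        k_up = i + int(np.argmax(dvdt[i:hi]))
        v_dia = vm[max(i - 1, 0)]
        v_peak = vm[i : j_end + 1].max()
        v90 = v_peak - repol_frac * (v_peak - v_dia)
        k_peak = i + int(np.argmax(vm[i : j_end + 1]))
        below = np.flatnonzero(vm[k_peak : j_end + 1] <= v90)
        if below.size == 0:
            continue  # never repolarized within the record
        k = k_peak + below[0]
        if k == 0 or vm[k] == vm[k - 1]:
            t90 = t[k]
        else:
            t90 = t[k - 1] + (v90 - vm[k - 1]) * (t[k] - t[k - 1]) / (vm[k] - vm[k - 1])
        out.append(t90 - t[k_up])
    return np.asarray(out)


# ----------------------------------------------------------------------
# spontaneous events
# ----------------------------------------------------------------------
@dataclass
class EventThresholds:
    """Detection and classification thresholds (all configurable)."""

    ca_event: float = 5.0e-5        # mM above diastolic (0.05 uM)
    activation_frac: float = 0.5    # fraction of local amplitude
    vm_deflection: float = 5.0      # mV above pre-event baseline
    dvdt_regenerative: float = 5.0  # mV/ms for a regenerative upstroke
    fast_wave_cutoff: float = 1000.0  # um/s
    merge_gap: float = 50.0         # ms between excursions of one event

    def __post_init__(self) -> None:
        for k in ("ca_event", "activation_frac", "vm_deflection",
                  "dvdt_regenerative", "fast_wave_cutoff"):
            if getattr(self, k) <= 0:
                raise ValueError(f"threshold {k} must be positive")


@dataclass
class WaveEvent:
    """A detected spontaneous calcium release event in one cell."""

    cell: int
    onset: float                      # ms
    t_end: float
    activation_times: np.ndarray      # (n_cru,) ms, NaN where not activated
    amplitude: float                  # uM, max over CRUs above diastolic
    velocity: float                   # um/s (NaN if not propagating)
    event_class: str                  # none | subthreshold_dad | suprathreshold_dad | triggered_beat
    wave_class: str                   # slow | fast | synchronous | non_propagating
    order: str = "first"              # first | subsequent
    peak_vm: float = np.nan
    max_dvdt: float = np.nan
    n_activated: int = 0


def wave_velocity(activation_times, positions, min_active: int = 3, min_spread: float = 1.0):
    """Propagation speed (um/s): |slope| of position vs activation time.

    ``activation_times`` in ms (NaN = not activated), ``positions`` in um.
    Returns ``(velocity, flag)`` with flag one of "propagating",
    "synchronous" (activation-time spread below ``min_spread`` ms — no
    resolvable finite velocity) or "non_propagating" (fewer than
    ``min_active`` activations).
    """
    at = np.asarray(activation_times, dtype=float)
    x = np.asarray(positions, dtype=float)
    ok = np.isfinite(at)
    if ok.sum() < min_active:
        return np.nan, "non_propagating"
    t = at[ok]
    if np.ptp(t) < min_spread:
        return np.nan, "synchronous"
    slope = np.polyfit(t, x[ok], 1)[0]  # um/ms
    return abs(slope) * 1000.0, "propagating"


def wave_amplitude(peak_ca, diastolic_ca):
    """Max over CRUs of (peak - diastolic) cytosolic calcium, in uM."""
    d = np.asarray(peak_ca, dtype=float) - np.asarray(diastolic_ca, dtype=float)
    return float(np.max(d)) * 1000.0


def _classify_vm(vm_win, t_win, thresholds: EventThresholds, vm_base):
    peak = float(vm_win.max())
    defl = peak - vm_base
    if vm_win.size > 2:
        dvdt = float(np.max(np.diff(vm_win) / np.diff(t_win)))
    else:
        dvdt = 0.0
    if defl < thresholds.vm_deflection:
        cls = "none"
    elif dvdt < thresholds.dvdt_regenerative:
        cls = "subthreshold_dad"
    elif peak < 0.0:
        cls = "suprathreshold_dad"
    else:
        cls = "triggered_beat"
    return cls, peak, dvdt


def detect_events(result, thresholds: EventThresholds | None = None) -> list[WaveEvent]:
    """Detect and classify spontaneous events in the observation window.

    Works per cell on the cytosolic-calcium traces of a
    :class:`~mecsim.engine.run.SimulationResult`; the per-CRU diastolic
    baseline is the running minimum over the observation window, so the decay
    of the final paced transient is not scored as an event.
    """
    if thresholds is None:
        thresholds = EventThresholds()
    sl = result.observation_slice()
    t = np.asarray(result.time[sl], dtype=float)
    if t.size < 3:
        return []
    events: list[WaveEvent] = []
    for c in range(result.n_cells):
        ca = np.asarray(result.cell(c, "Ca_cyto")[sl], dtype=float)
        vm = np.asarray(result.cell(c, "Vm")[sl], dtype=float)
        s, e = result.cell_bounds[c]
        pos = np.asarray(result.positions[s:e], dtype=float)

        baseline = np.minimum.accumulate(ca, axis=0)
        above = (ca - baseline) > thresholds.ca_event
        mask = above.any(axis=1)
        if not mask.any():
            continue
        # contiguous runs, merging gaps shorter than merge_gap
        idx = np.flatnonzero(mask)
        breaks = np.flatnonzero(np.diff(t[idx]) > thresholds.merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for order_k, (a, b) in enumerate(zip(starts, ends)):
            i0, i1 = idx[a], idx[b]
            # extend the window to capture the calcium peak and the membrane
            # response, which lags the calcium upstroke
            i1 = min(i1 + max(1, int(150.0 / max(t[1] - t[0], 1e-9))), t.size - 1)
            base = baseline[i0]
            win = ca[i0 : i1 + 1]
            amp_cru = win.max(axis=0) - base
            activated = amp_cru > thresholds.ca_event
            at = np.full(pos.size, np.nan)
            for i in np.flatnonzero(activated):
                level = base[i] + thresholds.activation_frac * amp_cru[i]
                cross = np.flatnonzero(win[:, i] >= level)
                if cross.size == 0:
                    continue
                k = cross[0]
                if k == 0 or win[k, i] == win[k - 1, i]:
                    at[i] = t[i0 + k]
                else:
                    frac = (level - win[k - 1, i]) / (win[k, i] - win[k - 1, i])
                    at[i] = t[i0 + k - 1] + frac * (t[i0 + k] - t[i0 + k - 1])
            vel, flag = wave_velocity(at, pos)
            amp = wave_amplitude(win.max(axis=0), base)
            vm_base = float(np.median(vm[max(i0 - 20, 0) : i0 + 1].max(axis=1)))
            cls, peak_vm, max_dvdt = _classify_vm(
                vm[i0 : i1 + 1].max(axis=1), t[i0 : i1 + 1], thresholds, vm_base
            )
            if flag == "propagating":
                wave_class = "fast" if vel > thresholds.fast_wave_cutoff else "slow"
            else:
                wave_class = flag
            events.append(
                WaveEvent(
                    cell=c,
                    onset=float(t[i0]),
                    t_end=float(t[i1]),
                    activation_times=at,
                    amplitude=amp,
                    velocity=vel,
                    event_class=cls,
                    wave_class=wave_class,
                    order="first" if order_k == 0 else "subsequent",
                    peak_vm=peak_vm,
                    max_dvdt=max_dvdt,
                    n_activated=int(activated.sum()),
                )
            )
    return events


# ----------------------------------------------------------------------
# dyssynchrony
# ----------------------------------------------------------------------
def dyssynchrony(per_cell_ttp) -> float:
    """Inter-cellular dyssynchrony (ms): sample standard deviation across
    cells of each cell's mean time-to-peak of the calcium transient.

    ``per_cell_ttp`` is a sequence (one entry per cell) of per-CRU
    time-to-peak values or already-averaged scalars.
    """
    cells = [float(np.mean(v)) for v in per_cell_ttp]
    if len(cells) < 2:
        raise ValueError("dyssynchrony needs at least 2 cells")
    return float(np.std(cells, ddof=1))


def cell_mean_ttp(result, cell: int = 0, thresholds: EventThresholds | None = None) -> float:
    """Mean over CRUs of the time-to-peak (ms) of the cell's first
    spontaneous calcium event, referenced to the observation start (the
    common time origin across runs that share a protocol).

    Raises ``ValueError`` if the cell shows no event.
    """
    events = [e for e in detect_events(result, thresholds) if e.cell == cell]
    if not events:
        raise ValueError(f"cell {cell} has no spontaneous event")
    ev = events[0]
    t = np.asarray(result.time, dtype=float)
    i0 = int(np.searchsorted(t, ev.onset))
    i1 = int(np.searchsorted(t, ev.t_end)) + 1
    ca = np.asarray(result.cell(cell, "Ca_cyto")[i0:i1], dtype=float)
    t_ref = result.metadata.get("observation_start", 0.0)
    return float(np.mean(t[i0 + np.argmax(ca, axis=0)] - t_ref))


def dyssynchrony_from_result(result, thresholds: EventThresholds | None = None) -> float:
    """Inter-cellular dyssynchrony (ms) of one multi-cell simulation: sample
    std across cells of each cell's mean first-event time-to-peak."""
    if result.n_cells < 2:
        raise ValueError("dyssynchrony needs at least 2 cells")
    return dyssynchrony(
        [cell_mean_ttp(result, c, thresholds) for c in range(result.n_cells)]
    )


def dyssynchrony_across_results(results, thresholds: EventThresholds | None = None) -> float:
    """Dyssynchrony across separately simulated (isolated) cells that ran
    the same protocol, so the observation start is a shared time origin."""
    return dyssynchrony([cell_mean_ttp(r, 0, thresholds) for r in results])


# ----------------------------------------------------------------------
# group statistics
# ----------------------------------------------------------------------
@dataclass
class StatsReport:
    """One-way ANOVA with Bonferroni-corrected pairwise comparisons."""

    labels: list
    means: np.ndarray
    stds: np.ndarray
    anova_p: float
    pairwise: list = field(default_factory=list)  # (label_a, label_b, p_raw, p_adj, tier)
    outliers_removed: dict = field(default_factory=dict)  # label -> indices

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.pairwise, columns=["group_a", "group_b", "p_raw", "p_adj", "significance"]
        )


def _tier(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def group_stats(groups, labels=None) -> StatsReport:
    """Three-sigma outlier removal per group, one-way ANOVA, then all-pairs
    mean comparisons with Bonferroni adjustment (p_adj = min(1, m * p_raw)).

    Significance tiers: *** p < 0.01, ** p < 0.05, * p < 0.1.
    """
    if len(groups) < 2:
        raise ValueError("group_stats needs at least 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    cleaned = []
    removed: dict = {}
    for lab, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        if g.size >= 2 and np.std(g, ddof=1) > 0:
            z = np.abs(g - g.mean()) / np.std(g, ddof=1)
            keep = z <= 3.0
        else:
            keep = np.ones(g.size, dtype=bool)
        removed[lab] = np.flatnonzero(~keep).tolist()
        g = g[keep]
        if g.size < 2:
            raise ValueError(f"group '{lab}' degenerate after outlier removal")
        cleaned.append(g)

    anova_p = float(sps.f_oneway(*cleaned).pvalue)
    pairs = list(combinations(range(len(cleaned)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        if np.ptp(cleaned[i]) == 0 and np.ptp(cleaned[j]) == 0:
            p_raw = 1.0 if cleaned[i].mean() == cleaned[j].mean() else 0.0
        else:
            p_raw = float(sps.ttest_ind(cleaned[i], cleaned[j]).pvalue)
        p_adj = min(1.0, m * p_raw)
        pairwise.append((labels[i], labels[j], p_raw, p_adj, _tier(p_adj)))
    return StatsReport(
        labels=list(labels),
        means=np.array([g.mean() for g in cleaned]),
        stds=np.array([g.std(ddof=1) for g in cleaned]),
        anova_p=anova_p,
        pairwise=pairwise,
        outliers_removed=removed,
    )


def events_table(events):
    """One row per WaveEvent, ready for CSV export."""
    import pandas as pd

    rows = []
    for ev in events:
        rows.append(
            {
                "cell": ev.cell,
                "onset_ms": ev.onset,
                "order": ev.order,
                "event_class": ev.event_class,
                "wave_class": ev.wave_class,
                "amplitude_uM": ev.amplitude,
                "velocity_um_per_s": ev.velocity,
                "n_activated": ev.n_activated,
                "peak_vm_mV": ev.peak_vm,
                "max_dvdt_mV_per_ms": ev.max_dvdt,
            }
        )
    return pd.DataFrame(rows)
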