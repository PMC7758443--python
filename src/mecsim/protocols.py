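"""Stretch waveforms, pacing schedules, the Ca_o sweep and the limit-cycle test.

Stretch is length-controlled: the protocol returns a dimensionless multiplier
s(t) of the per-sarcomere resting length (and its analytic time derivative,
needed for the strain-rate coupling).  Four patterns are provided:

* H — normal isotonic shortening: a sinusoid dipping to 20% compression,
  s = 1 - 0.20 * (1 - cos(2 pi t / CL)) / 2, range [0.80, 1].
* I — isometric: s = 1 identically.
* S — systolic stretch / diastolic compression: s = 1 + 0.10 sin(2 pi t / CL),
  range [0.90, 1.10] (stretch during the early-cycle systolic phase).
* P — systolic lengthening (ischemic-region-like): exponential rise from 1 to
  a 1.15 plateau at contraction onset, hold, exponential decay at relaxation.

All waveforms are periodic with the pacing cycle and continuous in value.
Pacing runs up to ``n_beats`` (default 200) with early exit once consecutive
action potentials agree to mean squared error < 0.01 (the limit-cycle
criterion); the Ca_o sweep steps extracellular calcium from 2.0 to 4.5 mM in
0.1 mM increments, each step followed by a quiescent observation window in
which spontaneous events are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fiber import ConductionParams

__all__ = [
    "StretchProtocol",
    "PacingProtocol",
    "SweepConfig",
    "ExperimentDescriptor",
    "stretch_scaling",
    "limit_cycle_reached",
    "run_sweep_schedule",
]

PATTERNS = ("H", "I", "S", "P")


@dataclass
class StretchProtocol:
    """One of the four stretch patterns with its timing parameters (ms)."""

    pattern: str = "I"
    cycle_length: float = 1000.0
    h_compression: float = 0.20   # H: minimum scaling 1 - h_compression
    s_amplitude: float = 0.10     # S: range 1 +/- s_amplitude
    p_plateau: float = 0.15       # P: plateau at 1 + p_plateau
    p_rise_tau: float = 60.0      # P: exponential rise spanning the transient
    p_decay_tau: float = 40.0     # P: exponential decay at relaxation
    p_off_frac: float = 0.35      # P: decay begins at this cycle fraction
    systole_frac: float = 0.4     # fraction of the cycle treated as systole
    phase_offset: float = 0.0     # ms added to t before evaluation

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown stretch pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")


def stretch_scaling(protocol: StretchProtocol, t):
    """(scaling, d scaling/dt) of the SL command at time t (ms) in the cycle.

    Vectorized over t.  The derivative is analytic, for use as the imposed
    strain-rate component of the mechano-electric coupling.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    cl = protocol.cycle_length
    tc = np.mod(t + protocol.phase_offset, cl)
    w = 2.0 * np.pi / cl

    if protocol.pattern == "I":
        return np.ones_like(tc), np.zeros_like(tc)
    if protocol.pattern == "H":
        a = protocol.h_compression / 2.0
        s = 1.0 - a * (1.0 - np.cos(w * tc))
        ds = -a * w * np.sin(w * tc)
        return s, ds
    if protocol.pattern == "S":
        s = 1.0 + protocol.s_amplitude * np.sin(w * tc)
        ds = protocol.s_amplitude * w * np.cos(w * tc)
        return s, ds
    # pattern P
    t_off = protocol.p_off_frac * cl
    rise = protocol.p_plateau * (1.0 - np.exp(-tc / protocol.p_rise_tau))
    peak = protocol.p_plateau * (1.0 - np.exp(-t_off / protocol.p_rise_tau))
    decay = peak * np.exp(-(tc - t_off) / protocol.p_decay_tau)
    on = tc < t_off
    s = np.where(on, 1.0 + rise, 1.0 + decay)
    ds = np.where(
        on,
        protocol.p_plateau / protocol.p_rise_tau * np.exp(-tc / protocol.p_rise_tau),
        -decay / protocol.p_decay_tau,
    )
    return s, ds


@dataclass
class PacingProtocol:
    """Pacing cycle length, beat budget and stimulus description."""

    cycle_length: float = 1000.0
    n_beats: int = 200
    conduction: ConductionParams = field(default_factory=ConductionParams)
    early_exit: bool = True  # stop pacing once the limit cycle is reached

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")

    def stim_onsets(self) -> np.ndarray:
        return np.arange(self.n_beats) * self.cycle_length


@dataclass
class SweepConfig:
    """Extracellular calcium sweep with a post-pacing observation window."""

    cao_start: float = 2.0   # mM
    cao_stop: float = 4.5
    cao_step: float = 0.1
    observation_window: float = 5000.0  # ms after pacing stops

    def __post_init__(self) -> None:
        if self.cao_step <= 0:
            raise ValueError("cao_step must be positive")
        if self.cao_start > self.cao_stop:
            raise ValueError("cao_start must be <= cao_stop")

    def cao_values(self) -> np.ndarray:
        n = int(round((self.cao_stop - self.cao_start) / self.cao_step)) + 1
        return np.round(self.cao_start + self.cao_step * np.arange(n), 10)


@dataclass
class ExperimentDescriptor:
    """One sweep step: pace-and-stretch to limit cycle, then observe quiescently."""

    Ca_o: float
    pacing: PacingProtocol
    stretch: StretchProtocol
    observation_window: float
    seeds: dict = field(default_factory=dict)


def limit_cycle_reached(ap_prev, ap_last, threshold: float = 0.01):
    """Beat-to-beat steady-state test: MSE between consecutive APs < threshold.

    Traces (mV) must cover the upstroke, plateau and repolarization of one
    beat; unequal-length traces are resampled onto a common normalized grid.
    Returns ``(reached, mse)`` with mse in mV^2.
    """
    a = np.asarray(ap_prev, dtype=float)
    b = np.asarray(ap_last, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty AP trace")
    if a.shape != b.shape:
        n = max(a.size, b.size)
        grid = np.linspace(0.0, 1.0, n)
        a = np.interp(grid, np.linspace(0.0, 1.0, a.size), a)
        b = np.interp(grid, np.linspace(0.0, 1.0, b.size), b)
    mse = float(np.mean((a - b) ** 2))
    return mse < threshold, mse


def run_sweep_schedule(
    sweep: SweepConfig,
    pacing: PacingProtocol,
    stretch: StretchProtocol,
    seeds: dict | None = None,
) -> list[ExperimentDescriptor]:
    """Ordered experiment descriptors, one per Ca_o step (deterministic)."""
    seeds = dict(seeds or {})
    return [
        ExperimentDescriptor(
            Ca_o=float(cao),
            pacing=replace(pacing),
            stretch=replace(stretch),
            observation_window=sweep.observation_window,
            seeds=dict(seeds),
        )
        for cao in sweep.cao_values()
    ]
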