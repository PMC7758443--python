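"""Simulation driver: pacing phase, limit-cycle detection, observation phase.

A run executes the protocol the calcium-wave experiments use: pace the tissue
(stimulating CRU 1 of cell 1) under the configured stretch pattern for up to
``n_beats`` beats, optionally exiting early once consecutive action
potentials agree to MSE < 0.01 (the limit-cycle criterion), then stop both
pacing and stretching and record a quiescent observation window in which
spontaneous calcium release events are scored.  Traces are sampled on a
regular grid (finer during observation, where wave timing is measured).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ..protocols import PacingProtocol, StretchProtocol, limit_cycle_reached
from .model import TissueModel

__all__ = [
    "SolverConfig",
    "SimulationResult",
    "SimulationAborted",
    "run",
    "run_descriptor",
    "save_result",
    "load_result",
]

RESULT_VERSION = 1

TRACE_FIELDS = ("Vm", "Ca_cyto", "Ca_SR", "Ca_SS", "SL", "force")


@dataclass
class SolverConfig:
    """Integration and sampling settings.

    ``dt`` is the fixed operator-splitting step for fiber/tissue runs;
    ``rtol``/``atol`` apply when the adaptive 0D path is used.  Sampling uses
    ``sample_interval`` during pacing and the finer
    ``observation_sample_interval`` during the observation window.
    """

    dt: float = 0.02                 # ms
    rtol: float = 1.0e-6
    atol: float = 1.0e-8
    max_step: float = 1.0            # ms (adaptive path)
    sample_interval: float = 1.0     # ms
    observation_sample_interval: float = 0.5  # ms
    use_compiled: bool = True        # numba step kernel (falls back if absent)

    def __post_init__(self) -> None:
        if min(self.dt, self.rtol, self.atol, self.sample_interval,
               self.observation_sample_interval) <= 0:
            raise ValueError("solver settings must be strictly positive")


class SimulationAborted(RuntimeError):
    """Raised when the state becomes non-finite; carries the partial result."""

    def __init__(self, message: str, partial: "SimulationResult | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class SimulationResult:
    """Time-resolved per-CRU traces plus provenance metadata."""

    time: np.ndarray                    # (nt,) ms
    traces: dict                        # field -> (nt, n_cru_total) arrays
    vf: np.ndarray                      # (nt, n_fib) fibroblast potentials
    positions: np.ndarray               # (n_cru_total,) um, per-cell coordinates
    cell_bounds: list
    metadata: dict = field(default_factory=dict)

    def cell(self, c: int, field_name: str) -> np.ndarray:
        s, e = self.cell_bounds[c]
        return self.traces[field_name][:, s:e]

    @property
    def n_cells(self) -> int:
        return len(self.cell_bounds)

    def observation_slice(self) -> slice:
        t0 = self.metadata.get("observation_start", 0.0)
        return slice(int(np.searchsorted(self.time, t0)), len(self.time))

    def summary_frame(self):
        """Per-sample aggregate table (one row per sampled time)."""
        import pandas as pd

        cols = {"time_ms": self.time}
        for c in range(self.n_cells):
            cols[f"Vm_mean_cell{c}"] = self.cell(c, "Vm").mean(axis=1)
            cols[f"Ca_cyto_mean_cell{c}"] = self.cell(c, "Ca_cyto").mean(axis=1)
            cols[f"Ca_SR_mean_cell{c}"] = self.cell(c, "Ca_SR").mean(axis=1)
            cols[f"SL_mean_cell{c}"] = self.cell(c, "SL").mean(axis=1)
        return pd.DataFrame(cols)


def _check_finite(s: dict, t: float) -> None:
    for k, v in s.items():
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in state variable '{k}' at t = {t:.3f} ms")


def run(
    spec,
    stretch: StretchProtocol | None = None,
    pacing: PacingProtocol | None = None,
    observation_window: float = 5000.0,
    ionic_params=None,
    myof_params=None,
    coupling=None,
    diffusion=None,
    solver: SolverConfig | None = None,
    initial_state: dict | None = None,
    sarcomere_mode: str | None = None,
) -> SimulationResult:
    """Integrate a tissue through pacing + observation; return sampled traces.

    Raises :class:`SimulationAborted` (with the partial result attached) if
    the state becomes non-finite; NaNs are never silently dropped.
    """
    pacing = pacing or PacingProtocol()
    solver = solver or SolverConfig()
    onsets = pacing.stim_onsets()
    pace_end = pacing.n_beats * pacing.cycle_length

    model = TissueModel(
        spec,
        ionic_params=ionic_params,
        myof_params=myof_params,
        coupling=coupling,
        diffusion=diffusion,
        conduction=pacing.conduction,
        stretch=stretch,
        sarcomere_mode=sarcomere_mode,
        stim_onsets=onsets,
        stretch_until=pace_end,
    )
    init = model.initial_state() if initial_state is None else initial_state
    # state lives in two matrices so the compiled kernel can walk it; the
    # dict holds row views and keeps the pure-python stepper working too
    from ..cell_models.fibroblast import FIB_NAMES
    from .state import FIELDS

    S = np.empty((len(FIELDS), model.layout.n_cru_total))
    Fb = np.empty((len(FIB_NAMES), model.layout.n_fib))
    s: dict[str, np.ndarray] = {}
    for k, f in enumerate(FIELDS):
        S[k, :] = init[f]
        s[f] = S[k]
    for k, f in enumerate(FIB_NAMES):
        Fb[k, :] = init[f]
        s[f] = Fb[k]

    kernel_fn = None
    if solver.use_compiled:
        from . import kernel as _kernel

        if _kernel.HAVE_NUMBA:
            kernel_fn = _kernel.step_chunk

    times: list[float] = []
    samples: dict[str, list] = {f: [] for f in TRACE_FIELDS}
    vf_samples: list = []
    mid = (model.layout.cell_bounds[0][0] + model.layout.cell_bounds[0][1]) // 2

    def take_sample(t: float) -> None:
        times.append(t)
        for f in ("Vm", "Ca_cyto", "Ca_SR", "Ca_SS", "SL"):
            samples[f].append(s[f].astype(np.float32))
        samples["force"].append(model.force(s).astype(np.float32))
        vf_samples.append(s["V_f"].astype(np.float32))

    def build_result(meta_extra: dict) -> SimulationResult:
        return SimulationResult(
            time=np.asarray(times),
            traces={f: np.asarray(v) for f, v in samples.items()},
            vf=np.asarray(vf_samples) if vf_samples else np.zeros((len(times), 0)),
            positions=model.positions.copy(),
            cell_bounds=list(model.layout.cell_bounds),
            metadata={
                **model.metadata(),
                "solver": {
                    "dt": solver.dt,
                    "sample_interval": solver.sample_interval,
                    "observation_sample_interval": solver.observation_sample_interval,
                },
                "pacing": {
                    "cycle_length": pacing.cycle_length,
                    "n_beats": pacing.n_beats,
                    "early_exit": pacing.early_exit,
                },
                "result_version": RESULT_VERSION,
                **meta_extra,
            },
        )

    kargs = model.kernel_args(solver.dt) if kernel_fn is not None else None

    def integrate(t0: float, t1: float, sample_dt: float, beat_probe: list | None):
        """March t0 -> t1 with fixed steps, sampling every sample_dt."""
        n_steps = int(round((t1 - t0) / solver.dt))
        stride = max(1, int(round(sample_dt / solver.dt)))
        t = t0
        if kernel_fn is not None:
            k = kargs
            done = 0
            while done < n_steps:
                chunk = min(stride, n_steps - done)
                kernel_fn(
                    S, Fb, t, solver.dt, chunk,
                    k["ip"], k["mp"], k["cell_starts"], k["cell_ends"],
                    k["resting_SL"], k["cm_cru"], k["dl"], k["dd"], k["du"],
                    k["stim_idx"], k["stim_amp"], k["stim_dur"],
                    np.asarray(model.stim_onsets, dtype=float),
                    k["stretch_code"], k["stretch_p"], float(model.stretch_until),
                    k["tau_ss"], k["tau_sr"], k["tau_cyto"],
                    k["mode_relaxed"], k["kappa"], k["mech_ju"], k["mech_jv"],
                    k["fib_gidx"], k["fib_g"], k["fp"],
                )
                done += chunk
                t = t0 + done * solver.dt
                if done % stride == 0 or done == n_steps:
                    _check_finite(s, t)
                    take_sample(t)
                    if beat_probe is not None:
                        beat_probe.append(s["Vm"][mid])
            return t
        for k in range(n_steps):
            model.step(t, s, solver.dt)
            t = t0 + (k + 1) * solver.dt
            if (k + 1) % stride == 0:
                _check_finite(s, t)
                take_sample(t)
                if beat_probe is not None:
                    beat_probe.append(s["Vm"][mid])
        return t

    t = 0.0
    take_sample(t)
    beats_run = 0
    mse = np.nan
    prev_beat: np.ndarray | None = None
    try:
        for b in range(pacing.n_beats):
            probe: list = []
            t = integrate(t, (b + 1) * pacing.cycle_length, solver.sample_interval, probe)
            beats_run = b + 1
            beat = np.asarray(probe)
            if prev_beat is not None and beat.size == prev_beat.size:
                reached, mse = limit_cycle_reached(prev_beat, beat)
                if reached and pacing.early_exit:
                    break
            prev_beat = beat
        # stop pacing and stretching; observe quiescently
        model.stim_onsets = onsets[:beats_run]
        model.stretch_until = t
        obs_start = t
        t = integrate(t, t + observation_window, solver.observation_sample_interval, None)
    except ValueError as exc:
        partial = build_result({"aborted": str(exc)})
        raise SimulationAborted(str(exc), partial) from exc

    return build_result(
        {
            "observation_start": obs_start,
            "beats_run": beats_run,
            "limit_cycle_mse": None if np.isnan(mse) else float(mse),
        }
    )


def run_descriptor(spec, descriptor, ionic_params=None, **kwargs) -> SimulationResult:
    """Run one sweep step: the descriptor's Ca_o, pacing and stretch."""
    from ..cell_models.ionic import IonicParams

    base = ionic_params or IonicParams()
    params = replace(base, Ca_o=descriptor.Ca_o)
    params.remodeled = base.remodeled
    return run(
        spec,
        stretch=descriptor.stretch,
        pacing=descriptor.pacing,
        observation_window=descriptor.observation_window,
        ionic_params=params,
        **kwargs,
    )


# ----------------------------------------------------------------------
def save_result(result: SimulationResult, path) -> None:
    """Lossless HDF5 round-trip of traces and metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["result_version"] = RESULT_VERSION
        f.attrs["metadata"] = json.dumps(result.metadata, default=_json_default)
        f.create_dataset("time", data=result.time)
        f.create_dataset("vf", data=result.vf)
        f.create_dataset("positions", data=result.positions)
        f.create_dataset("cell_bounds", data=np.asarray(result.cell_bounds, dtype=int))
        g = f.create_group("traces")
        for k, v in result.traces.items():
            g.create_dataset(k, data=v)


def load_result(path) -> SimulationResult:
    """Load a saved result; explicit errors on version mismatch / corruption."""
    import h5py

    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("result_version", -1))
            if version != RESULT_VERSION:
                raise ValueError(
                    f"result version mismatch: file has {version}, reader expects {RESULT_VERSION}"
                )
            return SimulationResult(
                time=f["time"][:],
                traces={k: v[:] for k, v in f["traces"].items()},
                vf=f["vf"][:],
                positions=f["positions"][:],
                cell_bounds=[tuple(b) for b in f["cell_bounds"][:]],
                metadata=json.loads(f.attrs["metadata"]),
            )
    except OSError as exc:
        raise OSError(f"could not read result file {path}: corrupt or truncated ({exc})") from exc


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
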