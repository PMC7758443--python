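"""Adaptive-solver path for single-CRU (0D) cell runs.

The 0D electromechanical cell — one ionic CRU strongly coupled to one
sarcomere — is integrated with scipy's stiff adaptive solvers (LSODA by
default).  Used for calibration, cell-level fidelity tests and anywhere the
spatial couplings are irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ..cell_models.ionic import IonicParams, IonicState, STATE_NAMES, ionic_rhs, resting_state
from ..cell_models.myofilament import (
    MECH_NAMES,
    MyofilamentParams,
    SarcomereState,
    StrainCouplingParams,
    myofilament_rhs,
    overlap,
    resting_sarcomere,
)
from ..protocols import StretchProtocol, stretch_scaling

__all__ = ["CellResult", "run_cell"]

_ALL = STATE_NAMES + MECH_NAMES


@dataclass
class CellResult:
    time: np.ndarray
    states: dict  # name -> (nt,) arrays
    force: np.ndarray

    def __getitem__(self, k):
        return self.states[k]


def _split(y):
    ion = IonicState(**{n: np.atleast_1d(y[i]) for i, n in enumerate(STATE_NAMES)})
    k = len(STATE_NAMES)
    mech = SarcomereState(
        SL=np.atleast_1d(y[k]), tnc_ca=np.atleast_1d(y[k + 1]), xb=np.atleast_1d(y[k + 2])
    )
    return ion, mech


def run_cell(
    ionic_params: IonicParams | None = None,
    coupling: StrainCouplingParams | None = None,
    myof_params: MyofilamentParams | None = None,
    stretch: StretchProtocol | None = None,
    t_end: float = 1000.0,
    stim_onsets=(),
    stim_amplitude: float = 20.0,  # per-CRU share of the fiber stimulus

    stim_duration: float = 3.0,
    sample_dt: float = 1.0,
    SL_rest: float = 1.89,
    y0: np.ndarray | None = None,
    stretch_until: float = np.inf,
    method: str = "LSODA",
    rtol: float = 1.0e-6,
    atol: float = 1.0e-8,
) -> CellResult:
    """Integrate one electromechanical cell; returns sampled traces.

    The stimulus is an additive dVm/dt pulse (mV/ms).  With ``stretch`` set,
    the commanded sarcomere length is SL_rest times the protocol scaling
    until ``stretch_until``; strain rate is the realized dSL/dt / SL_rest.
    """
    p = ionic_params or IonicParams()
    coup = coupling or StrainCouplingParams()
    myof = myof_params or MyofilamentParams()
    onsets = np.sort(np.asarray(stim_onsets, dtype=float))

    if y0 is None:
        ion0 = resting_state(p)
        mech0 = resting_sarcomere(1, SL_rest)
        y0 = np.array(
            [float(np.atleast_1d(getattr(ion0, n))[0]) for n in STATE_NAMES]
            + [float(np.atleast_1d(getattr(mech0, n))[0]) for n in MECH_NAMES]
        )

    cl = stretch.cycle_length if stretch is not None else 1000.0

    def rhs(t, y):
        ion, mech = _split(y)
        if stretch is not None and t < stretch_until:
            scale, _ = stretch_scaling(stretch, float(np.mod(t, cl)))
            cmd = SL_rest * float(scale)
        else:
            cmd = SL_rest
        iso = (cmd - mech.SL) / myof.tau_track
        strain_rate = iso / SL_rest
        dmech, _, j_tnc = myofilament_rhs(
            mech, np.maximum(ion.Ca_cyto, 1e-9), strain_rate, coup, myof, sl_cmd=cmd
        )

        I_stim = 0.0
        if onsets.size:
            k = np.searchsorted(onsets, t, side="right") - 1
            if k >= 0 and t < onsets[k] + stim_duration:
                I_stim = stim_amplitude
        dion, _ = ionic_rhs(ion, p, tnc_flux=j_tnc, I_stim=I_stim)
        return np.concatenate(
            [np.atleast_1d(dion[n]) for n in STATE_NAMES]
            + [np.atleast_1d(dmech[n]) for n in MECH_NAMES]
        )

    t_eval = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    # cap the step while pacing so the adaptive solver cannot skip a stimulus
    max_step = 1.0 if onsets.size else np.inf
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        max_step=max_step,
    )
    if not sol.success:
        raise RuntimeError(f"cell integration failed: {sol.message}")
    states = {n: sol.y[i] for i, n in enumerate(_ALL)}
    force = states["xb"] * overlap(states["SL"], myof)
    return CellResult(time=sol.t, states=states, force=force)
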