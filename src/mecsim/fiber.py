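"""Intra-myocyte spatial couplings: a myocyte as a string of 50 CRUs.

Three couplings connect adjacent CRUs along the fiber:

* calcium diffusion per compartment k in {SS, SR, cyto}:
  dCa_k[i] += (Ca_k[i+1] + Ca_k[i-1] - 2 Ca_k[i]) / tau_k, single-neighbor
  forms at the ends — a zero-sum graph-Laplacian stencil;
* membrane-potential conduction with the same stencil divided by tau_Vm,
  plus a stimulus term applied to CRU 1 during the stimulus window;
* inter-sarcomere mechanical coupling mixing the per-sarcomere isotonic
  length-change rates.  The "verbatim" mode uses the interior form
  2*own - (left + right) with single-neighbor boundary forms own - neighbor.
  That form is degenerate (interior output vanishes under uniform
  shortening), so a "relaxed" neighbor-averaging mode
  own + kappa*(neighbor mean - own) is also provided; the mode used is
  recorded in result metadata.

CRU indices are 1-based in configuration (matching the field convention);
CRU i's center sits at (i - 1/2) * spacing for velocity conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberGeometry",
    "DiffusionParams",
    "ConductionParams",
    "ca_coupling_term",
    "vm_coupling_term",
    "sarcomere_coupling",
    "laplacian_matrix",
    "assemble_fiber_rhs",
]


@dataclass
class FiberGeometry:
    """Fiber discretization: CRU count and per-sarcomere resting lengths (um)."""

    n_cru: int = 50
    resting_SL: np.ndarray | None = None
    spacing: np.ndarray | None = None  # um; defaults to the local resting SL

    def __post_init__(self) -> None:
        if self.n_cru < 2:
            raise ValueError("n_cru must be >= 2")
        if self.resting_SL is None:
            self.resting_SL = np.full(self.n_cru, 1.89)
        self.resting_SL = np.asarray(self.resting_SL, dtype=float)
        if self.resting_SL.shape != (self.n_cru,):
            raise ValueError("resting_SL must have length n_cru")
        if np.any(self.resting_SL <= 0):
            raise ValueError("resting lengths must be positive")
        if self.spacing is None:
            self.spacing = self.resting_SL.copy()
        self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def positions(self) -> np.ndarray:
        """CRU center positions (um): cumulative spacing minus half a unit."""
        return np.cumsum(self.spacing) - 0.5 * self.spacing


@dataclass
class DiffusionParams:
    """Inter-CRU calcium exchange time constants (ms)."""

    tau_SS: float = 0.4533
    tau_SR: float = 150.0
    tau_cyto: float = 1.2

    def __post_init__(self) -> None:
        if min(self.tau_SS, self.tau_SR, self.tau_cyto) <= 0:
            raise ValueError("diffusion time constants must be strictly positive")


@dataclass
class ConductionParams:
    """Inter-CRU voltage transfer and stimulus description.

    The stimulus is an additive dVm/dt term (mV/ms, equivalently pA/pF)
    applied to ``stim_target`` (1-based) while t lies inside an active
    window.  The default 1000 mV/ms into one CRU is the smallest decade
    multiple that reliably elicits a propagated action potential: the
    near-instant voltage equalization (tau_Vm = 1e-5 ms) spreads the injected
    charge over all 50 CRUs, so the whole-fiber depolarization is about
    1000 * 3 ms / 50 = 60 mV.
    """

    tau_Vm: float = 1.0e-5
    stim_amplitude: float = 1000.0
    stim_duration: float = 3.0
    stim_target: int = 1

    def __post_init__(self) -> None:
        if self.tau_Vm <= 0 or self.stim_duration <= 0:
            raise ValueError("tau_Vm and stim_duration must be positive")
        if self.stim_target < 1:
            raise ValueError("stim_target is a 1-based CRU index")


def _laplacian(vec: np.ndarray) -> np.ndarray:
    """Zero-sum chain Laplacian with single-neighbor ends."""
    v = np.asarray(vec, dtype=float)
    if v.ndim != 1 or v.shape[0] < 2:
        raise ValueError("coupling terms need a 1D vector of length >= 2")
    out = np.empty_like(v)
    out[1:-1] = v[2:] + v[:-2] - 2.0 * v[1:-1]
    out[0] = v[1] - v[0]
    out[-1] = v[-2] - v[-1]
    return out


def laplacian_matrix(n: int) -> np.ndarray:
    """Dense chain-Laplacian matrix (for analytic matrix-exponential oracles)."""
    L = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            L[i, i - 1] += 1.0
            L[i, i] -= 1.0
        if i < n - 1:
            L[i, i + 1] += 1.0
            L[i, i] -= 1.0
    return L


def ca_coupling_term(ca: np.ndarray, tau: float) -> np.ndarray:
    """Inter-CRU calcium exchange rates (mM/ms) for one compartment."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return _laplacian(ca) / tau


def stimulus_active(t, cp: ConductionParams, stim_onsets) -> bool:
    """True if t (ms) lies inside any stimulus window."""
    t = float(t)
    for t0 in stim_onsets:
        if t0 <= t < t0 + cp.stim_duration:
            return True
    return False


def vm_coupling_term(vm: np.ndarray, cp: ConductionParams, t: float, stim_onsets=(0.0,)) -> np.ndarray:
    """Voltage conduction rates (mV/ms) plus the stimulus contribution."""
    out = _laplacian(vm) / cp.tau_Vm
    if stimulus_active(t, cp, stim_onsets):
        out[cp.stim_target - 1] += cp.stim_amplitude
    return out


def sarcomere_coupling(iso_rates: np.ndarray, mode: str = "verbatim", kappa: float = 0.5) -> np.ndarray:
    """Effective dSL/dt from per-sarcomere isotonic rates (um/ms)."""
    r = np.asarray(iso_rates, dtype=float)
    if r.ndim != 1 or r.shape[0] < 2:
        raise ValueError("sarcomere_coupling needs >= 2 sarcomeres")
    if mode == "verbatim":
        out = np.empty_like(r)
        out[1:-1] = 2.0 * r[1:-1] - (r[2:] + r[:-2])
        out[0] = r[0] - r[1]
        out[-1] = r[-1] - r[-2]
        return out
    if mode == "relaxed":
        nb_mean = np.empty_like(r)
        nb_mean[1:-1] = 0.5 * (r[2:] + r[:-2])
        nb_mean[0] = r[1]
        nb_mean[-1] = r[-2]
        return r + kappa * (nb_mean - r)
    raise ValueError(f"unknown sarcomere coupling mode: {mode!r}")


def assemble_fiber_rhs(
    geometry: FiberGeometry,
    diffusion: DiffusionParams,
    conduction: ConductionParams,
    ionic_params=None,
    myof_params=None,
    coupling=None,
    stretch=None,
    sarcomere_mode: str = "verbatim",
    stim_onsets=(0.0,),
):
    """Full single-myocyte right-hand side as a callable f(t, y) -> dy.

    Combines the per-CRU cell models with the three coupling stencils.  The
    state layout is the engine's packed layout for a single-cell tissue; the
    callable is deterministic given (t, y).
    """
    from .tissue import TissueSpec
    from .engine.model import TissueModel

    spec = TissueSpec(n_cells=1, geometries=[geometry], junctions=[], fibroblasts=[])
    model = TissueModel(
        spec,
        ionic_params=ionic_params,
        myof_params=myof_params,
        coupling=coupling,
        diffusion=diffusion,
        conduction=conduction,
        stretch=stretch,
        sarcomere_mode=sarcomere_mode,
        stim_onsets=stim_onsets,
    )
    return model.rhs
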