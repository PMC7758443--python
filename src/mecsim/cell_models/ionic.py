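"""Rabbit ventricular calcium-release-unit (CRU) ionic model.

A compact deterministic rabbit ventricular myocyte model with the current and
flux structure needed for mechanically triggered calcium waves: fast sodium
current, L-type calcium current with calcium-dependent inactivation (GHK flux,
so the driving force carries the extracellular-calcium dependence), transient
outward / rapid / slow delayed-rectifier and inward-rectifier potassium
currents, Na/K pump, Na/Ca exchanger with allosteric calcium activation,
background and sarcolemmal-pump calcium fluxes, and a three-compartment
calcium subsystem (subsarcolemmal space SS, junctional SR, bulk cytosol) with
SERCA uptake, passive leak and a ryanodine-receptor release flux governed by
a steep calcium-induced opening function whose sensitivity grows with SR
load (luminal regulation) and a luminal deactivation gate that terminates
each release episode when the store depletes.  Under SR calcium overload the
diastolic state loses stability, producing spontaneous release, inward
exchanger current and delayed after-depolarizations — the arrhythmogenic
phenotype this package studies.

Troponin-C calcium buffering is deliberately *absent* here: the sarcomere
mechanics model owns TnC and returns its net calcium flux, which enters the
cytosolic balance through the ``tnc_flux`` argument of :func:`ionic_rhs`
(strong electromechanical coupling).  Intracellular K+ is held fixed.

All rate functions are vectorized over CRUs: state fields may be scalars or
equally shaped numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from ..constants import FARADAY, RTF

__all__ = [
    "IonicParams",
    "IonicState",
    "RemodelingSpec",
    "apply_remodeling",
    "ionic_rhs",
    "ionic_currents",
    "gate_inf_tau",
    "resting_state",
    "GATE_NAMES",
    "STATE_NAMES",
]

# Gate fields updated by inf/tau (Rush-Larsen-able); ryr_w is the luminal
# deactivation (release availability) gate.
GATE_NAMES = ("m", "h", "j", "d", "f", "fca", "xto", "yto", "xkr", "xks", "ryr_w")
CONC_NAMES = ("Ca_SS", "Ca_SR", "Ca_cyto", "Na_i")
STATE_NAMES = ("Vm",) + GATE_NAMES + CONC_NAMES


@dataclass
class IonicParams:
    """Maximal conductances / fluxes and cell geometry.

    Conductance densities are nS/pF, pump/exchanger maxima pA/pF, volumes pL
    (whole cell; per-CRU scaling cancels because capacitance and volume are
    divided by the CRU count together).
    """

    # -- membrane currents -------------------------------------------------
    g_Na: float = 16.0
    P_CaL: float = 10.0         # GHK scaling, pA/pF per mM
    g_to: float = 0.06
    g_Kr: float = 0.07
    g_Ks: float = 0.01
    g_K1: float = 0.50
    g_Cab: float = 2.0e-3
    g_Nab: float = 3.0e-3
    I_NaK_max: float = 1.2
    Km_Nai: float = 10.0        # mM
    Km_Ko: float = 1.5          # mM
    k_NCX: float = 1000.0       # pA/pF
    Km_Nai_ncx: float = 87.5    # mM
    Km_Ca_ncx: float = 1.38     # mM
    ksat_ncx: float = 0.1
    gamma_ncx: float = 0.35
    alpha_ncx: float = 2.5
    Kd_act_ncx: float = 2.56e-4  # mM, allosteric Ca activation
    I_pCa_max: float = 0.02
    Km_pCa: float = 5.0e-4      # mM

    # -- calcium handling --------------------------------------------------
    # SR release: J_rel = k_rel * w * h(Ca_SS) * (Ca_SR - Ca_SS).
    # h is a steep Hill function of cleft calcium whose half-point
    # K_eff = K_rel_ca / f_lum(Ca_SR) falls as the SR loads (luminal
    # sensitization of calcium-induced opening); w is the luminal
    # deactivation gate — release shuts when the store depletes below
    # K_term and cannot re-ignite until cleft calcium triggers h again.
    # Under SR overload the diastolic state loses stability and the store
    # releases spontaneously (the substrate for calcium waves and DADs).
    k_rel: float = 10.0         # 1/ms, maximal release rate constant
    K_rel_ca: float = 2.0e-2    # mM, half-activation of h at low SR load
    n_rel: float = 6.0          # Hill exponent of h
    a_lum: float = 12.0         # luminal sensitization amplitude
    ec50_sr: float = 1.2        # mM, SR load at half sensitization
    n_lum: float = 6.0          # Hill exponent of the luminal factor
    K_term: float = 0.40        # mM, SR load below which release deactivates
    reopen_band: float = 0.05   # mM, hysteresis: reopen only above K_term + band
    K_ss_cold: float = 1.5e-3   # mM, cleft must cool below this to reopen
    tau_w_close: float = 5.0    # ms, deactivation on SR depletion
    tau_w_open: float = 300.0   # ms, recovery of availability
    V_up_max: float = 5.3e-3    # mM/ms, SERCA
    Km_up_f: float = 2.46e-4    # mM, forward
    Km_up_r: float = 1.2        # mM, reverse
    H_up: float = 2.2
    k_leak: float = 5.3e-6      # 1/ms
    tau_xfer: float = 1.0       # ms, SS -> cytosol transfer

    # -- buffers (rapid-equilibrium; TnC excluded, owned by mechanics) -----
    B_cmdn: float = 0.07        # mM calmodulin + high-Km sites (cytosol)
    K_cmdn: float = 2.38e-3
    B_srb: float = 0.14         # mM myosin/SR-membrane sites (cytosol)
    K_srb: float = 8.7e-4
    B_ss: float = 0.03          # mM sarcolemmal buffer (SS)
    K_ss: float = 1.3e-2
    B_csqn: float = 2.6         # mM calsequestrin (SR volume)
    K_csqn: float = 0.65

    # -- geometry & environment -------------------------------------------
    C_m: float = 138.0          # pF whole cell
    V_cyto: float = 21.45       # pL
    V_SR: float = 1.16
    V_SS: float = 0.66          # subsarcolemmal release space (~2% of cell)
    Ca_o: float = 2.0           # mM
    Na_o: float = 140.0
    K_o: float = 5.4
    K_i: float = 135.0          # mM, fixed

    remodeled: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("remodeled",):
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"IonicParams.{f.name} must be finite and >= 0, got {v}")


@dataclass
class RemodelingSpec:
    """Multiplicative conductance remodeling applied once at construction.

    Defaults implement the remodeled phenotype: transient outward K+ +30%,
    slow delayed rectifier -15%, inward rectifier -30%, Na/K pump +15%.
    """

    scale_Ito: float = 1.30
    scale_IKs: float = 0.85
    scale_IK1: float = 0.70
    scale_INaK: float = 1.15

    def is_identity(self) -> bool:
        return self.scale_Ito == self.scale_IKs == self.scale_IK1 == self.scale_INaK == 1.0


def apply_remodeling(params: IonicParams, spec: RemodelingSpec | None = None) -> IonicParams:
    """Return a remodeled copy of ``params``; the original is untouched.

    Raises ``ValueError`` on a second application (prevents silent
    compounding of the multiplicative factors).
    """
    if spec is None:
        spec = RemodelingSpec()
    if params.remodeled:
        raise ValueError("apply_remodeling called on already-remodeled parameters")
    out = replace(
        params,
        g_to=params.g_to * spec.scale_Ito,
        g_Ks=params.g_Ks * spec.scale_IKs,
        g_K1=params.g_K1 * spec.scale_IK1,
        I_NaK_max=params.I_NaK_max * spec.scale_INaK,
    )
    out.remodeled = not spec.is_identity()
    return out


@dataclass
class IonicState:
    """Per-CRU ionic state; every field is a scalar or an (n,) array."""

    Vm: np.ndarray
    m: np.ndarray
    h: np.ndarray
    j: np.ndarray
    d: np.ndarray
    f: np.ndarray
    fca: np.ndarray
    xto: np.ndarray
    yto: np.ndarray
    xkr: np.ndarray
    xks: np.ndarray
    ryr_w: np.ndarray
    Ca_SS: np.ndarray
    Ca_SR: np.ndarray
    Ca_cyto: np.ndarray
    Na_i: np.ndarray

    @property
    def gates(self) -> np.ndarray:
        """Channel gating variables stacked (gates, n)."""
        return np.stack([np.atleast_1d(getattr(self, g)) for g in GATE_NAMES])

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in STATE_NAMES}

    def copy(self) -> "IonicState":
        return IonicState(**{k: np.array(v, dtype=float) for k, v in self.as_dict().items()})

    def validate_finite(self) -> None:
        """Raise ``ValueError`` naming the first non-finite variable."""
        for name in STATE_NAMES:
            v = np.asarray(getattr(self, name))
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite value in state variable '{name}'")

    def validate(self, tol: float = 1e-6) -> None:
        """Full invariant check; raises naming the first offending variable."""
        self.validate_finite()
        for g in GATE_NAMES:
            v = np.asarray(getattr(self, g))
            if np.any(v < -tol) or np.any(v > 1 + tol):
                raise ValueError(f"gating variable '{g}' outside [0, 1]")
        for c in CONC_NAMES:
            v = np.asarray(getattr(self, c))
            if np.any(v <= 0):
                raise ValueError(f"concentration '{c}' not strictly positive")


def _safe_exp(x):
    return np.exp(np.clip(x, -80.0, 80.0))


def gate_inf_tau(Vm, Ca_SS, Ca_SR, p: IonicParams, ryr_w=None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Steady-state and time constant (ms) for every inf/tau gate.

    Hodgkin-Huxley sodium gates use the classical formulations; the remaining
    gates use Boltzmann steady states with bell-shaped time constants tuned to
    rabbit ventricular kinetics.
    """
    V = np.asarray(Vm, dtype=float)

    # INa activation
    dv = V + 47.13
    a_m = np.where(np.abs(dv) < 1e-6, 3.2, 0.32 * dv / (1.0 - _safe_exp(-0.1 * dv)))
    b_m = 0.08 * _safe_exp(-V / 11.0)
    # INa fast/slow inactivation (piecewise at -40 mV)
    low = V < -40.0
    a_h = np.where(low, 0.135 * _safe_exp(-(80.0 + V) / 6.8), 0.0)
    b_h = np.where(
        low,
        3.56 * _safe_exp(0.079 * V) + 3.1e5 * _safe_exp(0.35 * V),
        1.0 / (0.13 * (1.0 + _safe_exp(-(V + 10.66) / 11.1))),
    )
    a_j = np.where(
        low,
        (-1.2714e5 * _safe_exp(0.2444 * V) - 3.474e-5 * _safe_exp(-0.04391 * V))
        * (V + 37.78)
        / (1.0 + _safe_exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        low,
        0.1212 * _safe_exp(-0.01052 * V) / (1.0 + _safe_exp(-0.1378 * (V + 40.14))),
        0.3 * _safe_exp(-2.535e-7 * V) / (1.0 + _safe_exp(-0.1 * (V + 32.0))),
    )

    def ab(a, b):
        s = a + b
        return a / s, 1.0 / s

    m_inf, tau_m = ab(a_m, b_m)
    h_inf, tau_h = ab(a_h, b_h)
    j_inf, tau_j = ab(a_j, b_j)

    d_inf = 1.0 / (1.0 + _safe_exp(-(V + 10.0) / 6.24))
    tau_d = 0.7 + 2.5 * _safe_exp(-(((V + 12.0) / 15.0) ** 2))
    f_inf = 1.0 / (1.0 + _safe_exp((V + 35.06) / 8.6)) + 0.25 / (1.0 + _safe_exp((50.0 - V) / 20.0))
    tau_f = 25.0 + 45.0 * _safe_exp(-(((V + 25.0) / 12.0) ** 2))
    ca = np.asarray(Ca_SS, dtype=float)
    fca_inf = 1.0 / (1.0 + (ca / 5.0e-2) ** 2)
    tau_fca = np.full_like(V, 5.0)

    xto_inf = 1.0 / (1.0 + _safe_exp(-(V - 19.0) / 13.0))
    tau_xto = 0.6 + 2.8 * _safe_exp(-(((V + 10.0) / 25.0) ** 2))
    yto_inf = 1.0 / (1.0 + _safe_exp((V + 33.5) / 10.0))
    tau_yto = 8.0 + 30.0 * _safe_exp(-(((V + 40.0) / 15.0) ** 2))

    xkr_inf = 1.0 / (1.0 + _safe_exp(-(V + 21.0) / 7.5))
    tau_xkr = 50.0 + 300.0 * _safe_exp(-(((V + 30.0) / 30.0) ** 2))
    xks_inf = 1.0 / (1.0 + _safe_exp(-(V - 1.5) / 16.7))
    tau_xks = 300.0 + 350.0 * _safe_exp(-(((V - 20.0) / 30.0) ** 2))

    # Luminal deactivation with a hard hysteresis band: availability
    # collapses (tau_w_close) once the SR depletes below K_term, recovers
    # (tau_w_open) only once the store has refilled past K_term +
    # reopen_band AND the cleft has cooled below K_ss_cold, and is frozen in
    # between.  The band leaves no interior equilibrium, so release is
    # strictly episodic — it cannot smolder as a standing leak balanced by
    # SERCA recirculation of its own calcium.
    sr = np.asarray(Ca_SR, dtype=float)
    closing = sr < p.K_term
    opening = (sr > p.K_term + p.reopen_band) & (ca < p.K_ss_cold)
    w_inf = np.where(opening, 1.0, 0.0)
    # inside the band the gate keeps drifting closed (slowly), so a partial
    # closure cannot be trapped at a small conducting value
    tau_w = np.where(opening, p.tau_w_open, np.where(closing, p.tau_w_close, 20.0 * p.tau_w_close))

    return {
        "m": (m_inf, tau_m),
        "h": (h_inf, tau_h),
        "j": (j_inf, tau_j),
        "d": (d_inf, tau_d),
        "f": (f_inf, tau_f),
        "fca": (fca_inf, tau_fca),
        "xto": (xto_inf, tau_xto),
        "yto": (yto_inf, tau_yto),
        "xkr": (xkr_inf, tau_xkr),
        "xks": (xks_inf, tau_xks),
        "ryr_w": (w_inf, tau_w),
    }


def ionic_currents(state: IonicState, p: IonicParams) -> dict[str, np.ndarray]:
    """All membrane current densities (pA/pF) and SR fluxes (mM/ms)."""
    V = np.asarray(state.Vm, dtype=float)
    Ca_SS = np.asarray(state.Ca_SS, dtype=float)
    Ca_SR = np.asarray(state.Ca_SR, dtype=float)
    Ca_cyto = np.asarray(state.Ca_cyto, dtype=float)
    Na_i = np.asarray(state.Na_i, dtype=float)

    E_Na = RTF * np.log(p.Na_o / Na_i)
    E_K = RTF * np.log(p.K_o / p.K_i)
    E_Ks = RTF * np.log((p.K_o + 0.01833 * p.Na_o) / (p.K_i + 0.01833 * Na_i))
    E_Ca = 0.5 * RTF * np.log(p.Ca_o / Ca_cyto)

    I_Na = p.g_Na * state.m**3 * state.h * state.j * (V - E_Na)
    # GHK flux for ICaL, linear in Ca_SS at fixed V (slope exported for the
    # semi-implicit junctional-calcium update in the tissue stepper)
    x = 2.0 * V / RTF
    ex = _safe_exp(x)
    small = np.abs(x) < 1e-6
    pref = np.where(small, 2.0 * (1.0 - x / 2.0), 2.0 * x / np.where(small, 1.0, ex - 1.0))
    ghk_gain = p.P_CaL * pref * state.d * state.f * state.fca
    I_CaL = ghk_gain * (Ca_SS * ex - 0.341 * p.Ca_o)
    dICaL_dCaSS = ghk_gain * ex
    I_to = p.g_to * state.xto * state.yto * (V - E_K)
    rkr = 1.0 / (1.0 + _safe_exp((V + 33.0) / 22.4))
    I_Kr = p.g_Kr * np.sqrt(p.K_o / 5.4) * state.xkr * rkr * (V - E_K)
    I_Ks = p.g_Ks * state.xks**2 * (V - E_Ks)

    a_k1 = 1.02 / (1.0 + _safe_exp(0.2385 * (V - E_K - 59.215)))
    b_k1 = (
        0.49124 * _safe_exp(0.08032 * (V - E_K + 5.476))
        + _safe_exp(0.06175 * (V - E_K - 594.31))
    ) / (1.0 + _safe_exp(-0.5143 * (V - E_K + 4.753)))
    I_K1 = p.g_K1 * np.sqrt(p.K_o / 5.4) * a_k1 / (a_k1 + b_k1) * (V - E_K)

    sigma = (np.exp(p.Na_o / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * _safe_exp(-0.1 * V / RTF) + 0.0365 * sigma * _safe_exp(-V / RTF))
    I_NaK = (
        p.I_NaK_max
        * f_nak
        * (p.K_o / (p.K_o + p.Km_Ko))
        / (1.0 + (p.Km_Nai / Na_i) ** 1.5)
    )

    # NCX, sarcolemmal pump and background Ca operate on the bulk cytosolic
    # calcium; only ICaL feeds the junctional cleft (the CICR trigger).
    ka = 1.0 / (1.0 + (p.Kd_act_ncx / Ca_cyto) ** 2)
    eg = _safe_exp(p.gamma_ncx * V / RTF)
    egm = _safe_exp((p.gamma_ncx - 1.0) * V / RTF)
    I_NCX = (
        ka
        * p.k_NCX
        * (eg * Na_i**3 * p.Ca_o - egm * p.Na_o**3 * Ca_cyto * p.alpha_ncx)
        / (
            (p.Km_Nai_ncx**3 + p.Na_o**3)
            * (p.Km_Ca_ncx + p.Ca_o)
            * (1.0 + p.ksat_ncx * egm)
        )
    )

    I_Cab = p.g_Cab * (V - E_Ca)
    I_pCa = p.I_pCa_max * Ca_cyto / (Ca_cyto + p.Km_pCa)
    I_Nab = p.g_Nab * (V - E_Na)

    # -- SR fluxes ---------------------------------------------------------
    p_open = release_open_fraction(Ca_SS, Ca_SR, p)
    J_rel = p.k_rel * state.ryr_w * p_open * (Ca_SR - Ca_SS)  # on SR volume
    up_f = (Ca_cyto / p.Km_up_f) ** p.H_up
    up_r = (Ca_SR / p.Km_up_r) ** p.H_up
    J_up = p.V_up_max * (up_f - up_r) / (1.0 + up_f + up_r)  # on cytosol volume
    J_leak = p.k_leak * (Ca_SR - Ca_cyto)  # on cytosol volume
    J_xfer = (Ca_SS - Ca_cyto) / p.tau_xfer  # on SS volume

    return {
        "I_Na": I_Na, "I_CaL": I_CaL, "I_to": I_to, "I_Kr": I_Kr, "I_Ks": I_Ks,
        "I_K1": I_K1, "I_NaK": I_NaK, "I_NCX": I_NCX, "I_Cab": I_Cab,
        "I_pCa": I_pCa, "I_Nab": I_Nab,
        "J_rel": J_rel, "J_up": J_up, "J_leak": J_leak, "J_xfer": J_xfer,
        "dICaL_dCaSS": dICaL_dCaSS, "p_open": p_open,
    }


def _buffer_factor(ca, pairs):
    denom = 1.0
    for b_tot, k_d in pairs:
        denom = denom + b_tot * k_d / (k_d + ca) ** 2
    return 1.0 / denom


def ryr_luminal_factor(Ca_SR, p: IonicParams):
    """Luminal sensitization f_lum >= 1: a loaded SR lowers the cleft-calcium
    half-activation of release to K_rel_ca / f_lum."""
    sr = np.asarray(Ca_SR, dtype=float) ** p.n_lum
    return 1.0 + p.a_lum * sr / (sr + p.ec50_sr**p.n_lum)


def release_open_fraction(Ca_SS, Ca_SR, p: IonicParams):
    """Instantaneous RyR open fraction h(Ca_SS; Ca_SR), a steep Hill function
    of cleft calcium with SR-load-dependent half-point."""
    k_eff = p.K_rel_ca / ryr_luminal_factor(Ca_SR, p)
    x = (np.asarray(Ca_SS, dtype=float) / k_eff) ** p.n_rel
    return x / (1.0 + x)


def ionic_core(state: IonicState, p: IonicParams, tnc_flux=0.0):
    """Non-gate derivatives and total membrane current (no validation).

    Returns ``(d, I_m, cur)`` where ``d`` holds the concentration
    derivatives, ``I_m`` the total membrane current and ``cur`` every
    individual current/flux; the voltage contribution is ``-I_m`` plus
    whatever stimulus/coupling the caller adds.  Shared by
    :func:`ionic_rhs` and the tissue stepper so both integration paths use
    identical equations.
    """
    cur = ionic_currents(state, p)

    I_m = (
        cur["I_Na"] + cur["I_CaL"] + cur["I_to"] + cur["I_Kr"] + cur["I_Ks"]
        + cur["I_K1"] + cur["I_NaK"] + cur["I_NCX"] + cur["I_Cab"]
        + cur["I_pCa"] + cur["I_Nab"]
    )

    d = {}

    # current -> concentration conversion: dC (mM/ms) = I_pA / (z * F * V_pL)
    j_ca_ss = -cur["I_CaL"] * p.C_m / (2.0 * FARADAY * p.V_SS)
    j_ca_cyto = -(cur["I_Cab"] + cur["I_pCa"] - 2.0 * cur["I_NCX"]) * p.C_m / (
        2.0 * FARADAY * p.V_cyto
    )

    beta_ss = _buffer_factor(state.Ca_SS, [(p.B_ss, p.K_ss)])
    beta_cyto = _buffer_factor(state.Ca_cyto, [(p.B_cmdn, p.K_cmdn), (p.B_srb, p.K_srb)])
    beta_sr = _buffer_factor(state.Ca_SR, [(p.B_csqn, p.K_csqn)])

    d["Ca_SS"] = beta_ss * (
        j_ca_ss + cur["J_rel"] * (p.V_SR / p.V_SS) - cur["J_xfer"]
    )
    d["Ca_cyto"] = beta_cyto * (
        j_ca_cyto + cur["J_xfer"] * (p.V_SS / p.V_cyto) + cur["J_leak"] - cur["J_up"] - tnc_flux
    )
    d["Ca_SR"] = beta_sr * (
        cur["J_up"] * (p.V_cyto / p.V_SR)
        - cur["J_leak"] * (p.V_cyto / p.V_SR)
        - cur["J_rel"]
    )
    d["Na_i"] = -(
        cur["I_Na"] + cur["I_Nab"] + 3.0 * cur["I_NaK"] + 3.0 * cur["I_NCX"]
    ) * p.C_m / (FARADAY * p.V_cyto)

    return d, I_m, cur


def ionic_rhs(
    state: IonicState,
    params: IonicParams,
    tnc_flux=0.0,
    I_stim=0.0,
    I_extra=0.0,
):
    """Time derivative of the ionic state plus total membrane current.

    Parameters
    ----------
    tnc_flux : mM/ms
        Net calcium flux *onto* troponin C supplied by the mechanics model
        (positive = calcium leaving the cytosol).  It replaces the ionic
        model's own TnC buffering term (strong coupling).
    I_stim, I_extra : pA/pF
        Stimulus and externally injected current densities (gap junction,
        fibroblast junction).  Positive values depolarize.

    Returns
    -------
    (dstate, I_m) : dict of derivatives keyed by state name, and the total
        membrane current density (pA/pF) entering the voltage equation.
    """
    state.validate_finite()
    tnc_flux = np.asarray(tnc_flux, dtype=float)
    if not np.all(np.isfinite(tnc_flux)):
        raise ValueError("non-finite value in input 'tnc_flux'")

    d, I_m, _ = ionic_core(state, params, tnc_flux)
    d["Vm"] = -I_m + I_stim + I_extra
    for g, (ginf, gtau) in gate_inf_tau(state.Vm, state.Ca_SS, state.Ca_SR, params, state.ryr_w).items():
        d[g] = (ginf - getattr(state, g)) / gtau
    return d, I_m


#: Paced-quiescent initial condition at Ca_o = 2.0 mM (model's own resting
#: values, frozen from a long unpaced relaxation of this implementation).
_REST = {
    "Vm": -82.674,
    "m": 2.274e-3, "h": 0.9747, "j": 0.9841,
    "d": 8.75e-6, "f": 0.9964, "fca": 0.99998,
    "xto": 4.01e-4, "yto": 0.9927,
    "xkr": 2.68e-4, "xks": 6.43e-3,
    "ryr_w": 1.0,
    "Ca_SS": 1.940e-4, "Ca_SR": 0.9407, "Ca_cyto": 1.932e-4,
    "Na_i": 8.430,
}


def resting_state(params: IonicParams | None = None, n: int = 1) -> IonicState:
    """Resting ionic state replicated over ``n`` CRUs."""
    return IonicState(**{k: np.full(n, v, dtype=float) for k, v in _REST.items()})
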