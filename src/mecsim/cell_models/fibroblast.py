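"""Active cardiac fibroblast membrane model.

An "active" fibroblast in the sense of carrying time- and voltage-dependent
membrane currents and its own ion concentration dynamics (five state
variables: membrane potential, two gates of the time-dependent K+ current,
intracellular Na+ and K+).  Four ionic currents are included: a time- and
voltage-dependent K+ current (I_Kv), an inward-rectifying K+ current (I_K1),
a Na+/K+ pump (I_NaK), and a background Na+ current (I_b,Na) balancing the
pump's sodium efflux.  The model rests near -50 mV, well depolarized relative
to a myocyte, so a coupled fibroblast drains depolarizing charge from the
myocyte whenever the myocyte is above the fibroblast potential (AP plateau,
DADs) — the charge-sink behavior whose consequences this package quantifies.

Junction convention: ``I_fgap = G_f_gap * (V_f - V_m)`` is the current
*into the myocyte* in pA (positive depolarizes the myocyte); the same current
with opposite sign enters the fibroblast voltage equation scaled by C_f, so
charge is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ..constants import RTF

__all__ = [
    "FibroblastParams",
    "FibroblastState",
    "fibroblast_rhs",
    "fibroblast_junction_current",
    "resting_fibroblast",
    "FIB_NAMES",
]

FIB_NAMES = ("V_f", "r_kv", "s_kv", "Na_f", "K_f")


@dataclass
class FibroblastParams:
    """Fibroblast membrane parameters (densities in nS/pF or pA/pF)."""

    C_f: float = 6.3          # pF
    g_Kv: float = 0.25        # nS/pF
    g_K1: float = 0.4822      # nS/pF
    g_bNa: float = 0.0095     # nS/pF
    I_NaK_max: float = 2.002  # pA/pF
    Km_K: float = 1.0         # mM
    Km_Na: float = 11.0       # mM
    V_rev_NaK: float = -68.0  # mV
    B_NaK: float = -150.0     # mV, pump voltage-dependence offset
    G_f_gap: float = 3.0      # nS, myocyte-fibroblast junction conductance
    Na_o: float = 140.0       # mM
    K_o: float = 5.4          # mM

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("V_rev_NaK", "B_NaK"):
                continue
            if v < 0:
                raise ValueError(f"FibroblastParams.{f.name} must be >= 0")


@dataclass
class FibroblastState:
    """Fibroblast potential (mV), I_Kv gates, and ion concentrations (mM)."""

    V_f: np.ndarray
    r_kv: np.ndarray
    s_kv: np.ndarray
    Na_f: np.ndarray
    K_f: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in FIB_NAMES}

    def validate(self) -> None:
        for n in FIB_NAMES:
            v = np.asarray(getattr(self, n))
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite value in fibroblast variable '{n}'")
        for n in ("r_kv", "s_kv"):
            v = np.asarray(getattr(self, n))
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError(f"fibroblast gate '{n}' outside [0, 1]")
        for n in ("Na_f", "K_f"):
            if np.any(np.asarray(getattr(self, n)) <= 0):
                raise ValueError(f"fibroblast concentration '{n}' not positive")


def _exp(x):
    return np.exp(np.clip(x, -80.0, 80.0))


def fibroblast_gates(V_f):
    """(inf, tau) pairs for the I_Kv activation r and inactivation s gates."""
    V = np.asarray(V_f, dtype=float)
    r_inf = 1.0 / (1.0 + _exp(-(V + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * _exp(-(((V + 20.0) / 25.9) ** 2))
    s_inf = 1.0 / (1.0 + _exp((V + 23.0) / 2.7))
    tau_s = 1574.0 + 5268.0 * _exp(-(((V + 23.0) / 22.7) ** 2))
    return {"r_kv": (r_inf, tau_r), "s_kv": (s_inf, tau_s)}


def fibroblast_currents(state: FibroblastState, p: FibroblastParams):
    """Current densities (pA/pF) of the four fibroblast membrane currents."""
    V = np.asarray(state.V_f, dtype=float)
    E_K = RTF * np.log(p.K_o / state.K_f)
    E_Na = RTF * np.log(p.Na_o / state.Na_f)

    I_Kv = p.g_Kv * state.r_kv * state.s_kv * (V - E_K)

    a_k1 = 0.1 / (1.0 + _exp(0.06 * (V - E_K - 200.0)))
    b_k1 = (
        3.0 * _exp(2.0e-4 * (V - E_K + 100.0)) + _exp(0.1 * (V - E_K - 10.0))
    ) / (1.0 + _exp(-0.5 * (V - E_K)))
    I_K1 = p.g_K1 * a_k1 / (a_k1 + b_k1) * (V - E_K)

    I_NaK = (
        p.I_NaK_max
        * (p.K_o / (p.K_o + p.Km_K))
        * (state.Na_f**1.5 / (state.Na_f**1.5 + p.Km_Na**1.5))
        * (V - p.V_rev_NaK)
        / (V - p.B_NaK)
    )
    I_bNa = p.g_bNa * (V - E_Na)
    return {"I_Kv": I_Kv, "I_K1": I_K1, "I_NaK": I_NaK, "I_bNa": I_bNa}


def fibroblast_junction_current(V_f, V_myocyte, g_f_gap):
    """Junctional current into the myocyte, pA: G * (V_f - V_m).

    Antisymmetric under exchange of the two potentials; a fibroblast below
    the myocyte potential drains depolarizing charge from the myocyte.
    """
    return np.asarray(g_f_gap, dtype=float) * (np.asarray(V_f, dtype=float) - np.asarray(V_myocyte, dtype=float))


def fibroblast_rhs(state: FibroblastState, params: FibroblastParams, V_myocyte):
    """Fibroblast state derivative plus junctional current into the myocyte.

    Returns ``(dstate, I_junc_pA)``.  The junction term enters dV_f/dt with
    opposite sign scaled by C_f, conserving charge with the myocyte side.
    """
    state.validate()
    p = params
    cur = fibroblast_currents(state, p)
    I_ion = cur["I_Kv"] + cur["I_K1"] + cur["I_NaK"] + cur["I_bNa"]
    I_junc = fibroblast_junction_current(state.V_f, V_myocyte, p.G_f_gap)

    d = {"V_f": -I_ion - I_junc / p.C_f}
    for g, (ginf, gtau) in fibroblast_gates(state.V_f).items():
        d[g] = (ginf - getattr(state, g)) / gtau

    # concentration change: dC (mM/ms) = I_pA / (z F V); effective fibroblast
    # volume from a ~1 pF/um^2, surface-to-volume-based estimate
    vol = 1.3  # pL
    from ..constants import FARADAY

    d["Na_f"] = -(cur["I_bNa"] + 3.0 * cur["I_NaK"]) * p.C_f / (FARADAY * vol)
    d["K_f"] = -(cur["I_Kv"] + cur["I_K1"] - 2.0 * cur["I_NaK"]) * p.C_f / (FARADAY * vol)
    return d, I_junc


def resting_fibroblast(n: int = 1) -> FibroblastState:
    """Fibroblast resting state (near the ~-50 mV published resting potential)."""
    return FibroblastState(
        V_f=np.full(n, -49.6),
        r_kv=np.full(n, 0.06),
        s_kv=np.full(n, 1.0),
        Na_f=np.full(n, 8.5),
        K_f=np.full(n, 140.0),
    )
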