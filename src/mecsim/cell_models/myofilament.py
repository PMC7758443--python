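"""Sarcomere mechanics with strain-rate-dependent troponin-C calcium kinetics.

A compact crossbridge-cycling sarcomere model in the tradition of
mean-field myofilament models: a single regulatory TnC calcium-binding pool
gates cooperative crossbridge attachment, active force follows attached
crossbridges scaled by a filament-overlap function of sarcomere length, and
length dynamics track a commanded length (the stretch protocols are
length-controlled; the isometric limit holds length fixed).

The mechano-electric coupling lives here: both TnC rates are modulated
multiplicatively by an exponential of the sarcomere strain rate,

    kon = kon0 * exp(alpha_on * dSL/dt / SL_rest)
    koff = koff0 * exp(alpha_off * dSL/dt / SL_rest)

so that stretch (positive strain rate) promotes calcium dissociation from the
myofilaments (alpha_off > 0) and disfavors binding (alpha_on < 0).  Crossbridge
detachment carries the same exponential strain-rate dependence.  Because exp is
convex, even a zero-mean cyclic strain raises the *mean* off-rate, and the
phase of stretch relative to the calcium transient determines how much calcium
is shed from TnC into the cytosol — the substrate for SR overload and
mechanically triggered calcium waves.  The net calcium flux onto TnC is
returned so the ionic model can use it in place of its own TnC buffer term
(strong coupling).

Attached crossbridges reduce the TnC off-rate (thin-filament cooperativity),
which is how the crossbridge strain dependence feeds back onto calcium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "SarcomereState",
    "StrainCouplingParams",
    "MyofilamentParams",
    "strain_modulated_rates",
    "myofilament_rhs",
    "resting_sarcomere",
]

logger = logging.getLogger(__name__)

MECH_NAMES = ("SL", "tnc_ca", "xb")


@dataclass
class StrainCouplingParams:
    """Baseline TnC kinetics and exponential strain-rate sensitivities.

    Units: rates 1/ms (kon0 per mM); alphas multiply a strain rate in 1/ms,
    so they carry units of ms.  At zero strain rate the modulated rates equal
    the baselines exactly.  Alpha defaults are a calibration: chosen so that a
    10% stretch applied over 100 ms raises diastolic cytosolic calcium by
    more than 5% (see docs/methods.md).
    """

    kon0: float = 50.0        # 1/(mM ms)
    koff0: float = 0.025      # 1/ms
    alpha_on: float = 0.0     # ms (dissociation-only default)
    alpha_off: float = 1500.0  # ms
    alpha_xb: float = 500.0   # ms, crossbridge detachment strain constant

    def __post_init__(self) -> None:
        if not (self.kon0 > 0 and self.koff0 > 0):
            raise ValueError("kon0 and koff0 must be strictly positive")


def strain_modulated_rates(coupling: StrainCouplingParams, strain_rate):
    """Effective (kon, koff) at the given strain rate (1/ms).

    Total function: finite for any finite strain rate, strictly positive,
    continuous and monotone in strain rate for nonzero alphas.
    """
    sr = np.asarray(strain_rate, dtype=float)
    kon = coupling.kon0 * np.exp(np.clip(coupling.alpha_on * sr, -40.0, 40.0))
    koff = coupling.koff0 * np.exp(np.clip(coupling.alpha_off * sr, -40.0, 40.0))
    return kon, koff


@dataclass
class MyofilamentParams:
    """Crossbridge cycling, buffering capacity and length-control constants."""

    B_tnc: float = 0.07       # mM, total TnC regulatory sites
    f_xb: float = 0.05        # 1/ms, attachment rate scale
    g_xb: float = 0.012       # 1/ms, baseline detachment rate
    n_coop: float = 3.0       # cooperativity of activation by TnC occupancy
    xb_coop: float = 0.5      # fractional koff reduction at full attachment
    tau_track: float = 4.0    # ms, relaxation toward commanded length
    SL_min: float = 1.4       # um, validity range of the overlap function
    SL_max: float = 2.4
    SL_rest: float = 1.89     # um, reference resting length

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"MyofilamentParams.{f.name} must be > 0")


@dataclass
class SarcomereState:
    """Sarcomere length (um), TnC occupancy and attached crossbridge fraction."""

    SL: np.ndarray
    tnc_ca: np.ndarray
    xb: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in MECH_NAMES}

    def validate(self, tol: float = 1e-6) -> None:
        for n in MECH_NAMES:
            v = np.asarray(getattr(self, n))
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite value in state variable '{n}'")
        if np.any(np.asarray(self.SL) <= 0):
            raise ValueError("SL must be strictly positive")
        for n in ("tnc_ca", "xb"):
            v = np.asarray(getattr(self, n))
            if np.any(v < -tol) or np.any(v > 1 + tol):
                raise ValueError(f"occupancy '{n}' outside [0, 1]")


def overlap(SL, p: MyofilamentParams):
    """Normalized thick/thin filament overlap, a hat function of SL."""
    SL = np.asarray(SL, dtype=float)
    return np.clip(np.minimum((SL - p.SL_min) / 0.6, (p.SL_max + 0.1 - SL) / 0.4), 0.0, 1.0)


def myofilament_rhs(
    state: SarcomereState,
    ca_cyto,
    strain_rate,
    coupling: StrainCouplingParams,
    params: MyofilamentParams | None = None,
    sl_cmd=None,
):
    """Sarcomere state derivative, active force, and the TnC calcium flux.

    Parameters
    ----------
    ca_cyto : mM
        Local cytosolic free calcium.
    strain_rate : 1/ms
        Realized fractional length-change rate dSL/dt / SL_rest.
    sl_cmd : um, optional
        Commanded sarcomere length; defaults to the current length
        (isometric).  The returned ``SL`` derivative is the *isotonic* rate
        toward the command; inter-sarcomere coupling is applied downstream.

    Returns
    -------
    (dstate, force, j_tnc) : derivative dict, normalized active force, and
        the net calcium flux onto TnC in mM/ms (positive = leaving cytosol).
    """
    if params is None:
        params = MyofilamentParams()
    state.validate()
    ca = np.asarray(ca_cyto, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca_cyto must be strictly positive")

    SL = np.asarray(state.SL, dtype=float)
    out_of_range = (SL < params.SL_min) | (SL > params.SL_max)
    if np.any(out_of_range):
        logger.warning(
            "sarcomere length outside validity range [%g, %g] um; overlap clamped",
            params.SL_min,
            params.SL_max,
        )

    kon, koff0 = strain_modulated_rates(coupling, strain_rate)
    koff = koff0 * (1.0 - params.xb_coop * np.asarray(state.xb))

    dtnc = kon * ca * (1.0 - state.tnc_ca) - koff * state.tnc_ca
    j_tnc = params.B_tnc * dtnc

    act = np.asarray(state.tnc_ca) ** params.n_coop
    g_eff = params.g_xb * np.exp(np.clip(coupling.alpha_xb * np.asarray(strain_rate), -40.0, 40.0))
    dxb = params.f_xb * act * (1.0 - state.xb) - g_eff * state.xb
    force = np.asarray(state.xb) * overlap(SL, params)

    cmd = SL if sl_cmd is None else np.asarray(sl_cmd, dtype=float)
    dsl = (cmd - SL) / params.tau_track

    return {"SL": dsl, "tnc_ca": dtnc, "xb": dxb}, force, j_tnc


def resting_sarcomere(n: int = 1, SL_rest=1.89) -> SarcomereState:
    """Relaxed sarcomere at the given resting length(s)."""
    sl = np.full(n, SL_rest, dtype=float) if np.isscalar(SL_rest) else np.asarray(SL_rest, dtype=float)
    return SarcomereState(
        SL=sl.copy(),
        tnc_ca=np.full_like(sl, 0.288),
        xb=np.full_like(sl, 0.090),
    )
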