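"""Assembled electromechanical tissue model.

``TissueModel`` binds the three cell models to the fiber stencils, gap
junctions, fibroblast attachments and the stretch protocol, and exposes two
integration surfaces over one shared set of equations:

* :meth:`rhs` — the full right-hand side ``f(t, y)`` on the packed state
  vector, bit-deterministic given ``(t, y)``, suitable for scipy's adaptive
  stiff solvers on small problems and for analytic oracles;
* :meth:`step` — one fixed step of the production operator-splitting scheme
  (exponential/Rush-Larsen gate updates, explicit concentrations and
  mechanics, implicit tridiagonal solve for the voltage coupling, whose
  1e-5 ms time constant is far too stiff for any explicit step).

Voltage coupling (within-cell conduction and inter-cell gap junctions) is a
single global tridiagonal operator A over all CRUs in chain order:
``dVm/dt = local + A Vm`` with the junction entries already divided by the
per-CRU capacitance.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from ..cell_models.fibroblast import (
    FIB_NAMES,
    FibroblastState,
    fibroblast_currents,
    fibroblast_gates,
)
from ..cell_models.ionic import (
    GATE_NAMES,
    IonicParams,
    IonicState,
    gate_inf_tau,
    ionic_core,
)
from ..cell_models.myofilament import (
    MyofilamentParams,
    SarcomereState,
    StrainCouplingParams,
    myofilament_rhs,
    overlap,
)
from ..fiber import ConductionParams, DiffusionParams
from ..protocols import StretchProtocol, stretch_scaling
from .state import FIELDS, StateLayout

__all__ = ["TissueModel"]

_CA_FIELDS = (("Ca_SS", "tau_SS"), ("Ca_SR", "tau_SR"), ("Ca_cyto", "tau_cyto"))


class TissueModel:
    def __init__(
        self,
        spec,
        ionic_params: IonicParams | None = None,
        myof_params: MyofilamentParams | None = None,
        coupling: StrainCouplingParams | None = None,
        diffusion: DiffusionParams | None = None,
        conduction: ConductionParams | None = None,
        stretch: StretchProtocol | None = None,
        sarcomere_mode: str | None = None,
        stim_onsets=(0.0,),
        stretch_until: float = np.inf,
        ca_diffusion: bool = True,
    ):
        self.spec = spec
        self.ionic = ionic_params or IonicParams()
        self.myof = myof_params or MyofilamentParams()
        self.coupling = coupling or StrainCouplingParams()
        self.diffusion = diffusion or DiffusionParams()
        self.conduction = conduction or ConductionParams()
        self.stretch = stretch
        self.mode = sarcomere_mode or getattr(spec, "sarcomere_mode", "relaxed")
        if self.mode not in ("verbatim", "relaxed"):
            raise ValueError(f"unknown sarcomere coupling mode: {self.mode!r}")
        self.kappa = 0.5
        self.stim_onsets = np.sort(np.atleast_1d(np.asarray(stim_onsets, dtype=float)))
        self.stretch_until = stretch_until
        self.ca_diffusion = ca_diffusion

        self.layout = StateLayout(spec)
        n = self.layout.n_cru_total
        self.resting_SL = np.concatenate([g.resting_SL for g in spec.geometries])
        self.positions = np.concatenate(
            [g.positions for g in spec.geometries]
        )  # per-cell coordinates; analysis uses per-cell views
        self.cm_cru = np.concatenate(
            [np.full(g.n_cru, self.ionic.C_m / g.n_cru) for g in spec.geometries]
        )

        # fibroblast attachment arrays
        nf = self.layout.n_fib
        self.fib_gidx = np.zeros(nf, dtype=int)
        self.fib_g = np.zeros(nf)
        self.fib_cf = np.zeros(nf)
        self.fib_params = [fb.params for fb in spec.fibroblasts]
        for k, fb in enumerate(spec.fibroblasts):
            s, _ = self.layout.cell_bounds[fb.cell]
            self.fib_gidx[k] = s + fb.cru - 1
            self.fib_g[k] = fb.params.G_f_gap
            self.fib_cf[k] = fb.params.C_f

        self._build_vm_operator()
        self._stim_idx = self.layout.cell_bounds[0][0] + self.conduction.stim_target - 1
        self._m_cache: tuple[float, np.ndarray] | None = None

    # ------------------------------------------------------------------
    def _build_vm_operator(self) -> None:
        n = self.layout.n_cru_total
        diag = np.zeros(n)
        upper = np.zeros(n - 1)  # coupling of i to i+1
        lower = np.zeros(n - 1)  # coupling of i+1 to i
        inv_tau = 1.0 / self.conduction.tau_Vm
        for s, e in self.layout.cell_bounds:
            for i in range(s, e - 1):
                diag[i] -= inv_tau
                diag[i + 1] -= inv_tau
                upper[i] += inv_tau
                lower[i] += inv_tau
        for j in getattr(self.spec, "junctions", []):
            u = self.layout.cell_bounds[j.upstream][1] - 1
            v = self.layout.cell_bounds[j.downstream][0]
            if v != u + 1:
                raise ValueError("junctions must connect adjacent cells in chain order")
            gu = j.g_gap / self.cm_cru[u]
            gv = j.g_gap / self.cm_cru[v]
            if getattr(self.spec, "verbatim_junction_signs", False):
                # verbatim orientation: +I on upstream, -I on downstream
                diag[u] += gu
                upper[u] -= gu
                diag[v] += gv
                lower[u] -= gv
            else:
                diag[u] -= gu
                upper[u] += gu
                diag[v] -= gv
                lower[u] += gv
        self._vm_diag, self._vm_upper, self._vm_lower = diag, upper, lower

    def _vm_matvec(self, v: np.ndarray) -> np.ndarray:
        out = self._vm_diag * v
        out[:-1] += self._vm_upper * v[1:]
        out[1:] += self._vm_lower * v[:-1]
        return out

    def _vm_banded(self, dt: float) -> np.ndarray:
        """Banded form of M = I - dt*A for solve_banded."""
        if self._m_cache is not None and self._m_cache[0] == dt:
            return self._m_cache[1]
        n = self.layout.n_cru_total
        ab = np.zeros((3, n))
        ab[0, 1:] = -dt * self._vm_upper
        ab[1, :] = 1.0 - dt * self._vm_diag
        ab[2, :-1] = -dt * self._vm_lower
        self._m_cache = (dt, ab)
        return ab

    # ------------------------------------------------------------------
    def initial_state(self) -> dict[str, np.ndarray]:
        from ..cell_models.fibroblast import resting_fibroblast
        from ..cell_models.ionic import resting_state
        from ..cell_models.myofilament import resting_sarcomere

        n = self.layout.n_cru_total
        s: dict[str, np.ndarray] = {}
        s.update(resting_state(self.ionic, n).as_dict())
        s.update(resting_sarcomere(n, self.resting_SL).as_dict())
        fib = resting_fibroblast(self.layout.n_fib)
        s.update(fib.as_dict())
        return {k: np.array(v, dtype=float) for k, v in s.items()}

    def pack(self, s: dict[str, np.ndarray]) -> np.ndarray:
        return self.layout.pack(s)

    # ------------------------------------------------------------------
    def _stim_active(self, t: float) -> bool:
        k = np.searchsorted(self.stim_onsets, t, side="right") - 1
        return k >= 0 and t < self.stim_onsets[k] + self.conduction.stim_duration

    def sl_command(self, t: float) -> np.ndarray:
        if self.stretch is None or t >= self.stretch_until:
            return self.resting_SL
        scale, _ = stretch_scaling(self.stretch, np.mod(t, self.stretch.cycle_length))
        return self.resting_SL * scale

    def _coupled_sl_rates(self, iso: np.ndarray) -> np.ndarray:
        """Inter-sarcomere coupling within each cell plus the inter-cell
        boundary forms across mechanical junctions."""
        from ..fiber import sarcomere_coupling

        out = np.empty_like(iso)
        for s, e in self.layout.cell_bounds:
            out[s:e] = sarcomere_coupling(iso[s:e], self.mode, self.kappa)
        for j in getattr(self.spec, "junctions", []):
            u = self.layout.cell_bounds[j.upstream][1] - 1
            v = self.layout.cell_bounds[j.downstream][0]
            if self.mode == "verbatim":
                # interior-like zero-sum form at the junction; the
                # single-weighted boundary form has a positive row
                # sum and is dynamically unstable under length tracking
                out[u] = 2.0 * iso[u] - iso[u - 1] - iso[v]
                out[v] = 2.0 * iso[v] - iso[v + 1] - iso[u]
            else:
                out[u] = iso[u] + self.kappa * (0.5 * (iso[u - 1] + iso[v]) - iso[u])
                out[v] = iso[v] + self.kappa * (0.5 * (iso[v + 1] + iso[u]) - iso[v])
        return out

    # ------------------------------------------------------------------
    def _eval(self, t: float, s: dict[str, np.ndarray]):
        """Everything both integrators need at (t, state)."""
        p = self.ionic
        ion = IonicState(**{k: s[k] for k in IonicState.__dataclass_fields__})
        mech = SarcomereState(SL=s["SL"], tnc_ca=s["tnc_ca"], xb=s["xb"])

        cmd = self.sl_command(t)
        iso = (cmd - s["SL"]) / self.myof.tau_track
        dsl = self._coupled_sl_rates(iso)
        strain_rate = dsl / self.resting_SL

        dmech, force, j_tnc = myofilament_rhs(
            mech, np.maximum(s["Ca_cyto"], 1e-9), strain_rate, self.coupling, self.myof, sl_cmd=cmd
        )
        dmech["SL"] = dsl

        d, I_m, cur = ionic_core(ion, p, tnc_flux=j_tnc)

        vm_local = -I_m
        if self._stim_active(t):
            vm_local = vm_local.copy()
            vm_local[self._stim_idx] += self.conduction.stim_amplitude

        # fibroblasts
        dfib: dict[str, np.ndarray] = {}
        if self.layout.n_fib:
            fib = FibroblastState(**{k: s[k] for k in FIB_NAMES})
            fcur = fibroblast_currents(fib, self.fib_params[0])
            I_ion_f = fcur["I_Kv"] + fcur["I_K1"] + fcur["I_NaK"] + fcur["I_bNa"]
            I_junc = self.fib_g * (s["V_f"] - s["Vm"][self.fib_gidx])
            vm_local = vm_local.copy()
            np.add.at(vm_local, self.fib_gidx, I_junc / self.cm_cru[self.fib_gidx])
            dfib["V_f"] = -I_ion_f - I_junc / self.fib_cf
            from ..constants import FARADAY

            vol = 1.3
            dfib["Na_f"] = -(fcur["I_bNa"] + 3.0 * fcur["I_NaK"]) * self.fib_cf / (FARADAY * vol)
            dfib["K_f"] = -(fcur["I_Kv"] + fcur["I_K1"] - 2.0 * fcur["I_NaK"]) * self.fib_cf / (FARADAY * vol)

        # calcium diffusion between adjacent CRUs, per compartment
        dca_coupling: dict[str, np.ndarray] = {}
        if self.ca_diffusion:
            for field, tau_name in _CA_FIELDS:
                tau = getattr(self.diffusion, tau_name)
                term = np.zeros_like(s[field])
                if np.isfinite(tau):
                    for cs, ce in self.layout.cell_bounds:
                        v = s[field][cs:ce]
                        term[cs + 1 : ce - 1] = (v[2:] + v[:-2] - 2.0 * v[1:-1]) / tau
                        term[cs] = (v[1] - v[0]) / tau
                        term[ce - 1] = (v[-2] - v[-1]) / tau
                dca_coupling[field] = term

        return {
            "d": d,
            "cur": cur,
            "dmech": dmech,
            "dfib": dfib,
            "vm_local": vm_local,
            "dca_coupling": dca_coupling,
            "force": force,
            "I_m": I_m,
            "strain_rate": strain_rate,
        }

    # ------------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Full derivative of the packed state vector (for adaptive solvers
        and analytic oracles).  Deterministic given (t, y)."""
        s = self.layout.unpack(np.asarray(y, dtype=float))
        ev = self._eval(t, s)
        dy = np.zeros(self.layout.size)
        out = self.layout.unpack(dy)

        out["Vm"][:] = ev["vm_local"] + self._vm_matvec(s["Vm"])
        inf_tau = gate_inf_tau(s["Vm"], s["Ca_SS"], s["Ca_SR"], self.ionic, s["ryr_w"])
        for g in GATE_NAMES:
            ginf, gtau = inf_tau[g]
            out[g][:] = (ginf - s[g]) / gtau
        out["Na_i"][:] = ev["d"]["Na_i"]
        for field, _ in _CA_FIELDS:
            out[field][:] = ev["d"][field] + ev["dca_coupling"].get(field, 0.0)
        for k in ("SL", "tnc_ca", "xb"):
            out[k][:] = ev["dmech"][k]
        if self.layout.n_fib:
            fg = fibroblast_gates(s["V_f"])
            for g in ("r_kv", "s_kv"):
                ginf, gtau = fg[g]
                out[g][:] = (ginf - s[g]) / gtau
            for k in ("V_f", "Na_f", "K_f"):
                out[k][:] = ev["dfib"][k]
        return dy

    # ------------------------------------------------------------------
    def step(self, t: float, s: dict[str, np.ndarray], dt: float) -> None:
        """One operator-splitting step, updating ``s`` in place."""
        ev = self._eval(t, s)

        # Rush-Larsen (exact exponential relaxation) for inf/tau gates
        inf_tau = gate_inf_tau(s["Vm"], s["Ca_SS"], s["Ca_SR"], self.ionic, s["ryr_w"])
        for g in GATE_NAMES:
            ginf, gtau = inf_tau[g]
            s[g][:] = ginf + (s[g] - ginf) * np.exp(-dt / gtau)

        # explicit update for slow concentrations and mechanics;
        # subsarcolemmal and SR calcium are updated semi-implicitly because
        # an open release channel couples them far faster than any usable dt
        s["Na_i"] += dt * ev["d"]["Na_i"]
        self._ca_release_update(s, ev, dt)
        s["Ca_cyto"] += dt * (ev["d"]["Ca_cyto"] + ev["dca_coupling"].get("Ca_cyto", 0.0))
        np.clip(s["Ca_cyto"], 1e-8, None, out=s["Ca_cyto"])
        s["SL"] += dt * ev["dmech"]["SL"]
        for k in ("tnc_ca", "xb"):
            np.clip(s[k] + dt * ev["dmech"][k], 0.0, 1.0, out=s[k])

        # voltage: explicit local currents, implicit coupling operator
        vstar = s["Vm"] + dt * ev["vm_local"]
        s["Vm"][:] = solve_banded((1, 1), self._vm_banded(dt), vstar)

        if self.layout.n_fib:
            fg = fibroblast_gates(s["V_f"])
            for g in ("r_kv", "s_kv"):
                ginf, gtau = fg[g]
                s[g][:] = ginf + (s[g] - ginf) * np.exp(-dt / gtau)
            for k in ("V_f", "Na_f", "K_f"):
                s[k] += dt * ev["dfib"][k]

    # ------------------------------------------------------------------
    def _ca_release_update(self, s: dict[str, np.ndarray], ev: dict, dt: float) -> None:
        """Exponential (semi-implicit) update of Ca_SS and Ca_SR.

        Both balances are linear in their own concentration once the gates,
        the GHK slope and the opposite compartment are frozen over the step:
        dC/dt = beta * (A - B*C) integrates exactly to
        C -> A/B + (C - A/B) exp(-beta*B*dt).
        """
        from ..cell_models.ionic import _buffer_factor

        p = self.ionic
        cur = ev["cur"]
        ca_ss, ca_sr, ca_cy = s["Ca_SS"], s["Ca_SR"], s["Ca_cyto"]
        k_conv = p.C_m / (2.0 * 96485.0 * p.V_SS)
        g_rel = p.k_rel * s["ryr_w"] * cur["p_open"]

        # SS: ICaL (linear in Ca_SS through the GHK numerator), release,
        # transfer to cytosol, plus the frozen inter-CRU diffusion term
        b_ical = cur["dICaL_dCaSS"] * k_conv
        a_ical = -(cur["I_CaL"] - cur["dICaL_dCaSS"] * ca_ss) * k_conv
        A = a_ical + g_rel * (p.V_SR / p.V_SS) * ca_sr + ca_cy / p.tau_xfer
        A = A + ev["dca_coupling"].get("Ca_SS", 0.0)
        B = b_ical + g_rel * (p.V_SR / p.V_SS) + 1.0 / p.tau_xfer
        beta_ss = _buffer_factor(ca_ss, [(p.B_ss, p.K_ss)])
        inf = A / B
        ss_new = inf + (ca_ss - inf) * np.exp(-beta_ss * B * dt)

        # SR: release out (linear), uptake and leak frozen
        C = cur["J_up"] * (p.V_cyto / p.V_SR) - cur["J_leak"] * (p.V_cyto / p.V_SR) + g_rel * ca_ss
        C = C + ev["dca_coupling"].get("Ca_SR", 0.0)
        D = g_rel
        beta_sr = _buffer_factor(ca_sr, [(p.B_csqn, p.K_csqn)])
        with np.errstate(divide="ignore", invalid="ignore"):
            inf_sr = np.where(D > 0, C / np.where(D > 0, D, 1.0), 0.0)
        sr_new = np.where(
            D * dt > 1e-12,
            inf_sr + (ca_sr - inf_sr) * np.exp(-beta_sr * D * dt),
            ca_sr + dt * beta_sr * C,
        )
        s["Ca_SS"][:] = np.clip(ss_new, 1e-8, None)
        s["Ca_SR"][:] = np.clip(sr_new, 1e-8, None)

    def kernel_args(self, dt: float) -> dict:
        """Static argument set for the compiled step kernel at step size dt."""
        from ..cell_models.fibroblast import FibroblastParams
        from . import kernel as K

        n = self.layout.n_cru_total
        dl = np.zeros(n)
        du = np.zeros(n)
        dd = 1.0 - dt * self._vm_diag
        du[:-1] = -dt * self._vm_upper
        dl[1:] = -dt * self._vm_lower
        mech_ju = []
        mech_jv = []
        for j in getattr(self.spec, "junctions", []):
            mech_ju.append(self.layout.cell_bounds[j.upstream][1] - 1)
            mech_jv.append(self.layout.cell_bounds[j.downstream][0])
        code = {"I": 0, "H": 1, "S": 2, "P": 3}[self.stretch.pattern] if self.stretch else 0
        sp = np.zeros(8)
        if self.stretch is not None:
            st = self.stretch
            sp[:] = [st.cycle_length, st.h_compression, st.s_amplitude, st.p_plateau,
                     st.p_rise_tau, st.p_decay_tau, st.p_off_frac, st.phase_offset]
        fp = K.fib_vector(self.fib_params[0] if self.fib_params else FibroblastParams())
        return {
            "ip": K.ion_vector(self.ionic),
            "mp": K.myo_vector(self.myof, self.coupling),
            "cell_starts": np.array([b[0] for b in self.layout.cell_bounds], dtype=np.int64),
            "cell_ends": np.array([b[1] for b in self.layout.cell_bounds], dtype=np.int64),
            "resting_SL": self.resting_SL,
            "cm_cru": self.cm_cru,
            "dl": dl, "dd": dd, "du": du,
            "stim_idx": int(self._stim_idx),
            "stim_amp": float(self.conduction.stim_amplitude),
            "stim_dur": float(self.conduction.stim_duration),
            "stretch_code": code,
            "stretch_p": sp,
            "tau_ss": self.diffusion.tau_SS if self.ca_diffusion else np.inf,
            "tau_sr": self.diffusion.tau_SR if self.ca_diffusion else np.inf,
            "tau_cyto": self.diffusion.tau_cyto if self.ca_diffusion else np.inf,
            "mode_relaxed": 0 if self.mode == "verbatim" else 1,
            "kappa": self.kappa,
            "mech_ju": np.asarray(mech_ju, dtype=np.int64),
            "mech_jv": np.asarray(mech_jv, dtype=np.int64),
            "fib_gidx": self.fib_gidx.astype(np.int64),
            "fib_g": self.fib_g,
            "fp": fp,
        }

    def force(self, s: dict[str, np.ndarray]) -> np.ndarray:
        return np.asarray(s["xb"]) * overlap(s["SL"], self.myof)

    def metadata(self) -> dict:
        return {
            **self.layout.metadata(),
            "sarcomere_mode": self.mode,
            "verbatim_junction_signs": bool(getattr(self.spec, "verbatim_junction_signs", False)),
            "Ca_o": self.ionic.Ca_o,
            "remodeled": self.ionic.remodeled,
            "stretch_pattern": self.stretch.pattern if self.stretch else None,
            "seeds": dict(getattr(self.spec, "seeds", {}) or {}),
        }
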