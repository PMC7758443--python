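"""Unit tests for the three 0D cell models."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from mecsim.cell_models.fibroblast import (
    FibroblastParams,
    fibroblast_junction_current,
    fibroblast_rhs,
    resting_fibroblast,
)
from mecsim.cell_models.ionic import (
    IonicParams,
    IonicState,
    RemodelingSpec,
    apply_remodeling,
    ionic_rhs,
    resting_state,
)
from mecsim.cell_models.myofilament import (
    MyofilamentParams,
    SarcomereState,
    StrainCouplingParams,
    myofilament_rhs,
    resting_sarcomere,
    strain_modulated_rates,
)
from mecsim.engine.zero_d import run_cell


# ----------------------------------------------------------------------
# conductance remodeling
# ----------------------------------------------------------------------
class TestRemodeling:
    def test_default_factors_applied(self):
        p = IonicParams(g_to=0.06)
        q = apply_remodeling(p)
        assert q.g_to == pytest.approx(0.078)
        assert q.g_Ks == pytest.approx(p.g_Ks * 0.85)
        assert q.g_K1 == pytest.approx(p.g_K1 * 0.70)
        assert q.I_NaK_max == pytest.approx(p.I_NaK_max * 1.15)
        # original untouched
        assert p.g_to == 0.06 and not p.remodeled

    def test_identity_spec_changes_nothing(self):
        p = IonicParams()
        q = apply_remodeling(p, RemodelingSpec(1.0, 1.0, 1.0, 1.0))
        assert q.g_to == p.g_to and q.g_K1 == p.g_K1 and not q.remodeled

    def test_double_application_rejected(self):
        q = apply_remodeling(IonicParams())
        with pytest.raises(ValueError, match="already-remodeled"):
            apply_remodeling(q)


# ----------------------------------------------------------------------
# ionic CRU model
# ----------------------------------------------------------------------
class TestIonic:
    def test_zero_sources_give_zero_derivative(self):
        """With every conductance, pump and flux maximum set to zero the
        state is exactly stationary."""
        p = IonicParams()
        zeroed = {
            f: 0.0
            for f in (
                "g_Na P_CaL g_to g_Kr g_Ks g_K1 g_Cab g_Nab I_NaK_max k_NCX "
                "I_pCa_max k_rel V_up_max k_leak".split()
            )
        }
        p = replace(p, **zeroed)
        s = resting_state(p)
        s.Ca_SS[:] = s.Ca_cyto[:]  # no transfer gradient
        d, i_m = ionic_rhs(s, p, tnc_flux=0.0)
        assert np.allclose(i_m, 0.0)
        for name in ("Vm", "Ca_SS", "Ca_SR", "Ca_cyto", "Na_i"):
            assert np.allclose(d[name], 0.0), name

    def test_nonfinite_state_rejected_with_name(self):
        s = resting_state(IonicParams())
        s.Ca_SR[:] = np.nan
        with pytest.raises(ValueError, match="Ca_SR"):
            ionic_rhs(s, IonicParams())

    def test_resting_state_is_quiescent(self):
        """Unstimulated cell drifts less than 1 mV over a second and keeps
        all gates in [0, 1] and concentrations positive."""
        r = run_cell(IonicParams(), t_end=1000.0, sample_dt=5.0)
        assert abs(r["Vm"][-1] - r["Vm"][0]) < 1.0
        state = IonicState(**{n: r[n] for n in IonicState.__dataclass_fields__})
        state.validate()  # raises on any violation
        assert r["Ca_SR"][-1] > 0.5  # store stays loaded at rest

    def test_paced_action_potential_morphology(self):
        """1 Hz pacing yields physiological rabbit AP and calcium transient:
        overshoot, APD90 in the 150-350 ms range, transient 0.3-1.5 uM."""
        from mecsim.analysis import apd90

        onsets = np.arange(8) * 1000.0
        r = run_cell(IonicParams(), t_end=8000.0, stim_onsets=onsets, sample_dt=1.0)
        last = slice(7000, 8000)
        vm = r["Vm"][last]
        assert vm.max() > 20.0 and vm.min() < -78.0
        apds = apd90(vm, r.time[last])
        assert apds.size >= 1 and 150.0 < apds[-1] < 350.0
        ca = r["Ca_cyto"][last] * 1e3  # uM
        assert 0.3 < ca.max() - ca.min() < 1.5

    def test_trajectory_invariants_along_pacing(self):
        onsets = np.arange(3) * 400.0
        r = run_cell(IonicParams(), t_end=1200.0, stim_onsets=onsets, sample_dt=1.0)
        for g in ("m", "h", "j", "d", "f", "fca", "ryr_w"):
            assert np.all(r[g] >= -1e-6) and np.all(r[g] <= 1 + 1e-6), g
        for c in ("Ca_SS", "Ca_SR", "Ca_cyto", "Na_i"):
            assert np.all(r[c] > 0), c


# ----------------------------------------------------------------------
# sarcomere mechanics and strain coupling
# ----------------------------------------------------------------------
class TestMyofilament:
    def test_zero_strain_rate_recovers_baselines(self):
        c = StrainCouplingParams()
        kon, koff = strain_modulated_rates(c, 0.0)
        assert kon == pytest.approx(c.kon0)
        assert koff == pytest.approx(c.koff0)

    def test_stretch_rate_promotes_dissociation(self):
        c = StrainCouplingParams(alpha_off=250.0)
        _, koff = strain_modulated_rates(c, 1e-3)
        assert koff > c.koff0

    def test_exponential_form_exact_value(self):
        c = StrainCouplingParams(kon0=1.0, alpha_on=2.0)
        kon, _ = strain_modulated_rates(c, 0.5)
        assert kon == pytest.approx(np.e, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-5e-3, 5e-3), st.floats(-5e-3, 5e-3))
    def test_rates_monotone_and_positive(self, sr1, sr2):
        from hypothesis import assume

        assume(abs(sr1 - sr2) > 1e-9)
        c = StrainCouplingParams(alpha_on=-750.0, alpha_off=1500.0)
        kon1, koff1 = strain_modulated_rates(c, sr1)
        kon2, koff2 = strain_modulated_rates(c, sr2)
        assert kon1 > 0 and koff1 > 0
        if sr1 < sr2:
            assert koff1 < koff2 and kon1 > kon2

    def test_relaxation_without_calcium(self):
        """In the ca -> 0 limit the sarcomere relaxes: TnC empties and the
        force decays toward zero."""
        from mecsim.cell_models.myofilament import overlap

        p = MyofilamentParams()
        c = StrainCouplingParams()
        s = resting_sarcomere(1)
        dt = 1.0
        for _ in range(4000):
            d, force, _ = myofilament_rhs(s, 1e-9, 0.0, c, p)
            s.tnc_ca = np.clip(s.tnc_ca + dt * d["tnc_ca"], 0, 1)
            s.xb = np.clip(s.xb + dt * d["xb"], 0, 1)
        assert force.item() < 1e-3
        assert s.tnc_ca.item() < 1e-3

    def test_isometric_twitch_from_calcium_transient(self):
        """A calcium transient drives a force twitch that rises and relaxes."""
        p = MyofilamentParams()
        c = StrainCouplingParams()
        s = resting_sarcomere(1)
        dt = 1.0
        forces = []
        for k in range(800):
            t = k * dt
            ca = 1e-4 + 8e-4 * (t / 30.0) * np.exp(1.0 - t / 30.0) if t > 0 else 1e-4
            d, force, _ = myofilament_rhs(s, max(ca, 1e-9), 0.0, c, p)
            s.tnc_ca = np.clip(s.tnc_ca + dt * d["tnc_ca"], 0, 1)
            s.xb = np.clip(s.xb + dt * d["xb"], 0, 1)
            forces.append(force.item())
        forces = np.array(forces)
        k_peak = forces.argmax()
        assert 20 < k_peak < 400  # rises over tens of ms
        assert forces[k_peak] > 2.0 * forces[0]  # real twitch
        assert forces[-1] < 0.5 * forces[k_peak]  # relaxes

    def test_strain_rate_zero_equals_unmodified_model(self):
        p = MyofilamentParams()
        s = resting_sarcomere(1)
        d0, f0, j0 = myofilament_rhs(s, 5e-4, 0.0, StrainCouplingParams())
        d1, f1, j1 = myofilament_rhs(
            s, 5e-4, 0.0, StrainCouplingParams(alpha_on=0.0, alpha_off=0.0, alpha_xb=0.0)
        )
        assert np.allclose(d0["tnc_ca"], d1["tnc_ca"])
        assert np.allclose(j0, j1) and np.allclose(f0, f1)

    def test_out_of_range_length_warns_and_clamps(self, caplog):
        import logging

        s = resting_sarcomere(1, SL_rest=3.0)
        with caplog.at_level(logging.WARNING):
            _, force, _ = myofilament_rhs(s, 5e-4, 0.0, StrainCouplingParams())
        assert "validity range" in caplog.text
        assert force.item() == 0.0  # overlap clamped to zero


# ----------------------------------------------------------------------
# fibroblast
# ----------------------------------------------------------------------
class TestFibroblast:
    def test_junction_current_zero_at_equal_potentials(self):
        assert fibroblast_junction_current(-50.0, -50.0, 3.0) == 0.0

    def test_junction_antisymmetry(self):
        a = fibroblast_junction_current(-30.0, -80.0, 2.5)
        b = fibroblast_junction_current(-80.0, -30.0, 2.5)
        assert a == pytest.approx(-b)

    def test_charge_conservation_single_shared_term(self):
        """Current leaving the myocyte equals current entering the
        fibroblast at every instant (same I with opposite sign)."""
        s = resting_fibroblast(1)
        p = FibroblastParams(G_f_gap=4.0)
        d, i_junc = fibroblast_rhs(s, p, V_myocyte=-85.0)
        # fibroblast membrane receives -I/C_f on top of its ionic currents
        from mecsim.cell_models.fibroblast import fibroblast_currents

        cur = fibroblast_currents(s, p)
        i_ion = sum(cur.values())
        assert np.allclose(d["V_f"], -i_ion - i_junc / p.C_f)

    def test_uncoupled_resting_potential(self):
        """An uncoupled fibroblast settles near the ~-50 mV resting potential
        reported for active fibroblast membrane models."""
        from scipy.integrate import solve_ivp

        p = FibroblastParams(G_f_gap=0.0)
        s0 = resting_fibroblast(1)
        names = ("V_f", "r_kv", "s_kv", "Na_f", "K_f")
        y0 = np.array([float(getattr(s0, n)[0]) for n in names])
        y0[0] = -30.0  # start displaced; it must find its way back

        def rhs(t, y):
            from mecsim.cell_models.fibroblast import FibroblastState

            s = FibroblastState(*[np.atleast_1d(v) for v in y])
            d, _ = fibroblast_rhs(s, p, V_myocyte=0.0)
            return np.concatenate([np.atleast_1d(d[n]) for n in names])

        sol = solve_ivp(rhs, (0, 5000.0), y0, method="LSODA", rtol=1e-8, atol=1e-10)
        v_rest = sol.y[0, -1]
        assert -58.0 < v_rest < -42.0
        assert abs(sol.y[0, -1] - sol.y[0, -20]) < 0.5  # settled
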