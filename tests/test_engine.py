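"""Engine: state layout, integrator equivalence, determinism, persistence."""

import numpy as np
import pytest
from dataclasses import replace

from mecsim.cell_models.ionic import IonicParams
from mecsim.engine.model import TissueModel
from mecsim.engine.run import (
    SimulationAborted,
    SolverConfig,
    load_result,
    run,
    save_result,
)
from mecsim.engine.state import FIELDS, StateLayout
from mecsim.fiber import ConductionParams, DiffusionParams
from mecsim.protocols import PacingProtocol, StretchProtocol
from mecsim.tissue import TissueSpec, build_tissue_spec
from mecsim.fiber import FiberGeometry


def small_spec(n_cells=1, n_cru=4, **kw):
    return build_tissue_spec(n_cells=n_cells, n_cru=n_cru, homogeneous=True, **kw)


class TestStateLayout:
    def test_pack_unpack_round_trip(self):
        spec = build_tissue_spec(n_cells=2, n_cru=5, seed=1, n_fib_per_cell=1)
        lay = StateLayout(spec)
        rng = np.random.default_rng(0)
        d = {f: rng.random(lay.n_cru_total) for f in FIELDS}
        from mecsim.cell_models.fibroblast import FIB_NAMES

        d.update({f: rng.random(lay.n_fib) for f in FIB_NAMES})
        y = lay.pack(d)
        back = lay.unpack(y)
        for k, v in d.items():
            assert np.array_equal(back[k], v)

    def test_wrong_size_rejected(self):
        lay = StateLayout(small_spec())
        with pytest.raises(ValueError, match="size"):
            lay.unpack(np.zeros(lay.size + 1))


class TestRhs:
    def test_rhs_evaluation_deterministic(self):
        model = TissueModel(small_spec(), ionic_params=IonicParams())
        y0 = model.pack(model.initial_state())
        a = model.rhs(123.4, y0)
        b = model.rhs(123.4, y0.copy())
        assert np.array_equal(a, b)

    def test_split_stepper_matches_adaptive_reference(self):
        """The fixed-step operator-splitting scheme tracks scipy's LSODA on
        the same assembled right-hand side through a stimulated upstroke."""
        from scipy.integrate import solve_ivp

        spec = small_spec(n_cru=2)
        model = TissueModel(
            spec,
            ionic_params=IonicParams(),
            conduction=ConductionParams(stim_amplitude=40.0),
            stim_onsets=(0.0,),
        )
        y0 = model.pack(model.initial_state())
        sol = solve_ivp(
            model.rhs, (0.0, 60.0), y0, method="LSODA",
            rtol=1e-8, atol=1e-10, max_step=0.5,
        )
        s = model.initial_state()
        dt = 0.02
        for k in range(int(60.0 / dt)):
            model.step(k * dt, s, dt)
        ref = model.layout.unpack(sol.y[:, -1])
        assert np.allclose(s["Vm"], ref["Vm"], atol=0.5)
        assert np.allclose(s["Ca_cyto"], ref["Ca_cyto"], rtol=0.05)
        assert np.allclose(s["Ca_SR"], ref["Ca_SR"], rtol=0.02)

    def test_compiled_kernel_matches_python_stepper(self):
        """The numba kernel and the numpy stepper implement the same scheme:
        stepping the same state through a stimulated, stretched upstroke
        (fibroblast attached) agrees to 1e-6 before trajectory sensitivity
        can amplify rounding differences."""
        from mecsim.cell_models.fibroblast import FIB_NAMES
        from mecsim.engine import kernel as K

        if not K.HAVE_NUMBA:  # pragma: no cover
            pytest.skip("numba unavailable")
        spec = build_tissue_spec(n_cells=1, n_cru=6, seed=2, n_fib_per_cell=1)
        model = TissueModel(
            spec,
            ionic_params=IonicParams(),
            conduction=ConductionParams(stim_amplitude=300.0),
            stretch=StretchProtocol("S", cycle_length=150.0),
            stim_onsets=(0.0,),
            stretch_until=150.0,
        )
        dt = 0.02
        init = model.initial_state()
        S = np.vstack([init[f] for f in FIELDS])
        Fb = np.vstack([init[f] for f in FIB_NAMES])
        sdict = {f: S[i].copy() for i, f in enumerate(FIELDS)}
        sdict.update({f: Fb[i].copy() for i, f in enumerate(FIB_NAMES)})
        ka = model.kernel_args(dt)
        n_steps = 500  # 10 ms: stimulus and upstroke, before trajectory
        # sensitivity amplifies last-bit rounding differences
        K.step_chunk(
            S, Fb, 0.0, dt, n_steps,
            ka["ip"], ka["mp"], ka["cell_starts"], ka["cell_ends"],
            ka["resting_SL"], ka["cm_cru"], ka["dl"], ka["dd"], ka["du"],
            ka["stim_idx"], ka["stim_amp"], ka["stim_dur"],
            np.asarray(model.stim_onsets, dtype=float),
            ka["stretch_code"], ka["stretch_p"], 150.0,
            ka["tau_ss"], ka["tau_sr"], ka["tau_cyto"],
            ka["mode_relaxed"], ka["kappa"], ka["mech_ju"], ka["mech_jv"],
            ka["fib_gidx"], ka["fib_g"], ka["fp"],
        )
        for k in range(n_steps):
            model.step(k * dt, sdict, dt)
        for i, f in enumerate(FIELDS):
            assert np.max(np.abs(S[i] - sdict[f])) < 1e-6, f
        for i, f in enumerate(FIB_NAMES):
            assert np.max(np.abs(Fb[i] - sdict[f])) < 1e-6, f


class TestDecouplingLimit:
    def test_zero_gap_junction_reproduces_single_cells(self):
        """g_gap = 0, no fibroblasts, calcium diffusion off: a 2-cell tissue
        is numerically identical to the corresponding single-cell runs."""
        geo = FiberGeometry(n_cru=3)
        pacing = PacingProtocol(
            n_beats=1, early_exit=False, cycle_length=250.0,
            conduction=ConductionParams(stim_amplitude=600.0),
        )
        common = dict(pacing=pacing, observation_window=0.0, ionic_params=IonicParams())
        spec2 = build_tissue_spec(n_cells=2, n_cru=3, homogeneous=True, g_gap=0.0)
        r2 = run(spec2, **common)
        spec1 = TissueSpec(n_cells=1, geometries=[geo])
        r1 = run(spec1, **common)
        # cell 1 of the pair received the stimulus: matches the driven cell
        assert np.allclose(r2.cell(0, "Vm"), r1.cell(0, "Vm"), atol=1e-3)
        # cell 2 got nothing and stays at rest
        assert r2.cell(1, "Vm").max() < -70.0

    def test_coupled_cells_fire_without_direct_stimulus(self):
        spec = build_tissue_spec(n_cells=3, n_cru=4, homogeneous=True, g_gap=400.0)
        pacing = PacingProtocol(
            n_beats=1, early_exit=False, cycle_length=300.0,
            conduction=ConductionParams(stim_amplitude=800.0),
        )
        r = run(spec, pacing=pacing, observation_window=0.0, ionic_params=IonicParams())
        for c in (1, 2):
            assert r.cell(c, "Vm").max() > 0.0, f"cell {c} did not fire"

    def test_verbatim_junction_signs_are_anti_conservative(self):
        """The verbatim junction orientation feeds depolarization back into
        the depolarized side; integrating it faithfully diverges (the audit
        mode documents why the charge-conserving orientation is the
        default)."""
        spec = build_tissue_spec(
            n_cells=2, n_cru=4, homogeneous=True, g_gap=400.0, verbatim_junction_signs=True
        )
        pacing = PacingProtocol(
            n_beats=1, early_exit=False, cycle_length=200.0,
            conduction=ConductionParams(stim_amplitude=800.0),
        )
        with pytest.raises(SimulationAborted, match="non-finite"):
            run(spec, pacing=pacing, observation_window=0.0, ionic_params=IonicParams())


class TestRunContract:
    def test_same_config_reproducible(self):
        spec = build_tissue_spec(n_cells=1, n_cru=4, seed=8)
        pacing = PacingProtocol(
            n_beats=1, early_exit=False, cycle_length=200.0,
            conduction=ConductionParams(stim_amplitude=500.0),
        )
        a = run(spec, pacing=pacing, observation_window=100.0, ionic_params=IonicParams())
        b = run(spec, pacing=pacing, observation_window=100.0, ionic_params=IonicParams())
        for f in a.traces:
            assert np.array_equal(a.traces[f], b.traces[f])

    def test_nonfinite_state_aborts_with_name_and_partial(self):
        spec = small_spec(n_cru=2)
        bad = replace(IonicParams(), g_Na=1.0e9)  # guarantees blow-up
        pacing = PacingProtocol(
            n_beats=1, early_exit=False, cycle_length=100.0,
            conduction=ConductionParams(stim_amplitude=1000.0),
        )
        with pytest.raises(SimulationAborted) as err:
            run(spec, pacing=pacing, observation_window=0.0, ionic_params=bad)
        assert "non-finite" in str(err.value)
        assert err.value.partial is not None
        assert err.value.partial.metadata.get("aborted")

    def test_result_metadata_records_provenance(self):
        spec = build_tissue_spec(n_cells=1, n_cru=4, seed=5)
        pacing = PacingProtocol(
            n_beats=1, early_exit=False, cycle_length=100.0,
            conduction=ConductionParams(stim_amplitude=500.0),
        )
        r = run(spec, stretch=StretchProtocol("H", cycle_length=100.0),
                pacing=pacing, observation_window=50.0, ionic_params=IonicParams())
        md = r.metadata
        assert md["sarcomere_mode"] in ("verbatim", "relaxed")
        assert md["stretch_pattern"] == "H"
        assert md["seeds"]["base"] == 5
        assert md["beats_run"] == 1
        assert "observation_start" in md


class TestPersistence:
    @pytest.fixture()
    def result(self):
        spec = small_spec(n_cru=3)
        pacing = PacingProtocol(
            n_beats=1, early_exit=False, cycle_length=120.0,
            conduction=ConductionParams(stim_amplitude=500.0),
        )
        return run(spec, pacing=pacing, observation_window=30.0, ionic_params=IonicParams())

    def test_round_trip_equality(self, result, tmp_path):
        path = tmp_path / "res.h5"
        save_result(result, path)
        back = load_result(path)
        assert np.array_equal(back.time, result.time)
        for f in result.traces:
            assert np.array_equal(back.traces[f], result.traces[f])
        assert back.metadata["beats_run"] == result.metadata["beats_run"]

    def test_csv_summary_row_count(self, result, tmp_path):
        import pandas as pd

        path = tmp_path / "summary.csv"
        result.summary_frame().to_csv(path, index=False)
        assert len(pd.read_csv(path)) == len(result.time)

    def test_version_mismatch_explicit(self, result, tmp_path):
        import h5py

        path = tmp_path / "res.h5"
        save_result(result, path)
        with h5py.File(path, "a") as f:
            f.attrs["result_version"] = 999
        with pytest.raises(ValueError, match="version"):
            load_result(path)

    def test_truncated_file_raises_corruption_error(self, result, tmp_path):
        path = tmp_path / "res.h5"
        save_result(result, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(OSError, match="corrupt"):
            load_result(path)
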