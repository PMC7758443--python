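"""Shared fixtures: scaled study configurations and cached heavy runs.

Scaled experiments use 10-CRU myocytes, 12-15 paced beats and a 6 s
observation window — large enough for the threshold/ordering phenomenology,
small enough for a desk-scale suite.  Heavy simulations are session-scoped
so several tests can read the same sweep.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from mecsim.analysis import detect_events
from mecsim.cell_models.ionic import IonicParams, apply_remodeling
from mecsim.engine.run import SolverConfig, run
from mecsim.fiber import ConductionParams
from mecsim.protocols import PacingProtocol, StretchProtocol
from mecsim.tissue import TissueSpec, build_tissue_spec

SEED = 3
CAO_GRID = (2.0, 3.4, 3.6, 3.8, 4.0, 4.2)
PATTERNS = ("I", "H", "S", "P")


def scaled_pacing(n_beats=15, amp=200.0):
    return PacingProtocol(
        n_beats=n_beats,
        early_exit=False,
        conduction=ConductionParams(stim_amplitude=amp),
    )


def remodeled_params(cao):
    p = apply_remodeling(IonicParams())
    out = replace(p, Ca_o=cao)
    out.remodeled = p.remodeled
    return out


@pytest.fixture(scope="session")
def solver():
    return SolverConfig()


@pytest.fixture(scope="session")
def threshold_matrix(solver):
    """Events per (pattern, Ca_o) for the single heterogeneous myocyte sweep."""
    spec = build_tissue_spec(n_cells=1, n_cru=10, seed=SEED)
    out = {}
    for pat in PATTERNS:
        for cao in CAO_GRID:
            res = run(
                spec,
                stretch=StretchProtocol(pat),
                pacing=scaled_pacing(),
                observation_window=6000.0,
                ionic_params=IonicParams(Ca_o=cao),
                solver=solver,
            )
            out[(pat, cao)] = detect_events(res)
    return out


@pytest.fixture(scope="session")
def fibroblast_series(solver):
    """(APD90, first event) for 0-3 fibroblasts, remodeled myocyte."""
    from mecsim.analysis import apd90

    out = {}
    for n_fib in (0, 1, 2, 3):
        spec = build_tissue_spec(n_cells=1, n_cru=10, seed=SEED, n_fib_per_cell=n_fib)
        r_apd = run(
            spec,
            stretch=StretchProtocol("I"),
            pacing=scaled_pacing(n_beats=6),
            observation_window=0.0,
            ionic_params=remodeled_params(2.0),
            solver=solver,
        )
        vm = r_apd.traces["Vm"][:, 5]
        apds = apd90(vm[-1000:], r_apd.time[-1000:])
        r_ev = run(
            spec,
            stretch=StretchProtocol("P"),
            pacing=scaled_pacing(),
            observation_window=6000.0,
            ionic_params=remodeled_params(4.0),
            solver=solver,
        )
        events = detect_events(r_ev)
        out[n_fib] = {"apd90": float(apds[-1]), "events": events}
    return out


@pytest.fixture(scope="session")
def coupling_comparison(solver):
    """Isolated vs gap-junction-coupled 3-myocyte runs (remodeled, Ca_o 4.2)."""
    spec3 = build_tissue_spec(n_cells=3, n_cru=10, seed=SEED, g_gap=400.0)
    common = dict(
        stretch=StretchProtocol("P"),
        observation_window=6000.0,
        ionic_params=remodeled_params(4.2),
        solver=solver,
    )
    isolated = []
    for c in range(3):
        spec1 = TissueSpec(n_cells=1, geometries=[spec3.geometries[c]])
        isolated.append(run(spec1, pacing=scaled_pacing(), **common))
    coupled = run(spec3, pacing=scaled_pacing(amp=600.0), **common)
    return {"isolated": isolated, "coupled": coupled}


def first_event_cao(matrix, pattern, grid=CAO_GRID):
    """Smallest Ca_o on the grid with at least one spontaneous event."""
    for cao in grid:
        if matrix[(pattern, cao)]:
            return cao
    return np.inf
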