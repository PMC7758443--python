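"""Solver-facing state layout.

The global state vector concatenates, field by field, the per-CRU arrays of
all cells (cells in chain order, CRUs in fiber order within each cell),
followed by the fibroblast block.  Layout version and field order are
recorded in result metadata so saved states remain interpretable.
"""

from __future__ import annotations

import numpy as np

from ..cell_models.fibroblast import FIB_NAMES
from ..cell_models.ionic import STATE_NAMES
from ..cell_models.myofilament import MECH_NAMES

__all__ = ["StateLayout", "FIELDS", "LAYOUT_VERSION"]

FIELDS = STATE_NAMES + MECH_NAMES
LAYOUT_VERSION = 1


class StateLayout:
    """Maps between the packed vector and named per-CRU / fibroblast arrays."""

    def __init__(self, spec):
        self.n_cells = spec.n_cells
        self.cell_bounds: list[tuple[int, int]] = []
        start = 0
        for g in spec.geometries:
            self.cell_bounds.append((start, start + g.n_cru))
            start += g.n_cru
        self.n_cru_total = start
        self.n_fib = len(spec.fibroblasts)
        self.size = len(FIELDS) * self.n_cru_total + len(FIB_NAMES) * self.n_fib

    def unpack(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Views into ``y`` keyed by field name (no copies)."""
        if y.shape != (self.size,):
            raise ValueError(
                f"state vector has size {y.shape}, layout expects ({self.size},)"
            )
        n = self.n_cru_total
        out = {}
        for k, f in enumerate(FIELDS):
            out[f] = y[k * n : (k + 1) * n]
        off = len(FIELDS) * n
        for k, f in enumerate(FIB_NAMES):
            out[f] = y[off + k * self.n_fib : off + (k + 1) * self.n_fib]
        return out

    def pack(self, d: dict[str, np.ndarray]) -> np.ndarray:
        y = np.empty(self.size)
        for f, v in self.unpack(y).items():
            v[:] = d[f]
        return y

    def metadata(self) -> dict:
        return {
            "layout_version": LAYOUT_VERSION,
            "fields": list(FIELDS),
            "fibroblast_fields": list(FIB_NAMES),
            "n_cru_total": self.n_cru_total,
            "cell_bounds": list(self.cell_bounds),
            "n_fib": self.n_fib,
        }
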