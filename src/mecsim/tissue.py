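"""Multi-myocyte assembly: gap junctions, heterogeneity, fibroblast attachment.

Myocytes are coupled end-to-end in a simple chain.  Each junction carries a
linear (ohmic) gap-junction current between the last CRU of the upstream cell
and the first CRU of the downstream cell,

    I_gap = g_gap * (V_up - V_down)   [nS * mV = pA],

applied to the two boundary CRUs' voltage equations divided by the per-CRU
capacitance, with the charge-conserving orientation: the higher-potential
side loses depolarizing charge and the lower-potential side gains it.  (The
``verbatim_junction_signs`` flag flips to the anti-conservative orientation for
auditing; it prevents conduction and is not the default.)  Mechanical
boundary coupling links the terminal sarcomeres of adjacent cells the same
way interior sarcomeres couple within a cell.

Mechanical heterogeneity assigns each of the 50 sarcomeres a resting length
drawn uniformly from [mean*(1 - f), mean*(1 + f)] — with the defaults
(1.89 um, 10%) the interval [1.701, 2.079] um.  Fibroblasts attach to a CRU
within the terminal five CRUs of an end, with junction conductance drawn
uniformly from [0.5, 8.0] nS.  Every draw is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell_models.fibroblast import FibroblastParams
from .fiber import FiberGeometry

__all__ = [
    "GapJunction",
    "TissueSpec",
    "HeterogeneityConfig",
    "FibroblastAttachment",
    "gap_junction_current",
    "generate_resting_lengths",
    "attach_fibroblasts",
    "build_tissue_spec",
    "assemble_tissue_rhs",
]


@dataclass
class GapJunction:
    """Electrical junction between the last CRU of ``upstream`` and the
    first CRU of ``downstream`` (0-based cell indices)."""

    upstream: int
    downstream: int
    g_gap: float = 400.0  # nS

    def __post_init__(self) -> None:
        if self.g_gap < 0:
            raise ValueError("g_gap must be >= 0")
        if self.downstream != self.upstream + 1:
            raise ValueError("junctions must chain adjacent cells")


@dataclass
class FibroblastAttachment:
    """A fibroblast attached to CRU ``cru`` (1-based) of cell ``cell``."""

    cell: int
    cru: int
    params: FibroblastParams


@dataclass
class HeterogeneityConfig:
    """Uniform sarcomere resting-length heterogeneity."""

    mean_SL: float = 1.89   # um
    fraction: float = 0.10
    n_replicates: int = 10

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean_SL * (1.0 - self.fraction), self.mean_SL * (1.0 + self.fraction))


@dataclass
class TissueSpec:
    """Composition of one simulation: cells, junctions, fibroblasts, seeds."""

    n_cells: int
    geometries: list[FiberGeometry]
    junctions: list[GapJunction] = field(default_factory=list)
    fibroblasts: list[FibroblastAttachment] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    verbatim_junction_signs: bool = False
    sarcomere_mode: str = "relaxed"

    def __post_init__(self) -> None:
        if len(self.geometries) != self.n_cells:
            raise ValueError("need one FiberGeometry per cell")
        ups = [j.upstream for j in self.junctions]
        for j in self.junctions:
            if not (0 <= j.upstream < self.n_cells and 0 <= j.downstream < self.n_cells):
                raise ValueError("junction cell index out of range")
        if len(set(ups)) != len(ups):
            raise ValueError("junction list must form a simple chain")
        for fb in self.fibroblasts:
            geo = self.geometries[fb.cell]
            n = geo.n_cru
            k = min(5, n // 2)
            if not (1 <= fb.cru <= k or n - k + 1 <= fb.cru <= n):
                raise ValueError(
                    f"fibroblast CRU {fb.cru} outside the terminal {k} CRUs of cell {fb.cell}"
                )

    @property
    def n_cru_total(self) -> int:
        return sum(g.n_cru for g in self.geometries)


def gap_junction_current(v_up, v_down, g_gap=400.0):
    """Junctional current (pA) from upstream to downstream: g * (V_up - V_down)."""
    return np.asarray(g_gap, dtype=float) * (np.asarray(v_up, dtype=float) - np.asarray(v_down, dtype=float))


def generate_resting_lengths(cfg: HeterogeneityConfig, seed: int, n: int = 50) -> np.ndarray:
    """n i.i.d. uniform resting lengths (um) on the heterogeneity interval."""
    lo, hi = cfg.interval
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=n)


def attach_fibroblasts(
    n_fib: int,
    seed: int,
    n_cru: int = 50,
    ends: str = "both",
    g_range: tuple[float, float] = (0.5, 8.0),
    cell: int = 0,
    base_params: FibroblastParams | None = None,
) -> list[FibroblastAttachment]:
    """Randomly place ``n_fib`` fibroblasts on the terminal 5 CRUs of an end.

    Each fibroblast receives a CRU index uniform over the eligible terminal
    CRUs ({1..5} and/or {n-4..n}) and a junction conductance uniform on
    ``g_range`` nS.  Fully reproducible from ``seed``.
    """
    if n_fib not in (0, 1, 2, 3):
        raise ValueError("n_fib must be in {0, 1, 2, 3}")
    if base_params is None:
        base_params = FibroblastParams()
    rng = np.random.default_rng(seed)
    k = min(5, n_cru // 2)
    head = list(range(1, k + 1))
    tail = list(range(n_cru - k + 1, n_cru + 1))
    if ends == "both":
        eligible = head + tail
    elif ends == "distal":
        eligible = tail
    elif ends == "proximal":
        eligible = head
    else:
        raise ValueError(f"unknown ends option: {ends!r}")
    out = []
    for _ in range(n_fib):
        cru = int(rng.choice(eligible))
        g = float(rng.uniform(*g_range))
        out.append(FibroblastAttachment(cell=cell, cru=cru, params=replace(base_params, G_f_gap=g)))
    return out


def build_tissue_spec(
    n_cells: int = 1,
    n_cru: int = 50,
    het_cfg: HeterogeneityConfig | None = None,
    seed: int | None = None,
    n_fib_per_cell: int = 0,
    g_gap: float = 400.0,
    homogeneous: bool = False,
    **kwargs,
) -> TissueSpec:
    """Convenience builder: heterogeneous cells, chain junctions, fibroblasts.

    With ``seed`` given, cell replicate seeds and fibroblast placement seeds
    are derived deterministically (seed*1000 + offsets) and recorded in
    ``TissueSpec.seeds``.
    """
    if het_cfg is None:
        het_cfg = HeterogeneityConfig()
    seeds: dict = {"base": seed}
    geometries = []
    fibs: list[FibroblastAttachment] = []
    for c in range(n_cells):
        if homogeneous or seed is None:
            geometries.append(FiberGeometry(n_cru=n_cru))
            cell_seed = None
        else:
            cell_seed = (seed * 1000 + c) % (2**31)
            geometries.append(
                FiberGeometry(n_cru=n_cru, resting_SL=generate_resting_lengths(het_cfg, cell_seed, n_cru))
            )
        seeds[f"cell_{c}_SL"] = cell_seed
        if n_fib_per_cell:
            fib_seed = ((seed or 0) * 1000 + 500 + c) % (2**31)
            seeds[f"cell_{c}_fib"] = fib_seed
            fibs.extend(attach_fibroblasts(n_fib_per_cell, fib_seed, n_cru=n_cru, cell=c))
    junctions = [GapJunction(upstream=c, downstream=c + 1, g_gap=g_gap) for c in range(n_cells - 1)]
    return TissueSpec(
        n_cells=n_cells,
        geometries=geometries,
        junctions=junctions,
        fibroblasts=fibs,
        seeds=seeds,
        **kwargs,
    )


def assemble_tissue_rhs(spec: TissueSpec, **model_kwargs):
    """Global derivative callable f(t, y) for a multi-cell tissue."""
    from .engine.model import TissueModel

    return TissueModel(spec, **model_kwargs).rhs
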