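"""Multicellular assembly: PSM growth, control-protein gradient, coupling.

Each cell carries four state variables: total clock protein P, clock mRNA M,
signal (DeltaC-role) protein D, and signal mRNA MD.  Cells sit on a 1D line
or a 2D rectangular lattice (8-neighbour Moore coupling); the tailbud adds
cells to the posterior at a constant rate, so cell i exits the tailbud at
t_i = (i-1)/(sigma*omega).  Until then its total control protein is pinned at
G_max; afterwards it relaxes sigmoidally to G_min with half-life t_half.
The coupling signal a cell receives is the summed neighbour signal protein
divided by the lattice's maximal coordination number, so a boundary cell with
a single neighbour sees half the interior signal at equal expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dde import DelaySystemSpec, delayed_component
from .equilibrium import _solve_pg
from .params import ParameterSet, ScenarioConfig

__all__ = [
    "LatticeSpec",
    "GradientSpec",
    "entry_time",
    "control_protein",
    "coupling_signal",
    "assemble_system",
    "two_cell_system",
    "N_PER_CELL",
    "STATE_P", "STATE_M", "STATE_D", "STATE_MD",
]

STATE_P, STATE_M, STATE_D, STATE_MD = 0, 1, 2, 3

# per-cell parameter block layout in the packed RHS vector
N_PER_CELL = 30
(_I_ALPHA_P, _I_ALPHA_D, _I_KAPPA_M, _I_KAPPA_D, _I_DELTA_M, _I_DELTA_D,
 _I_DELTA_MD, _I_DELTA_P, _I_DELTA_HH, _I_DELTA_PG, _I_KHH, _I_KGG, _I_KPG,
 _I_Q, _I_KR, _I_CR, _I_KA, _I_CA, _I_NSITES, _I_GMIN, _I_GMAX, _I_THALF,
 _I_HEXP, _I_ENTRY, _I_TAU_P, _I_TAU_M, _I_TAU_DP, _I_TAU_DM, _I_FORCE,
 _I_QSIG) = range(N_PER_CELL)


@dataclass(frozen=True)
class LatticeSpec:
    """1D line (2-neighbour) or 2D rectangular grid (Moore 8-neighbour)."""

    n_axial: int = 50
    n_lateral: int = 1

    def __post_init__(self) -> None:
        if self.n_axial < 1 or self.n_lateral < 1:
            raise ValueError("lattice dimensions must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.n_axial * self.n_lateral

    @property
    def n_max(self) -> int:
        """Coordination normalizer: the maximal neighbour count."""
        return 2 if self.n_lateral == 1 else 8

    def cell_index(self, axial: int, lateral: int = 1) -> int:
        """0-based flat index from 1-based (axial, lateral) coordinates."""
        if not (1 <= axial <= self.n_axial and 1 <= lateral <= self.n_lateral):
            raise ValueError("cell coordinates out of range")
        return (lateral - 1) * self.n_axial + (axial - 1)

    def axial_of(self, idx: int) -> int:
        return idx % self.n_axial + 1

    def neighbors(self) -> list[list[int]]:
        """Symmetric nearest-neighbour lists (Moore neighbourhood in 2D)."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_cells)]
        for lat in range(self.n_lateral):
            for ax in range(self.n_axial):
                i = lat * self.n_axial + ax
                for dl in (-1, 0, 1):
                    for da in (-1, 0, 1):
                        if dl == 0 and da == 0:
                            continue
                        if self.n_lateral == 1 and dl != 0:
                            continue
                        if self.n_lateral == 1 and abs(da) != 1:
                            continue
                        l2, a2 = lat + dl, ax + da
                        if 0 <= l2 < self.n_lateral and 0 <= a2 < self.n_axial:
                            nbrs[i].append(l2 * self.n_axial + a2)
        return nbrs

    def neighbor_census(self) -> dict[int, int]:
        """Histogram of neighbour counts (2D 50x5: {8: interior, 5: edge, 3: corner})."""
        counts: dict[int, int] = {}
        for lst in self.neighbors():
            counts[len(lst)] = counts.get(len(lst), 0) + 1
        return counts


@dataclass(frozen=True)
class GradientSpec:
    """Prescribed control-protein gradient G(t) per cell.

    After a cell's tailbud exit at t_i, G falls from G_max to G_min following
    the normalized sigmoid s(x) = 1/(1 + x^h) of x = (t - t_i)/t_half, so
    exactly half the drop is realised one half-life after exit.
    """

    G_min: float
    G_max: float
    t_half: float = 60.0
    h: float = 3.0

    def __post_init__(self) -> None:
        if self.G_min > self.G_max:
            raise ValueError("G_min must not exceed G_max")
        if self.t_half <= 0 or self.h <= 0:
            raise ValueError("t_half and h must be positive")

    @classmethod
    def from_params(cls, params: ParameterSet, h: float = 3.0) -> "GradientSpec":
        return cls(G_min=params.G_min, G_max=params.G_max, t_half=params.t_half, h=h)


def entry_time(i: int, params: ParameterSet) -> float:
    """Tailbud-exit time of axial cell i (1-based): t_i = (i-1)/(sigma*omega)."""
    if i < 1:
        raise ValueError("cell index is 1-based")
    return (i - 1) / (params.sigma * params.omega)


@njit(cache=True, inline="always")
def _gradient_value(t, entry, g_min, g_max, t_half, h_exp, force_max):
    if force_max != 0.0 or t <= entry:
        return g_max
    x = (t - entry) / t_half
    return g_min + (g_max - g_min) / (1.0 + x ** h_exp)


def control_protein(i: int, t: float, gradient: GradientSpec, params: ParameterSet) -> float:
    """Prescribed total control protein in axial cell i at time t."""
    return float(
        _gradient_value(t, entry_time(i, params), gradient.G_min, gradient.G_max,
                        gradient.t_half, gradient.h, 0.0)
    )


def coupling_signal(neighbor_values, n_max: int) -> float:
    """Normalised Notch signal: sum of neighbour signal protein over n_max."""
    v = np.asarray(neighbor_values, dtype=float)
    if np.any(v < 0):
        raise ValueError("neighbor signal levels must be non-negative")
    return float(v.sum() / n_max)


@njit(cache=True)
def model_rhs(t, y, ts, hs, ys, qs, n, p, iv, out):
    """Clock/signal circuit derivatives for all cells on the lattice."""
    n_cells = iv[0]
    n_max = float(iv[1])
    for c in range(n_cells):
        b = c * N_PER_CELL
        s = 4 * c
        P = y[s]
        if P < 0.0:
            P = 0.0
        M = y[s + 1]
        D = y[s + 2]
        MD = y[s + 3]

        tau_p = p[b + _I_TAU_P]
        tau_m = p[b + _I_TAU_M]
        tau_dp = p[b + _I_TAU_DP]
        tau_dm = p[b + _I_TAU_DM]
        k_hh = p[b + _I_KHH]
        k_gg = p[b + _I_KGG]
        k_pg = p[b + _I_KPG]
        entry = p[b + _I_ENTRY]
        g_min = p[b + _I_GMIN]
        g_max = p[b + _I_GMAX]
        t_half = p[b + _I_THALF]
        h_exp = p[b + _I_HEXP]
        force = p[b + _I_FORCE]
        kr = p[b + _I_KR]

        # instantaneous equilibrium: differential decay flux
        G_now = _gradient_value(t, entry, g_min, g_max, t_half, h_exp, force)
        pm, gm = _solve_pg(P, G_now, k_hh, k_gg, k_pg)
        if pm < 0.0:  # equilibrium solver fallback (should not trigger)
            pm, gm = 0.0, 0.0
        hh = pm * pm / k_hh
        pg = pm * gm / k_pg
        decay = p[b + _I_DELTA_P] * pm + 2.0 * p[b + _I_DELTA_HH] * hh + p[b + _I_DELTA_PG] * pg
        m_del = delayed_component(ts, hs, ys, qs, n, t - tau_p, s + 1)
        if m_del < 0.0:
            m_del = 0.0
        out[s] = p[b + _I_ALPHA_P] * m_del - decay

        # clock mRNA: promoter sees homodimer and neighbour signal at t - tau_m
        t_m = t - tau_m
        P_del = delayed_component(ts, hs, ys, qs, n, t_m, s)
        if P_del < 0.0:
            P_del = 0.0
        G_del = _gradient_value(t_m, entry, g_min, g_max, t_half, h_exp, force)
        pmd, gmd = _solve_pg(P_del, G_del, k_hh, k_gg, k_pg)
        if pmd < 0.0:
            pmd = 0.0
        hh_m = pmd * pmd / k_hh
        sig = 0.0
        for jj in range(iv[2 + c], iv[2 + c + 1]):
            j = iv[3 + n_cells + jj]
            dv = delayed_component(ts, hs, ys, qs, n, t_m, 4 * j + 2)
            if dv > 0.0:
                sig += dv
        s_bar = sig / n_max
        q = p[b + _I_Q]
        ka = p[b + _I_KA]
        act = q * (1.0 + p[b + _I_CA] * ka * s_bar)
        x = kr * hh_m
        if p[b + _I_NSITES] < 1.5:
            f_r = 1.0 + x
        else:
            f_r = 1.0 + 2.0 * x + p[b + _I_CR] * x * x
        f = act / (act + (1.0 + ka * s_bar) * f_r)
        out[s + 1] = p[b + _I_KAPPA_M] * f - p[b + _I_DELTA_M] * M

        # signal protein
        md_del = delayed_component(ts, hs, ys, qs, n, t - tau_dp, s + 3)
        if md_del < 0.0:
            md_del = 0.0
        out[s + 2] = p[b + _I_ALPHA_D] * md_del - p[b + _I_DELTA_D] * D

        # signal mRNA: repressed by homodimer at t - tau_dm
        t_dm = t - tau_dm
        P_dm = delayed_component(ts, hs, ys, qs, n, t_dm, s)
        if P_dm < 0.0:
            P_dm = 0.0
        G_dm = _gradient_value(t_dm, entry, g_min, g_max, t_half, h_exp, force)
        pdm, gdm = _solve_pg(P_dm, G_dm, k_hh, k_gg, k_pg)
        if pdm < 0.0:
            pdm = 0.0
        hh_dm = pdm * pdm / k_hh
        qsig = p[b + _I_QSIG]
        f_d = qsig / (qsig + 1.0 + kr * hh_dm)
        out[s + 3] = p[b + _I_KAPPA_D] * f_d - p[b + _I_DELTA_MD] * MD


def _pack_cell(params: ParameterSet, scenario: ScenarioConfig, entry: float,
               gradient: GradientSpec, force_gmax: bool, q_signal: float | None) -> np.ndarray:
    blk = np.empty(N_PER_CELL)
    blk[_I_ALPHA_P] = params.alpha_p
    blk[_I_ALPHA_D] = params.alpha_d
    blk[_I_KAPPA_M] = params.kappa_m
    blk[_I_KAPPA_D] = params.kappa_d
    blk[_I_DELTA_M] = params.delta_M
    blk[_I_DELTA_D] = params.delta_d
    blk[_I_DELTA_MD] = params.delta_MD
    blk[_I_DELTA_P] = params.delta_p
    blk[_I_DELTA_HH] = params.delta_hh
    blk[_I_DELTA_PG] = params.delta_pg
    blk[_I_KHH] = params.K_hh
    blk[_I_KGG] = params.K_gg
    blk[_I_KPG] = params.K_pg
    blk[_I_Q] = params.q
    blk[_I_KR] = params.k_r
    blk[_I_CR] = params.c_r
    blk[_I_KA] = params.k_a
    blk[_I_CA] = params.c_a
    blk[_I_NSITES] = float(scenario.n_sites)
    blk[_I_GMIN] = gradient.G_min
    blk[_I_GMAX] = gradient.G_max
    blk[_I_THALF] = gradient.t_half
    blk[_I_HEXP] = gradient.h
    blk[_I_ENTRY] = entry
    blk[_I_TAU_P] = params.tau_p
    blk[_I_TAU_M] = params.tau_m
    blk[_I_TAU_DP] = params.tau_dp
    blk[_I_TAU_DM] = params.tau_dm
    blk[_I_FORCE] = 1.0 if force_gmax else 0.0
    blk[_I_QSIG] = params.q if q_signal is None else q_signal
    return blk


def assemble_system(
    lattice: LatticeSpec,
    cell_params: "ParameterSet | list[ParameterSet]",
    scenario: ScenarioConfig,
    gradient: GradientSpec | None = None,
    *,
    force_gmax: np.ndarray | None = None,
    per_cell_gradients: "list[GradientSpec] | None" = None,
    t0: float = 0.0,
    history: float = 0.0,
    q_signal: float | None = None,
) -> DelaySystemSpec:
    """Build the DDE system for all cells on the lattice.

    ``cell_params`` is one ParameterSet (homogeneous tissue) or one per cell.
    ``force_gmax`` pins G at G_max in the flagged cells for all time (FGF
    bead).  Scenario-derived decay constants are applied to every cell.
    Laterally adjacent cells share their axial entry time.
    """
    if isinstance(scenario, str):
        scenario = ScenarioConfig.from_name(scenario)
    n_cells = lattice.n_cells
    if isinstance(cell_params, ParameterSet):
        cell_params = [cell_params] * n_cells
    if len(cell_params) != n_cells:
        raise ValueError(f"expected {n_cells} parameter sets, got {len(cell_params)}")
    if force_gmax is None:
        force_gmax = np.zeros(n_cells, dtype=bool)
    cell_params = [ps.with_scenario(scenario) for ps in cell_params]

    p = np.empty(n_cells * N_PER_CELL)
    for c, ps in enumerate(cell_params):
        grad = (
            per_cell_gradients[c] if per_cell_gradients is not None
            else (gradient if gradient is not None else GradientSpec.from_params(ps))
        )
        entry = entry_time(lattice.axial_of(c), ps)
        p[c * N_PER_CELL:(c + 1) * N_PER_CELL] = _pack_cell(
            ps, scenario, entry, grad, bool(force_gmax[c]), q_signal
        )

    nbrs = lattice.neighbors()
    offsets = np.zeros(n_cells + 1, dtype=np.int64)
    for c in range(n_cells):
        offsets[c + 1] = offsets[c] + len(nbrs[c])
    flat = np.concatenate([np.asarray(lst, dtype=np.int64) for lst in nbrs]) \
        if offsets[-1] > 0 else np.zeros(0, dtype=np.int64)
    iv = np.concatenate([
        np.array([n_cells, lattice.n_max], dtype=np.int64), offsets, flat,
    ])

    delays = sorted({d for ps in cell_params for d in ps.delays})
    return DelaySystemSpec(
        dim=4 * n_cells, delays=delays, rhs=model_rhs, p=p, iv=iv,
        t0=t0, history=history,
    )


def two_cell_system(
    params: ParameterSet,
    scenario: ScenarioConfig,
    G: float,
    *,
    t0: float = 0.0,
    history: float = 0.0,
) -> DelaySystemSpec:
    """Two mutually coupled identical cells at a constant control level G.

    This is the stage-1 screening configuration: the lattice normalizer
    n_max = 2 applies, so each cell receives half its neighbour's signal.
    """
    lattice = LatticeSpec(n_axial=2, n_lateral=1)
    grad = GradientSpec(G_min=G, G_max=G, t_half=params.t_half)
    return assemble_system(
        lattice, params, scenario, grad, t0=t0, history=history,
    )
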