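"""Fast competitive-dimerization equilibrium.

Clock protein (total P) and control protein (total G) each exist as monomer,
homodimer, or the shared heterodimer.  Dimerization is fast relative to
production/decay, so at every instant the monomer levels (p, g) satisfy the
conservation system

    P = p + 2 p^2/K_hh + p g/K_pg
    G = g + 2 g^2/K_gg + p g/K_pg

with dimers following by mass action: hh = p^2/K_hh, gg = g^2/K_gg,
pg = p g/K_pg.  The right-hand sides are increasing in (p, g), so the
non-negative solution is unique.  The solver below runs a damped fixed-point
sweep to get inside the basin, then polishes with a safeguarded 2-D Newton
iteration; it is numba-compiled because it sits inside every DDE
right-hand-side evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ParameterSet

__all__ = ["EquilibriumState", "solve_dimer_equilibrium", "solve_monomers"]

_REL_TOL = 1e-12
_MAX_ITER = 200


@dataclass(frozen=True)
class EquilibriumState:
    """Monomer/dimer decomposition of total clock (P) and control (G) protein."""

    p: float    # clock monomer
    g: float    # control monomer
    hh: float   # clock homodimer
    gg: float   # control homodimer
    pg: float   # clock-control heterodimer

    @property
    def total_clock(self) -> float:
        return self.p + 2.0 * self.hh + self.pg

    @property
    def total_control(self) -> float:
        return self.g + 2.0 * self.gg + self.pg


@njit(cache=True, fastmath=False)
def _solve_pg(P: float, G: float, K_hh: float, K_gg: float, K_pg: float):
    """Return monomer levels (p, g) for totals (P, G); (-1, -1) on failure."""
    if P <= 0.0 and G <= 0.0:
        return max(P, 0.0), max(G, 0.0)
    scale = max(1.0, P, G)
    tol = _REL_TOL * scale

    # Start from the no-heterodimer quadratics: 2 x^2/K + x - T = 0.
    p = 0.25 * K_hh * (np.sqrt(1.0 + 8.0 * P / K_hh) - 1.0) if P > 0.0 else 0.0
    g = 0.25 * K_gg * (np.sqrt(1.0 + 8.0 * G / K_gg) - 1.0) if G > 0.0 else 0.0

    # Damped fixed point: contractive near the root, cheap per sweep.
    for _ in range(8):
        pn = P / (1.0 + 2.0 * p / K_hh + g / K_pg)
        gn = G / (1.0 + 2.0 * g / K_gg + p / K_pg)
        p = 0.5 * (p + pn)
        g = 0.5 * (g + gn)

    # Safeguarded Newton on the residuals.
    for _ in range(_MAX_ITER):
        f1 = p + 2.0 * p * p / K_hh + p * g / K_pg - P
        f2 = g + 2.0 * g * g / K_gg + p * g / K_pg - G
        if abs(f1) <= tol and abs(f2) <= tol:
            return p, g
        j11 = 1.0 + 4.0 * p / K_hh + g / K_pg
        j12 = p / K_pg
        j21 = g / K_pg
        j22 = 1.0 + 4.0 * g / K_gg + p / K_pg
        det = j11 * j22 - j12 * j21
        if det <= 0.0:
            break
        dp = (-f1 * j22 + f2 * j12) / det
        dg = (-f2 * j11 + f1 * j21) / det
        lam = 1.0
        # keep iterates non-negative; monotone residuals make this safe
        while (p + lam * dp < 0.0 or g + lam * dg < 0.0) and lam > 1e-12:
            lam *= 0.5
        p += lam * dp
        g += lam * dg
        if p < 0.0:
            p = 0.0
        if g < 0.0:
            g = 0.0
    f1 = p + 2.0 * p * p / K_hh + p * g / K_pg - P
    f2 = g + 2.0 * g * g / K_gg + p * g / K_pg - G
    if abs(f1) <= 1e-8 * scale and abs(f2) <= 1e-8 * scale:
        return p, g
    return -1.0, -1.0


def solve_monomers(P: float, G: float, K_hh: float, K_gg: float, K_pg: float):
    """Low-level scalar interface returning (p, g); raises on failure."""
    if P < 0 or G < 0:
        raise ValueError(f"totals must be non-negative, got P={P}, G={G}")
    if min(K_hh, K_gg, K_pg) <= 0:
        raise ValueError("dissociation constants must be strictly positive")
    p, g = _solve_pg(float(P), float(G), float(K_hh), float(K_gg), float(K_pg))
    if p < 0.0:
        raise RuntimeError(
            f"dimer equilibrium failed to converge for P={P}, G={G}, "
            f"K=({K_hh}, {K_gg}, {K_pg})"
        )
    return p, g


def solve_dimer_equilibrium(P: float, G: float, params: ParameterSet) -> EquilibriumState:
    """Decompose totals (P, G) into monomers and dimers at fast equilibrium."""
    p, g = solve_monomers(P, G, params.K_hh, params.K_gg, params.K_pg)
    return EquilibriumState(
        p=p,
        g=g,
        hh=p * p / params.K_hh,
        gg=g * g / params.K_gg,
        pg=p * g / params.K_pg,
    )
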