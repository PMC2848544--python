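"""Thermodynamic (Shea-Ackers) promoter occupancy and protein decay fluxes.

Transcription rate is proportional to the equilibrium probability that the
RNAP-II complex occupies the promoter.  The clock promoter carries one
activator site (Notch signal A, cooperativity c_a with RNAP) and n_sites
repressor sites for the clock homodimer R, whose occupancy excludes RNAP.
With statistical weight q for RNAP binding, the transcribing states are
RNAP-alone and RNAP+activator:

    f(R, A) = q (1 + c_a k_a A) / [ q (1 + c_a k_a A) + (1 + k_a A) F_R(R) ]

where F_R(R) = 1 + k_r R for one site and 1 + 2 k_r R + c_r (k_r R)^2 for two
equivalent sites with cooperativity c_r.  The coupling-signal promoter has no
activator and one repressor site: f_d(R) = q / (q + 1 + k_r R), sharing the
repressor affinity k_r (and, by default, the RNAP weight q) with the clock.
"""

from __future__ import annotations

import numpy as np

from .equilibrium import EquilibriumState, solve_dimer_equilibrium
from .params import ParameterSet, ScenarioConfig

__all__ = [
    "repressor_factor",
    "clock_promoter_activity",
    "signal_promoter_activity",
    "clock_decay_flux",
    "clock_production_curve",
]


def repressor_factor(R, k_r: float, c_r: float, n_sites: int):
    """Partition-function factor over repressor-site occupancy states."""
    x = k_r * np.asarray(R, dtype=float)
    if n_sites == 1:
        return 1.0 + x
    if n_sites == 2:
        return 1.0 + 2.0 * x + c_r * x * x
    raise ValueError(f"n_sites must be 1 or 2, got {n_sites}")


def clock_promoter_activity(R, A, params: ParameterSet, scenario: ScenarioConfig):
    """Probability that RNAP-II occupies the clock promoter.

    Strictly decreasing in the repressor homodimer level R and (for c_a > 1)
    strictly increasing in the activating signal level A.
    """
    R = np.asarray(R, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(R < 0) or np.any(A < 0):
        raise ValueError("R and A must be non-negative")
    act = params.q * (1.0 + params.c_a * params.k_a * A)
    rep = (1.0 + params.k_a * A) * repressor_factor(R, params.k_r, params.c_r, scenario.n_sites)
    out = act / (act + rep)
    return float(out) if out.ndim == 0 else out


def signal_promoter_activity(R, params: ParameterSet, q: float | None = None):
    """Probability that RNAP-II occupies the coupling-signal promoter.

    Uses the clock promoter's q unless an override is given.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be non-negative")
    qs = params.q if q is None else q
    out = qs / (qs + 1.0 + params.k_r * R)
    return float(out) if out.ndim == 0 else out


def clock_decay_flux(eq: EquilibriumState, params: ParameterSet) -> float:
    """Clock-subunit loss rate, copies/min.

    Homodimer decay removes two clock subunits, heterodimer decay one (the
    control protein is prescribed, so its half is not tracked).  When dimer
    decay constants equal the monomer's, the flux collapses to delta_p * P
    (linear decay); with monomer-only decay it is strictly sub-linear in P
    whenever dimers are present (cooperative stability).
    """
    return (
        params.delta_p * eq.p
        + 2.0 * params.delta_hh * eq.hh
        + params.delta_pg * eq.pg
    )


def clock_production_curve(
    P_grid, G: float, A: float, params: ParameterSet, scenario: ScenarioConfig
) -> np.ndarray:
    """Clock mRNA production rate kappa_m * f as a function of total clock protein.

    For each total P the dimer equilibrium is solved at the given total
    control protein G, and the promoter is evaluated at the resulting
    homodimer level.  The curve is monotone non-increasing in P; two binding
    sites shift it toward lower P, which raises the effective Hill
    coefficient of self-repression.
    """
    P_grid = np.asarray(P_grid, dtype=float)
    if np.any(P_grid < 0):
        raise ValueError("P grid must be non-negative")
    out = np.empty_like(P_grid)
    for i, P in enumerate(P_grid.ravel()):
        eq = solve_dimer_equilibrium(float(P), G, params)
        out.ravel()[i] = params.kappa_m * clock_promoter_activity(eq.hh, A, params, scenario)
    return out
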