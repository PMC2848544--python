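"""Model parameters and scenario bookkeeping.

The clock circuit is a single self-repressing clock gene (her7 in zebrafish)
whose protein competes for dimer partners with a prescribed, graded control
protein (the Her13.2 role), plus a clock-repressed coupling-signal gene (the
DeltaC role) that activates the clock promoter of neighbouring cells.  Four
model scenarios differ in the number of repressor binding sites on the clock
promoter (1 or 2) and in whether clock-protein dimers decay (not at all, or at
the monomer rate).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

__all__ = [
    "DimerDecay",
    "ScenarioConfig",
    "ParameterSet",
    "ESTIMATED_RANGES",
    "LOG_SAMPLED",
    "PERTURBABLE_PARAMS",
    "REFERENCE_SET_III",
    "REFERENCE_SET_IV",
    "parameter_sets_to_csv",
    "parameter_sets_from_csv",
]


class DimerDecay(str, enum.Enum):
    """Decay mode of clock-protein dimers relative to the monomer."""

    MONOMER_ONLY = "monomer_only"  # delta_hh = delta_pg = 0
    EQUAL = "equal"                # delta_hh = delta_pg = delta_p


@dataclass(frozen=True)
class ScenarioConfig:
    """One of the four genetic-control scenarios.

    I   = 1 binding site,  monomer-only decay
    II  = 1 binding site,  equal monomer/dimer decay
    III = 2 binding sites, monomer-only decay
    IV  = 2 binding sites, equal monomer/dimer decay
    """

    n_sites: int
    dimer_decay: DimerDecay

    _ROMAN = {
        ("I"): (1, DimerDecay.MONOMER_ONLY),
        ("II"): (1, DimerDecay.EQUAL),
        ("III"): (2, DimerDecay.MONOMER_ONLY),
        ("IV"): (2, DimerDecay.EQUAL),
    }

    def __post_init__(self) -> None:
        if self.n_sites not in (1, 2):
            raise ValueError(f"n_sites must be 1 or 2, got {self.n_sites}")
        if not isinstance(self.dimer_decay, DimerDecay):
            object.__setattr__(self, "dimer_decay", DimerDecay(self.dimer_decay))

    @classmethod
    def from_name(cls, name: str) -> "ScenarioConfig":
        try:
            n, d = cls._ROMAN[name.upper()]
        except KeyError:
            raise ValueError(f"unknown scenario {name!r}; expected I, II, III or IV")
        return cls(n, d)

    @property
    def name(self) -> str:
        for k, v in self._ROMAN.items():
            if v == (self.n_sites, self.dimer_decay):
                return k
        raise AssertionError("unreachable")


# Sampling ranges for the estimated parameters (copies, minutes, 1/min).
# G_min/G_max share the 0-2500 copies/nucleus range but are explored through
# the control-protein sweep rather than sampled.
ESTIMATED_RANGES: dict[str, tuple[float, float]] = {
    "K_hh": (10.0, 1000.0),
    "K_gg": (10.0, 1000.0),
    "K_pg": (10.0, 1000.0),
    "tau_m": (2.3, 8.1),
    "delta_p": (0.2, 0.5),
    "q": (0.03, 3.0),
    "k_r": (0.01, 1.0),
    "c_r": (1.0, 100.0),
}

# Parameters whose range spans powers of ten are drawn uniformly in the
# exponent; tau_m, delta_p and c_r are drawn uniformly on the raw scale.
LOG_SAMPLED = ("K_hh", "K_gg", "K_pg", "q", "k_r")


@dataclass(frozen=True)
class ParameterSet:
    """A full point in parameter space: fixed + estimated + scenario-derived.

    Units: delays and half-lives in minutes, decay constants in 1/min,
    production constants in copies/min (per mRNA for proteins), dissociation
    constants and copy numbers in copies per compartment, binding affinities
    in 1/copies; sigma in cells/somite, omega in somites/min.
    """

    # --- fixed block (experimentally determined) ---
    sigma: float = 5.0          # cells per somite
    omega: float = 1.0 / 30.0   # somite formation rate = tailbud clock frequency
    t_half: float = 60.0        # control-protein gradient half-life
    tau_p: float = 1.7          # clock protein translation delay
    alpha_p: float = 4.5        # clock protein production per mRNA
    alpha_d: float = 4.5        # signal protein production per mRNA
    kappa_m: float = 33.0       # clock mRNA production ceiling
    kappa_d: float = 33.0       # signal mRNA production ceiling
    k_a: float = 2e-6           # activator (Notch signal) binding affinity
    c_a: float = 25.0           # activator-RNAP cooperativity
    delta_M: float = 0.206      # clock mRNA decay
    tau_dp: float = 20.0        # signal protein translation delay
    delta_d: float = 0.23       # signal protein decay
    tau_dm: float = 12.4        # signal mRNA production delay
    delta_MD: float = 0.273     # signal mRNA decay

    # --- estimated block ---
    G_min: float = 0.0          # minimal total control protein (anterior PSM)
    G_max: float = 330.0        # maximal total control protein (tailbud)
    K_hh: float = 94.4          # clock homodimer dissociation constant
    K_gg: float = 133.0         # control homodimer dissociation constant
    K_pg: float = 47.6          # clock-control heterodimer dissociation constant
    tau_m: float = 4.23         # clock mRNA production delay
    delta_p: float = 0.393      # clock monomer decay
    q: float = 1.09             # RNAP-II binding weight (k_RNAP * [RNAP])
    k_r: float = 0.845          # clock homodimer DNA binding affinity
    c_r: float = 19.3           # homodimer-homodimer binding cooperativity

    # --- scenario-derived block ---
    delta_hh: float = 0.0       # clock homodimer decay
    delta_pg: float = 0.0       # heterodimer decay (clock subunit)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and non-negative, got {v}")
        if self.G_min > self.G_max:
            raise ValueError(f"G_min={self.G_min} exceeds G_max={self.G_max}")
        for d in ("tau_p", "tau_m", "tau_dp", "tau_dm"):
            if getattr(self, d) <= 0:
                raise ValueError(f"delay {d} must be strictly positive")

    def with_scenario(self, scenario: ScenarioConfig | str) -> "ParameterSet":
        """Return a copy with delta_hh/delta_pg set by the scenario."""
        if isinstance(scenario, str):
            scenario = ScenarioConfig.from_name(scenario)
        d = self.delta_p if scenario.dimer_decay is DimerDecay.EQUAL else 0.0
        return replace(self, delta_hh=d, delta_pg=d)

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    @property
    def delays(self) -> tuple[float, float, float, float]:
        return (self.tau_p, self.tau_m, self.tau_dp, self.tau_dm)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)


# The 22 strictly positive per-cell kinetic/regulatory constants perturbed in
# heterogeneity studies.  Scenario-derived dimer decays (zero in scenarios
# I/III) and the bookkeeping constants sigma/omega/G_min are excluded.
PERTURBABLE_PARAMS: tuple[str, ...] = (
    "alpha_p", "alpha_d", "kappa_m", "kappa_d",
    "tau_p", "tau_m", "tau_dp", "tau_dm",
    "delta_p", "delta_M", "delta_d", "delta_MD",
    "K_hh", "K_gg", "K_pg",
    "q", "k_r", "c_r", "k_a", "c_a",
    "t_half", "G_max",
)
assert len(PERTURBABLE_PARAMS) == 22


# Reference parameter sets: screen survivors with the largest period change
# Delta-T for scenarios III and IV.  The assignment of printed values to
# parameter names is reconstructed (every value falls inside its estimated
# range, and the scenario-III sweep loses its oscillation just above
# G = G_max = 330, matching the reported period-vs-G curve); treat these as
# representative realistic-wave parameter sets rather than exact optima.
REFERENCE_SET_III = ParameterSet(
    q=1.09, tau_m=4.23, k_r=0.845, K_pg=47.6, delta_p=0.393,
    K_hh=94.4, K_gg=133.0, c_r=19.3, G_min=0.0, G_max=330.0,
).with_scenario("III")

REFERENCE_SET_IV = ParameterSet(
    q=0.499, tau_m=5.93, k_r=0.578, K_pg=14.8, delta_p=0.210,
    K_hh=982.0, K_gg=738.0, c_r=12.4, G_min=80.0, G_max=2500.0,
).with_scenario("IV")


def parameter_sets_to_csv(sets: list[ParameterSet], path_or_buf) -> None:
    """Write parameter sets as a flat CSV, one row per set."""
    pd.DataFrame([s.to_dict() for s in sets]).to_csv(path_or_buf, index=False)


def parameter_sets_from_csv(path_or_buf) -> list[ParameterSet]:
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf)
    return [ParameterSet.from_dict(row.to_dict()) for _, row in df.iterrows()]
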