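"""Stage-1 parameter-space screen and per-collection sensitivity.

40,000 draws (or a reduced number) from the joint prior over the eight
estimated kinetic parameters are swept over control-protein levels in each
model scenario; the resulting collection memberships reproduce the
model-selection count table, and the coefficient of variation of each
parameter within a collection quantifies how tightly the corresponding
requirement pins that parameter down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .analysis import classify_collections, sweep_control_protein
from .params import ESTIMATED_RANGES, LOG_SAMPLED, ParameterSet, ScenarioConfig

__all__ = [
    "sample_parameter_sets",
    "run_screen",
    "sensitivity_cv",
    "ScreenResult",
    "ESTIMATED_NAMES",
]

ESTIMATED_NAMES = ("K_hh", "K_gg", "K_pg", "tau_m", "delta_p", "q", "k_r", "c_r")


def sample_parameter_sets(n: int, seed: int) -> pd.DataFrame:
    """Draw n joint samples of the eight estimated parameters.

    tau_m, delta_p and c_r are uniform on their ranges; the parameters whose
    ranges span powers of ten (the three dissociation constants, q and k_r)
    are uniform in the exponent.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in ESTIMATED_NAMES:
        lo, hi = ESTIMATED_RANGES[name]
        if name in LOG_SAMPLED:
            cols[name] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
        else:
            cols[name] = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(cols)


@dataclass
class ScreenResult:
    """Per-(sample, scenario) sweep outcomes plus batch metadata."""

    records: pd.DataFrame
    samples: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        """Collection count matrix: rows A (periodic), B, C, D; one column per scenario."""
        out = {}
        for scn, grp in self.records.groupby("scenario"):
            out[scn] = [int(grp[c].sum()) for c in ("A", "B", "C", "D")]
        return pd.DataFrame(out, index=["A", "B", "C", "D"])

    def collection(self, scenario: str, which: str) -> pd.DataFrame:
        """Estimated-parameter table of the samples in one collection."""
        grp = self.records[self.records["scenario"] == scenario.upper()]
        idx = grp.loc[grp[which.upper()], "sample"].to_numpy()
        return self.samples.iloc[idx]


def _sweep_one(sample_row: dict, scenario_name: str, base: ParameterSet,
               sweep_kwargs: dict) -> dict:
    ps = base.replace(**sample_row).with_scenario(scenario_name)
    sweep = sweep_control_protein(ps, scenario_name, **sweep_kwargs)
    flags = classify_collections(sweep)
    mask = sweep.periodic_mask
    periods = sweep.periods[mask]
    return {
        "scenario": scenario_name,
        **flags,
        "delta_T": sweep.delta_T,
        "n_periodic_levels": int(mask.sum()),
        "period_min": float(periods.min()) if periods.size else np.nan,
        "period_max": float(periods.max()) if periods.size else np.nan,
        "G_at_min_period": sweep.G_at_extremes[0],
        "G_at_max_period": sweep.G_at_extremes[1],
        "n_failures": len(sweep.failures),
    }


def run_screen(
    samples: pd.DataFrame,
    scenarios: "list[str] | tuple[str, ...]" = ("I", "II", "III", "IV"),
    G_step: float = 100.0,
    base: ParameterSet | None = None,
    n_jobs: int = 1,
    seed: int | None = None,
    progress: bool = False,
    **sweep_kwargs,
) -> ScreenResult:
    """Sweep every sample in every scenario and tabulate collection flags.

    Embarrassingly parallel over samples; output ordering is independent of
    the worker count.  Integration failures inside a sweep are recorded per
    level, never fatal.
    """
    scenarios = [ScenarioConfig.from_name(s).name for s in scenarios]
    base = base if base is not None else ParameterSet()
    sweep_kwargs = {"G_step": G_step, **sweep_kwargs}
    rows = [row._asdict() if hasattr(row, "_asdict") else dict(row)
            for _, row in samples.iterrows()]
    jobs = [(i, row, scn) for i, row in enumerate(rows) for scn in scenarios]
    it = jobs
    if progress:
        from tqdm import tqdm

        it = tqdm(jobs, desc="screen")
    if n_jobs == 1:
        results = [_sweep_one(row, scn, base, sweep_kwargs) for _, row, scn in it]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_sweep_one)(row, scn, base, sweep_kwargs) for _, row, scn in it
        )
    records = pd.DataFrame(results)
    records.insert(0, "sample", [i for i, _, _ in jobs])
    return ScreenResult(
        records=records,
        samples=samples.reset_index(drop=True),
        meta={"n_samples": len(samples), "scenarios": scenarios,
              "G_step": G_step, "seed": seed, **sweep_kwargs},
    )


def refine_delta_T(
    start: ParameterSet,
    scenario: str = "III",
    n_iter: int = 60,
    seed: int = 7,
    step: float = 0.18,
    period_band: tuple[float, float] = (27.0, 33.0),
    G_step: float = 25.0,
    sweep_margin: float = 100.0,
) -> tuple[ParameterSet, dict]:
    """Seeded stochastic coordinate ascent on Delta-T.

    From ``start``, multiplicatively jitters two random estimated parameters
    (plus G_max) per iteration, keeping a move when it raises Delta-T while
    the minimal period stays inside ``period_band`` (moves violating the
    band are penalised).  A cheap local helper for finding realistic-wave
    parameter sets; it makes no claim of global optimality.
    """
    rng = np.random.default_rng(seed)
    names = list(ESTIMATED_NAMES) + ["G_max"]
    bounds = {**ESTIMATED_RANGES, "G_max": (100.0, 2500.0)}

    def _score(ps: ParameterSet):
        sweep = sweep_control_protein(
            ps, scenario, G_step=G_step, G_max_sweep=ps.G_max + sweep_margin
        )
        per = sweep.periods[sweep.periodic_mask]
        if per.size == 0:
            return -np.inf, {}
        pmin = float(per.min())
        in_band = period_band[0] <= pmin <= period_band[1]
        score = sweep.delta_T - (0.0 if in_band else 10.0 * abs(pmin - np.mean(period_band)))
        return score, {"delta_T": sweep.delta_T, "period_min": pmin,
                       "period_max": float(per.max()),
                       **classify_collections(sweep)}

    cur = start.with_scenario(scenario)
    cur_score, cur_info = _score(cur)
    for _ in range(n_iter):
        cand = cur
        for nm in rng.choice(names, size=2, replace=False):
            lo, hi = bounds[nm]
            val = float(np.clip(getattr(cand, nm) * np.exp(rng.normal(0.0, step)), lo, hi))
            cand = cand.replace(**{nm: val})
        cand = cand.with_scenario(scenario)
        sc, info = _score(cand)
        if sc > cur_score:
            cur, cur_score, cur_info = cand, sc, info
    return cur, cur_info


def sensitivity_cv(result: ScreenResult, collection: str,
                   scenario: str | None = None) -> pd.DataFrame:
    """Coefficient of variation of each estimated parameter in a collection.

    C.V. = population standard deviation / mean over the member samples,
    computed on the raw parameter values, per scenario.  Scenarios whose
    collection is empty are omitted (an explicitly empty frame results if
    all are).
    """
    which = collection.upper()
    if which not in ("A", "B", "C", "D"):
        raise ValueError("collection must be one of A, B, C, D")
    scenarios = [scenario.upper()] if scenario else sorted(
        result.records["scenario"].unique()
    )
    out = {}
    for scn in scenarios:
        members = result.collection(scn, which)
        if len(members) == 0:
            continue
        vals = members[list(ESTIMATED_NAMES)]
        out[scn] = vals.std(ddof=0) / vals.mean()
    return pd.DataFrame(out)
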