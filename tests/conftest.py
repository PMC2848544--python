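"""Shared fixtures: synthetic trajectories, mini-lattice runs, reduced screen."""

from __future__ import annotations

import numpy as np
import pytest

from clockwave.analysis import SweepResult
from clockwave.fixtures import WAVE_DEMO_III
from clockwave.experiments import Intervention, simulate_tissue
from clockwave.tissue import LatticeSpec


class SyntheticTrajectory:
    """Duck-typed stand-in for dde.Trajectory built from an analytic signal.

    Synthetic: wraps a callable t -> state vector so classifier tests can
    feed known waveforms without integrating anything.
    """

    def __init__(self, fn, t0: float, t_end: float, dim: int = 8):
        self.fn = fn
        self.t0 = t0
        self.t_end = t_end
        self.dim = dim

    def sample(self, dt, t_start=None, t_stop=None):
        a = self.t0 if t_start is None else t_start
        b = self.t_end if t_stop is None else t_stop
        t = np.arange(a, b + 0.5 * dt, dt)
        vals = np.stack([np.broadcast_to(np.asarray(self.fn(x), float), (self.dim,))
                         for x in t])
        return t, vals


@pytest.fixture
def synthetic_trajectory():
    return SyntheticTrajectory


def sweep_from_curve(df) -> SweepResult:
    """Build a SweepResult from a synthetic period-vs-G table."""
    n = len(df)
    periods = df["period"].to_numpy(dtype=float)
    cls = list(df["classification"])
    amps = np.where(np.array(cls) == "periodic", 10.0, 0.0)[:, None] * np.ones((n, 8))
    return SweepResult(
        G_levels=df["G"].to_numpy(dtype=float), classifications=cls,
        periods=np.where([c == "periodic" for c in cls], periods, np.nan),
        amplitudes=amps,
    )


@pytest.fixture(scope="session")
def wave_demo():
    """Scenario-III collection-D parameter set used for stage-2 demonstrations."""
    return WAVE_DEMO_III


@pytest.fixture(scope="session")
def mini_lattice():
    return LatticeSpec(n_axial=10, n_lateral=1)


@pytest.fixture(scope="session")
def mini_her7kd(mini_lattice, wave_demo):
    return simulate_tissue(
        mini_lattice, wave_demo, "III",
        intervention=Intervention("her7_knockdown"), settle=500.0, t_end=200.0,
    )


@pytest.fixture(scope="session")
def mini_controlkd(mini_lattice, wave_demo):
    return simulate_tissue(
        mini_lattice, wave_demo, "III",
        intervention=Intervention("control_knockdown"), settle=500.0, t_end=200.0,
    )


@pytest.fixture(scope="session")
def demo_wave_run(wave_demo):
    """Homogeneous 50-cell stage-2 run with the realistic-wave set."""
    return simulate_tissue(
        LatticeSpec(50, 1), wave_demo, "III", settle=500.0, t_end=400.0,
    )


@pytest.fixture(scope="session")
def reduced_screen():
    """The scaled-down stage-1 screen: 500 sampled sets, all four scenarios,
    G step 100 (seeded).  Shared across the acceptance statistics tests."""
    from clockwave.screening import run_screen, sample_parameter_sets

    samples = sample_parameter_sets(500, seed=42)
    return run_screen(samples, scenarios=("I", "II", "III", "IV"), G_step=100.0)
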