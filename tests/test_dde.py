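"""DDE engine: closed forms, dense output, warm start, ODE limit."""

import numpy as np
import pytest
from numba import njit
from scipy.integrate import solve_ivp

from clockwave.dde import DelaySystemSpec, IntegrationError, delayed_component, integrate
from clockwave.equilibrium import solve_monomers
from clockwave.params import ParameterSet
from clockwave.tissue import two_cell_system


@njit(cache=True)
def rhs_zero(t, y, ts, hs, ys, qs, n, p, iv, out):
    out[0] = 0.0


@njit(cache=True)
def rhs_linear_delay(t, y, ts, hs, ys, qs, n, p, iv, out):
    out[0] = -delayed_component(ts, hs, ys, qs, n, t - 1.0, 0)


def _spec(rhs, history, delays=(1.0,)):
    return DelaySystemSpec(
        dim=1, delays=list(delays), rhs=rhs, p=np.zeros(1),
        iv=np.zeros(1, dtype=np.int64), t0=0.0, history=history,
    )


def test_constant_rhs_is_exact():
    traj = integrate(_spec(rhs_zero, 3.5), 10.0)
    assert traj.evaluate(7.3, 0) == pytest.approx(3.5, abs=1e-14)
    assert traj.y_end[0] == pytest.approx(3.5, abs=1e-14)


def test_linear_dde_closed_form():
    # dx/dt = -x(t-1), x ≡ 1 on [-1, 0]:
    # x(t) = 1 - t on [0,1]; x(t) = 1 - t + (t-1)^2/2 on [1,2]
    traj = integrate(_spec(rhs_linear_delay, 1.0), 2.0, rtol=1e-8, atol=1e-12)
    assert traj.evaluate(1.0, 0) == pytest.approx(0.0, abs=1e-6)
    assert traj.evaluate(2.0, 0) == pytest.approx(-0.5, rel=1e-6)
    # dense output between mesh points: x(1.5) = t^2/2 - 2t + 3/2 = -0.375
    assert traj.evaluate(1.5, 0) == pytest.approx(-0.375, rel=1e-6)


def test_endpoint_evaluation_matches_final_state():
    traj = integrate(_spec(rhs_linear_delay, 1.0), 5.0)
    assert traj.evaluate(traj.t_end, 0) == pytest.approx(traj.y_end[0], rel=1e-12)
    # interior mesh point: stored left state of a step equals the interpolant
    i = traj.n // 2
    t_mesh = traj.ts[i]
    if t_mesh > traj.t0:
        assert traj.evaluate(t_mesh, 0) == pytest.approx(traj.ys[i, 0], rel=1e-12)


def test_out_of_window_access_raises():
    traj = integrate(_spec(rhs_zero, 1.0), 1.0)
    with pytest.raises(ValueError):
        traj.evaluate(2.0, 0)


def test_tolerance_tightening_converges():
    ends = {rt: integrate(_spec(rhs_linear_delay, 1.0), 8.0, rtol=rt, atol=rt * 1e-3).y_end[0]
            for rt in (1e-6, 1e-7, 1e-10)}
    err_coarse = abs(ends[1e-6] - ends[1e-10])
    err_fine = abs(ends[1e-7] - ends[1e-10])
    # global error stays a small multiple of the step tolerance and shrinks with it
    assert err_coarse < 1e-5
    assert err_fine < err_coarse


def test_warm_start_matches_single_call():
    one = integrate(_spec(rhs_linear_delay, 1.0), 6.0, rtol=1e-8, atol=1e-11)
    first = integrate(_spec(rhs_linear_delay, 1.0), 3.0, rtol=1e-8, atol=1e-11)
    second_spec = DelaySystemSpec(
        dim=1, delays=[1.0], rhs=rhs_linear_delay, p=np.zeros(1),
        iv=np.zeros(1, dtype=np.int64), t0=3.0, history=first,
    )
    second = integrate(second_spec, 6.0, rtol=1e-8, atol=1e-11)
    assert second.y_end[0] == pytest.approx(one.y_end[0], abs=1e-7)
    # chained trajectory remains evaluable across the junction
    assert second.evaluate(3.0, 0) == pytest.approx(one.evaluate(3.0, 0), abs=1e-7)


def _delay_free_reference(params, G, t_end, y0):
    """Stiff ODE integration of the delay-free circuit (independent route)."""
    sc_sites = 2.0

    def rhs(t, y):
        out = np.zeros(8)
        for c in range(2):
            s = 4 * c
            P, M, D, MD = y[s:s + 4]
            p, g = solve_monomers(max(P, 0.0), G, params.K_hh, params.K_gg, params.K_pg)
            hh = p * p / params.K_hh
            pg = p * g / params.K_pg
            out[s] = params.alpha_p * max(M, 0.0) - (
                params.delta_p * p + 2 * params.delta_hh * hh + params.delta_pg * pg)
            other = y[4 * (1 - c) + 2]
            sbar = max(other, 0.0) / 2.0
            act = params.q * (1 + params.c_a * params.k_a * sbar)
            x = params.k_r * hh
            fr = 1 + 2 * x + params.c_r * x * x if sc_sites == 2.0 else 1 + x
            f = act / (act + (1 + params.k_a * sbar) * fr)
            out[s + 1] = params.kappa_m * f - params.delta_M * M
            out[s + 2] = params.alpha_d * max(MD, 0.0) - params.delta_d * D
            fd = params.q / (params.q + 1 + params.k_r * hh)
            out[s + 3] = params.kappa_d * fd - params.delta_MD * MD
        return out

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-9, atol=1e-12)
    return sol.y[:, -1]


def test_ode_limit_matches_stiff_reference():
    """With all delays shrunk to numerically negligible values the DDE
    integration must agree with a delay-free stiff ODE solve."""
    tiny = 1e-7
    ps = ParameterSet(tau_p=tiny, tau_m=tiny, tau_dp=tiny, tau_dm=tiny)
    spec = two_cell_system(ps, "III", G=100.0)
    rtol = 1e-6
    traj = integrate(spec, 30.0, rtol=rtol, atol=1e-9)
    ref = _delay_free_reference(ps.with_scenario("III"), 100.0, 30.0, np.zeros(8))
    scale = np.maximum(1.0, np.abs(ref))
    assert np.all(np.abs(traj.y_end - ref) / scale < 10 * rtol)


def test_step_size_underflow_reported():
    @njit(cache=True)
    def rhs_blow(t, y, ts, hs, ys, qs, n, p, iv, out):
        out[0] = y[0] * y[0] + 1.0

    with pytest.raises(IntegrationError):
        integrate(_spec(rhs_blow, 1.0, delays=(10.0,)), 50.0)


def test_csv_and_binary_round_trip(tmp_path):
    traj = integrate(_spec(rhs_linear_delay, 1.0), 4.0)
    csv_path = tmp_path / "traj.csv"
    traj.to_csv(csv_path, dt=0.5)
    import pandas as pd

    df = pd.read_csv(csv_path)
    assert df.shape[0] == 9 and "y0" in df
    npz = tmp_path / "traj.npz"
    traj.save(npz)
    from clockwave.dde import Trajectory

    back = Trajectory.load(npz)
    for t in (0.7, 2.2, 3.9):
        assert back.evaluate(t, 0) == pytest.approx(traj.evaluate(t, 0), rel=1e-14)
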