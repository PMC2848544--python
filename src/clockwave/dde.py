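"""Method-of-steps integration of constant-delay DDE systems.

The integrator is an adaptive embedded Dormand-Prince 5(4) pair with the
standard quartic continuous extension.  Every accepted step stores its
interpolation polynomial, and delayed state values are served from this
accumulated piecewise polynomial (or from the history segment before t0).
The step size is capped at the smallest delay so that delayed lookups always
land on completed steps; for delays shorter than 0.5 min the cap is relaxed
and lookups just beyond the last completed step extrapolate its polynomial,
which is accurate to the same order as the method and lets the integrator
degenerate gracefully to the delay-free (ODE) limit.

Right-hand sides are numba-compiled functions with the fixed signature

    rhs(t, y, ts, hs, ys, qs, n, p, iv, out)

where (ts, hs, ys, qs, n) are the solution-buffer arrays (use
``delayed_component`` to read a delayed state component from them), ``p`` and
``iv`` are free float/int parameter vectors, and ``out`` receives dy/dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DelaySystemSpec",
    "Trajectory",
    "integrate",
    "evaluate",
    "delayed_component",
    "IntegrationError",
]

_HIST_PAD = 1e8  # pseudo-step width covering constant pre-history

# Dormand-Prince 5(4) tableau.
_C2, _C3, _C4, _C5 = 0.2, 0.3, 0.8, 8.0 / 9.0
_A21 = 0.2
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0, 49.0 / 176.0, -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E = np.array(
    [71.0 / 57600.0, 0.0, -71.0 / 16695.0, 71.0 / 1920.0,
     -17253.0 / 339200.0, 22.0 / 525.0, -1.0 / 40.0]
)
# Quartic dense-output coefficients (7 stages x 4 powers of theta).
_P = np.array([
    [1.0, -8048581381.0 / 2820520608.0, 8663915743.0 / 2820520608.0, -12715105075.0 / 11282082432.0],
    [0.0, 0.0, 0.0, 0.0],
    [0.0, 131558114200.0 / 32700410799.0, -68118460800.0 / 10900136933.0, 87487479700.0 / 32700410799.0],
    [0.0, -1754552775.0 / 470086768.0, 14199869525.0 / 1410260304.0, -10690763975.0 / 1880347072.0],
    [0.0, 127303824393.0 / 49829197408.0, -318862633887.0 / 49829197408.0, 701980252875.0 / 199316789632.0],
    [0.0, -282668133.0 / 205662961.0, 2019193451.0 / 616988883.0, -1453857185.0 / 822651844.0],
    [0.0, 40617522.0 / 29380423.0, -110615467.0 / 29380423.0, 69997945.0 / 29380423.0],
])


class IntegrationError(RuntimeError):
    pass


@njit(cache=True, inline="always")
def delayed_component(ts, hs, ys, qs, n, t, comp):
    """Evaluate state component ``comp`` at time ``t`` from the step buffers."""
    i = np.searchsorted(ts[:n], t, side="right") - 1
    if i < 0:
        i = 0
    elif i >= n:
        i = n - 1
    th = (t - ts[i]) / hs[i]
    q0 = qs[i, comp, 0]
    q1 = qs[i, comp, 1]
    q2 = qs[i, comp, 2]
    q3 = qs[i, comp, 3]
    return ys[i, comp] + hs[i] * ((((q3 * th + q2) * th + q1) * th + q0) * th)


@njit(cache=True)
def _sample_buffers(ts, hs, ys, qs, n, tgrid, out):
    for k in range(tgrid.shape[0]):
        t = tgrid[k]
        for c in range(ys.shape[1]):
            out[k, c] = delayed_component(ts, hs, ys, qs, n, t, c)


@njit(cache=True)
def _run(rhs, p, iv, t_end, max_step, min_delay, rtol, atol,
         ts, hs, ys, qs, n, t, y, h, E, P):
    """Advance the solution to t_end, appending accepted steps to the buffers.

    When the step exceeds the smallest delay, delayed lookups overlap the
    step being built; the step is then iterated against its own developing
    interpolant (predictor-corrector on the continuous extension) until the
    stage values settle, as short-delay DDE solvers do.

    Returns (status, n, t, h): status 0 = reached t_end, 1 = buffers full
    (caller grows and resumes), 2 = step-size underflow.
    """
    dim = y.shape[0]
    cap = ts.shape[0]
    k = np.empty((7, dim))
    ytmp = np.empty(dim)
    ynew = np.empty(dim)
    yprev = np.empty(dim)
    rhs(t, y, ts, hs, ys, qs, n, p, iv, k[0])
    min_h = 1e-10 * max(1.0, abs(t_end))
    while t < t_end - 1e-12 * max(1.0, abs(t_end)):
        if h > max_step:
            h = max_step
        clipped = False
        if t + h >= t_end:
            h = t_end - t
            clipped = True
        if n >= cap:
            return 1, n, t, h

        overlap = h > min_delay
        n_use = n
        n_iter = 5 if overlap else 1
        for it in range(n_iter):
            for i in range(dim):
                ytmp[i] = y[i] + h * _A21 * k[0, i]
            rhs(t + _C2 * h, ytmp, ts, hs, ys, qs, n_use, p, iv, k[1])
            for i in range(dim):
                ytmp[i] = y[i] + h * (_A31 * k[0, i] + _A32 * k[1, i])
            rhs(t + _C3 * h, ytmp, ts, hs, ys, qs, n_use, p, iv, k[2])
            for i in range(dim):
                ytmp[i] = y[i] + h * (_A41 * k[0, i] + _A42 * k[1, i] + _A43 * k[2, i])
            rhs(t + _C4 * h, ytmp, ts, hs, ys, qs, n_use, p, iv, k[3])
            for i in range(dim):
                ytmp[i] = y[i] + h * (
                    _A51 * k[0, i] + _A52 * k[1, i] + _A53 * k[2, i] + _A54 * k[3, i])
            rhs(t + _C5 * h, ytmp, ts, hs, ys, qs, n_use, p, iv, k[4])
            for i in range(dim):
                ytmp[i] = y[i] + h * (
                    _A61 * k[0, i] + _A62 * k[1, i] + _A63 * k[2, i]
                    + _A64 * k[3, i] + _A65 * k[4, i])
            rhs(t + h, ytmp, ts, hs, ys, qs, n_use, p, iv, k[5])
            for i in range(dim):
                ynew[i] = y[i] + h * (
                    _B1 * k[0, i] + _B3 * k[2, i] + _B4 * k[3, i]
                    + _B5 * k[4, i] + _B6 * k[5, i])
            rhs(t + h, ynew, ts, hs, ys, qs, n_use, p, iv, k[6])
            if not overlap:
                break
            # refresh the trial interpolant in scratch slot n and re-solve
            ts[n] = t
            hs[n] = h
            for i in range(dim):
                ys[n, i] = y[i]
                for j in range(4):
                    acc = 0.0
                    for s in range(7):
                        acc += k[s, i] * P[s, j]
                    qs[n, i, j] = acc
            if it > 0:
                settled = True
                for i in range(dim):
                    sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
                    if abs(ynew[i] - yprev[i]) > 0.05 * sc:
                        settled = False
                        break
                if settled:
                    break
            for i in range(dim):
                yprev[i] = ynew[i]
            n_use = n + 1

        errnorm = 0.0
        for i in range(dim):
            e = 0.0
            for s in range(7):
                e += E[s] * k[s, i]
            e *= h
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            errnorm += (e / sc) ** 2
        errnorm = np.sqrt(errnorm / dim)

        if errnorm <= 1.0:
            ts[n] = t
            hs[n] = h
            for i in range(dim):
                ys[n, i] = y[i]
                for j in range(4):
                    acc = 0.0
                    for s in range(7):
                        acc += k[s, i] * P[s, j]
                    qs[n, i, j] = acc
            n += 1
            t += h
            for i in range(dim):
                y[i] = ynew[i]
                k[0, i] = k[6, i]
            if errnorm == 0.0:
                fac = 10.0
            else:
                fac = min(10.0, max(0.2, 0.9 * errnorm ** -0.2))
            if not clipped:
                h *= fac
        else:
            h *= max(0.2, 0.9 * errnorm ** -0.2)
            if h < min_h:
                return 2, n, t, h
    return 0, n, t, h


@dataclass
class Trajectory:
    """Dense, interpolable DDE solution over [t0, t_end].

    The step buffers also hold the history segment (steps before t0), so a
    Trajectory can serve as the history function of a successor integration
    (warm start).
    """

    ts: np.ndarray      # step left endpoints, ascending
    hs: np.ndarray      # step widths
    ys: np.ndarray      # (n, dim) state at step left endpoints
    qs: np.ndarray      # (n, dim, 4) dense-output polynomial coefficients
    n: int              # number of valid steps
    t0: float
    t_end: float
    y_end: np.ndarray
    dim: int
    meta: dict = field(default_factory=dict)

    def evaluate(self, t, component: int | None = None):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo = self.ts[0] if self.n > 0 else self.t0
        if np.any(t_arr > self.t_end + 1e-9) or np.any(t_arr < lo - 1e-9):
            raise ValueError(
                f"evaluation time outside covered window [{lo}, {self.t_end}]"
            )
        out = np.empty((t_arr.shape[0], self.dim))
        _sample_buffers(self.ts, self.hs, self.ys, self.qs, self.n, t_arr, out)
        if component is not None:
            out = out[:, component]
        return out[0] if np.ndim(t) == 0 else out

    def sample(self, dt: float, t_start: float | None = None,
               t_stop: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Uniform-grid samples (times, values[(n_times, dim)])."""
        a = self.t0 if t_start is None else t_start
        b = self.t_end if t_stop is None else t_stop
        tgrid = np.arange(a, b + 0.5 * dt, dt)
        tgrid = tgrid[tgrid <= self.t_end + 1e-12]
        out = np.empty((tgrid.shape[0], self.dim))
        _sample_buffers(self.ts, self.hs, self.ys, self.qs, self.n, tgrid, out)
        return tgrid, out

    def to_frame(self, dt: float, columns: Sequence[str] | None = None) -> pd.DataFrame:
        tgrid, vals = self.sample(dt)
        cols = columns if columns is not None else [f"y{i}" for i in range(self.dim)]
        df = pd.DataFrame(vals, columns=cols)
        df.insert(0, "t", tgrid)
        return df

    def to_csv(self, path, dt: float, columns: Sequence[str] | None = None) -> None:
        self.to_frame(dt, columns).to_csv(path, index=False)

    def save(self, path) -> None:
        """Exact binary reload container."""
        np.savez_compressed(
            path, ts=self.ts[: self.n], hs=self.hs[: self.n], ys=self.ys[: self.n],
            qs=self.qs[: self.n], t0=self.t0, t_end=self.t_end, y_end=self.y_end,
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        z = np.load(path)
        ts = z["ts"]
        return cls(
            ts=ts, hs=z["hs"], ys=z["ys"], qs=z["qs"], n=ts.shape[0],
            t0=float(z["t0"]), t_end=float(z["t_end"]), y_end=z["y_end"],
            dim=z["ys"].shape[1],
        )

    def history_buffers(self, max_delay: float):
        """Copy of the trailing step window [t_end - max_delay, t_end]."""
        right = self.ts[: self.n] + self.hs[: self.n]
        keep = np.nonzero(right >= self.t_end - max_delay - 1e-9)[0]
        if keep.size == 0:
            raise ValueError("trajectory shorter than the requested history window")
        sl = slice(keep[0], self.n)
        return (
            self.ts[sl].copy(), self.hs[sl].copy(),
            self.ys[sl].copy(), self.qs[sl].copy(),
        )


@dataclass
class DelaySystemSpec:
    """A constant-delay DDE system ready for integration.

    ``history`` is either a constant state vector (used on the whole
    pre-window, e.g. zeros for a cold start) or a predecessor Trajectory whose
    end time equals ``t0`` (warm start).
    """

    dim: int
    delays: Sequence[float]
    rhs: Callable
    p: np.ndarray
    iv: np.ndarray
    t0: float = 0.0
    history: "np.ndarray | float | Trajectory" = 0.0

    def __post_init__(self) -> None:
        self.p = np.ascontiguousarray(self.p, dtype=np.float64)
        self.iv = np.ascontiguousarray(self.iv, dtype=np.int64)
        d = np.asarray(self.delays, dtype=float)
        if d.size == 0 or np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("delays must be a non-empty list of positive finite values")
        if isinstance(self.history, Trajectory):
            if abs(self.history.t_end - self.t0) > 1e-9:
                raise ValueError("warm-start history must end exactly at t0")
        else:
            h = np.asarray(self.history, dtype=float)
            if h.ndim == 0:
                h = np.full(self.dim, float(h))
            if h.shape != (self.dim,):
                raise ValueError("constant history must be scalar or length-dim")
            self.history = h


def integrate(
    spec: DelaySystemSpec,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_step: float | None = None,
) -> Trajectory:
    """Integrate the system from spec.t0 to t_end with dense output."""
    if t_end <= spec.t0:
        raise ValueError("t_end must exceed t0")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    min_delay = float(np.min(np.asarray(spec.delays, dtype=float)))
    max_delay = float(np.max(np.asarray(spec.delays, dtype=float)))
    if max_step is None:
        # keep delayed lookups behind the integration front when delays allow
        max_step = min_delay if min_delay >= 0.5 else 0.5

    dim = spec.dim
    span = t_end - spec.t0
    cap = int(span / (0.25 * max_step)) + 64

    if isinstance(spec.history, Trajectory):
        h_ts, h_hs, h_ys, h_qs = spec.history.history_buffers(max_delay)
        n0 = h_ts.shape[0]
        y0 = spec.history.y_end.copy()
    else:
        n0 = 1
        h_ts = np.array([spec.t0 - _HIST_PAD])
        h_hs = np.array([_HIST_PAD])
        h_ys = spec.history.reshape(1, dim).astype(float).copy()
        h_qs = np.zeros((1, dim, 4))
        y0 = spec.history.copy()

    ts = np.empty(n0 + cap)
    hs = np.empty(n0 + cap)
    ys = np.empty((n0 + cap, dim))
    qs = np.empty((n0 + cap, dim, 4))
    ts[:n0], hs[:n0], ys[:n0], qs[:n0] = h_ts, h_hs, h_ys, h_qs

    t = spec.t0
    y = np.array(y0, dtype=float)
    h = min(max_step, span / 10.0)
    n = n0
    while True:
        status, n, t, h = _run(
            spec.rhs, spec.p, spec.iv, float(t_end), float(max_step),
            float(min_delay), float(rtol), float(atol),
            ts, hs, ys, qs, n, t, y, h, _E, _P,
        )
        if status == 0:
            break
        if status == 2:
            raise IntegrationError(f"step size underflow at t={t:.6g}")
        grow = ts.shape[0] * 2
        ts = np.resize(ts, grow)
        hs = np.resize(hs, grow)
        ys2 = np.empty((grow, dim)); ys2[: ys.shape[0]] = ys; ys = ys2
        qs2 = np.empty((grow, dim, 4)); qs2[: qs.shape[0]] = qs; qs = qs2

    return Trajectory(
        ts=ts, hs=hs, ys=ys, qs=qs, n=n, t0=spec.t0, t_end=float(t_end),
        y_end=y.copy(), dim=dim,
        meta={"rtol": rtol, "atol": atol, "max_step": max_step,
              "n_steps": int(n - n0)},
    )


def evaluate(traj: Trajectory, t, component: int | None = None):
    """Interpolant value(s) of a trajectory at time(s) t."""
    return traj.evaluate(t, component)
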