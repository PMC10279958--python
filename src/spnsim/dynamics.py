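"""Time-course integration and steady-state location by integration.

Integration uses LSODA (stiff/non-stiff switching) with the tight tolerances
the stripe pattern requires (atol 1e-13, rtol 1e-8 by default).  A state that
turns non-finite mid-run — possible only with the exponentiation guards
disabled — is reported as ``invalid_state`` rather than raising.

Steady states are found purely by integration (no Newton polishing): the
model is advanced over doubling time spans and declared converged once both
the right-hand side and the state displacement over the last span drop below
the resolution ("distance and time" criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint

__all__ = ["Trajectory", "SteadyState", "run_timecourse", "find_steady_state"]


class _InvalidState(Exception):
    pass


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray
    status: str  # ok | invalid_state | no_convergence
    solver_stats: dict = field(default_factory=dict)
    species_names: list | None = None
    n_cells: int | None = None

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, cell, species, value) table."""
        names = self.species_names or [f"x{i}" for i in range(self.states.shape[1])]
        recs = []
        for ti, t in enumerate(self.times):
            for si, name in enumerate(names):
                parts = name.rsplit("_", 2)
                cell = f"{parts[1]}_{parts[2]}" if len(parts) == 3 else "0_0"
                sp = parts[0] if len(parts) == 3 else name
                recs.append((t, cell, sp, self.states[ti, si]))
        return pd.DataFrame(recs, columns=["time", "cell", "species", "value"])


@dataclass
class SteadyState:
    state: np.ndarray
    residual: float
    t_reached: float
    converged: bool
    status: str = "ok"


def _rhs_of(model, params):
    if params is not None:
        return model.rhs_for(params)
    return model.rhs


def _odeint_funcs(model, params):
    """(f(y,t), jac or None) plus an invalid-state raising wrapper."""
    if hasattr(model, "odeint_pair"):
        pvec = params if params is not None else model.param_vector
        f, jac, _ = model.odeint_pair(pvec)
        return f, jac
    rhs = _rhs_of(model, params)

    def f(y, t):
        dy = rhs(t, y)
        if not np.all(np.isfinite(dy)):
            raise _InvalidState
        return dy

    return f, None


def run_timecourse(
    model,
    x0,
    t_end: float = 1100.0,
    dt_out: float = 5.0,
    atol: float = 1e-13,
    rtol: float = 1e-8,
    params: np.ndarray | None = None,
    mxstep: int = 3000,
) -> Trajectory:
    """Integrate from ``x0`` and sample at 0, dt_out, ..., t_end."""
    if t_end <= 0 or dt_out <= 0:
        raise ValueError("t_end and dt_out must be positive")
    x0 = np.asarray(x0, dtype=float)
    f, jac = _odeint_funcs(model, params)
    times = np.arange(0.0, t_end + dt_out / 2, dt_out)

    status = "ok"
    info: dict = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            states, info = odeint(
                f, x0, times, Dfun=jac, atol=atol, rtol=rtol, mxstep=mxstep,
                full_output=True,
            )
        if not np.all(np.isfinite(states)):
            status = "invalid_state"
        elif info.get("message") != "Integration successful.":
            status = "no_convergence"
            n_ok = int(np.sum(info["tcur"] > 0)) + 1
            states = states[: max(n_ok, 1)]
            times = times[: states.shape[0]]
    except (_InvalidState, FloatingPointError):
        status = "invalid_state"
        states = x0[None, :]
        times = times[:1]
    except Exception:
        status = "no_convergence"
        states = x0[None, :]
        times = times[:1]
    stats = {"nst": int(info["nst"][-1]) if "nst" in info else 0, "message": info.get("message", status)}
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        status=status,
        solver_stats=stats,
        species_names=getattr(model, "species_names", None),
        n_cells=getattr(model, "n_cells", None),
    )


def find_steady_state(
    model,
    x0,
    resolution: float = 1e-4,
    t_max: float = 1e6,
    params: np.ndarray | None = None,
    atol: float = 1e-13,
    rtol: float = 1e-8,
    first_span: float = 50.0,
    mxstep: int = 20000,
) -> SteadyState:
    """Locate the steady state reachable from ``x0`` by integration alone.

    Convergence requires both max-norm RHS < resolution and state movement
    over the last (doubling) span < resolution.
    """
    x = np.asarray(x0, dtype=float)
    f, jac = _odeint_funcs(model, params)
    rhs = _rhs_of(model, params)

    t = 0.0
    span = float(first_span)
    while t < t_max:
        span = min(span, t_max - t)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out, info = odeint(
                    f, x, [0.0, span], Dfun=jac, atol=atol, rtol=rtol,
                    mxstep=mxstep, full_output=True,
                )
        except (_InvalidState, FloatingPointError):
            return SteadyState(x, np.inf, t, False, "invalid_state")
        except Exception:
            return SteadyState(x, np.inf, t, False, "no_convergence")
        if info.get("message") != "Integration successful." or not np.all(
            np.isfinite(out[-1])
        ):
            return SteadyState(x, np.inf, t, False, "no_convergence")
        x_new = out[-1]
        t += span
        moved = float(np.max(np.abs(x_new - x)))
        residual = float(np.max(np.abs(rhs(t, x_new))))
        x = x_new
        if residual < resolution and moved < resolution:
            return SteadyState(x, residual, t, True)
        span *= 2.0
    residual = float(np.max(np.abs(rhs(t, x))))
    return SteadyState(x, residual, t, False, "no_convergence")
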