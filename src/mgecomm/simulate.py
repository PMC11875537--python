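"""Time integration of community models and steady-state detection.

Single trajectories are integrated with an adaptive, stiff-capable solver
(LSODA by default).  Ensembles of independent initializations are integrated
as one stacked, vectorized system with an explicit adaptive solver
(:func:`solve_steady_batch`), in time chunks with per-member early
retirement once the residual ``max |dy/dt|`` drops below the convergence
tolerance.  Negative abundances and carrier overshoots produced by the
solver are clamped on output, never inside the RHS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import CommunityModel, CommunityState, Kernel

__all__ = [
    "IntegrationError",
    "Trajectory",
    "SteadyState",
    "integrate",
    "find_steady_state",
    "solve_steady_batch",
    "detect_limit_cycle",
]

#: default equilibrium criterion: max |d/dt| below this rate (hr^-1)
CONVERGENCE_TOL = 1e-6
#: abundances below this floor are treated as extinct in attractor analyses
EXTINCTION_FLOOR = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails (e.g. step-size collapse)."""


@dataclass
class Trajectory:
    """A saved trajectory: times (hr) and the packed ODE states."""

    model: Optional[CommunityModel]
    times: np.ndarray
    ys: np.ndarray  # (n_times, dim), kernel layout
    kernel: Optional[Kernel] = None
    rhs_fn: Optional[Callable] = None  # f(t, y) used for residuals

    @property
    def states(self) -> list:
        """Trajectory as a list of :class:`CommunityState`."""
        return self.kernel.unpack(self.ys)

    def state_at(self, t: float) -> np.ndarray:
        """Packed state at time t, linearly interpolated between saved points."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside trajectory range")
        out = np.empty(self.ys.shape[1])
        for k in range(self.ys.shape[1]):
            out[k] = np.interp(t, self.times, self.ys[:, k])
        return out

    def residual_at(self, t: float) -> float:
        y = self.state_at(t)
        if self.rhs_fn is not None:
            return float(np.abs(self.rhs_fn(t, y)).max())
        return float(self.kernel.residual(y[None, :])[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table with columns time, entity, value.

        Entities are labelled ``s_i`` and ``p_i_j`` (0-based indices).
        """
        if self.kernel is None:
            cols = [f"y_{k}" for k in range(self.ys.shape[1])]
        else:
            m = self.kernel.m
            cols = [f"s_{i}" for i in range(m)]
            if self.kernel.kind == "growth":
                cols += [f"p_{i}_{j}" for i, j in zip(*self.kernel.offdiag)]
            elif self.kernel.kind == "selection":
                j = self.kernel.model.donor_index
                cols += [f"p_{i}_{j}" for i in range(m)]
        df = pd.DataFrame(self.ys, columns=cols)
        df.insert(0, "time", self.times)
        return df.melt(id_vars="time", var_name="entity", value_name="value")


@dataclass
class SteadyState:
    """Final state of a relaxation run.

    ``converged`` is True iff ``residual`` (max |d/dt| at the final state,
    hr^-1) fell below the convergence tolerance within the time cap.
    """

    state: CommunityState
    converged: bool
    residual: float
    t_final: float


def _check_solution(sol, model, context=""):
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed{context}: {sol.message} "
            f"(model variant={getattr(model, 'variant', '?')})"
        )


def integrate(
    model: CommunityModel,
    init: CommunityState,
    t_end: float,
    *,
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
    rhs_override: Optional[Callable] = None,
) -> Trajectory:
    """Integrate one community from ``init`` to ``t_end`` hours.

    ``rhs_override(t, y)`` replaces the model RHS (used to inject synthetic
    vector fields in tests); the state layout is then caller-defined.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    kern = Kernel(model) if model is not None else None
    if rhs_override is not None:
        fun = rhs_override
        y0 = np.asarray(init, float) if not isinstance(init, CommunityState) else kern.pack([init])[0]
    else:
        fun = lambda t, y: kern.rhs(y[None, :])[0]
        y0 = kern.pack([init])[0]
    sol = solve_ivp(fun, (0.0, float(t_end)), y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    _check_solution(sol, model)
    ys = sol.y.T.copy()
    if rhs_override is None:
        kern.clamp(ys)
    return Trajectory(model=model, times=sol.t.copy(), ys=ys, kernel=kern, rhs_fn=rhs_override)


def find_steady_state(
    model: CommunityModel,
    init: CommunityState,
    horizon: float = 2000.0,
    *,
    tol: float = CONVERGENCE_TOL,
    hard_cap: float = 10000.0,
    extension: float = 500.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> SteadyState:
    """Relax one community to equilibrium.

    Integrates to ``horizon`` hours, then—if the residual max |d/dt| still
    exceeds ``tol``—extends in ``extension``-hour increments up to
    ``hard_cap``.  Non-convergence is reported through the ``converged``
    flag, not an error.
    """
    kern = Kernel(model)
    y = kern.pack([init])[0]
    t = 0.0
    target = float(horizon)
    while True:
        sol = solve_ivp(
            lambda tt, yy: kern.rhs(yy[None, :])[0],
            (t, target),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=[target],
        )
        _check_solution(sol, model, context=f" at t={t}")
        y = sol.y[:, -1].copy()
        kern.clamp(y[None, :])
        t = target
        res = float(kern.residual(y[None, :])[0])
        if res < tol:
            converged = True
            break
        if t >= hard_cap:
            converged = False
            break
        target = min(t + extension, hard_cap)
    return SteadyState(state=kern.unpack(y[None, :])[0], converged=converged, residual=res, t_final=t)


def solve_steady_batch(
    model: CommunityModel,
    inits,
    *,
    horizon: float = 2000.0,
    tol: float = CONVERGENCE_TOL,
    chunk: float = 250.0,
    hard_cap: float = 10000.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
    early_stop: bool = True,
):
    """Relax a batch of independent initializations to equilibrium.

    The batch is integrated as one stacked system (the members are
    decoupled, so stacking only shares the adaptive step control) in
    ``chunk``-hour segments; members whose residual drops below ``tol``
    retire from the batch.  With ``early_stop=False`` every member runs to
    at least ``horizon`` hours before retiring, matching the fixed-horizon
    protocol; the default retires converged members as soon as they
    equilibrate, which is equivalent within the convergence tolerance.

    Returns ``(Y, converged, residual, t_final)`` where ``Y`` is the
    (B, dim) array of final packed states (clamped to the physical domain).
    """
    kern = Kernel(model)
    if isinstance(inits, np.ndarray):
        Y = inits.astype(float).copy()
    else:
        Y = kern.pack(inits)
    B = Y.shape[0]
    converged = np.zeros(B, dtype=bool)
    residual = np.full(B, np.inf)
    t_final = np.zeros(B)
    active = np.arange(B)
    t = 0.0
    while active.size:
        t_next = min(t + chunk, hard_cap)
        Ya = Y[active]
        na = Ya.shape[0]
        sol = solve_ivp(
            kern.rhs_flat,
            (t, t_next),
            Ya.ravel(),
            args=(na,),
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=[t_next],
        )
        if sol.success:
            Ya = sol.y[:, -1].reshape(na, kern.dim)
        else:
            # step-size collapse in the stacked system: fall back to a
            # stiff-capable solver member by member for this chunk
            for row in range(na):
                single = solve_ivp(
                    lambda tt, yy: kern.rhs(yy[None, :])[0],
                    (t, t_next),
                    Ya[row],
                    method="LSODA",
                    rtol=rtol,
                    atol=atol,
                    t_eval=[t_next],
                )
                _check_solution(single, model, context=f" at t={t} (member fallback)")
                Ya[row] = single.y[:, -1]
        kern.clamp(Ya)
        Y[active] = Ya
        t = t_next
        res = kern.residual(Ya)
        residual[active] = res
        t_final[active] = t
        done = res < tol
        if not early_stop and t < horizon:
            done[:] = False
        if t >= hard_cap:
            converged[active] = done
            break
        converged[active[done]] = True
        active = active[~done]
    return Y, converged, residual, t_final


def detect_limit_cycle(
    trajectory: Trajectory,
    window: float,
    *,
    threshold: float = 0.05,
    tol: float = CONVERGENCE_TOL,
) -> bool:
    """Sustained-oscillation proxy on a finished trajectory.

    True iff the states at ``t_end`` and ``t_end - window`` differ by more
    than ``threshold`` (Euclidean, species abundances only) while the
    residual at both times exceeds the convergence tolerance — i.e. the
    system keeps moving but does not settle.
    """
    t_end = trajectory.times[-1]
    t0 = trajectory.times[0]
    if t_end - t0 < 2 * window:
        raise ValueError("trajectory must cover at least twice the window")
    y1 = trajectory.state_at(t_end - window)
    y2 = trajectory.state_at(t_end)
    if trajectory.kernel is not None:
        m = trajectory.kernel.m
        dist = float(np.linalg.norm(y2[:m] - y1[:m]))
    else:
        dist = float(np.linalg.norm(y2 - y1))
    if dist <= threshold:
        return False
    r1 = trajectory.residual_at(t_end - window)
    r2 = trajectory.residual_at(t_end)
    return r1 > tol and r2 > tol
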