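"""Numerical master-equation solvers: stationary null space and transient ODE.

This module is the independent oracle for the closed-form results: the
stationary distribution is obtained from the generator's null space by a
sparse direct solve, and the transient master equation is integrated with
a stiff implicit scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .analytic import DistributionPair
from .model_core import TransitionSystem

__all__ = ["TransientSolution", "stationary_solve", "evolve"]

_RESIDUAL_TOL = 1e-12
_NEG_TOL = 1e-10


def _check_irreducible(ts: TransitionSystem) -> None:
    """Require a unique stationary law: exactly one closed communicating class."""
    n = ts.space.n_states
    if not ts.transitions:
        raise ValueError("stationary distribution not unique: no transitions at all")
    src, dst, _ = zip(*ts.transitions)
    adj = sparse.coo_matrix((np.ones(len(src)), (src, dst)), shape=(n, n))
    _, labels = connected_components(adj, directed=True, connection="strong")
    open_classes = {labels[i] for i, j in zip(src, dst) if labels[i] != labels[j]}
    n_closed = len(set(labels)) - len(open_classes)
    if n_closed != 1:
        raise ValueError(
            "stationary distribution not unique: transition graph has "
            f"{n_closed} closed communicating classes; check for disconnected gene strands"
        )


def stationary_solve(ts: TransitionSystem) -> DistributionPair:
    """Unique stationary distribution from the generator's null space.

    Solves ``Q.T p = 0`` with one equation replaced by the normalization
    constraint, then verifies the residual ``||Q.T p||_inf <= 1e-12``.
    """
    _check_irreducible(ts)
    Q = ts.generator
    A = sparse.lil_matrix(Q.T)
    A[-1, :] = 1.0
    b = np.zeros(ts.space.n_states)
    b[-1] = 1.0
    p = spsolve(A.tocsr(), b)
    residual = float(np.abs(Q.T @ p).max())
    if residual > _RESIDUAL_TOL:
        raise RuntimeError(f"null-space residual {residual:.3e} exceeds {_RESIDUAL_TOL}")
    if p.min() < -_NEG_TOL:
        raise RuntimeError(f"stationary solve produced negative probability {p.min():.3e}")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return DistributionPair(
        p0=p[0::2].copy(), p1=p[1::2].copy(), provenance="cme",
        metadata={"params": ts.params.as_dict(), "m_max": ts.space.m_max,
                  "residual": residual},
    )


@dataclass
class TransientSolution:
    """Time-resolved solution of the truncated master equation."""

    times: np.ndarray
    snapshots: list
    rtol: float
    atol: float


def evolve(ts: TransitionSystem, p_init: DistributionPair, t_grid,
           rtol: float = 1e-10, atol: float = 1e-12) -> TransientSolution:
    """Integrate ``dp/dt = Q.T p`` from ``p_init`` over an increasing time grid.

    Uses a stiff-capable implicit scheme with the sparse transposed
    generator as the Jacobian.  Mass must be conserved at every snapshot to
    within 1e-8; entries below -1e-10 are an error, smaller negative noise
    is clipped to zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be increasing and start at t >= 0")
    y0 = p_init.as_flat()
    if abs(y0.sum() - 1.0) > 1e-8:
        raise ValueError(f"initial distribution sums to {y0.sum():.6f}, not 1")
    if len(y0) != ts.space.n_states:
        raise ValueError("initial distribution does not match the state space")
    QT = sparse.csr_matrix(ts.generator.T)
    t_span = (0.0, float(t_grid[-1])) if t_grid[0] > 0 else (0.0, float(max(t_grid[-1], 1e-12)))
    sol = solve_ivp(
        lambda _t, y: QT @ y, t_span, y0, method="BDF", t_eval=t_grid,
        jac=lambda _t, _y: QT, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    snapshots = []
    for k in range(sol.y.shape[1]):
        y = sol.y[:, k]
        if y.min() < -_NEG_TOL:
            raise RuntimeError(
                f"negative probability {y.min():.3e} at t={sol.t[k]:.4g} "
                "exceeds tolerance; tighten integrator tolerances"
            )
        if abs(y.sum() - 1.0) > 1e-8:
            raise RuntimeError(f"mass not conserved at t={sol.t[k]:.4g}: sum={y.sum():.10f}")
        y = np.clip(y, 0.0, None)
        snapshots.append(DistributionPair(
            p0=y[0::2].copy(), p1=y[1::2].copy(), provenance="cme",
            metadata={"t": float(sol.t[k])},
        ))
    return TransientSolution(times=sol.t.copy(), snapshots=snapshots, rtol=rtol, atol=atol)
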