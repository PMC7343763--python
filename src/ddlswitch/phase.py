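"""Mode classification, dominance factor, and (a, k3) phase-plane analysis.

Mode I means the total off-state probability mass exceeds the on-state
mass; Mode II the reverse.  The dominance factor delta compares the peak
heights of the two strand distributions:
``delta = |max_m P0(m) - max_m P1(m)| / max_m P1(m)``.
Note delta is defined through peaks while the modes are defined through
masses; the two need not agree, so both are reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytic import DistributionPair, stationary_distribution
from .model_core import DDLParameters, StateSpace, choose_truncation
from .thermo import EPBreakdown, ep_decomposition

__all__ = [
    "Mode",
    "PhasePoint",
    "PhaseMap",
    "classify_mode",
    "dominance_delta",
    "scan_plane",
    "find_boundary",
    "boundary_trace",
]

DEFAULT_TIE_TOL = 1e-9


class Mode(str, enum.Enum):
    I = "I"
    II = "II"
    BOUNDARY = "boundary"


def classify_mode(dist: DistributionPair, tie_tol: float = DEFAULT_TIE_TOL) -> Mode:
    """Mode I if off-mass dominates, Mode II if on-mass does, else boundary."""
    off, on = dist.mass_off, dist.mass_on
    if off > on + tie_tol:
        return Mode.I
    if on > off + tie_tol:
        return Mode.II
    return Mode.BOUNDARY


def dominance_delta(dist: DistributionPair) -> float:
    """Peak-height dominance factor |max P0 - max P1| / max P1."""
    peak0 = float(dist.p0.max())
    peak1 = float(dist.p1.max())
    if peak1 == 0:
        raise ValueError("dominance factor undefined: P1 is identically zero")
    return abs(peak0 - peak1) / peak1


@dataclass(frozen=True)
class PhasePoint:
    """One node of the (a, k3) phase plane."""

    a: float
    k3: float
    mode: Mode
    delta: float
    mass_off: float
    mass_on: float
    ep: EPBreakdown | None = None
    flagged: bool = False


@dataclass
class PhaseMap:
    """Grid of phase points; ``points[i][j]`` corresponds to (a_grid[i], k3_grid[j])."""

    a_grid: np.ndarray
    k3_grid: np.ndarray
    points: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for row in self.points:
            for pt in row:
                rec = {
                    "a": pt.a, "k3": pt.k3, "mode": pt.mode.value, "delta": pt.delta,
                    "mass_off": pt.mass_off, "mass_on": pt.mass_on, "flagged": pt.flagged,
                }
                if pt.ep is not None:
                    rec.update({"EP": pt.ep.ep, "EP1": pt.ep.ep1, "EP2": pt.ep.ep2,
                                "EP3": pt.ep.ep3, "EPm": pt.ep.ep_m,
                                "fraction_m": pt.ep.fraction_m})
                rows.append(rec)
        return pd.DataFrame(rows)


def _node_distribution(base: DDLParameters, a: float, k3: float,
                       tail_tol: float) -> DistributionPair:
    params = base.replace(a=a, k3=k3)
    space = StateSpace(choose_truncation(params, tail_tol))
    try:
        return stationary_distribution(params, space)
    except ValueError:
        # fall back to the numerical null-space oracle
        from .cme_numeric import stationary_solve
        from .model_core import build_transition_system

        return stationary_solve(build_transition_system(params, space))


def scan_plane(base: DDLParameters, a_grid, k3_grid, with_ep: bool = False,
               tail_tol: float = 1e-12, tie_tol: float = DEFAULT_TIE_TOL) -> PhaseMap:
    """Classify every node of an (a, k3) grid from the stationary distribution.

    Nodes whose distribution cannot be computed are flagged (NaN fields)
    and the scan continues.
    """
    a_grid = np.asarray(sorted(float(x) for x in a_grid))
    k3_grid = np.asarray(sorted(float(x) for x in k3_grid))
    if np.any(a_grid <= 0) or np.any(k3_grid <= 0):
        raise ValueError("grids must be positive")
    points = []
    for a in a_grid:
        row = []
        for k3 in k3_grid:
            try:
                dist = _node_distribution(base, a, k3, tail_tol)
            except Exception:
                row.append(PhasePoint(a=a, k3=k3, mode=Mode.BOUNDARY, delta=float("nan"),
                                      mass_off=float("nan"), mass_on=float("nan"),
                                      flagged=True))
                continue
            ep = ep_decomposition(dist, base.replace(a=a, k3=k3)) if with_ep else None
            row.append(PhasePoint(
                a=a, k3=k3, mode=classify_mode(dist, tie_tol),
                delta=dominance_delta(dist),
                mass_off=dist.mass_off, mass_on=dist.mass_on, ep=ep,
            ))
        points.append(row)
    return PhaseMap(a_grid=a_grid, k3_grid=k3_grid, points=points)


def find_boundary(base: DDLParameters, a: float, k3_lo: float, k3_hi: float,
                  xtol: float = 1e-4, tail_tol: float = 1e-12,
                  n_monotonic_probe: int = 8) -> float:
    """Locate the mode boundary in k3 at fixed ``a`` by bisection.

    The root of ``mass_off(k3) - mass_on(k3)`` is bracketed by
    ``[k3_lo, k3_hi]``; a coarse probe checks that the sign changes exactly
    once across the bracket before bisecting to ``|dk3| <= xtol``.
    """
    if not 0 < k3_lo < k3_hi:
        raise ValueError("require 0 < k3_lo < k3_hi")

    def f(k3: float) -> float:
        dist = _node_distribution(base, a, k3, tail_tol)
        return dist.mass_off - dist.mass_on

    f_lo, f_hi = f(k3_lo), f(k3_hi)
    if f_lo == 0.0:
        return k3_lo
    if f_hi == 0.0:
        return k3_hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"boundary not bracketed: sign of mass_off - mass_on is the same at "
            f"k3={k3_lo} and k3={k3_hi} for a={a}"
        )
    probes = np.linspace(k3_lo, k3_hi, n_monotonic_probe + 2)[1:-1]
    signs = [np.sign(f_lo)] + [np.sign(f(x)) for x in probes] + [np.sign(f_hi)]
    changes = sum(1 for s1, s2 in zip(signs, signs[1:]) if s1 != s2)
    if changes != 1:
        raise ValueError(f"sign of mass_off - mass_on changes {changes} times in the bracket")

    lo, hi = k3_lo, k3_hi
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def boundary_trace(base: DDLParameters, a_values, k3_lo: float, k3_hi: float,
                   xtol: float = 1e-4, tail_tol: float = 1e-12) -> pd.DataFrame:
    """Boundary k3 at each requested ``a``; the trace behind a phase map."""
    rows = [{"a": float(a),
             "k3_boundary": find_boundary(base, float(a), k3_lo, k3_hi,
                                          xtol=xtol, tail_tol=tail_tol)}
            for a in a_values]
    return pd.DataFrame(rows).sort_values("a", ignore_index=True)
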