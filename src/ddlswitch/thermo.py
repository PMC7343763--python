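"""Entropy and entropy-production machinery for the DDL switch.

At a non-equilibrium steady state the total entropy production rate can be
written either generically over transitions of the Markov generator or in
a model-specific closed form over the lattice.  It decomposes into three
transition classes: off-strand copy-number moves (EP1), on-strand
copy-number moves (EP2), and gene switching (EP3); ``EPm = EP1 + EP2`` is
the share spent on repressor synthesis and degradation.

Two decomposition conventions are provided.  ``"flux"`` (default) weights
each unordered transition pair by ``J * ln(flux_forward/flux_backward)``,
the standard per-pair entropy production; every class is then non-negative
and the three classes sum to the total at stationarity.  ``"rate"`` puts
only the rate ratio inside the logarithm; the classes still sum to the
total at stationarity, but because the copy-number marginal is exactly
Poisson the strand contributions cancel pairwise and EPm is identically
zero in that convention (see README).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytic import DistributionPair
from .model_core import DDLParameters, StateSpace, TransitionSystem, build_transition_system, choose_truncation

__all__ = [
    "EPBreakdown",
    "entropy",
    "entropy_production_rate",
    "ep_ness",
    "ddl_ep",
    "ep_decomposition",
    "ep_vs_a_profile",
]

_STATIONARY_TOL = 1e-8
_FLUX_TOL = 1e-12  # probability-flux dust below this is treated as zero


@dataclass(frozen=True)
class EPBreakdown:
    """Total entropy production (nats per 1/k4 time) and its three classes."""

    ep1: float
    ep2: float
    ep3: float
    convention: str = "flux"

    @property
    def ep(self) -> float:
        return self.ep1 + self.ep2 + self.ep3

    @property
    def ep_m(self) -> float:
        """Share spent on repressor synthesis-degradation: EP1 + EP2."""
        return self.ep1 + self.ep2

    @property
    def fraction_m(self) -> float:
        return self.ep_m / self.ep if self.ep != 0 else float("nan")


def entropy(dist: DistributionPair) -> float:
    """Sum of p*ln(p) over all lattice states (kB*T = 1), with 0*ln(0) = 0.

    Note the sign convention: this is the negative of the Shannon entropy,
    so the value is always <= 0.
    """
    p = np.concatenate([dist.p0, dist.p1])
    p = p[p > 0]
    return float(np.sum(p * np.log(p)))


def _xlogratio(fwd: np.ndarray, bwd: np.ndarray) -> float:
    """sum((fwd - bwd) * log(fwd/bwd)), pairs with a vanishing side contribute 0."""
    ok = (fwd > 0) & (bwd > 0)
    ratio = np.where(ok, fwd / np.where(ok, bwd, 1.0), 1.0)
    return float(np.sum(np.where(ok, (fwd - bwd) * np.log(ratio), 0.0)))


def entropy_production_rate(dist: DistributionPair, ts: TransitionSystem) -> float:
    """Instantaneous entropy production rate of a (possibly transient) state.

    Sum over unordered state pairs of ``(P_i q_ij - P_j q_ji) * ln(q_ij/q_ji)``
    with the 0*ln(.) = 0 convention.  A pair carrying probability flux in
    one direction only has no finite entropy production; such a pair raises
    an error (it cannot occur in this model with positive parameters).
    """
    p = dist.as_flat()
    if len(p) != ts.space.n_states:
        raise ValueError("distribution does not match the transition system's state space")
    rates = ts.rate_lookup()
    total = 0.0
    for (i, j), qij in rates.items():
        if i > j:
            continue
        qji = rates.get((j, i), 0.0)
        flux = p[i] * qij - p[j] * qji
        if qji == 0.0:
            if abs(flux) > _FLUX_TOL:
                raise ValueError(
                    f"irreversible transition {i}->{j}: entropy production undefined"
                )
            continue
        if flux != 0.0:
            total += flux * np.log(qij / qji)
    # pairs where only the j->i rate exists
    for (j, i), qji in rates.items():
        if j < i or (i, j) in rates:
            continue
        if p[j] * qji > _FLUX_TOL:
            raise ValueError(f"irreversible transition {j}->{i}: entropy production undefined")
    return total


def ep_ness(dist: DistributionPair, ts: TransitionSystem, strict: bool = True) -> float:
    """Steady-state entropy production from the generic transition sum.

    Ordered sum over transitions of ``P(s) k(s,s') ln(k(s,s')/k(s',s))``.
    ``dist`` must be stationary for ``ts``; the residual is checked against
    1e-8 and violations raise (strict) or are ignored (non-strict).
    """
    p = dist.as_flat()
    if len(p) != ts.space.n_states:
        raise ValueError("distribution does not match the transition system's state space")
    residual = float(np.abs(ts.generator.T @ p).max())
    if residual > _STATIONARY_TOL and strict:
        raise ValueError(
            f"distribution is not stationary (residual {residual:.3e} > {_STATIONARY_TOL}); "
            "pass strict=False to override"
        )
    rates = ts.rate_lookup()
    total = 0.0
    for (i, j), qij in rates.items():
        qji = rates.get((j, i), 0.0)
        if qji == 0.0:
            if p[i] * qij > _FLUX_TOL:
                raise ValueError(f"irreversible transition {i}->{j}: entropy production undefined")
            continue
        if p[i] != 0.0:
            total += p[i] * qij * np.log(qij / qji)
    return total


def ddl_ep(dist: DistributionPair, params: DDLParameters) -> float:
    """Model-specific closed-form steady-state entropy production.

    Six terms per lattice column m: synthesis and degradation on each
    strand against the reverse rate, plus the two switching terms, all
    with rate ratios inside the logarithm and 0*ln(.) = 0.
    """
    m = np.arange(dist.m_max + 1, dtype=float)
    ak3 = params.m_s
    up = params.kon + params.a * params.k1
    down = params.koff + m * params.k2
    p0, p1 = dist.p0, dist.p1
    total = 0.0
    if ak3 > 0:
        log_birth = np.log(ak3 / (m + 1))
        total += float(np.sum((p0 + p1) * ak3 * log_birth))
        total += float(np.sum((p0 + p1)[1:] * m[1:] * np.log(m[1:] / ak3)))
    elif np.any((p0 + p1)[1:] * m[1:] > _FLUX_TOL):
        raise ValueError("irreversible degradation with nonzero flux: EP undefined")
    if up > 0:
        ok = down > 0
        if np.any(~ok & (p0 * up > _FLUX_TOL)):
            raise ValueError("irreversible switching with nonzero flux: EP undefined")
        log_sw = np.where(ok, np.log(up / np.where(ok, down, 1.0)), 0.0)
        total += float(np.sum(p0 * up * log_sw) - np.sum(p1 * down * log_sw))
    elif np.any(p1 * down > _FLUX_TOL):
        raise ValueError("irreversible switching with nonzero flux: EP undefined")
    return total


def _strand_flux_ep(p: np.ndarray, ak3: float) -> float:
    """Per-bond flux entropy production of one strand's birth-death moves."""
    if ak3 == 0:
        return 0.0
    m = np.arange(1, len(p), dtype=float)
    fwd = p[:-1] * ak3
    bwd = p[1:] * m
    return _xlogratio(fwd, bwd)


def ep_decomposition(dist: DistributionPair, params: DDLParameters,
                     convention: str = "flux") -> EPBreakdown:
    """Decompose steady-state entropy production into the three transition classes.

    ``convention="flux"`` uses per-pair terms ``J * ln(P q / P' q')`` (each
    class >= 0); ``convention="rate"`` uses ``J * ln(q/q')`` only.  Both
    sum to the total entropy production at stationarity.
    """
    m = np.arange(dist.m_max + 1, dtype=float)
    ak3 = params.m_s
    up = params.kon + params.a * params.k1
    down = params.koff + m * params.k2
    p0, p1 = dist.p0, dist.p1

    if convention == "flux":
        ep1 = _strand_flux_ep(p0, ak3)
        ep2 = _strand_flux_ep(p1, ak3)
        ep3 = _xlogratio(p0 * up, p1 * down)
    elif convention == "rate":
        def strand_rate(p: np.ndarray) -> float:
            if ak3 == 0:
                return 0.0
            total = float(np.sum(p * ak3 * np.log(ak3 / (m + 1))))
            total += float(np.sum(p[1:] * m[1:] * np.log(m[1:] / ak3)))
            return total

        ep1 = strand_rate(p0)
        ep2 = strand_rate(p1)
        ok = (up > 0) & (down > 0)
        log_sw = np.where(ok, np.log(np.where(ok, up / np.where(ok, down, 1.0), 1.0)), 0.0)
        ep3 = float(np.sum(p0 * up * log_sw) - np.sum(p1 * down * log_sw))
    else:
        raise ValueError(f"unknown convention {convention!r}; use 'flux' or 'rate'")
    return EPBreakdown(ep1=ep1, ep2=ep2, ep3=ep3, convention=convention)


def ep_vs_a_profile(base: DDLParameters, a_grid, convention: str = "flux",
                    tail_tol: float = 1e-12) -> pd.DataFrame:
    """Entropy production and its decomposition along a grid of signal strengths.

    The stationary distribution is evaluated from the closed form at each
    ``a``; the returned table is sorted by ``a``.
    """
    from .analytic import stationary_distribution

    a_grid = sorted(float(a) for a in a_grid)
    if any(a <= 0 for a in a_grid):
        raise ValueError("a_grid must be positive")
    rows = []
    for a in a_grid:
        params = base.replace(a=a)
        space = StateSpace(choose_truncation(params, tail_tol))
        dist = stationary_distribution(params, space)
        br = ep_decomposition(dist, params, convention=convention)
        rows.append({
            "a": a, "EP": br.ep, "EP1": br.ep1, "EP2": br.ep2, "EP3": br.ep3,
            "EPm": br.ep_m, "fraction_m": br.fraction_m,
        })
    return pd.DataFrame(rows)
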