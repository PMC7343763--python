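"""Closed-form stationary distribution of the DDL switch.

The generating-function solution of the stationary master equation
expresses the joint distribution ``P0(m), P1(m)`` (gene off / gene on) in
terms of Kummer's confluent hypergeometric function.  With the shorthand

    lam  = a*k3 / (k2 + 1)
    alpha = a*k2*k3/(k2+1)**2 + (kon + koff + a*k1)/(k2+1)
    beta  = alpha + 1
    omega2 = -a*k2*k3/(k2+1)**2
    omega1 = a*k2*k3/(k2+1) - a*k2*k3/(k2+1)**2

the on-strand distribution is

    P1(m) = A0 * lam**m / m! * S(m; 0)
    S(m; s) = sum_{l=0}^{m} k2**l C(m,l) (alpha+s)_l/(beta+s)_l
              * 1F1(alpha+s+l, beta+s+l; omega2)

and the off-strand distribution is the three-term combination

    P0(m) = [ (a*k2*k3/(k2+1) + koff) * lam**m/m! * S(m; 0)
              - a*k2*k3/(k2+1) * (alpha/beta) * lam**m/m! * S(m; 1)
              + a*k2*k3 * (alpha/beta) * lam**(m-1)/(m-1)! * S(m-1; 1)
            ] / (kon + a*k1)

with the ``(m-1)`` term absent for m = 0.  The normalization constant A0
follows from the same ingredients evaluated at omega1.  The exact marginal
``P0(m) + P1(m)`` is Poisson with mean ``a*k3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import poisson

from .model_core import DDLParameters, StateSpace

__all__ = [
    "AnalyticCoefficients",
    "DistributionPair",
    "analytic_coefficients",
    "hyp1f1",
    "marginal_poisson",
    "normalization_A0",
    "pochhammer",
    "stationary_distribution",
    "stationary_p0",
    "stationary_p1",
    "total_variation",
]


def pochhammer(gamma: float, l: int) -> float:
    """Rising factorial (gamma)_l = gamma * (gamma+1) * ... * (gamma+l-1).

    Computed in log space via the gamma function for positive arguments to
    avoid overflow; (gamma)_0 = 1 for any gamma.
    """
    if l < 0:
        raise ValueError(f"l must be a non-negative integer, got {l}")
    if l == 0:
        return 1.0
    if gamma > 0:
        return math.exp(special.gammaln(gamma + l) - special.gammaln(gamma))
    # non-positive gamma: direct product (small l in practice)
    out = 1.0
    for i in range(l):
        out *= gamma + i
    return out


def _is_nonpositive_int(x: float) -> bool:
    return x <= 0 and float(x).is_integer()


def hyp1f1(alpha: float, beta: float, omega: float, rtol: float = 1e-14) -> float:
    """Kummer's confluent hypergeometric function M(alpha, beta; omega).

    For ``omega < 0`` the Kummer transformation
    ``M(a, b, w) = exp(w) * M(b - a, b, -w)`` is applied so the series is
    evaluated at a positive argument, avoiding catastrophic cancellation.
    For positive parameters the transformed series has positive terms and
    is summed directly; otherwise the implementation falls back to scipy
    and, if that fails an internal sanity check, to arbitrary precision.
    """
    if _is_nonpositive_int(beta):
        raise ValueError(f"beta must not be a non-positive integer, got {beta}")
    if omega < 0:
        return math.exp(omega) * hyp1f1(beta - alpha, beta, -omega, rtol=rtol)
    if omega == 0:
        return 1.0
    if alpha > 0 and beta > 0:
        term = 1.0
        total = 1.0
        for n in range(100_000):
            term *= (alpha + n) * omega / ((beta + n) * (n + 1))
            total += term
            if term < rtol * total:
                return total
        raise RuntimeError("hyp1f1 series did not converge")
    value = float(special.hyp1f1(alpha, beta, omega))
    if not math.isfinite(value):
        import mpmath  # arbitrary-precision fallback; rarely needed

        value = float(mpmath.hyp1f1(alpha, beta, omega))
    return value


@dataclass(frozen=True)
class AnalyticCoefficients:
    """Derived constants of the closed-form solution."""

    alpha: float
    beta: float
    omega1: float
    omega2: float


def analytic_coefficients(params: DDLParameters) -> AnalyticCoefficients:
    k2 = params.k2
    akk = params.a * k2 * params.k3
    alpha = akk / (k2 + 1) ** 2 + (params.kon + params.koff + params.a * params.k1) / (k2 + 1)
    return AnalyticCoefficients(
        alpha=alpha,
        beta=alpha + 1.0,
        omega1=akk / (k2 + 1) - akk / (k2 + 1) ** 2,
        omega2=-akk / (k2 + 1) ** 2,
    )


def _kummer_table(coeffs: AnalyticCoefficients, n: int, omega: float) -> np.ndarray:
    """M(alpha + l, beta + l; omega) for l = 0..n-1.

    Shifting both parameters by one gives the next entry, so a single
    table serves the shift-0 and shift-1 series alike.
    """
    return np.array([hyp1f1(coeffs.alpha + l, coeffs.beta + l, omega) for l in range(n)])


def _series(params: DDLParameters, coeffs: AnalyticCoefficients, m: int, shift: int,
            table: np.ndarray | None = None) -> float:
    """S(m; shift) = sum_l k2^l C(m,l) (alpha+shift)_l/(beta+shift)_l M(alpha+shift+l, ...)."""
    k2 = params.k2
    a, b = coeffs.alpha + shift, coeffs.beta + shift
    total = 0.0
    for l in range(m + 1):
        kum = table[shift + l] if table is not None else hyp1f1(a + l, b + l, coeffs.omega2)
        if k2 == 0 and l > 0:
            continue
        log_w = (special.gammaln(m + 1) - special.gammaln(l + 1) - special.gammaln(m - l + 1)
                 + (l * math.log(k2) if l else 0.0)
                 + special.gammaln(a + l) - special.gammaln(a)
                 - special.gammaln(b + l) + special.gammaln(b))
        total += math.exp(log_w) * kum
    return total


def _log_pref(lam: float, m: int) -> float:
    """log(lam**m / m!), with the 0**0 = 1 convention at lam = 0."""
    if lam == 0:
        return 0.0 if m == 0 else -math.inf
    return m * math.log(lam) - special.gammaln(m + 1)


def normalization_A0(params: DDLParameters) -> float:
    """Normalization constant of the closed-form stationary distribution."""
    up = params.kon + params.a * params.k1
    if up == 0:
        raise ValueError("kon + a*k1 must be positive for the closed-form solution")
    c = analytic_coefficients(params)
    k2 = params.k2
    lam = params.a * params.k3 / (k2 + 1)
    akk = params.a * k2 * params.k3
    f0 = hyp1f1(c.alpha, c.beta, c.omega1)
    f1 = hyp1f1(c.alpha + 1, c.beta + 1, c.omega1)
    ratio = c.alpha / c.beta
    bracket = ((akk / (k2 + 1) + params.koff) * f0 / up
               - (akk / (k2 + 1)) * ratio * f1 / up
               + akk * ratio * f1 / up)
    inv = math.exp(lam) * bracket + math.exp(lam) * f0
    return 1.0 / inv


def stationary_p1(params: DDLParameters, m: int, _ctx: tuple | None = None) -> float:
    """Stationary probability of (gene on, m copies)."""
    if m < 0:
        raise ValueError(f"m must be non-negative, got {m}")
    if _ctx is not None:
        a0, coeffs, table = _ctx
    else:
        a0, coeffs, table = normalization_A0(params), analytic_coefficients(params), None
    lam = params.a * params.k3 / (params.k2 + 1)
    pref = _log_pref(lam, m)
    if pref == -math.inf:
        return 0.0
    return a0 * math.exp(pref) * _series(params, coeffs, m, 0, table)


def stationary_p0(params: DDLParameters, m: int, _ctx: tuple | None = None) -> float:
    """Stationary probability of (gene off, m copies)."""
    if m < 0:
        raise ValueError(f"m must be non-negative, got {m}")
    up = params.kon + params.a * params.k1
    if up == 0:
        raise ValueError("kon + a*k1 must be positive for the closed-form solution")
    if _ctx is not None:
        a0, coeffs, table = _ctx
    else:
        a0, coeffs, table = normalization_A0(params), analytic_coefficients(params), None
    k2 = params.k2
    lam = params.a * params.k3 / (k2 + 1)
    akk = params.a * k2 * params.k3
    ratio = coeffs.alpha / coeffs.beta

    lp = _log_pref(lam, m)
    pref = a0 * math.exp(lp) if lp > -math.inf else 0.0
    t1 = (akk / (k2 + 1) + params.koff) * pref * _series(params, coeffs, m, 0, table)
    t2 = (akk / (k2 + 1)) * ratio * pref * _series(params, coeffs, m, 1, table)
    t3 = 0.0
    if m >= 1 and akk > 0:
        lp1 = _log_pref(lam, m - 1)
        pref1 = a0 * math.exp(lp1) if lp1 > -math.inf else 0.0
        t3 = akk * ratio * pref1 * _series(params, coeffs, m - 1, 1, table)
    return (t1 - t2 + t3) / up


def marginal_poisson(params: DDLParameters, m: int) -> float:
    """Marginal stationary probability of ``m`` copies: Poisson(a*k3)."""
    if m < 0:
        raise ValueError(f"m must be non-negative, got {m}")
    return float(poisson.pmf(m, params.m_s))


@dataclass
class DistributionPair:
    """Joint stationary distribution over (gene, m) on a truncated lattice.

    ``p0[m]``/``p1[m]`` are the probabilities of (off, m)/(on, m);
    ``overflow_mass`` collects any estimated mass beyond ``m_max`` (used by
    the simulation-based estimator, zero for exact methods).
    """

    p0: np.ndarray
    p1: np.ndarray
    provenance: str = "analytic"
    overflow_mass: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.p0.shape != self.p1.shape or self.p0.ndim != 1:
            raise ValueError("p0 and p1 must be 1-d arrays of equal length")

    @property
    def m_max(self) -> int:
        return len(self.p0) - 1

    @property
    def total(self) -> np.ndarray:
        """Marginal distribution of m: P0(m) + P1(m)."""
        return self.p0 + self.p1

    @property
    def mass_off(self) -> float:
        return float(self.p0.sum())

    @property
    def mass_on(self) -> float:
        return float(self.p1.sum())

    @property
    def mass(self) -> float:
        return self.mass_off + self.mass_on + self.overflow_mass

    def as_flat(self) -> np.ndarray:
        """Flat probability vector in StateSpace order (index = 2*m + gene)."""
        out = np.empty(2 * (self.m_max + 1))
        out[0::2] = self.p0
        out[1::2] = self.p1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "m": np.arange(self.m_max + 1),
            "P0": self.p0,
            "P1": self.p1,
            "P_total": self.total,
        })


def total_variation(d1: DistributionPair, d2: DistributionPair) -> float:
    """Total-variation distance between two joint distributions.

    Lattices of different lengths are zero-padded; overflow mass counts as
    additional discrepancy.
    """
    n = max(d1.m_max, d2.m_max) + 1

    def pad(x: np.ndarray) -> np.ndarray:
        return np.pad(x, (0, n - len(x)))

    tv = 0.5 * (np.abs(pad(d1.p0) - pad(d2.p0)).sum() + np.abs(pad(d1.p1) - pad(d2.p1)).sum())
    return float(tv + 0.5 * abs(d1.overflow_mass - d2.overflow_mass))


def stationary_distribution(params: DDLParameters, space: StateSpace,
                            norm_tol: float = 1e-6) -> DistributionPair:
    """Evaluate the closed-form stationary distribution on a truncated lattice.

    Raises if the truncated mass misses 1 by more than ``norm_tol``, which
    indicates the truncation level is too low for the parameter set.
    """
    coeffs = analytic_coefficients(params)
    a0 = normalization_A0(params)
    table = _kummer_table(coeffs, space.m_max + 2, coeffs.omega2)
    ctx = (a0, coeffs, table)
    p0 = np.array([stationary_p0(params, m, _ctx=ctx) for m in range(space.m_max + 1)])
    p1 = np.array([stationary_p1(params, m, _ctx=ctx) for m in range(space.m_max + 1)])
    mass = p0.sum() + p1.sum()
    if abs(mass - 1.0) > norm_tol:
        raise ValueError(
            f"stationary distribution sums to {mass:.3e}, off by more than {norm_tol}; "
            f"truncation m_max={space.m_max} is suspect for a*k3={params.m_s}"
        )
    return DistributionPair(p0=p0, p1=p1, provenance="analytic",
                            metadata={"params": params.as_dict(), "m_max": space.m_max})
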