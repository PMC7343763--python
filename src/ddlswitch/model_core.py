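"""Parameters, state lattice, and the Markov jump process of the DDL model.

The model couples a two-state gene (off/on) to the copy number ``m`` of a
repressor.  Six reaction channels drive the dynamics (rates in units of the
repressor degradation rate ``k4``, so the death rate of one copy is 1):

====================  =======================  ==================
jump                  channel                  propensity
====================  =======================  ==================
(g, m) -> (g, m+1)    repressor synthesis      ``a * k3``
(g, m) -> (g, m-1)    repressor degradation    ``m``
(off, m) -> (on, m)   gene activation          ``kon + a * k1``
(on, m) -> (off, m)   gene repression          ``koff + m * k2``
====================  =======================  ==================

``a`` is the (dimensionless) concentration of the upstream activating
signal; it scales both gene activation (``a*k1``) and repressor synthesis
(``a*k3``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple

import numpy as np
from scipy import sparse
from scipy.stats import poisson

GENE_OFF = 0
GENE_ON = 1

_RATE_KEYS = ("k1", "k2", "k3", "kon", "koff")


@dataclass(frozen=True)
class DDLParameters:
    """Rate constants of the switch, normalized by the degradation rate.

    All stored rates are divided by the raw degradation rate ``k4``; in
    these units the per-copy death rate is exactly 1 and time is measured
    in units of ``1/k4``.  The raw ``k4`` is retained for unit conversion
    on output only.
    """

    k1: float
    k2: float
    k3: float
    kon: float
    koff: float
    a: float
    k4_raw: float = 1.0

    def __post_init__(self) -> None:
        for name in (*_RATE_KEYS, "a"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"rate {name!r} must be non-negative, got {value}")
        if self.k4_raw <= 0:
            raise ValueError("degradation rate must be positive")

    @property
    def m_s(self) -> float:
        """Deterministic steady-state repressor copy number ``a*k3``."""
        return self.a * self.k3

    @property
    def gene_decoupled(self) -> bool:
        """True when gene and copy-number dynamics are independent (k1 = k2 = 0)."""
        return self.k1 == 0.0 and self.k2 == 0.0

    @property
    def gene_disconnected(self) -> bool:
        """True when the off and on strands cannot communicate at all.

        With ``kon + a*k1 = 0`` and ``koff = k2 = 0`` the two gene strands
        are disconnected and the stationary distribution is not unique.
        """
        return self.kon + self.a * self.k1 == 0.0 and self.koff == 0.0 and self.k2 == 0.0

    def replace(self, **changes: float) -> "DDLParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return {
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "kon": self.kon,
            "koff": self.koff,
            "a": self.a,
            "k4_raw": self.k4_raw,
        }


def make_params(raw_rates: Mapping[str, float], a: float) -> DDLParameters:
    """Build normalized parameters from raw rate constants.

    ``raw_rates`` must contain ``k1, k2, k3, kon, koff`` and may contain
    ``k4`` (default 1, meaning the input is already normalized).  Every
    stored rate equals the raw rate divided by raw ``k4``.
    """
    unknown = set(raw_rates) - {*_RATE_KEYS, "k4"}
    if unknown:
        raise ValueError(f"unknown rate keys: {sorted(unknown)}")
    missing = [k for k in _RATE_KEYS if k not in raw_rates]
    if missing:
        raise ValueError(f"missing rate keys: {missing}")
    k4 = float(raw_rates.get("k4", 1.0))
    if k4 <= 0:
        raise ValueError("degradation rate must be positive")
    if a < 0:
        raise ValueError(f"signal strength a must be non-negative, got {a}")
    return DDLParameters(
        k1=float(raw_rates["k1"]) / k4,
        k2=float(raw_rates["k2"]) / k4,
        k3=float(raw_rates["k3"]) / k4,
        kon=float(raw_rates["kon"]) / k4,
        koff=float(raw_rates["koff"]) / k4,
        a=float(a),
        k4_raw=k4,
    )


class DDLState(NamedTuple):
    """A lattice point: gene state (0 = off, 1 = on) and copy number ``m``."""

    gene: int
    m: int


@dataclass(frozen=True)
class StateSpace:
    """Truncated lattice {off, on} x {0..m_max} with flat index ``2*m + gene``."""

    m_max: int

    def __post_init__(self) -> None:
        if self.m_max < 1:
            raise ValueError(f"m_max must be >= 1, got {self.m_max}")

    @property
    def n_states(self) -> int:
        return 2 * (self.m_max + 1)

    def index(self, state: DDLState) -> int:
        gene, m = state
        if gene not in (GENE_OFF, GENE_ON):
            raise ValueError(f"gene must be 0 or 1, got {gene}")
        if not 0 <= m <= self.m_max:
            raise ValueError(f"m={m} outside [0, {self.m_max}]")
        return 2 * m + gene

    def state(self, index: int) -> DDLState:
        if not 0 <= index < self.n_states:
            raise ValueError(f"index {index} outside [0, {self.n_states})")
        return DDLState(gene=index % 2, m=index // 2)

    def __iter__(self) -> Iterator[DDLState]:
        for m in range(self.m_max + 1):
            yield DDLState(GENE_OFF, m)
            yield DDLState(GENE_ON, m)


def choose_truncation(params: DDLParameters, tail_tol: float = 1e-12) -> int:
    """Smallest ``m_max`` whose Poisson(a*k3) upper-tail mass is below ``tail_tol``.

    The exact marginal of ``m`` is Poisson with mean ``a*k3``, so the
    Poisson tail controls the truncation error.  Never returns less
    than 10.
    """
    if not 0 < tail_tol < 1:
        raise ValueError(f"tail_tol must lie in (0, 1), got {tail_tol}")
    lam = params.m_s
    if lam == 0:
        return 10
    m_max = int(poisson.ppf(1.0 - tail_tol, lam))
    # ppf can land one step off the smallest index with sf < tail_tol
    while poisson.sf(m_max, lam) >= tail_tol:
        m_max += 1
    while m_max > 0 and poisson.sf(m_max - 1, lam) < tail_tol:
        m_max -= 1
    return max(m_max, 10)


@dataclass(frozen=True)
class TransitionSystem:
    """Sparse list of allowed jumps with rates; the Markov generator.

    ``transitions`` holds (source index, target index, rate) triples with
    strictly positive rates.  The generator ``Q`` has ``Q[i, j]`` equal to
    the i -> j rate for i != j, and a diagonal making every row sum to
    zero; the master equation reads ``dp/dt = Q.T @ p``.
    """

    params: DDLParameters
    space: StateSpace
    transitions: tuple

    @property
    def generator(self) -> sparse.csr_matrix:
        n = self.space.n_states
        if self.transitions:
            src, dst, rate = map(np.asarray, zip(*self.transitions))
        else:  # fully frozen chain
            src = dst = np.array([], dtype=int)
            rate = np.array([])
        Q = sparse.coo_matrix((rate, (src, dst)), shape=(n, n)).tolil()
        out_rates = np.asarray(Q.sum(axis=1)).ravel()
        Q.setdiag(Q.diagonal() - out_rates)
        return Q.tocsr()

    def rate_lookup(self) -> dict:
        """Map (source index, target index) -> rate for positive-rate jumps."""
        return {(i, j): r for i, j, r in self.transitions}


def build_transition_system(params: DDLParameters, space: StateSpace) -> TransitionSystem:
    """Enumerate the six jump classes on the truncated lattice.

    The boundary at ``m_max`` is reflecting: the synthesis jump out of
    ``m_max`` is dropped, so probability is conserved exactly.
    """
    birth = params.m_s
    up = params.kon + params.a * params.k1
    transitions = []
    for m in range(space.m_max + 1):
        for gene in (GENE_OFF, GENE_ON):
            i = space.index(DDLState(gene, m))
            if m < space.m_max and birth > 0:
                transitions.append((i, space.index(DDLState(gene, m + 1)), birth))
            if m > 0:
                transitions.append((i, space.index(DDLState(gene, m - 1)), float(m)))
            if gene == GENE_OFF and up > 0:
                transitions.append((i, space.index(DDLState(GENE_ON, m)), up))
            if gene == GENE_ON:
                down = params.koff + m * params.k2
                if down > 0:
                    transitions.append((i, space.index(DDLState(GENE_OFF, m)), down))
    return TransitionSystem(params=params, space=space, transitions=tuple(transitions))
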