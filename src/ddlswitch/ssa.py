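"""Exact stochastic simulation (Gillespie direct method) of the DDL switch.

Simulation runs on the unbounded lattice; the stationary estimator weights
states by dwell time and bins any copy number above a requested truncation
into a flagged overflow bin, making truncation mismatch visible instead of
silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analytic import DistributionPair
from .model_core import GENE_OFF, GENE_ON, DDLParameters, DDLState

__all__ = ["Trajectory", "simulate", "estimate_stationary", "trajectory_seeds"]


@dataclass
class Trajectory:
    """Event log of one exact-SSA run.

    ``times[k]`` is the time of the k-th jump and ``genes[k]``/``ms[k]``
    the state entered by it.  ``frozen`` marks a run that stopped early
    because every propensity vanished.
    """

    init: DDLState
    times: np.ndarray
    genes: np.ndarray
    ms: np.ndarray
    t_end: float
    seed: int
    frozen: bool = False
    params: DDLParameters | None = field(default=None, repr=False)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def dwell_segments(self):
        """Yield (gene, m, t_start, t_stop) for the piecewise-constant path."""
        t_prev = 0.0
        gene, m = self.init
        for k in range(self.n_events):
            yield gene, m, t_prev, float(self.times[k])
            t_prev = float(self.times[k])
            gene, m = int(self.genes[k]), int(self.ms[k])
        yield gene, m, t_prev, self.t_end

    def time_average_m(self, burn_in: float = 0.0) -> float:
        """Dwell-time-weighted mean copy number after ``burn_in``."""
        num = den = 0.0
        for gene, m, t0, t1 in self.dwell_segments():
            w = max(0.0, min(t1, self.t_end) - max(t0, burn_in))
            num += w * m
            den += w
        if den == 0:
            raise ValueError("empty averaging window")
        return num / den


def trajectory_seeds(master_seed: int, n: int) -> list:
    """Per-trajectory seed sequences spawned from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


def simulate(params: DDLParameters, t_end: float, seed,
             init: DDLState = DDLState(GENE_OFF, 0)) -> Trajectory:
    """Exact direct-method SSA trajectory of length ``t_end`` (units 1/k4).

    Each event consumes two uniforms: one for the exponential waiting time
    at the total propensity, one for the channel choice.  ``seed`` may be
    an integer or a ``numpy.random.SeedSequence``; runs are reproducible
    given the seed.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    rng = np.random.default_rng(seed)
    birth = params.m_s
    up0 = params.kon + params.a * params.k1

    gene, m = init
    t = 0.0
    times, genes, ms = [], [], []
    frozen = False
    while True:
        death = float(m)
        switch = up0 if gene == GENE_OFF else params.koff + m * params.k2
        total = birth + death + switch
        if total == 0.0:
            frozen = True
            break
        t -= math.log(rng.random()) / total
        if t >= t_end:
            break
        u = rng.random() * total
        if u < birth:
            m += 1
        elif u < birth + death:
            m -= 1
        else:
            gene = GENE_ON if gene == GENE_OFF else GENE_OFF
        times.append(t)
        genes.append(gene)
        ms.append(m)
    seed_repr = seed if isinstance(seed, int) else int(np.random.default_rng(seed).integers(2**31))
    return Trajectory(
        init=init, times=np.asarray(times), genes=np.asarray(genes, dtype=np.int8),
        ms=np.asarray(ms, dtype=np.int64), t_end=float(t_end), seed=seed_repr,
        frozen=frozen, params=params,
    )


def estimate_stationary(trajs, burn_in: float, m_max: int | None = None) -> DistributionPair:
    """Dwell-time-weighted occupancy histogram over (gene, m).

    Discards the first ``burn_in`` time units of every trajectory.  With an
    explicit ``m_max``, visits above it are pooled into ``overflow_mass``;
    otherwise the lattice extends to the largest visited copy number.  The
    returned masses (including overflow) sum to 1 exactly.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories given")
    for tr in trajs:
        if tr.t_end <= burn_in and not tr.frozen:
            raise ValueError(f"trajectory shorter ({tr.t_end}) than burn_in ({burn_in})")
    if m_max is None:
        m_max = max(10, max((int(tr.ms.max()) if tr.n_events else tr.init.m) for tr in trajs))
    occ = np.zeros((2, m_max + 1))
    overflow = 0.0
    for tr in trajs:
        for gene, m, t0, t1 in tr.dwell_segments():
            w = max(0.0, min(t1, tr.t_end) - max(t0, burn_in))
            if w == 0.0:
                continue
            if m > m_max:
                overflow += w
            else:
                occ[gene, m] += w
    total = occ.sum() + overflow
    if total == 0:
        raise ValueError("empty post-burn-in window across all trajectories")
    occ /= total
    overflow /= total
    return DistributionPair(
        p0=occ[GENE_OFF], p1=occ[GENE_ON], provenance="ssa", overflow_mass=overflow,
        metadata={"n_traj": len(trajs), "burn_in": burn_in,
                  "total_time": sum(tr.t_end for tr in trajs)},
    )
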