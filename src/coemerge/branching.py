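"""Three-type branching process for evolutionary emergence.

An outbreak is modelled as a discrete-generation multi-type branching
process over wild-type infections (W), mutant infections (M) and
co-infections (C).  A wild-type infection mutates with probability ``mu1``
(and is then re-classified as a co-infection before reproducing); otherwise
it leaves Poisson(``Rw``) wild-type progeny.  A mutant infection reverts
with probability ``mu2`` (again becoming a co-infection); otherwise it
leaves Poisson(``Rm``) mutant progeny.  A co-infection leaves independent
Poisson numbers of wild-type, mutant and co-infection progeny with means

    Rcw = (1 - c)(1 - b) Rc,   Rcm = (1 - c) b Rc,   Rcc = c Rc,

where ``Rc = d Rm + (1 - d) Rw`` (clamped at zero for strongly
underdominant combinations) is the reproduction number of a co-infection,
``c`` the co-transmission probability and ``b`` the mutant share of
single-strain transmission.

Emergence is the complement of extinction.  Extinction probabilities are
the minimal fixed point of the probability generating function map

    fW(s) = (1 - mu1) exp(Rw (sW - 1)) + mu1 fC(s)
    fM(s) = (1 - mu2) exp(Rm (sM - 1)) + mu2 fC(s)
    fC(s) = exp(Rcw (sW - 1) + Rcm (sM - 1) + Rcc (sC - 1)),

obtained by functional iteration from the zero vector.  Types whose
reachable class has mean-matrix spectral radius <= 1 go extinct almost
surely; those components are set to one exactly before iterating, which
sidesteps the sublinear convergence of plain iteration at criticality.

A vectorized Monte-Carlo chain simulator is provided as an independent
check on the analytic solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "BranchingParams",
    "OffspringMeans",
    "ExtinctionSolution",
    "ChainResult",
    "offspring_means",
    "mean_matrix",
    "pgf",
    "extinction_probability",
    "emergence_probability",
    "simulate_chains",
]

TYPES = ("W", "M", "C")


@dataclass(frozen=True)
class BranchingParams:
    """Parameters of the three-type branching process.

    Defaults are the reference parameterization used for single-parameter
    sweeps: ``Rw=0.75, Rm=1.5, b=0.5, c=0.5, mu1=mu2=0.01`` with a fully
    dominant mutant (``d=1``).
    """

    Rw: float = 0.75
    Rm: float = 1.5
    d: float = 1.0
    c: float = 0.5
    b: float = 0.5
    mu1: float = 0.01
    mu2: float = 0.01

    def __post_init__(self) -> None:
        if self.Rw < 0 or self.Rm < 0:
            raise ValueError(f"Rw and Rm must be nonnegative, got Rw={self.Rw}, Rm={self.Rm}")
        for name in ("c", "b", "mu1", "mu2"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")

    @property
    def Rc(self) -> float:
        """Co-infection reproduction number ``max(0, d·Rm + (1−d)·Rw)``."""
        return max(0.0, self.d * self.Rm + (1.0 - self.d) * self.Rw)


@dataclass(frozen=True)
class OffspringMeans:
    """Mean progeny counts of a co-infection, by progeny type."""

    Rc: float
    Rcw: float
    Rcm: float
    Rcc: float


def offspring_means(params: BranchingParams) -> OffspringMeans:
    """Split ``Rc`` into wild-type, mutant and co-infection progeny means."""
    Rc = params.Rc
    return OffspringMeans(
        Rc=Rc,
        Rcw=(1.0 - params.c) * (1.0 - params.b) * Rc,
        Rcm=(1.0 - params.c) * params.b * Rc,
        Rcc=params.c * Rc,
    )


def mean_matrix(params: BranchingParams) -> np.ndarray:
    """Mean offspring matrix ``M[i, j]`` = expected type-j progeny of a type-i parent.

    Mutation/reversion re-classification is folded in: a mutating wild-type
    parent reproduces as a co-infection.
    """
    m = offspring_means(params)
    p = params
    return np.array(
        [
            [(1 - p.mu1) * p.Rw + p.mu1 * m.Rcw, p.mu1 * m.Rcm, p.mu1 * m.Rcc],
            [p.mu2 * m.Rcw, (1 - p.mu2) * p.Rm + p.mu2 * m.Rcm, p.mu2 * m.Rcc],
            [m.Rcw, m.Rcm, m.Rcc],
        ]
    )


def pgf(s, params: BranchingParams) -> tuple[float, float, float]:
    """One application of the three-type PGF map ``(sW, sM, sC) -> (fW, fM, fC)``."""
    sW, sM, sC = (float(v) for v in s)
    for v in (sW, sM, sC):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"PGF arguments must lie in [0, 1], got {s}")
    return _pgf_unchecked(sW, sM, sC, params, offspring_means(params))


def _pgf_unchecked(sW, sM, sC, p: BranchingParams, m: OffspringMeans):
    fC = math.exp(m.Rcw * (sW - 1.0) + m.Rcm * (sM - 1.0) + m.Rcc * (sC - 1.0))
    fW = (1.0 - p.mu1) * math.exp(p.Rw * (sW - 1.0)) + p.mu1 * fC
    fM = (1.0 - p.mu2) * math.exp(p.Rm * (sM - 1.0)) + p.mu2 * fC
    return fW, fM, fC


def _certain_extinction(params: BranchingParams) -> tuple[bool, bool, bool]:
    """Per-type almost-sure-extinction flags from the mean-matrix criterion.

    A lineage started from type i dies out almost surely iff the spectral
    radius of the mean matrix restricted to the types reachable from i is
    <= 1 (the offspring laws here are never the degenerate
    one-child-always case).
    """
    M = mean_matrix(params)
    flags = []
    for i in range(3):
        reach = {i}
        frontier = {i}
        while frontier:
            nxt = {
                j
                for k in frontier
                for j in range(3)
                if M[k, j] > 0 and j not in reach
            }
            reach |= nxt
            frontier = nxt
        idx = sorted(reach)
        rho = max(abs(np.linalg.eigvals(M[np.ix_(idx, idx)])))
        flags.append(bool(rho <= 1.0))
    return tuple(flags)


@dataclass(frozen=True)
class ExtinctionSolution:
    """Extinction probabilities and solver metadata."""

    qW: float
    qM: float
    qC: float
    iterations: int
    converged: bool
    residual: float

    @property
    def emergence_from_W(self) -> float:
        return 1.0 - self.qW

    @property
    def emergence_from_M(self) -> float:
        return 1.0 - self.qM

    @property
    def emergence_from_C(self) -> float:
        return 1.0 - self.qC

    def emergence(self, start_type: str) -> float:
        return 1.0 - {"W": self.qW, "M": self.qM, "C": self.qC}[start_type]


def extinction_probability(
    params: BranchingParams, tol: float = 1e-12, max_iter: int = 1_000_000
) -> ExtinctionSolution:
    """Minimal fixed point of the PGF map: extinction probability per start type.

    Components whose reachable class is (sub)critical are pinned to 1
    exactly; the remaining components are iterated ``q <- f(q)`` from zero,
    which converges monotonically to the minimal fixed point.  Convergence
    is declared when the sup-norm change of the free components drops
    below ``tol``.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    m = offspring_means(params)
    pinned = _certain_extinction(params)
    q = [1.0 if flag else 0.0 for flag in pinned]
    if all(pinned):
        return ExtinctionSolution(1.0, 1.0, 1.0, iterations=0, converged=True, residual=0.0)
    iterations = 0
    delta = math.inf
    while iterations < max_iter:
        f = _pgf_unchecked(q[0], q[1], q[2], params, m)
        delta = max(
            abs(f[i] - q[i]) for i in range(3) if not pinned[i]
        )
        for i in range(3):
            if not pinned[i]:
                q[i] = f[i]
        iterations += 1
        if delta < tol:
            break
    converged = delta < tol
    if not converged:
        warnings.warn(
            f"extinction fixed point not converged after {max_iter} iterations "
            f"(last change {delta:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    f = _pgf_unchecked(q[0], q[1], q[2], params, m)
    residual = max(abs(f[i] - q[i]) for i in range(3))
    return ExtinctionSolution(
        qW=q[0], qM=q[1], qC=q[2], iterations=iterations, converged=converged, residual=residual
    )


def emergence_probability(
    params: BranchingParams,
    start_type: str = "W",
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> float:
    """Probability that a chain started from one ``start_type`` infection emerges."""
    if start_type not in TYPES:
        raise ValueError(f"start_type must be one of {TYPES}, got {start_type!r}")
    return extinction_probability(params, tol=tol, max_iter=max_iter).emergence(start_type)


@dataclass(frozen=True)
class ChainResult:
    """Monte-Carlo tally over simulated outbreak chains.

    Censored chains (alive at the generation cap without reaching the
    emergence cap) are counted as emerged in ``estimate``; the censoring
    fraction bounds the resulting bias.
    """

    estimate: float
    se: float
    n_chains: int
    n_extinct: int
    n_emerged: int
    n_censored: int
    generations: np.ndarray
    final_counts: np.ndarray

    @property
    def censored_fraction(self) -> float:
        return self.n_censored / self.n_chains

    @property
    def tally(self) -> Mapping[str, int]:
        return {
            "extinct": self.n_extinct,
            "emerged": self.n_emerged,
            "censored": self.n_censored,
        }


def simulate_chains(
    params: BranchingParams,
    start_type: str = "W",
    n_chains: int = 20_000,
    seed: int | np.random.Generator | None = None,
    emergence_cap: int = 1_000,
    gen_cap: int = 200,
) -> ChainResult:
    """Simulate outbreak chains generation by generation (Monte-Carlo check).

    Each generation, per-infection mutation/reversion re-classifies a
    binomial number of W (resp. M) infections as co-infections, then every
    infection reproduces with its Poisson offspring law.  A chain emerges
    when the total infection count reaches ``emergence_cap`` (supercritical
    chains that grow this large escape extinction with overwhelming
    probability), goes extinct at zero, and is censored at ``gen_cap``.
    Deterministic under a fixed seed.
    """
    if start_type not in TYPES:
        raise ValueError(f"start_type must be one of {TYPES}, got {start_type!r}")
    if n_chains < 1 or emergence_cap < 1 or gen_cap < 1:
        raise ValueError("n_chains, emergence_cap and gen_cap must all be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = offspring_means(params)
    p = params

    counts = np.zeros((n_chains, 3), dtype=np.int64)
    counts[:, TYPES.index(start_type)] = 1
    # 0 = active, 1 = extinct, 2 = emerged
    status = np.zeros(n_chains, dtype=np.int8)
    generations = np.zeros(n_chains, dtype=np.int32)
    if emergence_cap == 1:
        status[:] = 2

    for gen in range(1, gen_cap + 1):
        active = np.flatnonzero(status == 0)
        if active.size == 0:
            break
        nW = counts[active, 0]
        nM = counts[active, 1]
        nC = counts[active, 2]
        mutW = rng.binomial(nW, p.mu1)
        mutM = rng.binomial(nM, p.mu2)
        nC_eff = nC + mutW + mutM
        newW = rng.poisson(p.Rw * (nW - mutW)) + rng.poisson(m.Rcw * nC_eff)
        newM = rng.poisson(p.Rm * (nM - mutM)) + rng.poisson(m.Rcm * nC_eff)
        newC = rng.poisson(m.Rcc * nC_eff)
        counts[active, 0] = newW
        counts[active, 1] = newM
        counts[active, 2] = newC
        generations[active] = gen
        total = newW + newM + newC
        status[active[total == 0]] = 1
        status[active[total >= emergence_cap]] = 2

    n_extinct = int(np.sum(status == 1))
    n_emerged = int(np.sum(status == 2))
    n_censored = int(np.sum(status == 0))
    estimate = (n_emerged + n_censored) / n_chains
    se = math.sqrt(max(estimate * (1.0 - estimate), 0.0) / n_chains)
    return ChainResult(
        estimate=estimate,
        se=se,
        n_chains=n_chains,
        n_extinct=n_extinct,
        n_emerged=n_emerged,
        n_censored=n_censored,
        generations=generations,
        final_counts=counts,
    )
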