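"""Two-strain within-host infection model with transmission bookkeeping.

A wild-type strain (density ``W``) and a mutant strain (density ``M``)
replicate exponentially inside a host and are killed by a shared,
strain-transcending immune response ``I``:

.. math::

    dW/dt = r_w W - k W I, \\qquad
    dM/dt = r_m M - k M I, \\qquad
    dI/dt = s I \\frac{W + M}{A + W + M}.

Transmission happens at rate ``lambda(t) = log10[(1 + x·deltaM)(W + zM)]``
(clamped at zero), pathology is ``alpha(t) = W + vM``, and the infection
ends when pathology exceeds the lethal threshold ``phi`` or the combined
pathogen density drops below the clearance threshold ``omega``.  The total
transmission ``Lambda = int_0^tau lambda dt`` is proportional to the basic
reproduction number of the infection.

For a co-infection, each transmitted inoculum of ``n`` particles draws
strains binomially with per-particle mutant probability
``theta(t) = zM / (W + zM)``.  Integrating over the infection gives the
co-transmission probability ``c`` (both strains transmitted) and the mutant
share ``b`` of single-strain transmission events.  Comparing total
transmission from wild-type-only, mutant-only and co-infections yields the
dominance ``d = (Lambda_c - Lambda_w) / (Lambda_m - Lambda_w)`` of the
mutant phenotype.

All integrals (``Lambda`` and the per-bottleneck ``b``/``c`` numerators)
are carried as auxiliary ODE states so they are event-accurate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "WithinHostParams",
    "Trajectory",
    "InfectionOutcome",
    "BottleneckStats",
    "DominanceEstimate",
    "PhenotypeScenario",
    "SCENARIOS",
    "derivatives",
    "transmission_rate",
    "pathology",
    "theta",
    "simulate_infection",
    "total_transmission",
    "cotransmission_probs",
    "dominance",
    "scan_phenotype",
]

#: relative inward shift of the clearance threshold used by event detection,
#: so an inoculum starting exactly at omega does not terminate at t = 0
CLEARANCE_SHIFT = 1e-12

DEFAULT_BOTTLENECKS = (1, 2, 5, 10)


@dataclass(frozen=True)
class WithinHostParams:
    """Parameters of the within-host model.

    Defaults are the baseline wild-type parameterization: a neutral mutant
    (``rm = rw``, ``z = v = 1``, ``x = 0``) and a pathology threshold eight
    orders of magnitude above the clearance threshold.

    Parameters
    ----------
    rw, rm : float
        Replication rates of wild-type and mutant (per unit time).
    k : float
        Immune killing rate (per unit immune density per unit time).
    s : float
        Immune growth rate (per unit time).
    A : float
        Immune-sensitivity tuning density; immune growth saturates in
        total pathogen density with half-maximum at ``A``.
    x : float
        Host-infectivity boost conferred by the mutant (dimensionless,
        >= 0); acts on transmission of both strains, only when the mutant
        is present.
    z : float
        Mutant transmissibility relative to wild-type (dimensionless, > 0).
    v : float
        Mutant virulence relative to wild-type (dimensionless, >= 0).
    phi : float
        Pathology (lethal) threshold: infection ends when ``W + vM > phi``.
    omega : float
        Clearance threshold: infection ends when ``W + M < omega``.
    w0, m0, i0 : float
        Initial densities of wild-type, mutant and immune response.
    t_max : float
        Integration horizon; runs that reach it are flagged.
    bottlenecks : tuple of int
        Bottleneck sizes ``n`` for which co-transmission summaries are
        accumulated during integration.
    """

    rw: float = 1.0
    rm: float = 1.0
    k: float = 1e-4
    s: float = 0.8
    A: float = 1e3
    x: float = 0.0
    z: float = 1.0
    v: float = 1.0
    phi: float = 1e8
    omega: float = 1.0
    w0: float = 1.0
    m0: float = 0.0
    i0: float = 1.0
    t_max: float = 1e4
    bottlenecks: tuple[int, ...] = DEFAULT_BOTTLENECKS

    def __post_init__(self) -> None:
        for name in ("rw", "rm", "k", "s", "A", "x", "v", "w0", "m0", "i0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.z <= 0:
            raise ValueError(f"z must be positive, got {self.z}")
        if not (self.phi > self.omega > 0):
            raise ValueError(f"need phi > omega > 0, got phi={self.phi}, omega={self.omega}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        ns = tuple(int(n) for n in self.bottlenecks)
        if any(n < 1 for n in ns) or any(n != m for n, m in zip(ns, self.bottlenecks)):
            raise ValueError(f"bottlenecks must be positive integers, got {self.bottlenecks}")
        object.__setattr__(self, "bottlenecks", ns)

    @property
    def mutant_present(self) -> bool:
        """Whether the infection contains the mutant (fixed per infection)."""
        return self.m0 > 0


class BottleneckStats(NamedTuple):
    """Per-bottleneck transmission split: ``b`` and ``c`` for one size ``n``."""

    b: float
    c: float


@dataclass(frozen=True)
class Trajectory:
    """Dense within-host trajectory with derived transmission quantities.

    ``co_mass[n]`` and ``mutant_mass[n]`` are the cumulative integrals
    ``int (1 - theta^n - (1-theta)^n) lambda dt`` and ``int theta^n lambda dt``
    used to compute ``c`` and ``b``.
    """

    t: np.ndarray
    W: np.ndarray
    M: np.ndarray
    I: np.ndarray
    lam: np.ndarray
    alpha: np.ndarray
    theta: np.ndarray
    Lambda_cum: np.ndarray
    co_mass: Mapping[int, np.ndarray]
    mutant_mass: Mapping[int, np.ndarray]
    params: WithinHostParams

    def to_frame(self) -> pd.DataFrame:
        """Tidy view with columns t, W, M, I, lambda, alpha, theta, Lambda_cum."""
        return pd.DataFrame(
            {
                "t": self.t,
                "W": self.W,
                "M": self.M,
                "I": self.I,
                "lambda": self.lam,
                "alpha": self.alpha,
                "theta": self.theta,
                "Lambda_cum": self.Lambda_cum,
            }
        )


@dataclass(frozen=True)
class InfectionOutcome:
    """Summary of one simulated infection."""

    tau: float
    total_transmission: float
    end_cause: str  # "pathology" | "clearance" | "horizon"
    bottleneck_stats: Mapping[int, BottleneckStats]


@dataclass(frozen=True)
class DominanceEstimate:
    """Total transmissions of the three infection types and the dominance."""

    lambda_w: float
    lambda_m: float
    lambda_c: float

    @property
    def d(self) -> float:
        return dominance(self.lambda_w, self.lambda_m, self.lambda_c)


def derivatives(
    state: Sequence[float], params: WithinHostParams
) -> tuple[float, float, float]:
    """Right-hand side of the within-host ODE system at one state.

    Raises ``ValueError`` for negative densities (integrator misuse).
    """
    W, M, I = state
    if W < 0 or M < 0 or I < 0:
        raise ValueError(f"negative state (W={W}, M={M}, I={I})")
    total = W + M
    return (
        params.rw * W - params.k * W * I,
        params.rm * M - params.k * M * I,
        params.s * I * total / (params.A + total),
    )


def transmission_rate(W, M, params: WithinHostParams, mutant_present: bool):
    """Transmission rate ``max(0, log10[(1 + x·deltaM)(W + zM)])``.

    ``deltaM`` is 1 iff the mutant is present in the infection.  The clamp
    at zero covers arguments below 1 (densities near the clearance
    threshold contribute no transmission) and makes the zero-density case
    well defined.  Accepts scalars or arrays.
    """
    delta = 1.0 if mutant_present else 0.0
    arg = (1.0 + params.x * delta) * (np.asarray(W, float) + params.z * np.asarray(M, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(arg > 1.0, np.log10(np.where(arg > 0, arg, 1.0)), 0.0)
    if np.ndim(W) == 0 and np.ndim(M) == 0:
        return float(lam)
    return lam


def pathology(W, M, v: float):
    """Pathology level ``alpha = W + vM``."""
    return W + v * M


def theta(W: float, M: float, z: float) -> float:
    """Per-particle mutant transmission probability ``zM / (W + zM)``.

    Undefined (raises) when both strains are absent.
    """
    denom = W + z * M
    if denom <= 0:
        raise ValueError("theta undefined: W + zM = 0 (both strains extinct)")
    return z * M / denom


def _rhs(t, y, p: WithinHostParams, delta: float, ns: tuple[int, ...]):
    W, M, I = y[0], y[1], y[2]
    Wc = W if W > 0.0 else 0.0
    Mc = M if M > 0.0 else 0.0
    total = Wc + Mc
    dW = p.rw * W - p.k * W * I
    dM = p.rm * M - p.k * M * I
    dI = p.s * I * total / (p.A + total)
    tz = Wc + p.z * Mc
    arg = (1.0 + p.x * delta) * tz
    lam = math.log10(arg) if arg > 1.0 else 0.0
    th = (p.z * Mc / tz) if tz > 0.0 else 0.0
    out = [dW, dM, dI, lam]
    one_minus = 1.0 - th
    for n in ns:
        out.append((1.0 - th**n - one_minus**n) * lam)
        out.append(th**n * lam)
    return out


def simulate_infection(
    params: WithinHostParams, n_points: int = 2001
) -> tuple[Trajectory, InfectionOutcome]:
    """Integrate one infection to its end and summarize transmission.

    The ODE system is integrated with LSODA (stiff-capable, adaptive;
    rtol 1e-8, atol 1e-10) with terminal events located by root-finding on
    ``alpha - phi`` (upward crossing) and ``(W + M) - omega`` (strict
    downward crossing; the threshold is shifted inward by the relative
    amount ``CLEARANCE_SHIFT`` so that an inoculum starting exactly at the
    clearance scale and growing does not terminate at t = 0, while a
    non-replicating inoculum is cleared immediately).  ``Lambda`` and the
    per-bottleneck co-transmission integrals ride along as auxiliary
    states.

    Returns the dense trajectory (``n_points`` grid points on [0, tau]) and
    the infection outcome.
    """
    p = params
    if p.w0 + p.m0 <= 0:
        raise ValueError("need a nonzero inoculum (w0 + m0 > 0)")
    if pathology(p.w0, p.m0, p.v) >= p.phi:
        raise ValueError("initial pathology already exceeds phi")
    delta = 1.0 if p.mutant_present else 0.0
    ns = p.bottlenecks
    y0 = [p.w0, p.m0, p.i0, 0.0] + [0.0] * (2 * len(ns))

    def pathology_event(t, y, *args):
        return max(y[0], 0.0) + p.v * max(y[1], 0.0) - p.phi

    pathology_event.terminal = True
    pathology_event.direction = 1

    clearance_level = p.omega * (1.0 - CLEARANCE_SHIFT)

    def clearance_event(t, y, *args):
        return max(y[0], 0.0) + max(y[1], 0.0) - clearance_level

    clearance_event.terminal = True
    clearance_event.direction = -1

    sol = solve_ivp(
        _rhs,
        (0.0, p.t_max),
        y0,
        args=(p, delta, ns),
        method="LSODA",
        events=(pathology_event, clearance_event),
        dense_output=True,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y[:, -1])):
        raise RuntimeError("non-finite state at end of integration")

    if sol.t_events[0].size:
        end_cause = "pathology"
    elif sol.t_events[1].size:
        end_cause = "clearance"
    else:
        end_cause = "horizon"
        warnings.warn(
            f"infection not resolved by t_max={p.t_max}; results truncated at the horizon",
            RuntimeWarning,
            stacklevel=2,
        )
    tau = float(sol.t[-1])
    y_end = sol.y[:, -1]
    Lambda = max(float(y_end[3]), 0.0)

    t_grid = np.linspace(0.0, tau, n_points)
    Y = sol.sol(t_grid)
    W = np.clip(Y[0], 0.0, None)
    M = np.clip(Y[1], 0.0, None)
    I = np.clip(Y[2], 0.0, None)
    lam = transmission_rate(W, M, p, p.mutant_present)
    alpha = pathology(W, M, p.v)
    tz = W + p.z * M
    with np.errstate(divide="ignore", invalid="ignore"):
        th = np.where(tz > 0, p.z * M / np.where(tz > 0, tz, 1.0), 0.0)
    th = np.clip(th, 0.0, 1.0)
    Lambda_cum = np.maximum.accumulate(np.clip(Y[3], 0.0, None))
    co_mass = {}
    mut_mass = {}
    stats: dict[int, BottleneckStats] = {}
    for i, n in enumerate(ns):
        co_mass[n] = Y[4 + 2 * i]
        mut_mass[n] = Y[5 + 2 * i]
        stats[n] = _bottleneck_stats(Lambda, float(y_end[4 + 2 * i]), float(y_end[5 + 2 * i]))

    traj = Trajectory(
        t=t_grid,
        W=W,
        M=M,
        I=I,
        lam=np.asarray(lam, float),
        alpha=alpha,
        theta=th,
        Lambda_cum=Lambda_cum,
        co_mass=co_mass,
        mutant_mass=mut_mass,
        params=p,
    )
    outcome = InfectionOutcome(
        tau=tau,
        total_transmission=Lambda,
        end_cause=end_cause,
        bottleneck_stats=stats,
    )
    return traj, outcome


def _bottleneck_stats(Lambda: float, co_int: float, mut_int: float) -> BottleneckStats:
    if Lambda <= 0:
        return BottleneckStats(b=math.nan, c=math.nan)
    c = min(max(co_int / Lambda, 0.0), 1.0)
    single = Lambda - co_int
    if single <= Lambda * 1e-12:
        return BottleneckStats(b=math.nan, c=c)
    b = min(max(mut_int / single, 0.0), 1.0)
    return BottleneckStats(b=b, c=c)


def total_transmission(trajectory: Trajectory) -> float:
    """Total transmission ``Lambda`` accumulated over the infection."""
    return float(trajectory.Lambda_cum[-1])


def cotransmission_probs(trajectory: Trajectory, n: int) -> BottleneckStats:
    """Co-transmission probability ``c`` and mutant single-strain share ``b``.

    Uses the event-accurate auxiliary integrals when ``n`` was requested at
    simulation time, falling back to trapezoid quadrature on the dense grid
    otherwise.  Raises if the trajectory carries no transmission
    (``Lambda = 0``) or if ``c = 1`` (``b`` undefined: no single-strain
    transmission events).
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"bottleneck size must be >= 1, got {n}")
    Lambda = total_transmission(trajectory)
    if Lambda <= 0:
        raise ValueError("co-transmission undefined: total transmission is zero")
    if n in trajectory.co_mass:
        co_int = float(trajectory.co_mass[n][-1])
        mut_int = float(trajectory.mutant_mass[n][-1])
    else:
        th = trajectory.theta
        lam = trajectory.lam
        co_int = float(np.trapezoid((1.0 - th**n - (1.0 - th) ** n) * lam, trajectory.t))
        mut_int = float(np.trapezoid(th**n * lam, trajectory.t))
    stats = _bottleneck_stats(Lambda, co_int, mut_int)
    if math.isnan(stats.b):
        raise ValueError("b undefined: c = 1, no single-strain transmission events")
    return stats


def dominance(lambda_w: float, lambda_m: float, lambda_c: float) -> float:
    """Dominance ``d = (Lambda_c - Lambda_w) / (Lambda_m - Lambda_w)``.

    May fall outside [0, 1] (under-/overdominance).  Undefined for a
    neutral mutant (``Lambda_m == Lambda_w``).
    """
    if lambda_m == lambda_w:
        raise ValueError("dominance undefined: Lambda_m == Lambda_w (neutral mutant)")
    return (lambda_c - lambda_w) / (lambda_m - lambda_w)


@dataclass(frozen=True)
class PhenotypeScenario:
    """One hypothetical mutant phenotype: varied parameter, range, threshold."""

    name: str
    param: str
    low: float
    high: float
    phi: float


SCENARIOS: dict[str, PhenotypeScenario] = {
    s.name: s
    for s in (
        PhenotypeScenario("increased_growth", "rm", 1.0, 2.0, 1e12),
        PhenotypeScenario("decreased_growth", "rm", 0.0, 1.0, 1e6),
        PhenotypeScenario("decreased_virulence", "v", 0.0, 1.0, 1e7),
        PhenotypeScenario("increased_transmissibility", "z", 1.0, 4.0, 1e8),
        PhenotypeScenario("increased_infectivity", "x", 0.0, 4.0, 1e8),
    )
}


def scan_phenotype(
    scenario: str,
    grid: Sequence[float] | None = None,
    params: WithinHostParams | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Scan one mutant phenotype over its parameter range.

    For each grid value the wild-type-only, mutant-only and co-infection
    runs are simulated with the scenario's pathology threshold ``phi`` and
    default other parameters; single infections use the base total
    inoculum, co-infections split the same total equally between strains so
    that the combined inoculum matches a single infection.  Returns a tidy
    table with one row per grid value: ``value``, the three ``lambda_*``
    totals, normalized ``lambda_m_rel``/``lambda_c_rel``, dominance ``d``
    (NaN where the mutant is exactly neutral), end causes, and ``b_n``/
    ``c_n`` for each requested bottleneck size.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    sc = SCENARIOS[scenario]
    base = replace(params if params is not None else WithinHostParams(), phi=sc.phi)
    if grid is None:
        grid = np.linspace(sc.low, sc.high, n_grid)
    grid = np.asarray(grid, float)
    eps = 1e-9 * max(1.0, abs(sc.high))
    if grid.min() < sc.low - eps or grid.max() > sc.high + eps:
        raise ValueError(
            f"grid outside the {scenario} range [{sc.low}, {sc.high}]"
        )
    total = base.w0 + base.m0
    if total <= 0:
        total = 1.0

    wild = replace(base, w0=total, m0=0.0)
    _, out_w = simulate_infection(wild)
    lw = out_w.total_transmission

    rows = []
    for value in grid:
        override = {sc.param: float(value)}
        mut = replace(base, w0=0.0, m0=total, **override)
        co = replace(base, w0=total / 2, m0=total / 2, **override)
        _, out_m = simulate_infection(mut)
        _, out_c = simulate_infection(co)
        lm = out_m.total_transmission
        lc = out_c.total_transmission
        d = math.nan if lm == lw else dominance(lw, lm, lc)
        row: dict[str, object] = {
            "scenario": scenario,
            "value": float(value),
            "lambda_w": lw,
            "lambda_m": lm,
            "lambda_c": lc,
            "lambda_m_rel": lm / lw if lw > 0 else math.nan,
            "lambda_c_rel": lc / lw if lw > 0 else math.nan,
            "d": d,
            "end_cause_m": out_m.end_cause,
            "end_cause_c": out_c.end_cause,
        }
        for n in base.bottlenecks:
            stats = out_c.bottleneck_stats[n]
            row[f"b_{n}"] = stats.b
            row[f"c_{n}"] = stats.c
        rows.append(row)
    return pd.DataFrame(rows)
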