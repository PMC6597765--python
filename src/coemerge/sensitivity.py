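"""Latin hypercube sampling and PRCC sensitivity analysis.

Global sensitivity of the emergence probability to the branching-process
parameters is assessed the standard way for monotone-ish epidemic models:
draw N parameter sets by Latin hypercube sampling (one draw per
equal-width stratum per parameter, independently permuted across
parameters), evaluate the model on each row, and summarize each
parameter's influence with the partial rank correlation coefficient
(PRCC) — the correlation between the residuals of that parameter's ranks
and of the response's ranks after regressing both on the ranks of all
other parameters.  Percentile bootstrap confidence intervals are obtained
by resampling design rows with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .branching import BranchingParams, emergence_probability

__all__ = [
    "PARAM_ORDER",
    "ParamRanges",
    "LHSDesign",
    "PRCCResult",
    "SensitivityResult",
    "lhs_sample",
    "prcc",
    "bootstrap_prcc_ci",
    "emergence_sensitivity",
]

PARAM_ORDER = ("Rw", "Rm", "d", "c", "b", "mu1", "mu2")

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Rw": (0.0, 1.0),
    "Rm": (1.0, 4.0),
    "d": (0.0, 1.0),
    "c": (0.0, 1.0),
    "b": (0.0, 1.0),
    "mu1": (0.0, 1.0),
    "mu2": (0.0, 1.0),
}

#: dominance range extended to under-/overdominance
EXTENDED_D_RANGE = (-0.5, 1.5)


@dataclass(frozen=True)
class ParamRanges:
    """Per-parameter sampling bounds for the branching-process parameters."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        clean = {}
        for name, (low, high) in self.bounds.items():
            if name not in PARAM_ORDER:
                raise ValueError(f"unknown parameter {name!r}; known: {PARAM_ORDER}")
            if low > high:
                raise ValueError(f"range for {name} has low > high: ({low}, {high})")
            clean[name] = (float(low), float(high))
        ordered = {name: clean[name] for name in PARAM_ORDER if name in clean}
        object.__setattr__(self, "bounds", ordered)

    @classmethod
    def default(cls, extended_d: bool = False) -> "ParamRanges":
        bounds = dict(_DEFAULT_BOUNDS)
        if extended_d:
            bounds["d"] = EXTENDED_D_RANGE
        return cls(bounds)

    def drop(self, names: Sequence[str]) -> "ParamRanges":
        """Ranges without the given parameters (used when pinning)."""
        return ParamRanges({k: v for k, v in self.bounds.items() if k not in names})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)


@dataclass(frozen=True)
class LHSDesign:
    """A Latin hypercube design: one sample per stratum per parameter."""

    samples: pd.DataFrame
    seed: object
    n_strata: int

    @property
    def N(self) -> int:
        return len(self.samples)


def lhs_sample(
    ranges: ParamRanges, N: int, seed: int | np.random.Generator | None = None
) -> LHSDesign:
    """Draw ``N`` Latin hypercube samples over the given ranges.

    Each parameter range is divided into ``N`` equal-width strata; one
    value is drawn uniformly within each stratum and strata are paired
    across parameters by independent random permutations.  Degenerate
    ranges (low == high) yield a constant column with a warning.
    Deterministic under a fixed seed.
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    names = ranges.names
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(names), seed=rng)
    unit = sampler.random(N)
    lows = np.array([ranges.bounds[n][0] for n in names])
    highs = np.array([ranges.bounds[n][1] for n in names])
    degenerate = lows == highs
    if degenerate.any():
        warnings.warn(
            f"degenerate range(s) for {[n for n, f in zip(names, degenerate) if f]}: "
            "constant column(s) emitted",
            UserWarning,
            stacklevel=2,
        )
    values = lows + unit * (highs - lows)
    return LHSDesign(
        samples=pd.DataFrame(values, columns=list(names)), seed=seed, n_strata=N
    )


@dataclass(frozen=True)
class PRCCResult:
    """PRCC point estimates with bootstrap confidence intervals."""

    table: pd.DataFrame  # index: parameter; columns: prcc, ci_low, ci_high
    N: int
    B: int


def _design_frame(design: LHSDesign | pd.DataFrame) -> pd.DataFrame:
    return design.samples if isinstance(design, LHSDesign) else design


def _prcc_from_ranks(rank_x: np.ndarray, rank_y: np.ndarray) -> np.ndarray:
    """PRCC per column of ``rank_x`` via residual-on-ranks regression."""
    n, k = rank_x.shape
    out = np.empty(k)
    intercept = np.ones((n, 1))
    for j in range(k):
        others = np.hstack([intercept, np.delete(rank_x, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, rank_x[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, rank_y, rcond=None)
        res_x = rank_x[:, j] - others @ beta_x
        res_y = rank_y - others @ beta_y
        denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
        out[j] = (res_x @ res_y) / denom if denom > 0 else np.nan
    return out


def prcc(design: LHSDesign | pd.DataFrame, response: Sequence[float]) -> pd.Series:
    """Partial rank correlation of each design column with the response.

    Ties are broken by average rank.  Raises for a constant response
    (ranks carry no information).
    """
    X = _design_frame(design)
    y = np.asarray(response, float)
    if len(y) != len(X):
        raise ValueError(f"response length {len(y)} != design size {len(X)}")
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    if np.ptp(y) == 0:
        raise ValueError("PRCC undefined for a constant response")
    rank_x = np.column_stack([rankdata(X[c].to_numpy()) for c in X.columns])
    rank_y = rankdata(y)
    return pd.Series(_prcc_from_ranks(rank_x, rank_y), index=list(X.columns), name="prcc")


def bootstrap_prcc_ci(
    design: LHSDesign | pd.DataFrame,
    response: Sequence[float],
    B: int = 500,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> PRCCResult:
    """PRCC point estimates with percentile bootstrap confidence intervals.

    Design rows (with their responses) are resampled with replacement ``B``
    times; the interval is the ``(1-level)/2`` and ``1-(1-level)/2``
    percentiles of the replicate PRCCs.  Deterministic under a fixed seed.
    """
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    X = _design_frame(design)
    y = np.asarray(response, float)
    point = prcc(X, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(X)
    Xv = X.to_numpy()
    reps = np.empty((B, Xv.shape[1]))
    for i in range(B):
        idx = rng.integers(0, n, size=n)
        rank_x = np.column_stack([rankdata(Xv[idx, j]) for j in range(Xv.shape[1])])
        rank_y = rankdata(y[idx])
        reps[i] = _prcc_from_ranks(rank_x, rank_y)
    alpha = (1.0 - level) / 2.0
    lo = np.nanpercentile(reps, 100 * alpha, axis=0)
    hi = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
    table = pd.DataFrame(
        {"prcc": point.to_numpy(), "ci_low": lo, "ci_high": hi}, index=point.index
    )
    return PRCCResult(table=table, N=n, B=B)


@dataclass(frozen=True)
class SensitivityResult:
    """LHS design, per-row emergence probabilities and the PRCC table."""

    design: LHSDesign
    response: np.ndarray
    table: pd.DataFrame
    fixed: Mapping[str, float]
    N: int
    B: int
    seed: object


def emergence_sensitivity(
    ranges: ParamRanges | None = None,
    N: int = 500,
    B: int = 500,
    seed: int | np.random.Generator | None = None,
    fixed: Mapping[str, float] | None = None,
    start_type: str = "W",
) -> SensitivityResult:
    """LHS + PRCC analysis of the emergence probability.

    Pinned parameters (``fixed``) are excluded from the design and held at
    the given values when evaluating the branching model, supporting both
    the all-parameters run and runs with dominance pinned at 0 or 1.
    """
    fixed = dict(fixed or {})
    ranges = ranges if ranges is not None else ParamRanges.default()
    ranges = ranges.drop(list(fixed))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = lhs_sample(ranges, N, seed=rng)
    response = np.empty(N)
    for i, row in enumerate(design.samples.itertuples(index=False)):
        params = BranchingParams(**{**row._asdict(), **fixed})
        response[i] = emergence_probability(params, start_type=start_type)
    result = bootstrap_prcc_ci(design, response, B=B, seed=rng)
    return SensitivityResult(
        design=design,
        response=response,
        table=result.table,
        fixed=fixed,
        N=N,
        B=B,
        seed=seed,
    )
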