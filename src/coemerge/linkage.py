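"""Within-host to between-host linkage: phenotype-resolved emergence.

The within-host model supplies, for each mutant phenotype value, the
dominance ``d``, the co-transmission probability ``c`` and mutant share
``b`` at each bottleneck size, and the transmission ratio
``Lambda_m / Lambda_w``.  Fixing the wild-type reproduction number ``Rw``
maps that ratio to ``Rm = Rw * Lambda_m / Lambda_w``; feeding everything
into the branching process then gives the probability that a chain started
from a single wild-type infection leads to emergence of the mutant, as a
function of phenotype and bottleneck size.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .branching import BranchingParams, emergence_probability
from .within_host import WithinHostParams, scan_phenotype

__all__ = ["phenotype_emergence"]


def phenotype_emergence(
    scenario: str,
    grid: Sequence[float] | None = None,
    bottlenecks: Sequence[int] = (1, 2, 5, 10),
    Rw: float = 0.9,
    mu1: float = 0.01,
    mu2: float = 0.01,
    params: WithinHostParams | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Emergence probability per phenotype value and bottleneck size.

    Runs the within-host scan for ``scenario``, then for every grid value
    and bottleneck ``n`` evaluates the branching process with
    ``Rm = Rw * Lambda_m / Lambda_w``, the scan's ``d`` and the
    bottleneck's ``(b, c)``, starting from one wild-type infection.  Grid
    values where the mutant is exactly neutral (``Lambda_m = Lambda_w``,
    dominance undefined) are retained with missing emergence so the grid
    stays aligned.

    Returns a tidy table with columns
    ``scenario, value, n, d, b, c, Rm, emergence``.
    """
    if Rw <= 0:
        raise ValueError(f"Rw must be positive, got {Rw}")
    base = params if params is not None else WithinHostParams()
    base = WithinHostParams(
        **{
            **{f: getattr(base, f) for f in base.__dataclass_fields__},
            "bottlenecks": tuple(int(n) for n in bottlenecks),
        }
    )
    scan = scan_phenotype(scenario, grid=grid, params=base, n_grid=n_grid)

    rows = []
    for rec in scan.itertuples(index=False):
        Rm = Rw * rec.lambda_m / rec.lambda_w
        for n in base.bottlenecks:
            b = getattr(rec, f"b_{n}")
            c = getattr(rec, f"c_{n}")
            if math.isnan(rec.d):
                emergence = math.nan
            else:
                # Rc = d·Rm + (1−d)·Rw and Rw·Λc/Λw are algebraically the same
                # quantity; disagreement beyond roundoff flags a pipeline bug.
                rc_dom = rec.d * Rm + (1.0 - rec.d) * Rw
                rc_ratio = Rw * rec.lambda_c / rec.lambda_w
                assert abs(rc_dom - rc_ratio) <= 1e-6 * max(1.0, abs(rc_ratio)), (
                    f"inconsistent Rc: {rc_dom} vs {rc_ratio} at value={rec.value}"
                )
                bp = BranchingParams(Rw=Rw, Rm=Rm, d=rec.d, c=c, b=b, mu1=mu1, mu2=mu2)
                emergence = emergence_probability(bp, start_type="W")
            rows.append(
                {
                    "scenario": rec.scenario,
                    "value": rec.value,
                    "n": n,
                    "d": rec.d,
                    "b": b,
                    "c": c,
                    "Rm": Rm,
                    "emergence": emergence,
                }
            )
    return pd.DataFrame(rows)
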