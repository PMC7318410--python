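"""Closed-form chemostat steady states in cell retention time (CRT).

For a single sugar under plain Monod growth (no substrate/product
inhibition) the steady-state balances reduce to

    S = Ks (1 + CRT * K_D) / (CRT (mu_max - K_D) - 1)
    X = Y^X (CRT/HRT) (S_in - S) / (K_D * CRT + 1)

where HRT = 1/D is the hydraulic retention time and CRT >= HRT is the cell
retention time (equal to HRT in a CFSTR, larger with membrane retention).
Washout occurs at CRT <= 1/(mu_max - K_D).  Steady-state lactate follows
from the consumed sugar via the lactate mass yield: S_la = Y^la (S_in - S).

Where inhibition matters, the ODE model in :mod:`lacferm.reactor` is the
ground truth; these expressions are its inhibition-free limit and serve as
an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import GrowthParams

__all__ = [
    "SteadyStateQuery",
    "WashoutError",
    "washout_crt",
    "effluent_substrate",
    "steady_biomass",
    "crt_sweep",
]


class WashoutError(ValueError):
    """Operation at or below the critical cell retention time."""

    def __init__(self, crt: float, critical: float):
        super().__init__(
            f"CRT {crt:.4g} h is at/below the washout limit {critical:.4g} h"
        )
        self.critical = critical


@dataclass(frozen=True)
class SteadyStateQuery:
    """One steady-state operating point (single sugar, plain Monod)."""

    growth: GrowthParams
    K_D: float
    CRT: float
    HRT: float
    S_in: float
    cell_mass_yield: float
    lactate_mass_yield: float = 0.0

    def __post_init__(self) -> None:
        if not self.HRT > 0.0:
            raise ValueError("HRT must be > 0")
        if self.CRT < self.HRT:
            raise ValueError("CRT must be >= HRT (cells cannot leave faster than liquid)")
        if not self.S_in > 0.0:
            raise ValueError("S_in must be > 0")
        if self.K_D < 0.0:
            raise ValueError("K_D must be >= 0")


def washout_crt(growth: GrowthParams, K_D: float) -> float:
    """Critical CRT below which cells wash out: 1/(mu_max - K_D), h."""
    if growth.mu_max <= K_D:
        raise ValueError(
            f"mu_max ({growth.mu_max}) <= K_D ({K_D}): no viable operation"
        )
    return 1.0 / (growth.mu_max - K_D)


def effluent_substrate(q: SteadyStateQuery) -> float:
    """Steady residual sugar (g/L); capped at S_in in the no-growth regime."""
    critical = washout_crt(q.growth, q.K_D)
    if q.CRT <= critical:
        raise WashoutError(q.CRT, critical)
    s = q.growth.Ks * (1.0 + q.CRT * q.K_D) / (q.CRT * (q.growth.mu_max - q.K_D) - 1.0)
    return min(s, q.S_in)


def steady_biomass(q: SteadyStateQuery) -> float:
    """Steady cell concentration (g/L); 0 under washout or no-growth."""
    try:
        s = effluent_substrate(q)
    except WashoutError:
        return 0.0
    return q.cell_mass_yield * (q.CRT / q.HRT) * (q.S_in - s) / (q.K_D * q.CRT + 1.0)


def crt_sweep(
    growth: GrowthParams,
    K_D: float,
    S_in: float,
    cell_mass_yield: float,
    lactate_mass_yield: float,
    crt_grid,
    hrt: float | None = None,
) -> pd.DataFrame:
    """Vectorized sweep of the steady-state expressions over a CRT grid.

    ``hrt=None`` means CFSTR operation (HRT = CRT at every grid point).
    Grid points at/below washout are flagged 'washout' (not dropped); points
    where the formula exceeds the feed are flagged 'no_growth'.  Columns:
    crt_h, hrt_h, substrate_gL, biomass_gL, lactate_gL, flag.
    """
    rows = []
    for crt in np.asarray(crt_grid, dtype=float):
        h = crt if hrt is None else hrt
        q = SteadyStateQuery(
            growth=growth,
            K_D=K_D,
            CRT=crt,
            HRT=h,
            S_in=S_in,
            cell_mass_yield=cell_mass_yield,
            lactate_mass_yield=lactate_mass_yield,
        )
        try:
            s = effluent_substrate(q)
        except WashoutError:
            rows.append((crt, h, S_in, 0.0, 0.0, "washout"))
            continue
        flag = "no_growth" if s >= q.S_in else "ok"
        x = steady_biomass(q)
        s_la = lactate_mass_yield * (S_in - s)
        rows.append((crt, h, s, x, s_la, flag))
    return pd.DataFrame(
        rows,
        columns=["crt_h", "hrt_h", "substrate_gL", "biomass_gL", "lactate_gL", "flag"],
    )
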