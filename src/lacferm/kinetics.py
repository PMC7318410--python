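"""Specific growth-rate kinetics: Monod with substrate and product inhibition.

The per-sugar specific growth rate is

    mu = mu_max * S / (Ks + S + S^2/Kis) * Kip / (Kip + S_la)

with S the sugar concentration, S_la the lactate concentration (pooled over
all sugars), Ks the half-saturation constant, Kis the substrate-inhibition
coefficient and Kip the product-inhibition coefficient (all g/L).  Setting
Kis or Kip to math.inf disables the corresponding inhibition term, reducing
the law to plain Monod.

Carbon catabolite repression (CCR) of xylose uptake by glucose is modeled,
when enabled, as a non-competitive factor K_ccr / (K_ccr + S_glu) on the
xylose term only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .stoich import SUGARS, YieldSet, yield_set_from_cell_mass_yield

__all__ = [
    "GrowthParams",
    "OrganismParams",
    "specific_growth_rate",
    "ccr_factor",
    "growth_rates",
    "gross_growth_rate",
    "qu25_table1",
    "TABLE1_QU25",
]


@dataclass(frozen=True)
class GrowthParams:
    """Growth-law parameters for one sugar (mu_max h^-1; Ks, Kis, Kip g/L)."""

    mu_max: float
    Ks: float
    Kis: float = math.inf
    Kip: float = math.inf

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks", "Kis", "Kip"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"GrowthParams.{name} must be > 0, got {v}")


@dataclass(frozen=True)
class OrganismParams:
    """Full kinetic parameter set of one strain.

    per_sugar / yields are keyed by sugar name; only sugars actually present
    in a simulation need entries.  K_D lumps decay, bleeding and endogenous
    losses (h^-1).  K_ccr (g/L), when not None, enables glucose-on-xylose
    repression.
    """

    per_sugar: dict[str, GrowthParams]
    yields: dict[str, YieldSet]
    K_D: float = 0.0
    K_ccr: float | None = None

    def __post_init__(self) -> None:
        for name in self.per_sugar:
            if name not in SUGARS:
                raise ValueError(f"unknown sugar {name!r} in per_sugar")
            if name not in self.yields:
                raise ValueError(f"sugar {name!r} has growth params but no yields")
        if self.K_D < 0.0:
            raise ValueError(f"K_D must be >= 0, got {self.K_D}")
        if self.per_sugar and self.K_D >= min(p.mu_max for p in self.per_sugar.values()):
            raise ValueError("K_D >= min(mu_max): no net growth ever possible")
        if self.K_ccr is not None and not self.K_ccr > 0.0:
            raise ValueError(f"K_ccr must be > 0 or None, got {self.K_ccr}")

    @property
    def sugars(self) -> tuple[str, ...]:
        return tuple(self.per_sugar)


def specific_growth_rate(params: GrowthParams, S: float, S_la: float) -> float:
    """Evaluate the inhibited Monod law (h^-1) at sugar S and lactate S_la."""
    if S < 0.0 or S_la < 0.0:
        raise ValueError(f"concentrations must be >= 0 (S={S}, S_la={S_la})")
    if S == 0.0:
        return 0.0
    denom = params.Ks + S + S * S / params.Kis  # S^2/inf -> 0 disables the term
    mu = params.mu_max * S / denom
    if math.isfinite(params.Kip):
        mu *= params.Kip / (params.Kip + S_la)
    return mu


def ccr_factor(S_glu: float, K_ccr: float) -> float:
    """Repression factor on xylose growth, in (0, 1]; 1 when no glucose."""
    if K_ccr <= 0.0:
        raise ValueError(f"K_ccr must be > 0, got {K_ccr}")
    if S_glu < 0.0:
        raise ValueError(f"S_glu must be >= 0, got {S_glu}")
    return K_ccr / (K_ccr + S_glu)


def growth_rates(state, params: OrganismParams) -> dict[str, float]:
    """Per-sugar specific growth rates (h^-1) for a reactor state.

    Applies the CCR factor to the xylose term when params.K_ccr is enabled.
    """
    mus: dict[str, float] = {}
    for name, gp in params.per_sugar.items():
        S = getattr(state, _STATE_FIELD[name])
        mu = specific_growth_rate(gp, S, state.S_la)
        if name == "xylose" and params.K_ccr is not None:
            mu *= ccr_factor(state.S_glu, params.K_ccr)
        mus[name] = mu
    return mus


def gross_growth_rate(state, params: OrganismParams) -> float:
    """Sum of per-sugar growth rates (h^-1), before the decay term -K_D."""
    return sum(growth_rates(state, params).values())


_STATE_FIELD = {"glucose": "S_glu", "cellobiose": "S_cel", "xylose": "S_xyl"}

#: Fitted kinetic parameters of E. mundtii QU 25 (batch studies):
#: (mu_max h^-1, Ks, Kis, Kip g/L, cell mass yield g/g) per sugar.
TABLE1_QU25: dict[str, tuple[float, float, float, float, float]] = {
    "glucose": (1.20, 55.6, 108.3, 1.8, 0.038),
    "cellobiose": (0.99, 8.95, 26.8, 1.5, 0.028),
    "xylose": (0.62, 20.1, 254.2, 3.3, 0.056),
}


def qu25_table1(
    sugars: tuple[str, ...] | None = None,
    K_D: float = 0.0,
    K_ccr: float | None = None,
) -> OrganismParams:
    """The E. mundtii QU 25 parameter preset.

    Lactate mass yields are derived from the cell mass yields through the
    carbon-balanced stoichiometry (0.950 glucose, 1.015 cellobiose,
    0.926 xylose g/g).  ``sugars`` restricts the entries (default all three).
    """
    names = tuple(TABLE1_QU25) if sugars is None else tuple(sugars)
    per_sugar = {}
    yields = {}
    for name in names:
        mu_max, Ks, Kis, Kip, yx = TABLE1_QU25[name]
        per_sugar[name] = GrowthParams(mu_max=mu_max, Ks=Ks, Kis=Kis, Kip=Kip)
        yields[name] = yield_set_from_cell_mass_yield(yx, SUGARS[name])
    return OrganismParams(per_sugar=per_sugar, yields=yields, K_D=K_D, K_ccr=K_ccr)
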