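"""Carbon-balanced stoichiometry of homolactic sugar fermentation.

Each sugar (glucose, cellobiose, xylose) is converted to cell biomass
(C5H7NO2) and lactate (C3H6O3) with no CO2 loss: glucose and cellobiose run
through the Embden-Meyerhof-Parnas pathway, xylose through the pentose
phosphate / glycolytic route.  Writing Y for the molar cell yield
(mol biomass per mol sugar), the half reactions are

    sugar + Y NH4+  ->  Y C5H7NO2 + n_la C3H6O3 + n_w H2O + Y H+

where carbon conservation fixes the lactate coefficient,

    n_la = (C_sugar - 5 Y) / 3,

i.e. 2 - 5/3 Y for glucose, 4 - 5/3 Y for cellobiose and 5/3 (1 - Y) for
xylose, and the hydrogen balance fixes the water coefficient (3 Y for the
monosaccharides, 3 Y - 1 for cellobiose, whose glycosidic bond consumes one
water on hydrolysis).  Mass yields (g/g) follow from the molar coefficients
and the molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SugarSpec",
    "StoichCoefficients",
    "YieldSet",
    "GLUCOSE",
    "CELLOBIOSE",
    "XYLOSE",
    "SUGARS",
    "CELL_MW",
    "LACTATE_MW",
    "molar_cell_yield_from_mass",
    "cell_mass_yield_from_molar",
    "stoichiometric_coefficients",
    "lactate_mass_yield",
    "yield_set_from_cell_mass_yield",
    "mass_balance_residual",
    "constants_table",
]

#: Molecular weight of dry biomass C5H7NO2, g/mol.
CELL_MW = 113.0
#: Molecular weight of lactic acid C3H6O3, g/mol.
LACTATE_MW = 90.0
_WATER_MW = 18.0
_AMMONIUM_MW = 18.0  # NH4+ at integer atomic masses
_PROTON_MW = 1.0


@dataclass(frozen=True)
class SugarSpec:
    """A fermentable sugar: formula constants used by the stoichiometry.

    ``hexose_units`` is the number of C6 equivalents (glucose 1,
    cellobiose 2, xylose 5/6).
    """

    name: str
    molecular_weight: float
    carbon_atoms: int
    hexose_units: float
    hydrogen_atoms: int

    def __post_init__(self) -> None:
        expected = {"glucose": (180.0, 6), "cellobiose": (342.0, 12), "xylose": (150.0, 5)}
        if self.name not in expected:
            raise ValueError(f"unknown sugar {self.name!r}")
        mw, c = expected[self.name]
        if self.molecular_weight != mw or self.carbon_atoms != c:
            raise ValueError(
                f"{self.name}: molecular_weight/carbon_atoms must be {mw}/{c}"
            )

    @property
    def max_molar_cell_yield(self) -> float:
        """Molar cell yield at which every sugar carbon ends up in biomass."""
        return self.carbon_atoms / 5.0


GLUCOSE = SugarSpec("glucose", 180.0, 6, 1.0, 12)
CELLOBIOSE = SugarSpec("cellobiose", 342.0, 12, 2.0, 22)
XYLOSE = SugarSpec("xylose", 150.0, 5, 5.0 / 6.0, 10)

#: Registry keyed by sugar name.
SUGARS: dict[str, SugarSpec] = {s.name: s for s in (GLUCOSE, CELLOBIOSE, XYLOSE)}


@dataclass(frozen=True)
class StoichCoefficients:
    """Molar coefficients of the fermentation half reaction, per mol sugar."""

    cell: float
    lactate: float
    water: float
    ammonium: float
    proton: float


@dataclass(frozen=True)
class YieldSet:
    """Consistent molar and mass yields for one sugar.

    cell_mass_yield is Y^X (g cell / g sugar), lactate_mass_yield is Y^la
    (g lactate / g sugar); both follow from the molar cell yield.
    """

    molar_cell_yield: float
    cell_mass_yield: float
    lactate_mass_yield: float


def molar_cell_yield_from_mass(cell_mass_yield: float, sugar: SugarSpec) -> float:
    """Invert Y^X = Y * 113 / MW_sugar to the molar cell yield (mol/mol)."""
    upper = CELL_MW * sugar.max_molar_cell_yield / sugar.molecular_weight
    if not 0.0 <= cell_mass_yield <= upper:
        raise ValueError(
            f"cell mass yield {cell_mass_yield} outside [0, {upper:.5f}] "
            f"(all-carbon-to-cell limit for {sugar.name})"
        )
    return cell_mass_yield * sugar.molecular_weight / CELL_MW


def cell_mass_yield_from_molar(molar_cell_yield: float, sugar: SugarSpec) -> float:
    """Forward mass-yield conversion Y^X = Y * 113 / MW_sugar (g/g)."""
    return molar_cell_yield * CELL_MW / sugar.molecular_weight


def stoichiometric_coefficients(
    molar_cell_yield: float, sugar: SugarSpec
) -> StoichCoefficients:
    """Full coefficient set of the half reaction at a given molar cell yield.

    Carbon (C = 5*cell + 3*lactate) and nitrogen (ammonium = cell) balances
    hold exactly by construction.
    """
    y = molar_cell_yield
    if not 0.0 <= y <= sugar.max_molar_cell_yield:
        raise ValueError(
            f"molar cell yield {y} outside [0, {sugar.max_molar_cell_yield:.4f}] "
            f"(lactate coefficient would go negative for {sugar.name})"
        )
    lactate = (sugar.carbon_atoms - 5.0 * y) / 3.0
    # hydrogen balance: H_sugar + 4y = 7y + 6*lactate + 2*water + y
    water = (sugar.hydrogen_atoms + 4.0 * y - 7.0 * y - 6.0 * lactate - y) / 2.0
    return StoichCoefficients(cell=y, lactate=lactate, water=water, ammonium=y, proton=y)


def lactate_mass_yield(molar_cell_yield: float, sugar: SugarSpec) -> float:
    """Lactate mass yield Y^la (g/g sugar) from the carbon-balanced coefficient."""
    coeffs = stoichiometric_coefficients(molar_cell_yield, sugar)
    return coeffs.lactate * LACTATE_MW / sugar.molecular_weight


def yield_set_from_cell_mass_yield(cell_mass_yield: float, sugar: SugarSpec) -> YieldSet:
    """Build the consistent YieldSet from a measured cell mass yield (g/g)."""
    y = molar_cell_yield_from_mass(cell_mass_yield, sugar)
    return YieldSet(
        molar_cell_yield=y,
        cell_mass_yield=cell_mass_yield,
        lactate_mass_yield=lactate_mass_yield(y, sugar),
    )


def mass_balance_residual(coeffs: StoichCoefficients, sugar: SugarSpec) -> float:
    """|mass(reactants) - mass(products)| per mole sugar, g/mol.

    Exact coefficient sets give ~0 (integer molecular weights make the
    balance close exactly up to float rounding).
    """
    reactants = sugar.molecular_weight + _AMMONIUM_MW * coeffs.ammonium
    products = (
        CELL_MW * coeffs.cell
        + LACTATE_MW * coeffs.lactate
        + _WATER_MW * coeffs.water
        + _PROTON_MW * coeffs.proton
    )
    return abs(reactants - products)


def constants_table() -> dict:
    """Machine-readable constants (for provenance blocks in result JSON)."""
    return {
        "cell_molecular_weight_g_mol": CELL_MW,
        "lactate_molecular_weight_g_mol": LACTATE_MW,
        "sugars": {
            name: {
                "molecular_weight_g_mol": s.molecular_weight,
                "carbon_atoms": s.carbon_atoms,
                "hexose_units": s.hexose_units,
            }
            for name, s in SUGARS.items()
        },
    }
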