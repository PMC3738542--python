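"""Elemental compositions and carbon bookkeeping.

Concentration-based carbon balances need the mass fraction of carbon in each
measured pool (biomass, organic acids, CO2).  Compositions are expressed as
stoichiometric subscripts, possibly fractional for biomass (the generalized
one-carbon formula CH_1.77 O_0.49 N_0.24 commonly used for *E. coli*).
Charges are carried for documentation; electron mass is neglected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

#: Standard atomic masses, g/mol.
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


@dataclass(frozen=True)
class ElementalComposition:
    """Stoichiometric subscripts of C, H, O, N plus formal charge."""

    c: float
    h: float = 0.0
    o: float = 0.0
    n: float = 0.0
    charge: int = 0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise DomainError("carbon subscript must be positive")
        if min(self.h, self.o, self.n) < 0:
            raise DomainError("subscripts must be non-negative")

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol (electron mass of charged species neglected)."""
        return (
            self.c * ATOMIC_MASS["C"]
            + self.h * ATOMIC_MASS["H"]
            + self.o * ATOMIC_MASS["O"]
            + self.n * ATOMIC_MASS["N"]
        )


def carbon_fraction(comp: ElementalComposition) -> float:
    """Mass fraction of carbon: ``12.011 * nC / molar_mass``."""
    return comp.c * ATOMIC_MASS["C"] / comp.molar_mass


# Generalized E. coli biomass monomer, ash-free.
BIOMASS = ElementalComposition(c=1, h=1.77, o=0.49, n=0.24)
# Fermentation by-products as the anions present at culture pH ~7.
ACETATE = ElementalComposition(c=2, h=3, o=2, charge=-1)  # CH3COO-
ACETIC_ACID = ElementalComposition(c=2, h=4, o=2)
FORMATE = ElementalComposition(c=1, h=1, o=2, charge=-1)  # HCOO-
PYRUVATE = ElementalComposition(c=3, h=3, o=3, charge=-1)
LACTATE = ElementalComposition(c=3, h=5, o=3, charge=-1)
CO2 = ElementalComposition(c=1, o=2)
GLUCOSE = ElementalComposition(c=6, h=12, o=6)

#: Default composition per carbon-balance pool.
POOL_COMPOSITIONS: dict[str, ElementalComposition] = {
    "biomass": BIOMASS,
    "acetate": ACETATE,
    "formate": FORMATE,
    "pyruvate": PYRUVATE,
    "lactate": LACTATE,
    "co2": CO2,
}

#: Grams of glucose consumed per gram of acetate under homoacetate
#: stoichiometry (1 glucose -> 2 acetic acid): M_glc / (2 * M_HAc) ~= 1.5.
#: HPLC acetate concentrations are reported on the neutral-acid mass basis,
#: so the stoichiometric factor uses acetic acid, not the anion.
GLUCOSE_PER_ACETATE = GLUCOSE.molar_mass / (2.0 * ACETIC_ACID.molar_mass)
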