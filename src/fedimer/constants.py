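"""Physical constants and basis-set conventions.

All energies are stored internally in hartree; reports use kJ/mol (one
decimal) and exchange couplings cm^-1, matching standard practice for
transition-metal thermochemistry tables.
"""

from __future__ import annotations

# CODATA conversion factors.
HARTREE_TO_KJMOL: float = 2625.4996395
HARTREE_TO_INVCM: float = 219474.6314
KJMOL_PER_INVCM: float = HARTREE_TO_KJMOL / HARTREE_TO_INVCM  # 0.011962657...

#: Unit labels accepted throughout the package, with their value in hartree.
UNIT_TO_HARTREE: dict[str, float] = {
    "hartree": 1.0,
    "kJ/mol": 1.0 / HARTREE_TO_KJMOL,
    "cm-1": 1.0 / HARTREE_TO_INVCM,
}

#: Basis-set cardinal numbers for the correlation-consistent family.
#: Only bases with a cardinal participate in CBS extrapolation; the def2
#: family is deliberately excluded.
BASIS_CARDINALS: dict[str, int | None] = {
    "cc-pVDZ-DK": 2,
    "cc-pVTZ-DK": 3,
    "cc-pVQZ-DK": 4,
    "def2-SV(P)": None,
}

#: Default two-point CBS exponent for correlation energies.
DEFAULT_CBS_BETA: float = 2.4

#: The four protonated dimer structures, in canonical order. HC carries the
#: proton on the bridging CH2 group, HS on the bridging sulfide, HFe
#: terminally on one iron, HFe2 bridging both irons.
STRUCTURES: tuple[str, ...] = ("HC", "HS", "HFe", "HFe2")


class UnitError(ValueError):
    """Raised for an unrecognised energy unit label."""


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between hartree, kJ/mol and cm-1.

    Conversion goes through hartree with the fixed constants above, so any
    round trip is an identity to better than 1e-12 relative.
    """
    try:
        f = UNIT_TO_HARTREE[from_unit]
    except KeyError:
        raise UnitError(f"unknown energy unit {from_unit!r}") from None
    try:
        t = UNIT_TO_HARTREE[to_unit]
    except KeyError:
        raise UnitError(f"unknown energy unit {to_unit!r}") from None
    return value * f / t
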