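"""Yamaguchi broken-symmetry spin decontamination.

An antiferromagnetic singlet described by an unrestricted broken-symmetry
(BS) determinant is spin-contaminated.  Given the BS and high-spin (HS)
energies of the same structure together with their spin expectation values
⟨S²⟩, the Yamaguchi scheme estimates the exchange coupling

    J = (E_BS − E_HS) / (⟨S²⟩_HS − ⟨S²⟩_BS)

and the pure-spin (PS) target-state energy

    E_PS = E_BS + (⟨S²⟩_BS − ⟨S²⟩_PS) · J.

With ⟨S²⟩_PS = 0 (a true singlet) the PS correction E_PS − E_BS equals
J·⟨S²⟩_BS, negative for antiferromagnetic pairs (E_BS < E_HS, J < 0).
No −2J spin-Hamiltonian prefactor is applied; J is defined operationally
by the quotient above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .constants import KJMOL_PER_INVCM, convert_units
from .energy_store import MissingDataError


@dataclass(frozen=True)
class SpinPair:
    """BS/HS energies of one structure with their ⟨S²⟩ values.

    Energies may be absolute or on a common relative scale, but must share
    ``unit`` and the same zero.
    """

    structure: str
    e_bs: float
    e_hs: float
    s2_bs: float
    s2_hs: float
    s2_ps: float = 0.0
    unit: str = "hartree"

    def __post_init__(self) -> None:
        if not (self.s2_hs > self.s2_bs >= 0.0):
            raise ValueError(
                f"{self.structure}: need S2_HS > S2_BS >= 0, "
                f"got {self.s2_hs}, {self.s2_bs}"
            )
        if not (0.0 <= self.s2_ps < self.s2_hs):
            raise ValueError(
                f"{self.structure}: need 0 <= S2_PS < S2_HS, got {self.s2_ps}"
            )


@dataclass(frozen=True)
class ProjectionResult:
    structure: str
    j_cm: float  # exchange coupling, cm^-1
    e_ps: float  # pure-spin energy, in the input unit
    ps_correction_kjmol: float  # E_PS - E_BS, kJ/mol


def exchange_coupling(pair: SpinPair) -> float:
    """Exchange coupling J in cm^-1 from a same-structure BS/HS pair."""
    denom = pair.s2_hs - pair.s2_bs
    if denom == 0.0:  # unreachable given SpinPair invariants; belt and braces
        raise ZeroDivisionError("S2_HS == S2_BS: coupling undefined")
    j = (pair.e_bs - pair.e_hs) / denom
    return convert_units(j, pair.unit, "cm-1")


def pure_spin_energy(pair: SpinPair) -> ProjectionResult:
    """Pure-spin energy estimate and its correction relative to BS."""
    j_cm = exchange_coupling(pair)
    j_native = convert_units(j_cm, "cm-1", pair.unit)
    corr_native = (pair.s2_bs - pair.s2_ps) * j_native
    return ProjectionResult(
        structure=pair.structure,
        j_cm=j_cm,
        e_ps=pair.e_bs + corr_native,
        ps_correction_kjmol=convert_units(corr_native, pair.unit, "kJ/mol"),
    )


def ps_correction_from_coupling(
    j_cm: float, s2_bs: float, s2_ps: float = 0.0
) -> float:
    """PS correction E_PS − E_BS in kJ/mol from a known coupling in cm^-1.

    Used when J is known (or tabulated) but the underlying absolute BS/HS
    energies are not: the correction is (⟨S²⟩_BS − ⟨S²⟩_PS)·J.
    """
    return (s2_bs - s2_ps) * j_cm * KJMOL_PER_INVCM


def ps_relative_table(
    bs_relative: Mapping[str, float],
    corrections: Mapping[str, float],
    reference: str,
) -> pd.Series:
    """Relative PS energies from relative BS energies and per-structure corrections.

    ΔE_PS(i) = ΔE_BS(i) + corr(i) − corr(ref); the reference maps to 0.
    All values in kJ/mol.
    """
    bs = pd.Series(dict(bs_relative), dtype=float)
    corr = pd.Series(dict(corrections), dtype=float)
    if set(bs.index) != set(corr.index):
        raise MissingDataError(
            "structure mismatch between BS table and corrections: "
            f"{sorted(set(bs.index) ^ set(corr.index))}"
        )
    if reference not in bs.index:
        raise MissingDataError(f"reference {reference!r} missing")
    out = bs + corr - corr[reference]
    out[reference] = 0.0
    return out.reindex(bs.index)


__all__ = [
    "SpinPair",
    "ProjectionResult",
    "exchange_coupling",
    "pure_spin_energy",
    "ps_correction_from_coupling",
    "ps_relative_table",
]
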