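"""Natural-orbital occupancy diagnostics.

Natural-orbital occupancies n_i (eigenvalues of the spin-averaged
one-particle density matrix, 0 ≤ n_i ≤ 2) measure multireference
character: closed-shell orbitals sit at 0 or 2, open-shell and strongly
correlated orbitals in between.  Two diagnostics are provided:

* active-space selection — keep the orbitals whose occupancy lies
  furthest from both 0 and 2, i.e. maximising d(n) = min(n, 2 − n);
* a fractional-occupancy census — count orbitals in the bands
  [0.2, 0.8] ∪ [1.2, 1.8], which excludes singly occupied (n ≈ 1)
  orbitals and so isolates multireference character beyond simple spin
  recoupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class OccupancyVector:
    """Natural-orbital occupancies of one structure.

    ``electron_count`` is optional; when given, the occupancies must sum
    to it to within 1e-6 (true for normalised density-matrix eigenvalues).
    """

    structure: str
    occupancies: tuple[float, ...]
    electron_count: int | None = None

    def __post_init__(self) -> None:
        occ = tuple(float(n) for n in self.occupancies)
        object.__setattr__(self, "occupancies", occ)
        if any(not (0.0 <= n <= 2.0) for n in occ):
            raise ValueError(f"{self.structure}: occupancies must lie in [0, 2]")
        if self.electron_count is not None:
            total = sum(occ)
            if abs(total - self.electron_count) > 1e-6:
                raise ValueError(
                    f"{self.structure}: occupancies sum to {total}, "
                    f"not {self.electron_count}"
                )


@dataclass(frozen=True)
class ActiveSpaceSpec:
    """A selected (n_orbitals, n_electrons) active space, e.g. (63o, 64e)."""

    orbital_indices: tuple[int, ...]
    n_orbitals: int
    n_electrons: int

    def __post_init__(self) -> None:
        if len(set(self.orbital_indices)) != self.n_orbitals:
            raise ValueError("orbital_indices must be n_orbitals distinct indices")
        if not (0 <= self.n_electrons <= 2 * self.n_orbitals):
            raise ValueError("0 <= n_electrons <= 2*n_orbitals violated")

    @property
    def label(self) -> str:
        return f"{self.n_orbitals}o,{self.n_electrons}e"


def occupancy_distance(n: float) -> float:
    """Distance of an occupancy from the nearer closed-shell value (0 or 2)."""
    return min(n, 2.0 - n)


def select_active_space(occ: OccupancyVector, n_orbitals: int) -> ActiveSpaceSpec:
    """Select the ``n_orbitals`` occupancies furthest from 0 or 2.

    Ranking is by descending d(n) = min(n, 2 − n) with ties broken by
    ascending orbital index, so enlarging the space always yields a
    superset of the smaller selection.  The electron count is the rounded
    sum of the selected occupancies.
    """
    occs = occ.occupancies
    if n_orbitals > len(occs):
        raise ValueError(
            f"requested {n_orbitals} orbitals but only {len(occs)} available"
        )
    d = [occupancy_distance(n) for n in occs]
    order = sorted(range(len(occs)), key=lambda i: (-d[i], i))
    chosen = tuple(sorted(order[:n_orbitals]))
    if chosen and all(d[i] == 0.0 for i in chosen):
        warnings.warn(
            f"{occ.structure}: no fractional character — all selected "
            "occupancies are exactly 0 or 2",
            stacklevel=2,
        )
    n_electrons = int(round(sum(occs[i] for i in chosen)))
    return ActiveSpaceSpec(
        orbital_indices=chosen, n_orbitals=n_orbitals, n_electrons=n_electrons
    )


def fractional_census(
    occ: OccupancyVector | Sequence[float],
    band: tuple[float, float] = (0.2, 0.8),
) -> int:
    """Count occupancies in [low, high] ∪ [2 − high, 2 − low], edges inclusive.

    The band is particle-hole symmetric (n and 2 − n count equally) and by
    construction excludes singly occupied orbitals near n = 1.
    """
    low, high = band
    if not (0.0 < low < high < 1.0):
        raise ValueError(f"band must satisfy 0 < low < high < 1, got {band}")
    values = occ.occupancies if isinstance(occ, OccupancyVector) else occ
    arr = np.asarray(values, dtype=float)
    in_band = ((arr >= low) & (arr <= high)) | (
        (arr >= 2.0 - high) & (arr <= 2.0 - low)
    )
    return int(np.count_nonzero(in_band))


__all__ = [
    "OccupancyVector",
    "ActiveSpaceSpec",
    "occupancy_distance",
    "select_active_space",
    "fractional_census",
]
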