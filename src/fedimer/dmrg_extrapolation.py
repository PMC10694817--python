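"""DMRG energy extrapolation and the multireference correction.

DMRG energies from a reverse schedule converge approximately linearly in
the discarded weight w; an ordinary least-squares line of E against w
gives the w → 0 limit.  The extrapolation error is estimated as one-fifth
of the gap between the extrapolated energy and the energy at the largest
bond dimension (the smallest discarded weight of the schedule).

The multireference correction to a CCSD(T) energy is the active-space
difference ΔE = E_DMRG-act − E_CCSD(T)-act, taken per structure and then
referenced to a chosen structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .energy_store import MissingDataError


@dataclass(frozen=True)
class DMRGSeries:
    """(bond dimension M, discarded weight w, energy) triples for one structure."""

    structure: str
    active_space: str
    points: tuple[tuple[int, float, float], ...]
    unit: str = "hartree"

    def __post_init__(self) -> None:
        pts = tuple((int(m), float(w), float(e)) for m, w, e in self.points)
        object.__setattr__(self, "points", pts)
        ms = [m for m, _, _ in pts]
        if len(set(ms)) != len(ms):
            raise ValueError(f"bond dimensions must be distinct, got {ms}")
        if any(w < 0 for _, w, _ in pts):
            raise ValueError("discarded weights must be >= 0")

    @property
    def max_bond_dimension(self) -> int:
        return max(m for m, _, _ in self.points)

    @property
    def energy_at_max_m(self) -> float:
        return max(self.points, key=lambda p: p[0])[2]


@dataclass(frozen=True)
class ExtrapolatedDMRG:
    e_extrap: float
    error_estimate: float  # |E_at_max_M - E_extrap| / 5, always >= 0
    e_at_max_m: float
    slope: float
    residual_rms: float

    def __post_init__(self) -> None:
        expected = abs(self.e_at_max_m - self.e_extrap) / 5.0
        if abs(self.error_estimate - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError("error_estimate violates the one-fifth rule")


def extrapolate_dmrg(series: DMRGSeries) -> ExtrapolatedDMRG:
    """Least-squares w → 0 extrapolation with the one-fifth error estimate.

    For noiseless variational input (energy decreasing with decreasing w)
    the intercept lies at or below every input energy; with noise this
    ordering may be violated and is not enforced.
    """
    if len(series.points) < 2:
        raise ValueError("extrapolation needs at least two points")
    w = np.array([p[1] for p in series.points])
    e = np.array([p[2] for p in series.points])
    if np.all(w == w[0]):
        raise ValueError("all discarded weights identical: slope not identifiable")
    slope, intercept = np.polyfit(w, e, 1)
    fitted = slope * w + intercept
    e_max_m = series.energy_at_max_m
    return ExtrapolatedDMRG(
        e_extrap=float(intercept),
        error_estimate=abs(e_max_m - float(intercept)) / 5.0,
        e_at_max_m=e_max_m,
        slope=float(slope),
        residual_rms=float(np.sqrt(np.mean((e - fitted) ** 2))),
    )


def multireference_correction(
    dmrg: Mapping[str, float],
    ccsdt_act: Mapping[str, float],
    reference: str,
    dmrg_errors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-structure ΔE = E_DMRG − E_CCSD(T) and its reference-relative value.

    Inputs are same-active-space energies on a common scale (absolute, or
    both relative to the same zero), in kJ/mol.  Extrapolation errors, if
    given, propagate additively onto the relative corrections — a
    deliberately conservative combination.
    """
    d = pd.Series(dict(dmrg), dtype=float)
    c = pd.Series(dict(ccsdt_act), dtype=float)
    if set(d.index) != set(c.index):
        raise MissingDataError(
            "structure mismatch between DMRG and CCSD(T) tables: "
            f"{sorted(set(d.index) ^ set(c.index))}"
        )
    if reference not in d.index:
        raise MissingDataError(f"reference {reference!r} missing")
    delta = (d - c).rename("delta_kJmol")
    relative = (delta - delta[reference]).rename("relative_kJmol")
    relative[reference] = 0.0
    out = pd.concat([delta, relative], axis=1).reindex(d.index)
    if dmrg_errors is not None:
        err = pd.Series(dict(dmrg_errors), dtype=float).reindex(d.index)
        if err.isna().any():
            raise MissingDataError("dmrg_errors must cover every structure")
        rel_err = err + err[reference]
        rel_err[reference] = 0.0
        out["relative_error_kJmol"] = rel_err
    return out


def mr_uncertainty(relative_corrections: Mapping[str, float]) -> float:
    """Half the largest-magnitude relative multireference correction, kJ/mol.

    The conservative uncertainty attached to the correction: the largest
    estimate still compatible with the correction improving the result.
    Callers round to whole kJ/mol for reporting.
    """
    s = pd.Series(dict(relative_corrections), dtype=float)
    if len(s) == 0:
        raise ValueError("mr_uncertainty requires at least one correction")
    return float(s.abs().max()) / 2.0


__all__ = [
    "DMRGSeries",
    "ExtrapolatedDMRG",
    "extrapolate_dmrg",
    "multireference_correction",
    "mr_uncertainty",
]
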