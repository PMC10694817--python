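"""Assembly of the final composite relative energies.

The composite best estimate for each structure is

    E = E_CCSD(T)-TZ + (E_DMRG-act − E_CCSD(T)-act) + ΔE_CCSD(T)-CBS,

i.e. the broken-symmetry CCSD(T)/TZ relative energy plus an active-space
multireference correction plus a basis-set correction.  The Yamaguchi
pure-spin correction is deliberately NOT added on top: the DMRG energies
entering the multireference correction are pure-spin singlet energies, so
adding the Yamaguchi correction as well would double-count the spin
recoupling.

The module also ranks structures, combines the two uncertainty estimates,
and scores DFT functionals against the composite reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .energy_store import MissingDataError

_ZERO_TOL = 1e-9


@dataclass(frozen=True)
class CompositeResult:
    """Per-structure composite energies and their three components, kJ/mol.

    ``table`` columns: uncorrected_tz, mr_correction, basis_correction,
    total; indexed by structure.  total is the exact (unrounded) component
    sum, and every component of the reference structure is 0.
    """

    table: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        t = self.table
        required = {"uncorrected_tz", "mr_correction", "basis_correction", "total"}
        if not required <= set(t.columns):
            raise ValueError(f"missing columns {sorted(required - set(t.columns))}")
        if self.reference not in t.index:
            raise ValueError(f"reference {self.reference!r} not in table")
        resid = (
            t["uncorrected_tz"] + t["mr_correction"] + t["basis_correction"]
            - t["total"]
        )
        if resid.abs().max() > _ZERO_TOL:
            raise ValueError("total != sum of components")
        if t.loc[self.reference].abs().max() > _ZERO_TOL:
            raise ValueError("reference row must be identically zero")

    @property
    def totals(self) -> pd.Series:
        return self.table["total"]


@dataclass(frozen=True)
class UncertaintyLedger:
    sigma_mr: float
    sigma_basis: float
    sigma_total: float


@dataclass(frozen=True)
class DeviationStats:
    functional: str
    deviations: pd.Series  # per non-reference structure, kJ/mol
    mean_abs: float
    max_abs: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_abs <= self.max_abs + _ZERO_TOL):
            raise ValueError("need 0 <= mean_abs <= max_abs")


def _aligned(name: str, values: Mapping[str, float], index) -> pd.Series:
    s = pd.Series(dict(values), dtype=float)
    if set(s.index) != set(index):
        raise MissingDataError(
            f"structure mismatch in {name}: {sorted(set(s.index) ^ set(index))}"
        )
    return s.reindex(index)


def assemble_composite(
    uncorrected_tz: Mapping[str, float],
    mr_corrections: Mapping[str, float],
    basis_corrections: Mapping[str, float],
    reference: str,
) -> CompositeResult:
    """Sum the three composite components per structure (all kJ/mol, relative)."""
    tz = pd.Series(dict(uncorrected_tz), dtype=float)
    structures = list(tz.index)
    if reference not in structures:
        raise MissingDataError(f"reference {reference!r} missing")
    mr = _aligned("mr_corrections", mr_corrections, structures)
    bs = _aligned("basis_corrections", basis_corrections, structures)
    for name, s in (("uncorrected_tz", tz), ("mr_corrections", mr),
                    ("basis_corrections", bs)):
        if abs(s[reference]) > _ZERO_TOL:
            raise ValueError(f"{name}[{reference}] must be 0, got {s[reference]}")
    table = pd.DataFrame(
        {
            "uncorrected_tz": tz,
            "mr_correction": mr,
            "basis_correction": bs,
        }
    )
    table["total"] = table.sum(axis=1)
    table.loc[reference] = 0.0
    return CompositeResult(table=table, reference=reference)


def rank_structures(result: CompositeResult) -> list[list[str]]:
    """Structures ascending by composite total; exact ties grouped together."""
    totals = result.totals.sort_values(kind="stable")
    groups: list[list[str]] = []
    last: float | None = None
    for structure, value in totals.items():
        if last is not None and value == last:
            groups[-1].append(structure)
        else:
            groups.append([structure])
        last = value
    return groups


def dft_deviation_stats(
    dft_relative: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    composite: CompositeResult,
) -> list[DeviationStats]:
    """Score DFT functionals against the composite relative energies.

    ``dft_relative`` maps functional -> per-structure relative energy
    (kJ/mol, same reference as the composite).  Deviations, their mean
    absolute value and maximum absolute value are taken over the
    non-reference structures only (the reference deviation is identically
    zero and would dilute the mean).
    """
    if isinstance(dft_relative, pd.DataFrame):
        items = {f: dft_relative.loc[f].to_dict() for f in dft_relative.index}
    else:
        items = {f: dict(v) for f, v in dft_relative.items()}
    ref = composite.reference
    targets = [s for s in composite.table.index if s != ref]
    out = []
    for functional, values in items.items():
        missing = [s for s in targets if s not in values]
        if missing:
            raise MissingDataError(
                f"functional {functional!r} missing structures {missing}"
            )
        dev = pd.Series(
            {s: values[s] - composite.totals[s] for s in targets}, dtype=float
        )
        out.append(
            DeviationStats(
                functional=functional,
                deviations=dev,
                mean_abs=float(dev.abs().mean()),
                max_abs=float(dev.abs().max()),
            )
        )
    return out


def uncertainty_ledger(
    mr_delta: float,
    basis_delta: float,
    mode: str = "paper",
    combine: str = "linear",
) -> UncertaintyLedger:
    """Combine the multireference and basis-set uncertainties, kJ/mol.

    ``mode='paper'`` rounds each component to whole kJ/mol before summing
    (the convention of reported ±N values); ``mode='exact'`` keeps full
    precision.  The components are treated as fully correlated and added
    linearly by default; ``combine='quadrature'`` is available for an
    independent-error reading.
    """
    if mr_delta < 0 or basis_delta < 0:
        raise ValueError("uncertainties must be non-negative")
    if mode not in {"paper", "exact"}:
        raise ValueError(f"unknown mode {mode!r}")
    if combine not in {"linear", "quadrature"}:
        raise ValueError(f"unknown combine {combine!r}")
    mr = float(round(mr_delta)) if mode == "paper" else float(mr_delta)
    bs = float(round(basis_delta)) if mode == "paper" else float(basis_delta)
    if combine == "linear":
        total = mr + bs
    else:
        total = (mr**2 + bs**2) ** 0.5
    return UncertaintyLedger(sigma_mr=mr, sigma_basis=bs, sigma_total=total)


__all__ = [
    "CompositeResult",
    "UncertaintyLedger",
    "DeviationStats",
    "assemble_composite",
    "rank_structures",
    "dft_deviation_stats",
    "uncertainty_ledger",
]
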