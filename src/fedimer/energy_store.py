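"""Canonical store for electronic energies.

Every energy in the study — mean-field, MP2, coupled-cluster, DMRG, DFT —
is one :class:`EnergyRecord`, keyed by structure, method (with an optional
functional / reference-orbital qualifier), basis, spin state, energy
component and relativistic flag.  A :class:`RecordSet` enforces key
uniqueness and offers the slicing and relative-energy utilities every
downstream stage builds on.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .constants import BASIS_CARDINALS, HARTREE_TO_KJMOL, convert_units

METHODS = frozenset({"mean-field", "MP2", "CCSD", "CCSD(T)", "DMRG", "DFT"})
SPIN_STATES = frozenset({"BS", "HS", "PS"})
COMPONENTS = frozenset({"total", "correlation", "triples-correction"})

#: Columns of the delimited-table record dialect, in canonical order.
RECORD_COLUMNS = (
    "structure",
    "method",
    "qualifier",
    "basis",
    "spin_state",
    "component",
    "relativistic",
    "energy",
    "unit",
)


class DuplicateKeyError(KeyError):
    """A record with an identical key is already present."""


class MissingDataError(LookupError):
    """A required record or structure is absent from the selected slice."""


def basis_cardinal(basis: str | None) -> int | None:
    """Cardinal number (2=DZ, 3=TZ, 4=QZ) of a basis label, if extrapolatable."""
    if basis is None:
        return None
    return BASIS_CARDINALS.get(basis)


@dataclass(frozen=True)
class EnergyRecord:
    """One electronic energy, stored in hartree.

    ``qualifier`` distinguishes e.g. a DFT functional or the reference
    orbitals of a coupled-cluster run (``UKS-TPSS`` vs ``UHF``).
    """

    structure: str
    method: str
    energy: float
    basis: str | None = None
    spin_state: str = "BS"
    component: str = "total"
    relativistic: bool = True
    qualifier: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.spin_state not in SPIN_STATES:
            raise ValueError(f"unknown spin state {self.spin_state!r}")
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if not math.isfinite(self.energy):
            raise ValueError(f"non-finite energy for {self.structure}")
        card = basis_cardinal(self.basis)
        if card is not None and card < 2:
            raise ValueError(f"basis cardinal must be >= 2, got {card}")
        if self.component == "triples-correction" and self.method != "CCSD(T)":
            raise ValueError(
                "component 'triples-correction' is only valid for CCSD(T)"
            )

    @property
    def key(self) -> tuple:
        return (
            self.structure,
            self.method,
            self.qualifier,
            self.basis,
            self.spin_state,
            self.component,
            self.relativistic,
        )

    @property
    def cardinal(self) -> int | None:
        return basis_cardinal(self.basis)

    def energy_in(self, unit: str) -> float:
        return convert_units(self.energy, "hartree", unit)


@dataclass
class RecordSet:
    """A key-unique collection of :class:`EnergyRecord`.

    ``reference`` names the structure a table of *relative* energies is
    measured against (``None`` for absolute energies); it is metadata
    carried along from the input table.
    """

    records: Mapping[tuple, EnergyRecord] = field(default_factory=dict)
    reference: str | None = None

    def __post_init__(self) -> None:
        recs = dict(self.records) if not isinstance(self.records, dict) else self.records
        self.records = {}
        for rec in recs.values():
            self.add(rec)

    @classmethod
    def from_records(
        cls, records: Iterable[EnergyRecord], reference: str | None = None
    ) -> "RecordSet":
        rs = cls(reference=reference)
        for rec in records:
            rs.add(rec)
        return rs

    def add(self, record: EnergyRecord) -> None:
        if record.key in self.records:
            raise DuplicateKeyError(f"duplicate record key {record.key}")
        self.records[record.key] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EnergyRecord]:
        return iter(self.records.values())

    @property
    def structures(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self:
            seen.setdefault(rec.structure, None)
        return tuple(seen)

    def subset(self, **criteria) -> "RecordSet":
        """Records matching every given field value (e.g. ``method='CCSD'``)."""
        out = RecordSet(reference=self.reference)
        for rec in self:
            if all(getattr(rec, k) == v for k, v in criteria.items()):
                out.add(rec)
        return out

    def energy(self, structure: str, unit: str = "hartree", **criteria) -> float:
        """The unique energy for one structure in a slice; error if not unique."""
        hits = [r for r in self.subset(**criteria) if r.structure == structure]
        if not hits:
            raise MissingDataError(
                f"no record for structure={structure!r}, {criteria}"
            )
        if len(hits) > 1:
            raise ValueError(
                f"ambiguous slice for structure={structure!r}, {criteria}"
            )
        return hits[0].energy_in(unit)

    def to_frame(self, unit: str = "hartree") -> pd.DataFrame:
        rows = [
            {
                "structure": r.structure,
                "method": r.method,
                "qualifier": r.qualifier,
                "basis": r.basis,
                "spin_state": r.spin_state,
                "component": r.component,
                "relativistic": r.relativistic,
                "energy": r.energy_in(unit),
                "unit": unit,
            }
            for r in self
        ]
        return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))

    def to_csv(self, path, unit: str = "kJ/mol") -> None:
        self.to_frame(unit=unit).to_csv(path, index=False)


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse relativistic flag {value!r}")


def load_records(source, reference: str | None = None) -> RecordSet:
    """Read a delimited table (comma or tab) of energy records.

    The header must name the :data:`RECORD_COLUMNS` fields; ``qualifier``,
    ``basis``, ``relativistic`` and ``unit`` may be omitted (defaults:
    none, none, true, hartree).  Energies are converted to hartree on
    ingest.  Duplicate keys and unknown enum values are hard errors that
    name the offending key or row.
    """
    if isinstance(source, (str, os.PathLike)):
        df = pd.read_csv(source, sep=None, engine="python")
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        df = pd.read_csv(source, sep=None, engine="python")
    else:
        raise TypeError("source must be a path or a readable file object")
    required = {"structure", "method", "energy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")

    rs = RecordSet(reference=reference)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        unit = str(d.get("unit", "hartree") or "hartree")
        if pd.isna(d.get("unit", "hartree")):
            unit = "hartree"
        try:
            energy = float(d["energy"])
        except (TypeError, ValueError):
            raise ValueError(f"row {i}: energy {d['energy']!r} not a number")
        basis = d.get("basis")
        qualifier = d.get("qualifier")
        rec_kwargs = dict(
            structure=str(d["structure"]),
            method=str(d["method"]),
            energy=convert_units(energy, unit, "hartree"),
            basis=None if pd.isna(basis) or basis in (None, "") else str(basis),
            qualifier=(
                None if pd.isna(qualifier) or qualifier in (None, "") else str(qualifier)
            ),
            relativistic=_parse_bool(d.get("relativistic", True), i)
            if not pd.isna(d.get("relativistic", True))
            else True,
        )
        if "spin_state" in d and not pd.isna(d["spin_state"]):
            rec_kwargs["spin_state"] = str(d["spin_state"])
        if "component" in d and not pd.isna(d["component"]):
            rec_kwargs["component"] = str(d["component"])
        try:
            rec = EnergyRecord(**rec_kwargs)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        rs.add(rec)
    return rs


def relative_energies(
    records: RecordSet, reference: str, **criteria
) -> pd.Series:
    """Per-structure energies relative to ``reference``, in kJ/mol.

    ``criteria`` select one slice (method, basis, spin state, ...); every
    structure present in ``records`` must have exactly one record in that
    slice, and the reference maps to exactly 0.
    """
    sub = records.subset(**criteria)
    all_structures = records.structures
    missing = [s for s in all_structures if s not in sub.structures]
    if missing:
        raise MissingDataError(
            f"structures {missing} have no record in slice {criteria}"
        )
    if reference not in sub.structures:
        raise MissingDataError(f"reference structure {reference!r} not in slice")
    e_ref = sub.energy(reference)
    out = {
        s: (sub.energy(s) - e_ref) * HARTREE_TO_KJMOL for s in all_structures
    }
    out[reference] = 0.0
    return pd.Series(out, name="dE_kJmol")


def relative_to_reference(values: Mapping[str, float], reference: str) -> pd.Series:
    """Shift a per-structure table so the reference entry is exactly zero."""
    s = pd.Series(dict(values), dtype=float)
    if reference not in s.index:
        raise MissingDataError(f"reference structure {reference!r} not present")
    out = s - s[reference]
    out[reference] = 0.0
    return out


def deviations_from_average(values: Mapping[str, float]) -> tuple[pd.Series, float]:
    """Per-structure deviations from the cross-structure mean.

    Returns ``(deviations, average)``; deviations sum to zero to machine
    precision and are invariant under a uniform shift of the inputs.
    """
    s = pd.Series(dict(values), dtype=float)
    if len(s) == 0:
        raise ValueError("deviations_from_average requires at least one value")
    avg = float(s.mean())
    return s - avg, avg


__all__ = [
    "EnergyRecord",
    "RecordSet",
    "DuplicateKeyError",
    "MissingDataError",
    "load_records",
    "relative_energies",
    "relative_to_reference",
    "deviations_from_average",
    "basis_cardinal",
    "convert_units",
]
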