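"""Synthetic study bundles with known ground truth.

Each generator is the exact inverse of one analysis operation in the
noiseless limit: basis ladders follow the power law the CBS formula
inverts, BS/HS pairs are built from a known exchange coupling, DMRG
series are linear in the discarded weight, and a full study bundle
carries a machine-readable answer key (true composite totals, ranking,
DFT deviation stats) for end-to-end recovery tests.

No electronic-structure physics is simulated — only the functional forms
the analysis formulas assume.  Optional zero-mean Gaussian noise (off by
default; real calculations are deterministic) exists purely to exercise
estimator robustness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .basis_extrapolation import BasisSeries
from .constants import DEFAULT_CBS_BETA, KJMOL_PER_INVCM, convert_units
from .dmrg_extrapolation import DMRGSeries
from .energy_store import EnergyRecord, RecordSet
from .spin_projection import SpinPair

_CARDINAL_TO_BASIS = {2: "cc-pVDZ-DK", 3: "cc-pVTZ-DK", 4: "cc-pVQZ-DK"}


def gen_basis_ladder(
    e_inf: float,
    amplitude: float,
    beta: float,
    cardinals: Sequence[int],
    structure: str = "X",
    method: str = "CCSD",
    component: str = "correlation",
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BasisSeries:
    """Power-law ladder E_X = e_inf + amplitude·X^(−beta), optional noise."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    cards = sorted(int(c) for c in cardinals)
    if len(set(cards)) != len(cards) or (cards and cards[0] < 2):
        raise ValueError(f"cardinals must be distinct integers >= 2, got {cards}")
    pts = []
    for x in cards:
        e = e_inf + amplitude * x ** (-beta)
        if noise > 0.0:
            if rng is None:
                raise ValueError("noise > 0 requires an rng")
            e += rng.normal(0.0, noise)
        pts.append((x, e))
    return BasisSeries(
        structure=structure, method=method, component=component,
        points=tuple(pts),
    )


def gen_spin_pair(
    j_cm: float,
    s2_bs: float,
    s2_hs: float,
    e_hs_base: float = 0.0,
    structure: str = "X",
    unit: str = "kJ/mol",
    s2_ps: float = 0.0,
) -> SpinPair:
    """BS/HS pair with E_BS − E_HS = J·(⟨S²⟩_HS − ⟨S²⟩_BS) exactly."""
    if not s2_hs > s2_bs:
        raise ValueError(f"need S2_HS > S2_BS, got {s2_hs}, {s2_bs}")
    gap = convert_units(j_cm * (s2_hs - s2_bs), "cm-1", unit)
    return SpinPair(
        structure=structure,
        e_bs=e_hs_base + gap,
        e_hs=e_hs_base,
        s2_bs=s2_bs,
        s2_hs=s2_hs,
        s2_ps=s2_ps,
        unit=unit,
    )


def gen_dmrg_series(
    e_true: float,
    slope: float,
    weights: Sequence[float],
    structure: str = "X",
    active_space: str = "63o,64e",
    bond_dims: Sequence[int] | None = None,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DMRGSeries:
    """Series E_i = e_true + slope·w_i (+ noise); weights descending > 0.

    Bond dimensions, if not supplied, are assigned so the largest M pairs
    with the smallest discarded weight, as in a reverse schedule.
    """
    w = [float(x) for x in weights]
    if any(x <= 0 for x in w):
        raise ValueError("discarded weights must be positive")
    if any(w[i + 1] >= w[i] for i in range(len(w) - 1)):
        raise ValueError("weights must be strictly descending")
    if slope < 0:
        raise ValueError("slope must be >= 0 (variational convergence)")
    if bond_dims is None:
        bond_dims = [500 * (i + 1) for i in range(len(w))]
    pts = []
    for m, wi in zip(bond_dims, w):
        e = e_true + slope * wi
        if noise > 0.0:
            if rng is None:
                raise ValueError("noise > 0 requires an rng")
            e += rng.normal(0.0, noise)
        pts.append((m, wi, e))
    return DMRGSeries(
        structure=structure, active_space=active_space, points=tuple(pts)
    )


def gen_occupancies(
    n_orbitals: int,
    n_fractional: int,
    n_singly: int = 2,
    structure: str = "X",
    rng: np.random.Generator | None = None,
) -> tuple[float, ...]:
    """Occupancy vector planting ``n_fractional`` band members (0.2–0.8 / 1.2–1.8).

    Remaining orbitals sit near 0 or 2 (outside the band) with ``n_singly``
    exactly singly occupied, mimicking antiferromagnetically coupled metal
    orbitals which the census must not count.
    """
    if n_fractional + n_singly > n_orbitals:
        raise ValueError("more planted orbitals than available")
    rng = rng or np.random.default_rng(0)
    occ: list[float] = []
    for i in range(n_fractional):
        lo = float(rng.uniform(0.25, 0.75))
        occ.append(lo if i % 2 == 0 else 2.0 - lo)
    occ.extend([1.0] * n_singly)
    n_rest = n_orbitals - len(occ)
    n_full = n_rest // 2
    occ.extend(float(rng.uniform(1.92, 2.0)) for _ in range(n_full))
    occ.extend(float(rng.uniform(0.0, 0.08)) for _ in range(n_rest - n_full))
    return tuple(occ)


@dataclass(frozen=True)
class StructureTruth:
    """Ground truth for one structure's energy components (kJ/mol scales)."""

    mean_field: dict[int, float]  # cardinal -> value; QZ is the CBS value
    ccsd_corr: tuple[float, float]  # (e_inf, amplitude)
    triples: tuple[float, float]  # (e_inf, amplitude)
    mp2_corr: tuple[float, float]  # (e_inf, amplitude)
    mr_offset: float  # planted E_DMRG-act - E_CCSD(T)-act, kJ/mol
    spin: tuple[float, float, float] = (-150.0, 3.9, 20.0)  # (J cm^-1, S2_BS, S2_HS)
    dmrg_limit: float = -10.0  # hartree
    dmrg_slope: float = 500.0  # hartree per unit discarded weight


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full specification of a synthetic study with known answers.

    The first structure is the reference.  Defaults mirror the observed
    scale of the real system: multireference corrections of a few to
    ~20 kJ/mol, basis corrections up to ~26 kJ/mol, antiferromagnetic
    couplings of order −100..−400 cm^-1.
    """

    structures: tuple[str, ...]
    truth: Mapping[str, StructureTruth]
    dft_errors: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    beta: float = DEFAULT_CBS_BETA
    dmrg_weights: tuple[float, ...] = (1e-5, 5e-6, 2e-6)
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.noise < 0:
            raise ValueError("noise scale must be >= 0")
        if set(self.structures) != set(self.truth):
            raise ValueError("structure list and truth table mismatch")
        for functional, errs in self.dft_errors.items():
            if set(errs) != set(self.structures) - {self.structures[0]}:
                raise ValueError(
                    f"dft_errors[{functional!r}] must cover the non-reference "
                    "structures exactly"
                )

    @property
    def reference(self) -> str:
        return self.structures[0]


@dataclass
class StudyBundle:
    """Everything a pipeline run consumes, plus the ground-truth answer key."""

    spec: SyntheticStudySpec
    records: RecordSet  # basis ladders in the record dialect
    dmrg_series: dict[str, DMRGSeries]
    ccsdt_act: dict[str, float]  # kJ/mol, same scale as extrapolated DMRG
    spin_pairs: dict[str, SpinPair]
    dft_relative: pd.DataFrame  # functional x structure, kJ/mol
    answer_key: dict

    def write(self, outdir: str | Path) -> None:
        """Emit delimited tables + answer_key.json consumable by the CLI."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", unit="kJ/mol")
        rows = [
            {
                "structure": s.structure,
                "active_space": s.active_space,
                "bond_dimension": m,
                "discarded_weight": w,
                "energy_hartree": e,
            }
            for s in self.dmrg_series.values()
            for m, w, e in s.points
        ]
        pd.DataFrame(rows).to_csv(out / "dmrg_series.csv", index=False)
        pd.DataFrame(
            [
                {"structure": k, "energy_kJmol": v}
                for k, v in self.ccsdt_act.items()
            ]
        ).to_csv(out / "ccsdt_active_space.csv", index=False)
        pd.DataFrame(
            [
                {
                    "structure": p.structure,
                    "E_BS": p.e_bs,
                    "E_HS": p.e_hs,
                    "S2_BS": p.s2_bs,
                    "S2_HS": p.s2_hs,
                    "S2_PS": p.s2_ps,
                    "unit": p.unit,
                }
                for p in self.spin_pairs.values()
            ]
        ).to_csv(out / "spin_pairs.csv", index=False)
        self.dft_relative.rename_axis("functional").to_csv(out / "dft_relative.csv")
        (out / "answer_key.json").write_text(
            json.dumps(self.answer_key, indent=2, sort_keys=True)
        )


def _ladder_records(
    rs: RecordSet,
    structure: str,
    method: str,
    component: str,
    values: Mapping[int, float],
) -> None:
    for card, value in values.items():
        rs.add(
            EnergyRecord(
                structure=structure,
                method=method,
                component=component,
                basis=_CARDINAL_TO_BASIS[card],
                energy=convert_units(value, "kJ/mol", "hartree"),
            )
        )


def gen_study(spec: SyntheticStudySpec) -> StudyBundle:
    """Build the full bundle and its analytic answer key.

    In the noiseless default every pipeline stage recovers the key
    exactly: the CBS formula inverts the power-law ladders, the DMRG fit
    inverts the linear series, and the composite totals follow in closed
    form from the planted components.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference
    beta = spec.beta
    rs = RecordSet()
    dmrg_series: dict[str, DMRGSeries] = {}
    ccsdt_act: dict[str, float] = {}
    spin_pairs: dict[str, SpinPair] = {}

    def noisy(value: float) -> float:
        return value + (rng.normal(0.0, spec.noise) if spec.noise > 0 else 0.0)

    pow_ = lambda x: x ** (-beta)
    tz_total: dict[str, float] = {}
    cbs_total: dict[str, float] = {}
    for s in spec.structures:
        t = spec.truth[s]
        _ladder_records(rs, s, "mean-field", "total",
                        {c: noisy(v) for c, v in t.mean_field.items()})
        for method, component, (e_inf, amp) in (
            ("CCSD", "correlation", t.ccsd_corr),
            ("CCSD(T)", "triples-correction", t.triples),
            ("MP2", "correlation", t.mp2_corr),
        ):
            _ladder_records(
                rs, s, method, component,
                {c: noisy(e_inf + amp * pow_(c)) for c in (2, 3, 4)},
            )
        tz_total[s] = (
            t.mean_field[3]
            + t.ccsd_corr[0] + t.ccsd_corr[1] * pow_(3)
            + t.triples[0] + t.triples[1] * pow_(3)
        )
        cbs_total[s] = t.mean_field[4] + t.ccsd_corr[0] + t.triples[0]
        dmrg_series[s] = gen_dmrg_series(
            t.dmrg_limit, t.dmrg_slope, spec.dmrg_weights, structure=s,
            noise=spec.noise and spec.noise * 1e-6, rng=rng,
        )
        ccsdt_act[s] = (
            convert_units(t.dmrg_limit, "hartree", "kJ/mol") - t.mr_offset
        )
        j_cm, s2_bs, s2_hs = t.spin
        spin_pairs[s] = gen_spin_pair(
            j_cm, s2_bs, s2_hs, e_hs_base=0.0, structure=s
        )

    # Analytic answers, straight from the planted truth.
    tz_rel = {s: tz_total[s] - tz_total[ref] for s in spec.structures}
    basis_corr = {
        s: (cbs_total[s] - cbs_total[ref]) - tz_rel[s] for s in spec.structures
    }
    mr_rel = {
        s: spec.truth[s].mr_offset - spec.truth[ref].mr_offset
        for s in spec.structures
    }
    totals = {s: tz_rel[s] + mr_rel[s] + basis_corr[s] for s in spec.structures}
    ranking = sorted(spec.structures, key=lambda s: totals[s])

    dft_rows = {}
    dft_stats = {}
    for functional, errs in spec.dft_errors.items():
        row = {ref: 0.0}
        row.update({s: totals[s] + errs[s] for s in errs})
        dft_rows[functional] = row
        abs_errs = [abs(e) for e in errs.values()]
        dft_stats[functional] = {
            "mean_abs": sum(abs_errs) / len(abs_errs),
            "max_abs": max(abs_errs),
        }
    dft_relative = pd.DataFrame(dft_rows).T.reindex(columns=list(spec.structures))

    answer_key = {
        "reference": ref,
        "uncorrected_tz": tz_rel,
        "mr_correction": mr_rel,
        "basis_correction": basis_corr,
        "total": totals,
        "ranking": ranking,
        "exchange_coupling_cm1": {
            s: spec.truth[s].spin[0] for s in spec.structures
        },
        "dmrg_limit_hartree": {
            s: spec.truth[s].dmrg_limit for s in spec.structures
        },
        "dft_stats": dft_stats,
    }
    return StudyBundle(
        spec=spec,
        records=rs,
        dmrg_series=dmrg_series,
        ccsdt_act=ccsdt_act,
        spin_pairs=spin_pairs,
        dft_relative=dft_relative,
        answer_key=answer_key,
    )


def default_study_spec(seed: int = 0, noise: float = 0.0) -> SyntheticStudySpec:
    """A four-structure spec mimicking the magnitudes of the real study."""
    structures = ("A", "B", "C", "D")
    base_mf = {
        "A": {2: -230.7, 3: -221.5, 4: -220.9},
        "B": {2: 113.1, 3: 120.7, 4: 121.1},
        "C": {2: 291.9, 3: 283.2, 4: 283.2},
        "D": {2: 365.7, 3: 356.1, 4: 355.6},
    }
    ccsd = {"A": (35.8, 181.0), "B": (125.1, 131.0), "C": (225.8, -99.0),
            "D": (153.3, -139.0)}
    trip = {"A": (34.7, -1.0), "B": (23.0, 10.6), "C": (-17.4, -17.4),
            "D": (-40.3, 7.9)}
    mp2 = {"A": (-9.5, 198.0), "B": (-63.3, 184.0), "C": (77.0, -214.0),
           "D": (-4.1, -168.0)}
    mr = {"A": -8.8, "B": -14.1, "C": -20.3, "D": -28.0}
    spins = {"A": (-94.0, 3.89, 20.01), "B": (-198.2, 3.78, 20.01),
             "C": (-342.0, 4.57, 20.32), "D": (-388.5, 4.15, 20.08)}
    truth = {
        s: StructureTruth(
            mean_field=base_mf[s],
            ccsd_corr=ccsd[s],
            triples=trip[s],
            mp2_corr=mp2[s],
            mr_offset=mr[s],
            spin=spins[s],
            dmrg_limit=-10.0 - 0.01 * i,
            dmrg_slope=400.0 + 50.0 * i,
        )
        for i, s in enumerate(structures)
    }
    dft_errors = {
        "good": {"B": -13.4, "C": -6.8, "D": 9.2},
        "poor": {"B": -42.4, "C": -85.0, "D": -112.1},
    }
    return SyntheticStudySpec(
        structures=structures, truth=truth, dft_errors=dft_errors,
        noise=noise, seed=seed,
    )


__all__ = [
    "gen_basis_ladder",
    "gen_spin_pair",
    "gen_dmrg_series",
    "gen_occupancies",
    "StructureTruth",
    "SyntheticStudySpec",
    "StudyBundle",
    "gen_study",
    "default_study_spec",
]
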