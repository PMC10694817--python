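"""Unit handling, record ingestion and relative-energy utilities."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fedimer.constants import UnitError, convert_units
from fedimer.energy_store import (
    DuplicateKeyError,
    EnergyRecord,
    MissingDataError,
    RecordSet,
    deviations_from_average,
    load_records,
    relative_energies,
)

UNITS = ["hartree", "kJ/mol", "cm-1"]


class TestConvertUnits:
    @pytest.mark.parametrize(
        "value,frm,to,expected,tol",
        [
            (1.0, "hartree", "kJ/mol", 2625.4996, 1e-4),
            (1.0, "hartree", "cm-1", 219474.6314, 1e-4),
            (-365.66, "cm-1", "kJ/mol", -4.374, 5e-4),
            (0.0, "cm-1", "hartree", 0.0, 0.0),
        ],
    )
    def test_known_conversions(self, value, frm, to, expected, tol):
        assert convert_units(value, frm, to) == pytest.approx(expected, abs=tol)

    def test_unknown_unit_raises(self):
        with pytest.raises(UnitError):
            convert_units(1.0, "eV", "hartree")

    @given(
        value=st.floats(-1e6, 1e6, allow_nan=False),
        frm=st.sampled_from(UNITS),
        to=st.sampled_from(UNITS),
    )
    def test_round_trip_identity(self, value, frm, to):
        back = convert_units(convert_units(value, frm, to), to, frm)
        assert back == pytest.approx(value, rel=1e-12, abs=1e-15)


class TestRecords:
    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError, match="method"):
            EnergyRecord(structure="HC", method="CASPT2", energy=0.0)

    def test_triples_component_requires_ccsdt(self):
        with pytest.raises(ValueError, match="triples"):
            EnergyRecord(
                structure="HC", method="CCSD", energy=0.0,
                component="triples-correction",
            )

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            EnergyRecord(structure="HC", method="CCSD", energy=float("nan"))

    def test_duplicate_key_named_in_error(self):
        rs = RecordSet()
        rec = EnergyRecord(structure="HC", method="CCSD", energy=-1.0)
        rs.add(rec)
        with pytest.raises(DuplicateKeyError, match="HC"):
            rs.add(EnergyRecord(structure="HC", method="CCSD", energy=-2.0))


QZ_CSV = """structure,method,component,basis,energy,unit
HC,mean-field,total,cc-pVQZ-DK,-220.9,kJ/mol
HS,mean-field,total,cc-pVQZ-DK,-17.9,kJ/mol
HFe,mean-field,total,cc-pVQZ-DK,83.2,kJ/mol
HFe2,mean-field,total,cc-pVQZ-DK,155.6,kJ/mol
"""


class TestLoadRecords:
    def test_four_row_table(self):
        rs = load_records(io.StringIO(QZ_CSV))
        assert len(rs) == 4
        assert rs.energy("HFe", unit="kJ/mol", method="mean-field") == pytest.approx(83.2)

    def test_empty_table_with_header(self):
        rs = load_records(io.StringIO("structure,method,energy\n"))
        assert len(rs) == 0

    def test_duplicate_row_raises(self):
        csv = QZ_CSV + "HC,mean-field,total,cc-pVQZ-DK,0.0,kJ/mol\n"
        with pytest.raises(DuplicateKeyError, match="HC"):
            load_records(io.StringIO(csv))

    def test_unknown_enum_reports_row(self):
        csv = "structure,method,energy\nHC,XYZ,0.0\n"
        with pytest.raises(ValueError, match="row 1"):
            load_records(io.StringIO(csv))


UHF_DZ = {"HC": 0.0, "HS": 203.8, "HFe": 322.5, "HFe2": 396.3}


class TestRelativeEnergies:
    @pytest.fixture()
    def uhf_records(self):
        return RecordSet.from_records(
            EnergyRecord(
                structure=s, method="mean-field", basis="cc-pVDZ-DK",
                energy=convert_units(e, "kJ/mol", "hartree"),
            )
            for s, e in UHF_DZ.items()
        )

    def test_published_uhf_row(self, uhf_records):
        rel = relative_energies(uhf_records, "HC", method="mean-field")
        for s, e in UHF_DZ.items():
            assert rel[s] == pytest.approx(e, abs=1e-9)
        assert rel["HC"] == 0.0

    def test_antisymmetric_under_reference_swap(self, uhf_records):
        rel_hc = relative_energies(uhf_records, "HC", method="mean-field")
        rel_hs = relative_energies(uhf_records, "HS", method="mean-field")
        assert rel_hc["HS"] == pytest.approx(-rel_hs["HC"], abs=1e-9)

    def test_missing_structure_listed(self, uhf_records):
        uhf_records.add(
            EnergyRecord(structure="HX", method="CCSD", energy=0.0)
        )
        with pytest.raises(MissingDataError, match="HX"):
            relative_energies(uhf_records, "HC", method="mean-field")


class TestDeviationsFromAverage:
    def test_hand_example(self):
        dev, avg = deviations_from_average({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert avg == pytest.approx(2.5)
        assert list(dev) == pytest.approx([-1.5, -0.5, 0.5, 1.5])

    def test_constant_input_is_all_zero(self):
        dev, avg = deviations_from_average({s: 7.0 for s in "abcd"})
        assert all(d == 0.0 for d in dev)
        assert avg == 7.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            deviations_from_average({})

    @given(
        values=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=8),
        shift=st.floats(-1e3, 1e3),
    )
    def test_sum_zero_and_translation_invariance(self, values, shift):
        labelled = {str(i): v for i, v in enumerate(values)}
        dev, _ = deviations_from_average(labelled)
        assert abs(dev.sum()) < 1e-9
        dev2, _ = deviations_from_average(
            {k: v + shift for k, v in labelled.items()}
        )
        assert dev2.values == pytest.approx(dev.values, abs=1e-9)

    def test_round_trip_with_published_deviations(self, basis_records):
        # reconstruct absolute-like values as average + deviation, re-derive
        devs = {
            s: basis_records.energy(
                s, unit="kJ/mol", method="mean-field", basis="cc-pVQZ-DK"
            )
            for s in basis_records.structures
        }
        rebuilt = {s: -4734.0044 * 2625.4996395 + d for s, d in devs.items()}
        dev2, _ = deviations_from_average(rebuilt)
        for s in devs:
            assert dev2[s] == pytest.approx(devs[s], abs=1e-6)
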