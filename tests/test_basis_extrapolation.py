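"""CBS extrapolation: exact recovery, published ladders, uncertainty."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fedimer import datasets
from fedimer.basis_extrapolation import (
    BasisSeries,
    basis_set_correction,
    cbs_two_point,
    cbs_uncertainty_mp2,
    mean_field_cbs,
)
from fedimer.energy_store import EnergyRecord, MissingDataError, RecordSet
from fedimer.synthetic import gen_basis_ladder

# Recomputation from one-decimal printed inputs: the DZ/TZ weights
# (1.61/-0.61) amplify input rounding by up to ~2.2x, hence 0.2 kJ/mol.
PRINTED_TOL = 0.2


class TestCbsTwoPoint:
    def test_converged_series_is_identity(self):
        res = cbs_two_point(3.7, 3.7, 2, 3)
        assert res.e_inf == pytest.approx(3.7, abs=1e-12)

    def test_equal_cardinals_rejected(self):
        with pytest.raises(ValueError):
            cbs_two_point(1.0, 2.0, 3, 3)

    @given(
        e_inf=st.floats(-100.0, 100.0),
        amp=st.floats(-50.0, 50.0),
        beta=st.floats(0.5, 5.0),
        pair=st.sampled_from([(2, 3), (3, 4), (2, 4)]),
    )
    def test_exact_power_law_recovery(self, e_inf, amp, beta, pair):
        x, y = pair
        e_x = e_inf + amp * x ** (-beta)
        e_y = e_inf + amp * y ** (-beta)
        res = cbs_two_point(e_x, e_y, x, y, beta)
        assert res.e_inf == pytest.approx(e_inf, rel=1e-10, abs=1e-9)

    def test_linearity_in_the_inputs(self):
        a = cbs_two_point(1.0, 2.0, 2, 3).e_inf
        b = cbs_two_point(5.0, -1.0, 2, 3).e_inf
        ab = cbs_two_point(6.0, 1.0, 2, 3).e_inf
        assert ab == pytest.approx(a + b, abs=1e-12)

    def test_weights_sign_and_magnitude(self):
        # E_inf = w_y*E_y + w_x*E_x with w_y > 1, w_x < 0, w_x + w_y = 1
        w_y = cbs_two_point(0.0, 1.0, 2, 3).e_inf
        w_x = cbs_two_point(1.0, 0.0, 2, 3).e_inf
        assert w_y > 1.0
        assert w_x < 0.0
        assert w_x + w_y == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "method,expected",
        [
            ("MP2", {"HC": -17.9, "HS": -67.4, "HFe": 84.3, "HFe2": 0.9}),
            ("CCSD", {"HC": 35.8, "HS": -14.9, "HFe": 25.8, "HFe2": -46.7}),
            ("(T)", {"HC": 34.7, "HS": 23.0, "HFe": -17.4, "HFe2": -40.3}),
        ],
    )
    def test_published_dz_tz_cbs_rows(self, method, expected):
        """Re-extrapolating the printed DZ/TZ ladders matches the printed CBS rows."""
        table = datasets.basis_series_table()
        dz = table.loc[(method, "cc-pVDZ-DK")]
        tz = table.loc[(method, "cc-pVTZ-DK")]
        for s, value in expected.items():
            res = cbs_two_point(dz[s], tz[s], 2, 3)
            assert res.e_inf == pytest.approx(value, abs=PRINTED_TOL), s


class TestMeanFieldCbs:
    def test_takes_largest_cardinal(self):
        series = BasisSeries("HFe", "mean-field", "total",
                             ((2, 91.9), (3, 83.2), (4, 83.2)))
        assert mean_field_cbs(series) == 83.2

    def test_single_point_identity(self):
        series = BasisSeries("X", "mean-field", "total", ((4, -1.5),))
        assert mean_field_cbs(series) == -1.5

    def test_unordered_ladder_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            BasisSeries("X", "mean-field", "total", ((3, 0.0), (2, 1.0)))


class TestBasisSetCorrection:
    def test_published_corrections(self, basis_records):
        corr = basis_set_correction(basis_records, "HC")
        printed = {"HC": 0.0, "HS": 2.1, "HFe": 25.9, "HFe2": 21.2}
        for s, value in printed.items():
            assert corr[s] == pytest.approx(value, abs=PRINTED_TOL), s

    def test_basis_converged_input_gives_zero(self):
        rs = RecordSet()
        for s, offset in (("A", 0.0), ("B", 5.0)):
            for card, basis in ((2, "cc-pVDZ-DK"), (3, "cc-pVTZ-DK"), (4, "cc-pVQZ-DK")):
                rs.add(EnergyRecord(structure=s, method="mean-field",
                                    component="total", basis=basis, energy=offset))
            for card, basis in ((2, "cc-pVDZ-DK"), (3, "cc-pVTZ-DK")):
                rs.add(EnergyRecord(structure=s, method="CCSD",
                                    component="correlation", basis=basis,
                                    energy=-1.0))
                rs.add(EnergyRecord(structure=s, method="CCSD(T)",
                                    component="triples-correction", basis=basis,
                                    energy=-0.1))
        corr = basis_set_correction(rs, "A")
        assert corr["B"] == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_study_recovers_analytic_correction(self, study_bundle):
        corr = basis_set_correction(study_bundle.records, "A")
        for s, value in study_bundle.answer_key["basis_correction"].items():
            assert corr[s] == pytest.approx(value, abs=1e-8), s

    def test_missing_component_reported(self, study_bundle):
        rs = RecordSet.from_records(
            r for r in study_bundle.records if r.method != "CCSD"
        )
        with pytest.raises(MissingDataError, match="CCSD"):
            basis_set_correction(rs, "A")

    def test_invariant_under_component_shift(self, study_bundle):
        base = basis_set_correction(study_bundle.records, "A")
        shifted = RecordSet.from_records(
            EnergyRecord(
                structure=r.structure, method=r.method, basis=r.basis,
                spin_state=r.spin_state, component=r.component,
                relativistic=r.relativistic, qualifier=r.qualifier,
                energy=r.energy + (0.01 if r.method == "CCSD" else 0.0),
            )
            for r in study_bundle.records
        )
        out = basis_set_correction(shifted, "A")
        for s in base.index:
            assert out[s] == pytest.approx(base[s], abs=1e-8)


class TestCbsUncertaintyMp2:
    def test_published_mp2_ladders_give_eight(self, basis_records):
        res = cbs_uncertainty_mp2(basis_records)
        assert res.pair == ("HC", "HFe")
        assert res.delta_kjmol == pytest.approx(7.88, abs=PRINTED_TOL)
        assert res.rounded == 8

    def test_explicit_pair(self, basis_records):
        res = cbs_uncertainty_mp2(basis_records, structure_pair=("HC", "HFe2"))
        assert res.pair == ("HC", "HFe2")
        assert 0.0 <= res.delta_kjmol < 7.88

    def test_exact_power_law_gives_zero(self):
        rs = RecordSet()
        for s, (e_inf, amp) in (("A", (-10.0, 7.0)), ("B", (4.0, -3.0))):
            for card, basis in ((2, "cc-pVDZ-DK"), (3, "cc-pVTZ-DK"), (4, "cc-pVQZ-DK")):
                rs.add(EnergyRecord(structure=s, method="MP2",
                                    component="correlation", basis=basis,
                                    energy=e_inf + amp * card ** -2.4))
        res = cbs_uncertainty_mp2(rs)
        assert res.delta_kjmol == pytest.approx(0.0, abs=1e-6)

    def test_missing_basis_rejected(self, basis_records):
        rs = RecordSet.from_records(
            r for r in basis_records if not (r.method == "MP2" and r.cardinal == 4)
        )
        with pytest.raises(MissingDataError, match="MP2"):
            cbs_uncertainty_mp2(rs)


def test_gen_basis_ladder_inverts_exactly():
    series = gen_basis_ladder(-10.0, 7.0, 2.4, (2, 3))
    (x, e_x), (y, e_y) = series.points
    assert cbs_two_point(e_x, e_y, x, y, 2.4).e_inf == pytest.approx(-10.0, abs=1e-12)
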