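import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcbrisk import (
    BasisConversion,
    MeasurementRecord,
    homolog_of,
    homolog_profile,
    sum_indicator,
    summarize,
    to_lipid_basis,
    to_wet_basis,
)
from pcbrisk.concentrations import ConfigurationError, DomainError
from pcbrisk.records import ValidationError
from pcbrisk.refdata import RESIDUE_SUMMARY_LW, SPECIES, SUM_IPCB_LW, TISSUES


def _rec(conc, tissue="muscle", lf=None, basis="wet_weight", congener=153):
    return MeasurementRecord(
        "b1", "tufted_duck", tissue, congener, conc, basis, lf
    )


class TestBasisConversion:
    def test_default_integer_factors(self):
        conv = BasisConversion()
        assert conv.factor("muscle") == 67
        assert conv.factor("liver") == 20
        assert conv.factor("fat") == 3

    def test_exact_factors(self):
        conv = BasisConversion(integer_factors=False)
        assert conv.factor("muscle") == pytest.approx(1 / 0.015)
        assert conv.factor("liver") == pytest.approx(20.0)

    def test_muscle_default_factor_applied(self):
        out = to_lipid_basis(_rec(1.0))
        assert out.concentration == 67.0
        assert out.basis == "lipid_weight"

    def test_measured_lipid_fraction_wins(self):
        out = to_lipid_basis(_rec(10.0, tissue="liver", lf=0.05))
        assert out.concentration == pytest.approx(200.0)

    def test_unit_lipid_fraction_is_identity(self):
        out = to_lipid_basis(_rec(3.7, lf=1.0))
        assert out.concentration == 3.7
        assert out.basis == "lipid_weight"

    def test_wrong_basis_rejected(self):
        with pytest.raises(ValidationError):
            to_lipid_basis(_rec(1.0, basis="lipid_weight"))
        with pytest.raises(ValidationError):
            to_wet_basis(_rec(1.0, basis="wet_weight"))

    def test_unknown_tissue_without_fraction(self):
        conv = BasisConversion(default_lipid_fraction={"muscle": 0.015})
        with pytest.raises(ConfigurationError, match="liver"):
            to_lipid_basis(_rec(1.0, tissue="liver"), conv)

    def test_bad_default_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            BasisConversion(default_lipid_fraction={"muscle": 0.0})

    @given(
        conc=st.floats(1e-6, 1e6),
        lf=st.floats(1e-3, 1.0),
    )
    def test_round_trip_with_measured_fraction(self, conc, lf):
        rec = _rec(conc, lf=lf)
        back = to_wet_basis(to_lipid_basis(rec))
        assert back.concentration == pytest.approx(conc, rel=1e-12)
        assert back.basis == "wet_weight"

    @given(conc=st.floats(1e-6, 1e6))
    def test_round_trip_with_exact_default_factors(self, conc):
        conv = BasisConversion(integer_factors=False)
        back = to_wet_basis(to_lipid_basis(_rec(conc), conv), conv)
        assert back.concentration == pytest.approx(conc, rel=1e-12)


GOLDENEYE_MUSCLE = {28: 9.11, 52: 2.09, 101: 3.18, 153: 398.04, 138: 245.01, 180: 296.44}
POCHARD_MUSCLE = {28: 6.52, 52: 3.46, 101: 4.37, 153: 243.01, 138: 141.61, 180: 164.42}


class TestSumIndicator:
    @pytest.mark.parametrize(
        "concs,expected",
        [(GOLDENEYE_MUSCLE, 953.87), (POCHARD_MUSCLE, 563.39)],
    )
    def test_published_mean_sums(self, concs, expected):
        assert sum_indicator(concs) == pytest.approx(expected, abs=1e-9)

    def test_pcb118_excluded(self):
        concs = {**GOLDENEYE_MUSCLE, 118: 119.73}
        assert sum_indicator(concs) == pytest.approx(953.87, abs=1e-9)

    def test_all_zero(self):
        assert sum_indicator({c: 0.0 for c in (28, 52, 101, 138, 153, 180)}) == 0

    def test_missing_congener_listed(self):
        with pytest.raises(ValidationError, match=r"\[52, 180\]"):
            sum_indicator({28: 1, 101: 1, 138: 1, 153: 1})

    def test_allow_missing(self):
        assert sum_indicator({153: 5.0}, allow_missing=True) == 5.0

    @given(
        st.dictionaries(
            st.sampled_from([28, 52, 101, 138, 153, 180]),
            st.floats(0, 1e3),
            max_size=6,
        ),
        st.dictionaries(
            st.sampled_from([28, 52, 101, 138, 153, 180]),
            st.floats(0, 1e3),
            max_size=6,
        ),
    )
    def test_additive_over_disjoint_maps(self, a, b):
        b = {k: v for k, v in b.items() if k not in a}
        merged = {**a, **b}
        assert sum_indicator(merged, allow_missing=True) == pytest.approx(
            sum_indicator(a, allow_missing=True)
            + sum_indicator(b, allow_missing=True)
        )

    def test_every_published_row_sums_to_printed_total(self):
        # printed congener means must re-add to the printed indicator sum
        # within rounding slack
        for species in SPECIES:
            for tissue in TISSUES:
                concs = {
                    c: RESIDUE_SUMMARY_LW[(species, tissue, c)][0]
                    for c in (28, 52, 101, 138, 153, 180)
                }
                printed = SUM_IPCB_LW[(species, tissue)]
                assert sum_indicator(concs) == pytest.approx(
                    printed, abs=0.02 + 1e-9
                ), (species, tissue)


class TestHomologs:
    @pytest.mark.parametrize(
        "congener,chlorines",
        [
            (1, 1), (3, 1), (4, 2), (15, 2), (16, 3), (28, 3), (39, 3),
            (40, 4), (52, 4), (77, 4), (81, 4), (82, 5), (101, 5), (114, 5),
            (118, 5), (126, 5), (127, 5), (128, 6), (138, 6), (153, 6),
            (156, 6), (157, 6), (169, 6), (170, 7), (180, 7), (193, 7),
            (194, 8), (205, 8), (206, 9), (208, 9), (209, 10),
        ],
    )
    def test_chlorine_counts(self, congener, chlorines):
        assert homolog_of(congener) == chlorines

    @pytest.mark.parametrize("bad", [0, 210, -5])
    def test_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            homolog_of(bad)

    def test_singleton_profile(self):
        profile = homolog_profile([_rec(5.0, basis="lipid_weight")])
        assert profile[6] == 5.0
        assert sum(profile.values()) == 5.0

    def test_hand_grouping(self):
        recs = [
            _rec(1.0, congener=28, basis="lipid_weight"),
            _rec(2.0, congener=52, basis="lipid_weight"),
            _rec(3.0, congener=153, basis="lipid_weight"),
            _rec(4.0, congener=138, basis="lipid_weight"),
        ]
        profile = homolog_profile(recs)
        assert profile[3] == 1.0
        assert profile[4] == 2.0
        assert profile[6] == 7.0
        assert profile[5] == 0.0

    def test_empty_input_all_zero(self):
        profile = homolog_profile([])
        assert set(profile) == set(range(1, 11))
        assert all(v == 0.0 for v in profile.values())

    def test_mixed_bases_rejected(self):
        with pytest.raises(ValidationError):
            homolog_profile([_rec(1.0), _rec(1.0, basis="lipid_weight")])

    @given(st.lists(st.tuples(st.integers(1, 209), st.floats(0, 1e3)), max_size=30))
    def test_mass_conservation(self, items):
        recs = [
            _rec(conc, congener=c, basis="lipid_weight") for c, conc in items
        ]
        profile = homolog_profile(recs)
        assert sum(profile.values()) == pytest.approx(
            sum(conc for _, conc in items)
        )


class TestSummarize:
    def test_singleton(self):
        s = summarize([5.0])
        assert (s.n, s.mean, s.min, s.max) == (1, 5.0, 5.0, 5.0)
        assert s.percentiles[50.0] == 5.0
        assert math.isnan(s.sd)

    def test_odd_length_median(self):
        assert summarize([1, 2, 3, 4, 5]).percentiles[50.0] == 3.0

    def test_linear_interpolation(self):
        assert summarize([1, 2, 3, 4]).percentiles[50.0] == 2.5

    def test_mean_and_sample_sd(self):
        s = summarize([2, 4, 4, 4, 5, 5, 7, 9])
        assert s.mean == 5.0
        assert s.sd == pytest.approx(math.sqrt(32 / 7), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            summarize([])

    def test_nan_rejected(self):
        with pytest.raises(DomainError):
            summarize([1.0, math.nan])
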