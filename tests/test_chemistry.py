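"""Formula arithmetic, the monomer registry and mass computation.

pyteomics is used throughout as the independent mass oracle: the
package embeds its own atomic-mass tables, so agreement is a genuine
cross-check, not a tautology.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from macrocode.chemistry import (
    AZIDE_REDUCTION,
    BOC_LOSS,
    ElementalFormula,
    FormulaError,
    MassMode,
    MassValue,
    WATER,
    apply_modification,
    carbamate,
    formula_mass,
    hydroxy_from_amino,
    ion_mz,
    parse_formula,
    residue_mass,
)

formulas = st.builds(
    ElementalFormula,
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "I"]),
        st.integers(min_value=0, max_value=40),
        max_size=6,
    ),
)


class TestParsing:
    @pytest.mark.parametrize(
        "text, counts",
        [
            ("H2O", {"H": 2, "O": 1}),
            ("C6H13NO3", {"C": 6, "H": 13, "N": 1, "O": 3}),
            ("C5H8O2", {"C": 5, "H": 8, "O": 2}),
            ("", {}),
        ],
    )
    def test_examples(self, text, counts):
        assert dict(parse_formula(text).element_counts) == counts

    @pytest.mark.parametrize("text", ["C6H13X3", "c6", "C6H-3", "C6 H13"])
    def test_malformed_or_unknown(self, text):
        with pytest.raises(FormulaError):
            parse_formula(text)

    def test_round_trip_on_registry(self, registry):
        for monomer in registry:
            assert parse_formula(monomer.formula_free.hill_format()) == monomer.formula_free

    @given(f=formulas)
    @settings(derandomize=True)
    def test_round_trip_property(self, f):
        assert parse_formula(f.hill_format()) == f


class TestFormulaArithmetic:
    def test_subtraction_below_zero_is_an_error(self):
        with pytest.raises(FormulaError):
            parse_formula("CH4") - parse_formula("O")

    @given(f1=formulas, f2=formulas, mode=st.sampled_from(list(MassMode)))
    @settings(derandomize=True)
    def test_mass_additivity(self, f1, f2, mode):
        total = formula_mass(f1 + f2, mode)
        assert total.value == pytest.approx(
            formula_mass(f1, mode).value + formula_mass(f2, mode).value, abs=1e-9
        )


class TestMasses:
    def test_boc_group_is_the_100_da_satellite(self):
        assert formula_mass(parse_formula("C5H8O2"), MassMode.NOMINAL).value == 100

    def test_water_monoisotopic(self):
        assert formula_mass(WATER, MassMode.MONOISOTOPIC).value == pytest.approx(
            18.0106, abs=1e-4
        )

    def test_empty_formula_is_massless(self):
        for mode in MassMode:
            assert formula_mass(ElementalFormula({}), mode).value == 0

    def test_monoisotopic_below_average_on_registry(self, registry):
        for monomer in registry:
            mono = formula_mass(monomer.formula_free, MassMode.MONOISOTOPIC).value
            avg = formula_mass(monomer.formula_free, MassMode.AVERAGE).value
            assert mono < avg

    @pytest.mark.parametrize("mode, average", [(MassMode.MONOISOTOPIC, False), (MassMode.AVERAGE, True)])
    def test_agreement_with_pyteomics(self, registry, mode, average):
        for monomer in registry:
            ours = formula_mass(monomer.formula_free, mode).value
            oracle = pt_mass.calculate_mass(
                formula=monomer.formula_free.hill_format(), average=average
            )
            assert ours == pytest.approx(oracle, abs=0.01)

    def test_mixed_mode_arithmetic_forbidden(self):
        a = MassValue(10.0, MassMode.MONOISOTOPIC)
        b = MassValue(10.0, MassMode.AVERAGE)
        with pytest.raises(ValueError):
            a + b

    def test_nominal_mass_values_are_integers(self):
        with pytest.raises(ValueError):
            MassValue(100.5, MassMode.NOMINAL)


class TestIonMz:
    def test_free_scaffold_positive_mode(self):
        scaffold = formula_mass(parse_formula("C6H13NO3"), MassMode.NOMINAL)
        assert ion_mz(scaffold, "M+H", 1) == 148

    def test_alkynk_oh_negative_mode(self, registry):
        neutral = formula_mass(registry.get("AlkynK-OH").formula_free, MassMode.NOMINAL)
        assert ion_mz(neutral, "M-H", 1) == 228

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            ion_mz(MassValue(100.0, MassMode.MONOISOTOPIC), "M+H", 0)

    def test_doubly_charged_positive_ion(self):
        neutral = MassValue(1000.0, MassMode.MONOISOTOPIC)
        assert ion_mz(neutral, "M+H", 2) == pytest.approx((1000.0 + 2 * 1.00727646) / 2)

    def test_monoisotopic_rounds_to_nominal_across_registry(self, registry):
        """Guards against formula-entry errors: the integer readout of a
        low-resolution spectrum must match the exact-mass prediction."""
        for monomer in registry:
            mono = ion_mz(formula_mass(monomer.formula_free, MassMode.MONOISOTOPIC), "M+H", 1)
            nominal = ion_mz(formula_mass(monomer.formula_free, MassMode.NOMINAL), "M+H", 1)
            assert round(mono) == nominal


class TestResidues:
    def test_glycine_residue_matches_standard_table(self, registry):
        assert residue_mass(registry.get("G")).value == pytest.approx(57.02146, abs=1e-4)

    def test_phenyllactic_residue(self, registry):
        m = registry.get("F-OH")
        assert formula_mass(m.formula_free).value == pytest.approx(166.0630, abs=1e-3)
        assert residue_mass(m).value == pytest.approx(148.0524, abs=1e-3)

    def test_residue_is_free_minus_water(self, registry):
        for monomer in registry:
            free = formula_mass(monomer.formula_free).value
            assert residue_mass(monomer).value == pytest.approx(free - 18.0106, abs=1e-4)


class TestModifications:
    def test_boc_loss_is_nominal_minus_100(self, registry):
        bock_oh = registry.get("BocK-OH").formula_free
        before = formula_mass(bock_oh, MassMode.NOMINAL).value
        after = formula_mass(apply_modification(bock_oh, BOC_LOSS), MassMode.NOMINAL).value
        assert before - after == 100

    def test_azide_reduction_shift(self, registry):
        pazf = registry.get("pAzF").formula_free
        before = formula_mass(pazf).value
        after = formula_mass(apply_modification(pazf, AZIDE_REDUCTION)).value
        # -N2 +H2 = -28.00615 + 2.01565
        assert after - before == pytest.approx(-25.99050, abs=1e-4)

    def test_impossible_modification_rejected(self, registry):
        glycine = registry.get("G").formula_free  # one N only
        with pytest.raises(FormulaError):
            apply_modification(glycine, AZIDE_REDUCTION)


class TestSynthesisRoutes:
    """The registry formulas must be reachable from the published
    synthesis chemistry (carbamoylation of the lysine-derived scaffold;
    diazotization of amino acids)."""

    def test_scaffold_from_lysine(self, registry):
        lysine = registry.get("K").formula_free
        assert hydroxy_from_amino(lysine) == parse_formula("C6H13NO3")

    @pytest.mark.parametrize(
        "alcohol, monomer_id",
        [
            ("C3H6O", "7"),   # allyl alcohol -> AllocK-OH
            ("C3H4O", "8"),   # propargyl alcohol -> AlkynK-OH
            ("C4H6O", "9"),   # but-3-yn-1-ol -> ButK-OH
            ("C5H8O", "10"),  # pent-4-yn-1-ol -> PenK-OH
            ("C8H12O", "11"),  # 5-norbornene-2-methanol -> NorK-OH
            ("C7H8O", "12"),  # benzyl alcohol -> CbzK-OH
        ],
    )
    def test_carbamate_route_reaches_registry_formula(self, registry, alcohol, monomer_id):
        scaffold = parse_formula("C6H13NO3")
        built = carbamate(scaffold, parse_formula(alcohol))
        assert built == registry.get(monomer_id).formula_free

    @pytest.mark.parametrize(
        "amino_acid, monomer_id",
        [
            ("C9H10INO2", "15"),  # 4-iodophenylalanine -> pIF-OH
            ("C13H13NO2", "16"),  # 3-(2-naphthyl)alanine -> NapA-OH
            ("C8H16N2O3", "13"),  # N6-acetyl-lysine -> AcK-OH
            ("C9H11NO2", "14"),  # phenylalanine -> F-OH
        ],
    )
    def test_diazotization_route(self, registry, amino_acid, monomer_id):
        built = hydroxy_from_amino(parse_formula(amino_acid))
        assert built == registry.get(monomer_id).formula_free
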