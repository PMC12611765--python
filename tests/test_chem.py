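"""Elemental formulas, masses, adduct m/z, shorthand parsing, KMD."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from epilipid.chem import (
    ADDUCTS,
    ATOMIC_MASS,
    PROTON_MASS,
    ElementalFormula,
    FattyAcyl,
    MalformedChainToken,
    ModificationSet,
    NonPositiveMz,
    UnknownLipidClass,
    adduct_mz,
    format_lipid_name,
    kendrick_mass_defect,
    monoisotopic_mass,
    parse_lipid_name,
    species_formula,
)

F = ElementalFormula.parse


class TestElementalFormula:
    def test_parse_and_str_roundtrip(self):
        for text in ["C59H90O4", "C10H6D6O4", "C42H82NO8P", "H2O"]:
            assert str(F(text)) == text
        # element-order variants parse to the same formula
        assert F("NH4") == F("H4N")

    def test_subtraction_never_negative(self):
        with pytest.raises(ValueError):
            F("CH4") - F("C2")

    def test_mass_additivity_examples(self):
        a, b = F("C10H12O4"), F("C59H90O4")
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9)

    @given(
        st.dictionaries(st.sampled_from(list(ATOMIC_MASS)), st.integers(0, 50), max_size=6),
        st.dictionaries(st.sampled_from(list(ATOMIC_MASS)), st.integers(0, 50), max_size=6),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mass_additivity_property(self, ca, cb):
        a, b = ElementalFormula(ca), ElementalFormula(cb)
        assert math.isclose(
            monoisotopic_mass(a + b), monoisotopic_mass(a) + monoisotopic_mass(b),
            abs_tol=1e-9)

    def test_known_masses(self):
        # sums of tabulated monoisotopic atomic masses
        assert monoisotopic_mass(F("C10H12O4")) == pytest.approx(196.073559, abs=1e-5)
        assert monoisotopic_mass(F("C10H6D6O4")) == pytest.approx(202.111219, abs=1e-5)
        assert monoisotopic_mass(ElementalFormula()) == 0.0


class TestAdductMz:
    @pytest.mark.parametrize("formula, adduct, convention, expected, places", [
        ("C10H12O4", "[M+H]+", "proton", 197.0808, 4),
        ("C10H6D6O4", "[M+H]+", "hydrogen", 203.11904, 5),
        ("C59H90O4", "[M+H]+", "proton", 863.7, 1),
        ("C59H90O4", "[M+NH4]+", "proton", 880.7, 1),
        ("C10H12O2", "[M+H]+", "proton", 165.091, 3),
        ("C12H10O2", "[M+H]+", "proton", 187.0754, 4),
    ])
    def test_printed_transition_mz(self, formula, adduct, convention, expected, places):
        assert round(adduct_mz(F(formula), adduct, convention), places) == expected

    @given(st.dictionaries(st.sampled_from(["C", "H", "O", "N", "P"]),
                           st.integers(1, 60), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_proton_convention_symmetry(self, counts):
        # [M+H]+ minus [M-H]- spans exactly two proton masses
        counts.setdefault("H", 2)
        m = ElementalFormula(counts)
        diff = adduct_mz(m, "[M+H]+") - adduct_mz(m, "[M-H]-")
        assert diff == pytest.approx(2 * PROTON_MASS, abs=1e-9)

    def test_electron_convention_gap(self):
        m = F("C10H12O4")
        gap = adduct_mz(m, "[M+H]+", "hydrogen") - adduct_mz(m, "[M+H]+", "proton")
        assert gap == pytest.approx(0.000548579909, abs=1e-9)


# a corpus covering every supported class, both separators, ether
# subclasses, species- and chain-level modifications
ROUNDTRIP_CORPUS = [
    "TG 18:1/18:1/18:1", "TG 16:0/18:1/18:2", "TG 56:6", "TG 56:6<OOH>",
    "TG 52:2", "TG 54:2", "TG 16:0_18:1_20:4", "TG 58:8<2OH>",
    "TG 50:1<oxo>", "TG 56:6<OH,OOH>", "TG 48:0",
    "DG 36:2", "DG 16:0/18:1", "DG 38:4<OH>",
    "CE 18:2", "CE 20:4", "CE 22:6", "CE 20:4<OOH>", "CE 18:1<OH,oxo>",
    "PC 34:1", "PC 16:0/18:1", "PC 36:4<OOH>", "PC O-34:1", "PC P-36:4",
    "PC O-16:0/18:1", "PC 38:6", "PC 32:0",
    "PE 34:2", "PE 18:0/20:4", "PE O-36:4", "PE P-38:4", "PE 38:4<OH>",
    "LPC 18:0", "LPC 16:0", "LPC 18:1<OH>",
    "LPE 18:1", "LPE 20:4",
    "PS 36:1", "PS 18:0/18:1", "PI 38:4", "PI 18:0/20:4",
    "PG 34:1", "PG 16:0/18:1",
    "SM 34:1", "SM 18:1/16:0", "SM 42:2",
    "Cer 34:1", "Cer 18:1/24:1", "Cer 42:2",
    "FA18:0", "FA18:2<OOH>", "FA20:4", "FA22:6<OH>",
]


class TestParsing:
    @pytest.mark.parametrize("name", ROUNDTRIP_CORPUS)
    def test_roundtrip_identity(self, name):
        assert format_lipid_name(parse_lipid_name(name)) == name

    def test_tg_example(self):
        sp = parse_lipid_name("TG 18:1/18:1/18:1")
        assert sp.lipid_class == "TG"
        assert [(c.carbons, c.double_bonds) for c in sp.chains] == [(18, 1)] * 3

    def test_oxidized_free_fatty_acid(self):
        sp = parse_lipid_name("FA18:2<OOH>")
        assert sp.chains[0].modifications.n_OOH == 1
        assert sp.is_oxidized

    def test_unknown_class_is_error(self):
        with pytest.raises(UnknownLipidClass):
            parse_lipid_name("XX 34:1")

    def test_malformed_chain_is_error(self):
        with pytest.raises(MalformedChainToken):
            parse_lipid_name("TG 18:1/18:x/18:1")

    def test_double_bond_cap(self):
        with pytest.raises(MalformedChainToken):
            FattyAcyl(4, 3)

    def test_named_compound(self):
        sp = parse_lipid_name("CoQ10")
        assert str(species_formula(sp)) == "C59H90O4"


class TestSpeciesFormula:
    @pytest.mark.parametrize("name, expected", [
        ("TG 18:1/18:1/18:1", "C57H104O6"),   # glycerol + 3 oleate - 3 H2O
        ("FA18:0", "C18H36O2"),
        ("FA18:2<OOH>", "C18H32O4"),
        ("PC 16:0/18:1", "C42H82NO8P"),
        ("PC O-16:0/18:1", "C42H84NO7P"),
        ("PC P-34:1", "C42H82NO7P"),
        ("PE 18:0/20:4", "C43H78NO8P"),
        ("SM 18:1/16:0", "C39H79N2O6P"),
        ("Cer 18:1/16:0", "C34H67NO3"),
        ("CoQ10", "C59H90O4"),
    ])
    def test_known_compositions(self, name, expected):
        assert str(species_formula(parse_lipid_name(name))) == expected

    def test_species_level_equals_chain_level(self):
        # sum composition and resolved chains give the same formula
        a = species_formula(parse_lipid_name("TG 16:0/18:1/18:2"))
        b = species_formula(parse_lipid_name("TG 52:3"))
        assert str(a) == str(b)

    def test_modification_deltas(self):
        base = species_formula(parse_lipid_name("TG 56:6"))
        ooh = species_formula(parse_lipid_name("TG 56:6<OOH>"))
        oxo = species_formula(parse_lipid_name("TG 56:6<oxo>"))
        assert ooh["O"] - base["O"] == 2 and ooh["H"] == base["H"]
        assert oxo["O"] - base["O"] == 1 and base["H"] - oxo["H"] == 2


class TestModificationSet:
    def test_oxygen_accounting(self):
        m = ModificationSet(n_OH=1, n_oxo=1, n_OOH=1, n_epoxy=1)
        assert m.added_oxygens == 1 + 1 + 2 + 1
        assert m.total_groups == 4

    def test_shorthand_roundtrip(self):
        for m in [ModificationSet(2), ModificationSet(0, 1, 1),
                  ModificationSet(1, 1, 0, 0)]:
            assert ModificationSet.parse(m.shorthand()[1:-1]) == m


class TestKendrick:
    def test_single_ch2_maps_to_nominal(self):
        km, defect = kendrick_mass_defect(14.01565)
        assert km == pytest.approx(14.0, abs=1e-6)
        assert defect == pytest.approx(0.0, abs=1e-6)

    def test_homologues_share_defect(self):
        from epilipid.chem import ElementalFormula, monoisotopic_mass
        ch2 = monoisotopic_mass(ElementalFormula.parse("CH2"))
        mz = 760.5851
        _, d1 = kendrick_mass_defect(mz)
        _, d2 = kendrick_mass_defect(mz + ch2)  # one exact CH2 step
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_tg_homologue_pair(self):
        mz = [adduct_mz(species_formula(parse_lipid_name(n)), "[M+NH4]+")
              for n in ("TG 52:2", "TG 54:2")]
        defects = [kendrick_mass_defect(m)[1] for m in mz]
        assert defects[0] == pytest.approx(defects[1], abs=1e-9)

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(NonPositiveMz):
            kendrick_mass_defect(0.0)
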