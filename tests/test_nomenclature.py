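"""Shorthand name parsing, ceramide assembly, and pathway mass identities."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from gangliotk.chem import ADDUCT_2H, ADDUCT_H, adduct_mz, ppm_error
from gangliotk.nomenclature import (
    DEFAULT_REGISTRY,
    FattyAcyl,
    LipidSpecies,
    ParseError,
    SphingoidBase,
    ceramide_composition,
    parse_ion,
    parse_species,
    render_species,
    species_neutral_mass,
)

H2O = 18.0105646859


def test_parse_basic_species():
    sp, adduct = parse_ion("GM3(d18:1_18:0)-H")
    assert sp.class_name == "GM3"
    assert sp.base == SphingoidBase("d", 18, 1)
    assert sp.acyl == FattyAcyl(18, 0)
    assert adduct == ADDUCT_H


def test_parse_extra_oxygen_modifier():
    sp, adduct = parse_ion("Hex1Cer(d17:0_18:2+2O)-H")
    assert sp.acyl.extra_oxygens == 2
    assert sp.base == SphingoidBase("d", 17, 0)


def test_parse_tolerates_whitespace():
    # printed tables sometimes break names: "GM 2 (d18:1_16:0)-H"
    sp, adduct = parse_ion("GM 2 (d18:1_16:0)-H")
    assert sp.class_name == "GM2"
    assert adduct == ADDUCT_H


@pytest.mark.parametrize("sep", ["_", "-", "/"])
def test_chain_separators(sep):
    sp = parse_species(f"GD1(d18:1{sep}20:0)")
    assert sp.acyl == FattyAcyl(20, 0)


def test_parse_errors_carry_position():
    with pytest.raises(ParseError, match="hydroxyl class"):
        parse_species("GM3(x18:1_18:0)")
    with pytest.raises(ParseError, match="unknown class"):
        parse_species("GZ9(d18:1_18:0)")
    with pytest.raises(ParseError):
        parse_species("GM3(d18:1_18)")
    with pytest.raises(ParseError, match="adduct"):
        parse_ion("GM3(d18:1_18:0)+H")


def test_sphp_takes_no_acyl():
    sp = parse_species("SPHP(d18:1)")
    assert sp.acyl is None
    # sphingosine-1-phosphate: base + HPO3
    assert species_neutral_mass(sp) == pytest.approx(
        299.28242943 + 79.96633052, abs=1e-5
    )
    with pytest.raises(ParseError):
        parse_species("SPHP(d18:1_16:0)")
    with pytest.raises(ParseError):
        parse_species("GM3(d18:1)")


@pytest.mark.parametrize(
    "base, acyl, formula, mass",
    [
        # masses frozen from NIST atomic-mass sums (base + acid - H2O)
        (("d", 18, 1), (18, 0, 0), "C36H71NO3", 565.543395),
        (("d", 18, 1), (16, 0, 0), "C34H67NO3", 537.512095),
        (("m", 17, 1), (12, 0, 0), "C29H57NO2", 451.438930),
    ],
)
def test_ceramide_composition(base, acyl, formula, mass):
    comp = ceramide_composition(SphingoidBase(*base), FattyAcyl(*acyl))
    assert comp.formula() == formula
    assert comp.monoisotopic_mass() == pytest.approx(mass, abs=1e-5)


def test_chain_range_warning_not_error():
    with pytest.warns(UserWarning, match="chain length"):
        ceramide_composition(SphingoidBase("d", 18, 1), FattyAcyl(30, 0))


def test_species_neutral_mass_examples():
    gm1 = parse_species("GM1(d18:1_16:0)")
    assert species_neutral_mass(gm1) == pytest.approx(1517.845357, abs=1e-5)
    assert ppm_error(
        1516.8375, adduct_mz(species_neutral_mass(gm1), ADDUCT_H)
    ) < 1.0
    lac = parse_species("Hex2Cer(m17:1_12:0)")
    assert ppm_error(
        774.5373, adduct_mz(species_neutral_mass(lac), ADDUCT_H)
    ) < 1.0
    cer = parse_species("Cer(d18:1_18:0)")
    assert species_neutral_mass(cer) == pytest.approx(
        ceramide_composition(
            SphingoidBase("d", 18, 1), FattyAcyl(18, 0)
        ).monoisotopic_mass(),
        abs=1e-9,
    )


# residue increments along the biosynthesis pathway, Da
HEX = 162.052824
HEXNAC = 203.079373
NEUAC = 291.095417

_bases = st.builds(
    SphingoidBase,
    hydroxyl_class=st.sampled_from("mdt"),
    carbons=st.integers(14, 22),
    double_bonds=st.integers(0, 2),
)
_acyls = st.builds(
    FattyAcyl,
    carbons=st.integers(12, 26),
    double_bonds=st.integers(0, 2),
    extra_oxygens=st.integers(0, 2),
)


@settings(max_examples=50, derandomize=True)
@given(base=_bases, acyl=_acyls)
def test_pathway_mass_identities(base, acyl):
    """GM3 -> GM2 -> GM1 -> GD1 -> GT1 -> GQ1 differ by the condensed
    HexNAc / Hex / NeuAc residue masses for any shared ceramide."""
    def mass(cls):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return species_neutral_mass(
                LipidSpecies(class_name=cls, base=base, acyl=acyl)
            )

    assert mass("GM2") - mass("GM3") == pytest.approx(HEXNAC, abs=1e-6)
    assert mass("GM1") - mass("GM2") == pytest.approx(HEX, abs=1e-6)
    assert mass("GD1") - mass("GM1") == pytest.approx(NEUAC, abs=1e-6)
    assert mass("GT1") - mass("GD1") == pytest.approx(NEUAC, abs=1e-6)
    assert mass("GQ1") - mass("GT1") == pytest.approx(NEUAC, abs=1e-6)
    # sialylation series on the short glycan, and the asialo series
    assert mass("GD3") - mass("GM3") == pytest.approx(NEUAC, abs=1e-6)
    assert mass("GT3") - mass("GD3") == pytest.approx(NEUAC, abs=1e-6)
    assert mass("GM2") - mass("GA2") == pytest.approx(NEUAC, abs=1e-6)
    assert mass("GM1") - mass("GA1") == pytest.approx(NEUAC, abs=1e-6)


def test_isomer_names_share_composition():
    base = SphingoidBase("d", 18, 1)
    acyl = FattyAcyl(18, 0)
    for iso in ("GD1a", "GD1b"):
        sp = parse_species(f"{iso}(d18:1_18:0)")
        assert sp.composition == LipidSpecies("GD1", base, acyl).composition
    entry = DEFAULT_REGISTRY.resolve("GD1")
    assert entry.isomer_group == ("GD1a", "GD1b")
    assert "GD1a" in entry.elution_note  # elution order is annotation only


@pytest.mark.parametrize(
    "name",
    [
        "Hex1Cer(d17:0_18:2+2O)", "Hex2Cer(m17:1_12:0)", "GM3(d18:1_18:0)",
        "GD3(d18:1_16:0)", "GT3(t16:1_12:0)", "GD2(d18:1_18:0)",
        "GT2(d18:1_21:5)", "GM1(d18:1_16:0)", "GT1(d18:1_18:0)",
        "GD1(d18:1_18:0)", "GQ1(d18:1_18:0)", "GM2(d18:1_16:0)",
        "Cer(d18:1_18:0)", "CerP(d18:1_16:0)", "ST(d18:1_24:1)",
        "SPHP(d18:1)", "CerG2GNAc1(d18:1_16:0)", "CerG3GNAc2(d18:1_16:0)",
        "GM1-d3(d18:1_18:0)",
    ],
)
def test_render_parse_round_trip(name):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sp = parse_species(name)
        assert render_species(sp) == name
        assert parse_species(render_species(sp)) == sp


def test_deuterated_internal_standard_mass_shift():
    gm1 = parse_species("GM1(d18:1_18:0)")
    gm1_d3 = parse_species("GM1-d3(d18:1_18:0)")
    shift = species_neutral_mass(gm1_d3) - species_neutral_mass(gm1)
    assert shift == pytest.approx(3 * (2.014102 - 1.007825), abs=1e-4)
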