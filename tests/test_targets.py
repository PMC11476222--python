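"""Target enumeration, ppm matching, and CSV round-trip."""

import pytest
from hypothesis import given, settings, strategies as st

from gangliotk.chem import ADDUCT_2H, ADDUCT_H, adduct_mz, ppm_error
from gangliotk.nomenclature import parse_species, species_neutral_mass
from gangliotk.targets import (
    EnumerationConfig,
    enumerate_targets,
    make_target,
    match_mz,
    read_target_db,
    write_target_db,
)


def test_enumeration_counting():
    cfg = EnumerationConfig(
        classes=["GM3"], bases=["d18:1"],
        acyl_carbons=(16, 18), acyl_double_bonds=(0, 0),
        adducts_by_class={"GM3": ("-H",)},
    )
    targets = enumerate_targets(cfg)
    assert len(targets) == 3  # 16:0, 17:0, 18:0
    names = [t.name for t in targets]
    assert names == sorted(names)  # deterministic order


def test_enumeration_keeps_both_charge_states_in_window():
    cfg = EnumerationConfig(
        classes=["GD1"], bases=["d18:1"],
        acyl_carbons=(18, 18), acyl_double_bonds=(0, 0),
    )
    targets = enumerate_targets(cfg)
    # GD1(d18:1_18:0): [M-H]- ~1836 and [M-2H]2- ~917 both inside 500-2000
    assert len(targets) == 2
    assert {t.adduct.label for t in targets} == {"-H", "-2H"}
    mono = [t for t in targets if t.adduct.label == "-H"][0]
    assert 500 <= mono.theoretical_mz <= 2000


def test_enumeration_window_excludes():
    cfg = EnumerationConfig(
        classes=["GD1"], bases=["d18:1"],
        acyl_carbons=(18, 18), acyl_double_bonds=(0, 0),
        mz_window=(500.0, 1000.0),
    )
    targets = enumerate_targets(cfg)
    assert [t.adduct.label for t in targets] == ["-2H"]


def test_gd1_20_0_primary_mass():
    sp = parse_species("GD1(d18:1_20:0)")
    t = make_target(sp, ADDUCT_2H)
    assert ppm_error(931.4940, t.theoretical_mz) < 1.0


def test_empty_enumeration_warns():
    cfg = EnumerationConfig(
        classes=["GM3"], bases=["d18:1"],
        acyl_carbons=(16, 16), acyl_double_bonds=(0, 0),
        mz_window=(1900.0, 2000.0),
    )
    with pytest.warns(UserWarning, match="no entries"):
        assert enumerate_targets(cfg) == []


@pytest.fixture()
def gm3_target():
    return make_target(parse_species("GM3(d18:1_18:0)"), ADDUCT_H)


def test_match_mz_at_tolerance(gm3_target):
    # observed value printed for this ion reads ~4 ppm high
    hits = match_mz(1179.7419, [gm3_target], tolerance_ppm=10.0)
    assert len(hits) == 1
    assert match_mz(1179.7419, [gm3_target], tolerance_ppm=1.0) == []
    exact = match_mz(gm3_target.theoretical_mz, [gm3_target])
    assert exact[0][1] == 0.0
    with pytest.raises(ValueError):
        match_mz(1179.7419, [gm3_target], tolerance_ppm=0.0)


def test_match_ties_prefer_fewer_sialic_acids():
    # GD1a/GD1b resolve to the same composition: equal ppm, name-tie-broken;
    # a lower-NeuAc candidate at equal ppm error ranks first.
    gd1 = make_target(parse_species("GD1(d18:1_18:0)"), ADDUCT_2H)
    ga1_mass_match = make_target(parse_species("GA1(d18:1_18:0)"), ADDUCT_2H)
    fake_gd1 = type(gd1)(
        species=gd1.species, adduct=gd1.adduct,
        theoretical_mz=ga1_mass_match.theoretical_mz,
        isotope_pattern=gd1.isotope_pattern,
    )
    hits = match_mz(ga1_mass_match.theoretical_mz, [fake_gd1, ga1_mass_match])
    assert hits[0][0].species.class_name == "GA1"


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    observed=st.floats(700.0, 1900.0),
    tol=st.floats(0.5, 20.0),
)
def test_match_monotonic_in_tolerance(observed, tol, targets_pool):
    narrow = match_mz(observed, targets_pool, tol)
    wide = match_mz(observed, targets_pool, 2 * tol)
    assert len(wide) >= len(narrow)
    narrow_names = {t.name for t, _ in narrow}
    assert narrow_names <= {t.name for t, _ in wide}


@pytest.fixture(scope="module")
def targets_pool():
    cfg = EnumerationConfig(
        classes=["GM3", "GM1", "GD1", "GT1"], bases=["d18:1"],
        acyl_carbons=(16, 24), acyl_double_bonds=(0, 1),
    )
    return enumerate_targets(cfg)


def test_stored_mz_recomputable(targets_pool):
    for t in targets_pool:
        recomputed = adduct_mz(species_neutral_mass(t.species), t.adduct)
        assert abs(recomputed - t.theoretical_mz) < 1e-6


def test_csv_round_trip(tmp_path, targets_pool):
    path = tmp_path / "targets.csv"
    subset = targets_pool[:100]
    write_target_db(subset, path)
    back = read_target_db(path)
    assert len(back) == len(subset)
    for a, b in zip(subset, back):
        assert a.name == b.name
        assert a.adduct == b.adduct
        assert abs(a.theoretical_mz - b.theoretical_mz) < 1e-6
        assert a.rt_window == b.rt_window
        assert a.species.composition == b.species.composition


def test_csv_round_trip_empty(tmp_path):
    path = tmp_path / "empty.csv"
    write_target_db([], path)
    assert read_target_db(path) == []
    assert path.read_text().startswith("class,")


def test_csv_missing_column_error(tmp_path, targets_pool):
    path = tmp_path / "targets.csv"
    write_target_db(targets_pool[:3], path)
    lines = path.read_text().splitlines()
    header = lines[0].replace("theoretical_mz", "wrong_name")
    broken = tmp_path / "broken.csv"
    broken.write_text("\n".join([header] + lines[1:]))
    with pytest.raises(ValueError, match="theoretical_mz"):
        read_target_db(broken)


def test_rt_window_membership():
    t = make_target(
        parse_species("GM3(d18:1_18:0)"), ADDUCT_H, rt_window=(6.0, 0.5)
    )
    assert t.in_rt_window(6.4) and t.in_rt_window(5.5)
    assert not t.in_rt_window(6.6)
    open_t = make_target(parse_species("GM3(d18:1_18:0)"), ADDUCT_H)
    assert open_t.in_rt_window(99.0)
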