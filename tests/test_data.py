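"""Transcription and lookup tests for the packaged data tables."""

import pytest

from nmshield import data
from nmshield.errors import (
    MissingArcherPairError,
    UnknownAreaError,
    UnknownMaterialError,
    UnknownNuclideError,
)

# Frozen transcription of the nuclide constants (checked-in copy).
NUCLIDE_CONSTANTS = {
    "Tc-99m": dict(gamma=0.795, f=0.959, hl=6.02, unit="h", lines=((140.0, 0.8907),)),
    "I-131": dict(gamma=2.2, f=0.963, hl=8.02, unit="d", lines=((364.0, 0.812), (637.0, 0.0726))),
    "Lu-177": dict(gamma=0.181, f=0.957, hl=6.65, unit="d", lines=((113.0, 0.06), (208.0, 0.11))),
    "F-18": dict(gamma=5.7, f=0.876, hl=109.8, unit="min", lines=((511.0, 1.94),)),
}

# Frozen transcription of all fitted Archer parameter rows.
ARCHER_ROWS = {
    ("Tc-99m", "lead", "this report"): (2.558, 1.010, 4.344),
    ("Tc-99m", "gypsum", "this report"): (0.009549, -0.005312, 1.430),
    ("Tc-99m", "lw_concrete", "this report"): (0.02047, -0.01122, 0.4389),
    ("Tc-99m", "nw_concrete", "this report"): (0.03102, -0.01729, 0.3622),
    ("Tc-99m", "a514_steel", "this report"): (0.1581, -0.04346, 0.2602),
    ("Tc-99m", "glass", "this report"): (0.03419, -0.02009, 0.3076),
    ("Lu-177", "lead", "this report"): (0.3855, 1.071, 0.2822),
    ("Lu-177", "gypsum", "this report"): (0.009594, -0.003783, 0.3739),
    ("Lu-177", "lw_concrete", "this report"): (0.01615, -0.007056, 0.5194),
    ("Lu-177", "nw_concrete", "this report"): (0.02477, -0.01173, 0.4404),
    ("Lu-177", "a514_steel", "this report"): (0.0797, 2.243, 28.74),
    ("Lu-177", "glass", "this report"): (0.02456, -0.01197, 0.6480),
    ("I-131", "lead", "this report"): (0.1082, 0.2072, 0.5385),
    ("I-131", "lw_concrete", "this report"): (0.01363, -0.007896, 0.4847),
    ("I-131", "nw_concrete", "this report"): (0.02062, -0.01220, 0.4179),
    ("I-131", "a514_steel", "this report"): (0.05786, -0.02574, 0.8742),
    ("I-131", "glass", "this report"): (0.02191, -0.01319, 0.4497),
    ("F-18", "lead", "this report"): (0.166, -0.02184, 0.2436),
    ("F-18", "lw_concrete", "this report"): (0.01126, -0.006463, 0.7475),
    ("F-18", "nw_concrete", "this report"): (0.01558, -0.008775, 0.8600),
    ("F-18", "a514_steel", "this report"): (0.05032, -0.02632, 1.223),
    ("F-18", "lead", "TG-108"): (0.1543, -0.04406, 2.133),
    ("F-18", "nw_concrete", "TG-108"): (0.01539, -0.01161, 2.076),
    ("F-18", "iron", "TG-108"): (0.05705, -0.03063, 0.6319),
}


@pytest.mark.parametrize("name,expected", NUCLIDE_CONSTANTS.items())
def test_nuclide_constants_transcribed(name, expected):
    nuc = data.get_nuclide(name)
    assert nuc.gamma_constant == expected["gamma"]
    assert nuc.f_factor == expected["f"]
    assert nuc.half_life == expected["hl"]
    assert nuc.half_life_unit == expected["unit"]
    assert nuc.photon_lines == expected["lines"]
    assert nuc.gamma_constant > 0
    assert 0 < nuc.f_factor <= 1
    for energy, yield_ in nuc.photon_lines:
        assert energy >= 15.0
        assert yield_ > 100e-6


def test_exactly_four_nuclides_shipped():
    assert sorted(data.list_nuclides()) == ["F-18", "I-131", "Lu-177", "Tc-99m"]


@pytest.mark.parametrize("alias", ["Tc99m", "Tc-99m", "99mTc", "tc-99M"])
def test_nuclide_aliases_resolve(alias):
    assert data.get_nuclide(alias).name == "Tc-99m"


def test_unknown_nuclide_names_supported_set():
    with pytest.raises(UnknownNuclideError, match="Lu-177"):
        data.get_nuclide("Xe-133")


@pytest.mark.parametrize("key,expected", ARCHER_ROWS.items())
def test_archer_rows_transcribed(key, expected):
    nuc, mat, src = key
    p = data.get_archer_params(nuc, mat, source=src)
    assert (p.alpha, p.beta, p.gamma_exp) == expected
    assert p.alpha > 0 and p.gamma_exp > 0


def test_archer_pair_counts():
    assert len(data.list_archer_pairs()) == 21
    assert len(data.list_archer_pairs("TG-108")) == 3


@pytest.mark.parametrize("nuclide", ["F-18", "I-131"])
def test_gypsum_excluded_for_high_energy_emitters(nuclide):
    with pytest.raises(MissingArcherPairError, match="negligible attenuation"):
        data.get_archer_params(nuclide, "gypsum")


def test_tg108_rows_not_returned_by_default():
    default = data.get_archer_params("F-18", "lead")
    assert default.source_tag == "this report"
    assert default.alpha == 0.166


def test_material_compositions_sum_to_unity():
    for name in data.list_materials():
        mat = data.get_material(name)
        assert mat.density > 0
        assert abs(mat.composition_sum - 1.0) <= 1e-3, name


def test_material_lookup_cells():
    gyp = data.get_material("gypsum")
    assert gyp.density == 2.33
    assert gyp.composition["Ca"] == 0.23279
    assert data.get_material("LW concrete").density == 1.6
    assert data.get_material("NW concrete").density == 2.3
    lead = data.get_material("lead")
    assert lead.density == 11.35
    assert not lead.tabulated  # added beyond the source material table
    with pytest.raises(UnknownMaterialError):
        data.get_material("adamantium")


def test_occupancy_factors_are_the_tabulated_set():
    factors = {e.occupancy_factor for e in data.occupancy_table()}
    assert factors == {1.0, 0.5, 0.2, 0.125, 0.05, 0.025}


@pytest.mark.parametrize(
    "key,factor",
    [
        ("office", 1.0),
        ("nuclear medicine hot lab", 0.5),
        ("corridor", 0.2),
        ("corridor door", 0.125),
        ("unattended waiting room", 0.05),
        ("stairway", 0.025),
    ],
)
def test_occupancy_keyword_lookup(key, factor):
    assert data.get_occupancy(key) == factor


def test_unknown_area_lists_valid_areas():
    with pytest.raises(UnknownAreaError, match="Corridor"):
        data.get_occupancy("launchpad")
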