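"""Mass bookkeeping: residue masses, modification strings, fragment m/z."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import peakboost as pb
from peakboost.chem import DEFAULT_REGISTRY, MAX_PEPTIDE_LENGTH

# Independent element-composition oracle: residue formulas summed from atomic
# monoisotopic masses (CODATA/IUPAC), kept deliberately separate from the
# implementation's mass source.
ATOM = {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221,
        "S": 31.97207069}
RESIDUE_FORMULA = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO", "V": "C5H9NO",
    "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO", "I": "C6H11NO",
    "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2", "K": "C6H12N2O",
    "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O", "F": "C9H9NO",
    "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}


def formula_mass(formula: str) -> float:
    import re

    total = 0.0
    for elem, count in re.findall(r"([A-Z])(\d*)", formula):
        total += ATOM[elem] * (int(count) if count else 1)
    return total


WATER_ORACLE = 2 * ATOM["H"] + ATOM["O"]
PROTON_ORACLE = 1.00727646688


@pytest.mark.parametrize("aa", sorted(RESIDUE_FORMULA))
def test_residue_masses_match_element_composition(aa):
    table = pb.load_residue_masses()
    assert table[aa] == pytest.approx(formula_mass(RESIDUE_FORMULA[aa]), abs=1e-5)


def test_residue_table_basics():
    table = pb.load_residue_masses()
    assert table["G"] == pytest.approx(57.02146, abs=1e-5)
    assert table["A"] == pytest.approx(71.03711, abs=1e-5)
    assert set(RESIDUE_FORMULA) == set(table.masses)
    assert max(table.masses, key=table.masses.get) == "W"
    assert pb.load_residue_masses() is table  # singleton


@pytest.mark.parametrize(
    "seq, expected",
    [("G", 75.03203), ("AG", 146.06913), ("ACDEK", None)],
)
def test_neutral_mass_against_oracle(seq, expected):
    oracle = sum(formula_mass(RESIDUE_FORMULA[aa]) for aa in seq) + WATER_ORACLE
    got = pb.peptide_neutral_mass(seq)
    assert got == pytest.approx(oracle, abs=1e-5)
    if expected is not None:
        assert got == pytest.approx(expected, abs=2e-5)


def test_modification_deltas_are_additive():
    p = pb.Peptide("EENGVLVLNDANFDNFVADK", charge=2)
    labeled = pb.apply_flavor_labels(p, pb.get_flavor("TMT"))
    delta = DEFAULT_REGISTRY["TMT6plex"].delta_mass
    assert pb.peptide_neutral_mass(labeled) == pytest.approx(
        pb.peptide_neutral_mass(p) + 2 * delta, abs=1e-9
    )


@pytest.mark.parametrize(
    "s, expected",
    [
        ("-", []),
        ("", []),
        ("3|Phospho", [(3, "Phospho")]),
        ("0|TMT6plex|20|TMT6plex", [(0, "TMT6plex"), (20, "TMT6plex")]),
    ],
)
def test_parse_modification_string(s, expected):
    got = [(pos, m.name) for pos, m in pb.parse_modification_string(s)]
    assert got == expected


@pytest.mark.parametrize("bad", ["3|Phospho|7", "x|Phospho", "1|NotAMod"])
def test_parse_modification_string_errors(bad):
    with pytest.raises(pb.PeptideError):
        pb.parse_modification_string(bad)


def test_fragment_mz_examples():
    assert pb.fragment_mz("AG", "b", 1, 1) == pytest.approx(72.04439, abs=2e-5)
    assert pb.fragment_mz("AG", "y", 1, 1) == pytest.approx(76.03930, abs=2e-5)


def test_fragment_index_and_series_errors():
    p = pb.Peptide("ACDEK")
    with pytest.raises(pb.PeptideError):
        pb.fragment_mz(p, "b", 5, 1)
    with pytest.raises(pb.PeptideError):
        pb.fragment_mz(p, "a", 1, 1)


@st.composite
def random_modified_peptide(draw):
    n = draw(st.integers(5, 30))
    seq = "".join(draw(st.sampled_from(pb.CANONICAL_RESIDUES)) for _ in range(n))
    mods = []
    if draw(st.booleans()):
        mods.append((0, "TMT6plex"))
    for i, aa in enumerate(seq, start=1):
        if aa == "S" and draw(st.integers(0, 4)) == 0:
            mods.append((i, "Phospho"))
        elif aa == "M" and draw(st.integers(0, 4)) == 0:
            mods.append((i, "Oxidation"))
    charge = draw(st.integers(1, 4))
    return pb.Peptide(seq, tuple(mods), charge)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(random_modified_peptide())
def test_by_complementarity_identity(p):
    """mz(b_i, 1+) + mz(y_{n-i}, 1+) == neutral mass + 2 protons, any mods."""
    n = len(p.sequence)
    total = pb.peptide_neutral_mass(p) + 2 * pb.PROTON_MASS
    for i in range(1, n):
        got = pb.fragment_mz(p, "b", i, 1) + pb.fragment_mz(p, "y", n - i, 1)
        assert got == pytest.approx(total, abs=1e-6)


def test_fragment_mz_monotone_in_index_for_homopolymer():
    p = pb.Peptide("AAAAAAAAAA")
    for series in ("b", "y"):
        mzs = [pb.fragment_mz(p, series, i) for i in range(1, 10)]
        assert np.all(np.diff(mzs) > 0)


@pytest.mark.parametrize(
    "n, doubly, charge, expected",
    [(5, False, 2, 8), (3, False, 2, 4), (20, True, 3, 76), (20, True, 2, 38)],
)
def test_theoretical_fragment_counts(n, doubly, charge, expected):
    p = pb.Peptide("A" * (n - 1) + "K", charge=charge)
    frags = pb.theoretical_fragments(p, pb.FragmentConfig(include_doubly_charged=doubly))
    assert len(frags) == expected
    # sorted by series then index within each charge
    b = [f for f in frags if f.series == "b" and f.charge == 1]
    assert [f.index for f in b] == list(range(1, n))


@pytest.mark.parametrize("bad", ["ACDEB", "ACXDE", "AJK", "AOU"])
def test_noncanonical_residues_rejected(bad):
    with pytest.raises(pb.PeptideError):
        pb.Peptide(bad)


def test_peptide_length_bounds():
    with pytest.raises(pb.PeptideError):
        pb.Peptide("AK")
    with pytest.raises(pb.PeptideError):
        pb.Peptide("A" * (MAX_PEPTIDE_LENGTH + 1))


def test_one_modification_per_position():
    with pytest.raises(pb.PeptideError):
        pb.Peptide("ASDK", ((2, "Phospho"), (2, "Phospho")))


def test_apply_flavor_labels():
    tmt = pb.get_flavor("TMT")
    p = pb.Peptide("EENGVLVLNDANFDNFVADK", charge=2)
    labeled = pb.apply_flavor_labels(p, tmt)
    assert labeled.modifications == ((0, "TMT6plex"), (20, "TMT6plex"))
    # no lysine: N-term only
    p2 = pb.Peptide("PEPTIDER", charge=2)
    assert pb.apply_flavor_labels(p2, tmt).modifications == ((0, "TMT6plex"),)
    # unlabeled flavor: identity
    assert pb.apply_flavor_labels(p, pb.get_flavor("HCD")) is p
    # idempotent
    assert pb.apply_flavor_labels(labeled, tmt) == labeled
    # clash with a different modification
    clash = pb.Peptide("PEPTIDEK", ((0, "iTRAQ4plex"),))
    with pytest.raises(pb.PeptideError, match="iTRAQ4plex"):
        pb.apply_flavor_labels(clash, tmt)


def test_flavor_registry_complete():
    assert set(pb.FLAVORS) == {"CID", "HCD", "TripleTOF5600", "TMT", "iTRAQ", "iTRAQphospho"}
    for f in pb.FLAVORS.values():
        if f.name in ("TMT", "iTRAQ", "iTRAQphospho"):
            assert f.fixed_labels


def test_registry_from_yaml(tmp_path):
    cfg = tmp_path / "mods.yaml"
    cfg.write_text(
        "modifications:\n"
        "  - name: Acetyl\n"
        "    composition: C2H2O\n"
        "    targets: [N-term, K]\n"
    )
    reg = pb.ModificationRegistry.from_yaml(cfg)
    assert reg["Acetyl"].delta_mass == pytest.approx(42.010565, abs=1e-5)
    assert "TMT6plex" in reg  # builtins retained
    with pytest.raises(pb.PeptideError):
        reg["Nonexistent"]
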