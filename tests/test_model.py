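"""Topology construction and square-well parameter tables."""

import math

import numpy as np
import pytest

from absheet.model import (AMINO_ACIDS, MODIFICATIONS, ParameterTable,
                           build_topology, default_parameter_table,
                           load_parameter_table, make_default_table,
                           pair_potential, EPS_HB_KJ_PER_MOL)
from absheet.xlink import composition_mono_mass


@pytest.mark.parametrize("seq,expected", [
    ("KLVFFAE", 28),       # 7 residues x 4 beads, no glycine
    ("G", 3),              # glycine has no sidechain bead
    ("GAG", 10),           # 4n - #Gly = 12 - 2
    ("ACDEFGHIKLMNPQRSTVWY", 79),
])
def test_bead_count_formula(seq, expected):
    t = build_topology(seq)
    assert t.n_beads == expected
    assert t.n_beads == 4 * len(seq) - seq.count("G")


def test_unknown_residue_rejected():
    with pytest.raises(ValueError, match="unknown residue"):
        build_topology("KLXFF")
    with pytest.raises(ValueError, match="empty"):
        build_topology("")


def test_bond_walls_bracket_template_geometry():
    t = build_topology("KLVFFAE")
    for (i, j, lo, hi) in t.bonds + t.pseudobonds:
        d = float(np.linalg.norm(t.template_coords[i] - t.template_coords[j]))
        assert lo < d < hi
        assert math.isclose((hi - lo) / (hi + lo), 0.02, rel_tol=1e-9)  # +-2% walls


def test_tfmd_modification_mass_from_composition():
    # +C2N2F3, -H assembled from the element-mass table
    nist = {"C": 12.0, "N": 14.0030740048, "F": 18.9984031627, "H": 1.0078250319}
    expected = 2 * nist["C"] + 2 * nist["N"] + 3 * nist["F"] - nist["H"]
    mod = MODIFICATIONS["TFMD"]
    assert abs(mod.mass_delta_mono - expected) < 1e-4
    t_plain = build_topology("KLVFFAE")
    t_mod = build_topology("KLVFFAE", modifications=[(5, "TFMD")])
    assert t_mod.n_beads == t_plain.n_beads
    sc = t_mod.sc_bead_index(4)
    delta = t_mod.beads[sc].mass - t_plain.beads[t_plain.sc_bead_index(4)].mass
    assert abs(delta - mod.mass_delta_mono) < 1e-6


def test_modification_requires_compatible_residue():
    with pytest.raises(ValueError, match="attaches to F"):
        build_topology("KLVFFAE", modifications=[(1, "TFMD")])
    with pytest.raises(ValueError, match="outside sequence"):
        build_topology("KLVFFAE", modifications=[(9, "TFMD")])


def test_default_table_has_210_pairs(table):
    assert len(table.pair_well_width) == 210
    # every unordered pair over the 20 types present exactly once
    types = sorted(AMINO_ACIDS)
    assert len(types) == 20
    for a in types:
        for b in types:
            assert table.width(a, b) > 0


def test_pair_potential_symmetry_all_pairs(table):
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            assert pair_potential(a, b, table) == pair_potential(b, a, table)


def test_pair_potential_values(table):
    c, w, e = pair_potential("F", "F", table)
    assert e > 0 and w > c            # hydrophobic pair attracts
    assert pair_potential("K", "E", table)[2] > 0    # opposite charges attract
    assert pair_potential("K", "K", table)[2] == 0.0  # like charges: hard sphere
    assert pair_potential("E", "E", table)[2] == 0.0
    with pytest.raises(KeyError):
        pair_potential("X", "F", table)


def test_widths_at_least_contact(table):
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            c, w, _ = pair_potential(a, b, table)
            assert w >= c


def test_energy_unit_round_trip():
    e = 3.7
    kj = ParameterTable.to_kj_per_mol(e)
    assert math.isclose(kj, e * EPS_HB_KJ_PER_MOL)
    assert math.isclose(ParameterTable.from_kj_per_mol(kj), e, rel_tol=1e-15)


def test_table_file_round_trip(tmp_path):
    t = make_default_table()
    p = tmp_path / "table.txt"
    t.write(p)
    t2 = load_parameter_table(p)
    assert t2.pair_well_width == pytest.approx(t.pair_well_width)
    assert t2.hb_width == t.hb_width
    assert t2.width("K", "E") == t2.width("E", "K")  # symmetry of lookup


def test_truncated_table_names_missing_pair(tmp_path):
    t = make_default_table()
    p = tmp_path / "table.txt"
    t.write(p)
    lines = [l for l in p.read_text().splitlines() if not l.startswith("PAIR A C")]
    p2 = tmp_path / "trunc.txt"
    p2.write_text("\n".join(lines))
    with pytest.raises(ValueError, match=r"missing pair \('A', 'C'\)"):
        load_parameter_table(p2)


def test_conflicting_duplicate_rejected(tmp_path):
    t = make_default_table()
    p = tmp_path / "table.txt"
    t.write(p)
    with open(p, "a") as fh:
        fh.write("PAIR E K 9.9 0.5\n")   # asymmetric duplicate, different value
    with pytest.raises(ValueError, match="conflicting duplicate"):
        load_parameter_table(p)


def test_nonpositive_width_rejected(tmp_path):
    t = make_default_table()
    key = ("A", "A")
    t.pair_well_width[key] = 4.7
    p = tmp_path / "table.txt"
    t.write(p)
    text = p.read_text().replace("PAIR A A 4.7000", "PAIR A A -1.0")
    p.write_text(text)
    with pytest.raises(ValueError, match="non-positive|below contact"):
        load_parameter_table(p)


def test_topology_dump_readable(topo):
    text = topo.to_text()
    assert "SC-F" in text and "bond" in text
    assert str(topo.n_beads) in text
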