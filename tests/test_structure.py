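"""PDB I/O, atom classification, and the alanine reduction."""

import numpy as np
import pytest

from dipolecd.builder import build_chain, helix_recipe
from dipolecd.errors import EmptyStructureError, MissingAtomError
from dipolecd.structure import (
    Atom, alanize, classify_units, read_pdb, write_classification_report,
    write_pdb,
)


def _pdb_line(serial, name, resname, chain, resnum, xyz, occ=1.0, altloc=" ",
              element=None, record="ATOM  "):
    element = element or name[0]
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record}{serial:5d} {nm:<4s}{altloc}{resname:>3s} {chain}"
            f"{resnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


def _ala_lines(resnum, origin, serial0=1, chain="A"):
    x, y, z = origin
    coords = {"N": (x, y, z), "CA": (x + 1.46, y, z),
              "C": (x + 2.0, y + 1.4, z), "O": (x + 1.4, y + 2.4, z),
              "CB": (x + 2.0, y - 1.4, z)}
    return [_pdb_line(serial0 + i, n, "ALA", chain, resnum, c)
            for i, (n, c) in enumerate(coords.items())]


def test_roundtrip_of_builder_output(tmp_path):
    st = build_chain(helix_recipe(3))
    path = tmp_path / "tri.pdb"
    write_pdb(st, path)
    again = read_pdb(path)
    assert again.p == 3
    assert len(again.chains) == 1
    for r1, r2 in zip(st.iter_residues(), again.iter_residues()):
        for a1 in r1.atoms:
            a2 = r2.atom(a1.name)
            assert np.allclose(a1.position, a2.position, atol=2e-3)


def test_hetatm_only_file_is_empty(tmp_path):
    lines = [_pdb_line(1, "O", "HOH", "A", 1, (0, 0, 0), record="HETATM"),
             _pdb_line(2, "O", "HOH", "A", 2, (3, 0, 0), record="HETATM"),
             "END"]
    path = tmp_path / "waters.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(EmptyStructureError):
        read_pdb(path)


def test_model_selection_reads_requested_model(tmp_path):
    m1 = _ala_lines(1, (0.0, 0.0, 0.0)) + _ala_lines(2, (0.0, 0.0, 4.0),
                                                     serial0=6)
    m2 = _ala_lines(1, (10.0, 0.0, 0.0)) + _ala_lines(2, (10.0, 0.0, 4.0),
                                                      serial0=6)
    content = (["MODEL        1"] + m1 + ["ENDMDL", "MODEL        2"]
               + m2 + ["ENDMDL", "END"])
    path = tmp_path / "two_models.pdb"
    path.write_text("\n".join(content) + "\n")
    st2 = read_pdb(path, model_index=2)
    n = st2.chains[0].residues[0].atom("N")
    assert np.allclose(n.position, [10.0, 0.0, 0.0])
    st1 = read_pdb(path, model_index=1)
    assert np.allclose(st1.chains[0].residues[0].atom("N").position,
                       [0.0, 0.0, 0.0])


def test_altloc_resolution_prefers_occupancy_then_label(tmp_path):
    lines = _ala_lines(1, (0.0, 0.0, 0.0))
    # residue 2 with a split CA: B has the higher occupancy and must win
    lines += [
        _pdb_line(6, "N", "ALA", "A", 2, (0.0, 0.0, 4.0)),
        _pdb_line(7, "CA", "ALA", "A", 2, (1.46, 0.0, 4.0), occ=0.4,
                  altloc="A"),
        _pdb_line(8, "CA", "ALA", "A", 2, (1.50, 0.1, 4.0), occ=0.6,
                  altloc="B"),
        _pdb_line(9, "C", "ALA", "A", 2, (2.0, 1.4, 4.0)),
        _pdb_line(10, "O", "ALA", "A", 2, (1.4, 2.4, 4.0)),
        # split CB at equal occupancy: alphabetically first label wins
        _pdb_line(11, "CB", "ALA", "A", 2, (2.0, -1.4, 4.0), occ=0.5,
                  altloc="A"),
        _pdb_line(12, "CB", "ALA", "A", 2, (2.2, -1.5, 4.0), occ=0.5,
                  altloc="B"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    st = read_pdb(path)
    res2 = st.chains[0].residues[1]
    assert len([a for a in res2.atoms if a.name == "CA"]) == 1
    assert np.allclose(res2.atom("CA").position, [1.50, 0.1, 4.0])
    assert np.allclose(res2.atom("CB").position, [2.0, -1.4, 4.0])


def test_missing_backbone_atom_names_the_residue(tmp_path):
    lines = [ln for ln in _ala_lines(1, (0, 0, 0)) if " O " not in ln]
    lines += _ala_lines(2, (0, 0, 4.0), serial0=5) + ["END"]
    path = tmp_path / "noO.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(MissingAtomError, match="A1"):
        read_pdb(path)


# --- classification ---------------------------------------------------------


def test_single_chain_oscillator_count_is_p_minus_1():
    st = build_chain(helix_recipe(129))
    cl = classify_units(st)
    assert cl.p == 129
    assert cl.q == 128


def test_dipeptide_isotropic_enumeration():
    st = build_chain(helix_recipe(2))
    cl = classify_units(st, include_hydrogens=False)
    assert cl.q == 1
    species = sorted((a.name, s) for a, s in cl.isotropic_atoms)
    assert species == [("CA", "C_aliphatic"), ("CA", "C_aliphatic"),
                       ("CB", "C_aliphatic"), ("CB", "C_aliphatic")]
    reasons = {a.name: r for a, r in cl.ignored_atoms}
    assert "free amine" in reasons["N"]       # N-terminal nitrogen
    assert "terminal carbonyl" in reasons["C"]  # C-terminal carbonyl


def test_methyl_hydrogens_dropped_but_carbon_kept():
    st = build_chain(helix_recipe(2), include_hydrogens=True)
    cl = classify_units(st, include_hydrogens=True, drop_methyl_hydrogens=True)
    iso_names = {a.name for a, _ in cl.isotropic_atoms}
    assert "CB" in iso_names
    assert not any(n.startswith("HB") for n in iso_names)
    dropped = {a.name for a, r in cl.ignored_atoms if "methyl" in r}
    assert dropped == {"HB1", "HB2", "HB3"}
    # amide H and HA survive with their species
    by_species = {}
    for a, s in cl.isotropic_atoms:
        by_species.setdefault(s, set()).add(a.name)
    assert "H" in by_species["H_amide"]
    assert "HA" in by_species["H_aliphatic"]


def test_methyl_hydrogens_kept_when_requested():
    st = build_chain(helix_recipe(2), include_hydrogens=True)
    cl = classify_units(st, include_hydrogens=True,
                        drop_methyl_hydrogens=False)
    iso_names = {a.name for a, _ in cl.isotropic_atoms}
    assert {"HB1", "HB2", "HB3"} <= iso_names


def test_numbering_gap_breaks_the_chain():
    st = build_chain(helix_recipe(5))
    for offset, res in zip([0, 0, 1, 1, 1], st.chains[0].residues):
        res.index += offset
        for a in res.atoms:
            a.residue_index = res.index
    cl = classify_units(st)  # numbering 1,2,4,5,6
    assert cl.q == 3


def test_stretched_peptide_bond_breaks_the_chain():
    st = build_chain(helix_recipe(4))
    for res in st.chains[0].residues[2:]:
        for a in res.atoms:
            a.position = a.position + np.array([50.0, 0.0, 0.0])
    cl = classify_units(st)
    assert cl.q == 2  # bonds 1-2 and 3-4 survive; 2-3 is broken


def test_classification_is_pure_and_deterministic():
    st = build_chain(helix_recipe(6))
    before = [a.position.copy() for a in st.iter_atoms()]
    c1 = classify_units(st)
    c2 = classify_units(st)
    after = [a.position for a in st.iter_atoms()]
    for b, a in zip(before, after):
        assert np.array_equal(b, a)
    assert c1.q == c2.q
    assert [s for _, s in c1.isotropic_atoms] == [s for _, s in c2.isotropic_atoms]


def test_classification_report_written(tmp_path):
    st = build_chain(helix_recipe(3))
    cl = classify_units(st)
    out = tmp_path / "report.tsv"
    write_classification_report(cl, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["atom", "category", "detail"]
    n_atoms = sum(1 for _ in st.iter_atoms())
    assert len(lines) - 1 == n_atoms


def test_one_residue_structure_has_no_amide():
    st = build_chain(helix_recipe(1))
    with pytest.raises(MissingAtomError):
        classify_units(st)


# --- alanize ----------------------------------------------------------------


def _with_sidechain(resname, extra):
    """3-residue chain whose middle residue gets a renamed side chain."""
    st = build_chain(helix_recipe(3), include_hydrogens=True)
    res = st.chains[0].residues[1]
    res.name = resname
    for a in res.atoms:
        a.residue_name = resname
    cb = res.atom("CB").position
    for i, (name, element) in enumerate(extra):
        res.atoms.append(Atom(name=name, element=element,
                              residue_index=res.index, residue_name=resname,
                              chain_id=res.chain_id,
                              position=cb + np.array([1.5 * (i + 1), 0.2, 0.1])))
    return st


def test_alanize_strips_phe_ring_and_keeps_cb():
    st = _with_sidechain("PHE", [("CG", "C"), ("CD1", "C"), ("CD2", "C"),
                                 ("CE1", "C"), ("CE2", "C"), ("CZ", "C")])
    cb_before = st.chains[0].residues[1].atom("CB").position.copy()
    out = alanize(st)
    res = out.chains[0].residues[1]
    assert res.name == "ALA"
    assert res.atom("CG") is None and res.atom("CZ") is None
    assert np.array_equal(res.atom("CB").position, cb_before)


def test_alanize_removes_ser_og_and_hg():
    st = _with_sidechain("SER", [("OG", "O"), ("HG", "H")])
    # put HG next to OG so it follows its parent out
    res = st.chains[0].residues[1]
    res.atom("HG").position = res.atom("OG").position + np.array([0.9, 0, 0])
    out = alanize(st)
    res = out.chains[0].residues[1]
    assert res.name == "ALA"
    assert res.atom("OG") is None and res.atom("HG") is None
    assert res.atom("CB") is not None
    assert res.atom("HB1") is not None  # CB hydrogens stay with CB


def test_alanize_identity_on_aliphatic_chain():
    st = build_chain(helix_recipe(4), include_hydrogens=True)
    out = alanize(st)
    assert out.p == st.p
    for r1, r2 in zip(st.iter_residues(), out.iter_residues()):
        assert len(r1.atoms) == len(r2.atoms)
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert np.array_equal(a1.position, a2.position)
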