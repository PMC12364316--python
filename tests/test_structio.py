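"""Structure/map I/O and selection semantics."""

import struct

import numpy as np
import pytest

from emligfit.structio import (Atom, DensityGrid, MapFormatError, ParseError,
                               Selection, Structure, heavy_atoms,
                               protein_selection, read_map, read_structure,
                               select_ligand, select_pocket, write_map,
                               write_structure)

from conftest import random_structure


def make_toy_complex(n_waters=2):
    atoms = [
        Atom(1, "N", "N", "ALA", 1, "A", [0.0, 0.0, 0.0]),
        Atom(2, "CA", "C", "ALA", 1, "A", [1.5, 0.0, 0.0]),
        Atom(3, "C", "C", "ALA", 1, "A", [2.3, 1.2, 0.0]),
    ]
    serial = 4
    # 16 heavy ligand atoms + hydrogens
    for i in range(16):
        atoms.append(Atom(serial, f"C{i}", "C", "LIG", 2, "B",
                          [5.0 + 0.9 * i, 1.0, 0.0], is_hetero=True))
        serial += 1
    for i in range(10):
        atoms.append(Atom(serial, f"H{i}", "H", "LIG", 2, "B",
                          [5.0 + 0.9 * i, 1.8, 0.4], is_hetero=True))
        serial += 1
    for i in range(n_waters):
        atoms.append(Atom(serial, "O", "O", "HOH", 10 + i, "W",
                          [20.0 + i, 20.0, 20.0], is_hetero=True))
        serial += 1
    return Structure(atoms)


class TestStructureIO:
    def test_read_minimal_pdb(self, tmp_path, pdb_text_3atoms):
        p = tmp_path / "mini.pdb"
        p.write_text(pdb_text_3atoms)
        st = read_structure(p)
        assert len(st) == 3
        assert {a.element for a in st} == {"N", "C", "O"}
        assert np.allclose(st.atoms[0].position, [11.104, 6.134, -6.504])

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  N  AALA A   1      11.104   6.134  -6.504  0.40"
            " 10.00           N\n"
            "ATOM      2  N  BALA A   1      99.000   6.134  -6.504  0.60"
            " 10.00           N\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        st = read_structure(p)
        assert len(st) == 1
        assert st.atoms[0].position[0] == pytest.approx(99.0)

    def test_altloc_tie_keeps_first(self, tmp_path):
        text = (
            "ATOM      1  N  AALA A   1      11.104   6.134  -6.504  0.50"
            " 10.00           N\n"
            "ATOM      2  N  BALA A   1      99.000   6.134  -6.504  0.50"
            " 10.00           N\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        st = read_structure(p)
        assert st.atoms[0].position[0] == pytest.approx(11.104)

    def test_round_trip_preserves_coordinates(self, tmp_path):
        st = random_structure(500, seed=11)
        p = tmp_path / "rt.pdb"
        write_structure(st, p)
        st2 = read_structure(p)
        assert len(st2) == 500
        assert np.allclose(st.coords(), st2.coords(), atol=1e-3)
        assert [a.name for a in st] == [a.name for a in st2]

    def test_single_atom_write(self, tmp_path):
        st = Structure([Atom(1, "C1", "C", "LIG", 1, "A", [1, 2, 3],
                             is_hetero=True)])
        p = tmp_path / "one.pdb"
        write_structure(st, p)
        records = [l for l in p.read_text().splitlines()
                   if l.startswith(("ATOM", "HETATM"))]
        assert len(records) == 1
        assert records[0].startswith("HETATM")

    def test_long_chain_id_raises(self, tmp_path):
        st = Structure([Atom(1, "C1", "C", "LIG", 1, "AB", [1, 2, 3])])
        with pytest.raises(ValueError, match="chain"):
            write_structure(st, tmp_path / "bad.pdb")

    def test_unreadable_file_raises(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not\x00 a pdb file at all")
        with pytest.raises((ParseError, ValueError)):
            read_structure(p)

    def test_minimal_mmcif(self, tmp_path):
        cif = """data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
ATOM 1 N N ALA A 1 11.104 6.134 -6.504 1.00
ATOM 2 C CA ALA A 1 11.639 6.071 -5.147 1.00
HETATM 3 C C1 LIG B 2 1.0 2.0 3.0 1.00
"""
        p = tmp_path / "mini.cif"
        p.write_text(cif)
        st = read_structure(p)
        assert len(st) == 3
        assert st.atoms[2].is_hetero
        assert st.atoms[2].residue_name == "LIG"
        assert np.allclose(st.atoms[0].position, [11.104, 6.134, -6.504])


class TestMapIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = DensityGrid(origin=[1.0, -2.0, 3.5], voxel_size=[1.0, 1.2, 0.8],
                           values=rng.normal(size=(8, 6, 10)))
        p = tmp_path / "map.mrc"
        write_map(grid, p)
        grid2 = read_map(p)
        assert np.allclose(grid2.values, grid.values, atol=1e-5)
        assert np.allclose(grid2.origin, grid.origin, atol=1e-5)
        assert np.allclose(grid2.voxel_size, grid.voxel_size, atol=1e-6)

    def test_constant_grid_size_and_stats(self, tmp_path):
        grid = DensityGrid(origin=[0, 0, 0], voxel_size=[1, 1, 1],
                           values=np.full((8, 8, 8), 2.5))
        p = tmp_path / "c.mrc"
        write_map(grid, p)
        # 1024-byte header + 8^3 float32 values
        assert p.stat().st_size == 1024 + 8 ** 3 * 4
        assert np.allclose(read_map(p).values, 2.5)

    def test_nan_values_rejected(self, tmp_path):
        values = np.zeros((4, 4, 4))
        grid = DensityGrid(origin=[0, 0, 0], voxel_size=[1, 1, 1],
                           values=values)
        grid.values = grid.values.copy()
        grid.values[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN|finite"):
            write_map(grid, tmp_path / "nan.mrc")

    def test_nonzero_start_shifts_origin(self, tmp_path):
        """Origin equals start indices times voxel size (header arithmetic)."""
        grid = DensityGrid(origin=[0, 0, 0], voxel_size=[1.5, 1.5, 1.5],
                           values=np.arange(27.0).reshape(3, 3, 3))
        p = tmp_path / "s.mrc"
        write_map(grid, p)
        raw = bytearray(p.read_bytes())
        # words 5-7 (0-based 4-6): nxstart/nystart/nzstart
        struct.pack_into("<3i", raw, 4 * 4, 2, 3, 4)
        # zero the ORIGIN words (49-51 zero-based) so start is authoritative
        struct.pack_into("<3f", raw, 49 * 4, 0.0, 0.0, 0.0)
        p.write_bytes(bytes(raw))
        grid2 = read_map(p)
        # independent header arithmetic: origin = start * voxel
        assert np.allclose(grid2.origin, [2 * 1.5, 3 * 1.5, 4 * 1.5])

    def test_permuted_axis_order(self, tmp_path):
        """Maps stored slow-to-fast in a permuted order read back canonical."""
        rng = np.random.default_rng(1)
        values = rng.normal(size=(4, 5, 6))
        grid = DensityGrid(origin=[0, 0, 0], voxel_size=[1, 1, 1],
                           values=values)
        p = tmp_path / "perm.mrc"
        write_map(grid, p)
        raw = bytearray(p.read_bytes())
        # rewrite as if stored with fast=y, medium=x, slow=z; the file is a
        # C-ordered (ns, nr, nc) block, i.e. axes (z, x, y) of the original
        perm_values = np.transpose(values, (2, 0, 1)).astype("<f4")
        struct.pack_into("<3i", raw, 0, 5, 4, 6)           # nc, nr, ns
        struct.pack_into("<3i", raw, 16 * 4, 2, 1, 3)      # mapc, mapr, maps
        new = raw[:1024] + perm_values.tobytes(order="C")
        p.write_bytes(bytes(new))
        grid2 = read_map(p)
        assert np.allclose(grid2.values, values, atol=1e-6)

    def test_wrong_mode_rejected(self, tmp_path):
        grid = DensityGrid(origin=[0, 0, 0], voxel_size=[1, 1, 1],
                           values=np.zeros((4, 4, 4)))
        p = tmp_path / "m.mrc"
        write_map(grid, p)
        raw = bytearray(p.read_bytes())
        struct.pack_into("<i", raw, 3 * 4, 1)   # mode word
        p.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError, match="mode"):
            read_map(p)


class TestSelections:
    def test_ligand_auto_picks_largest_heavy(self):
        st = make_toy_complex()
        sel = select_ligand(st, "auto")
        names = {st.atoms[i].residue_name for i in sel.indices}
        assert names == {"LIG"}
        assert len(heavy_atoms(sel, st)) == 16
        # hydrogens of the ligand come along
        assert len(sel) == 26

    def test_named_ligand_missing_lists_candidates(self):
        st = make_toy_complex()
        with pytest.raises(ValueError, match="LIG"):
            select_ligand(st, "XYZ")

    def test_heavy_atom_counts(self):
        st = make_toy_complex()
        sel = select_ligand(st, "LIG")
        assert len(heavy_atoms(sel, st)) == 16
        h_only = Selection(np.array([i for i in sel.indices
                                     if st.atoms[i].is_hydrogen]))
        assert len(heavy_atoms(h_only, st)) == 0

    def test_pocket_threshold_boundary(self):
        atoms = [
            Atom(1, "C1", "C", "LIG", 1, "B", [0.0, 0.0, 0.0], is_hetero=True),
            Atom(2, "CA", "C", "GLY", 1, "A", [3.9, 0.0, 0.0]),
            Atom(3, "CA", "C", "GLY", 2, "A", [0.0, 4.1, 0.0]),
        ]
        st = Structure(atoms)
        lig = select_ligand(st, "LIG")
        pocket = select_pocket(st, lig, cutoff=4.0)
        residues = {st.atoms[i].residue_seq for i in pocket.indices}
        assert residues == {1}

    def test_pocket_cutoff_zero_empty(self):
        st = make_toy_complex()
        lig = select_ligand(st, "LIG")
        assert len(select_pocket(st, lig, cutoff=0.0)) == 0

    def test_pocket_matches_brute_force(self):
        rng = np.random.default_rng(7)
        atoms = []
        serial = 1
        for r in range(50):
            base = rng.uniform(0, 30, size=3)
            for k in range(3):
                atoms.append(Atom(serial, f"C{k}", "C", "GLY", r + 1, "A",
                                  base + rng.normal(scale=0.8, size=3)))
                serial += 1
        for k in range(5):
            atoms.append(Atom(serial, f"C{k}", "C", "LIG", 99, "B",
                              [15.0 + k, 15.0, 15.0], is_hetero=True))
            serial += 1
        st = Structure(atoms)
        lig = select_ligand(st, "LIG")
        pocket = select_pocket(st, lig, cutoff=4.0)

        # brute-force O(n*m) oracle over all residue/ligand atom pairs
        coords = st.coords()
        lig_xyz = coords[lig.indices]
        near_res = set()
        for i, a in enumerate(st.atoms):
            if a.is_hetero:
                continue
            d = np.linalg.norm(lig_xyz - coords[i], axis=1).min()
            if d <= 4.0:
                near_res.add((a.chain, a.residue_seq))
        expected = [i for i, a in enumerate(st.atoms)
                    if not a.is_hetero and (a.chain, a.residue_seq) in near_res]
        assert sorted(pocket.indices.tolist()) == sorted(expected)

    def test_ligand_pocket_disjoint(self, default_fixture):
        st = default_fixture.ground_truth
        lig = select_ligand(st, "auto")
        pocket = select_pocket(st, lig)
        assert len(np.intersect1d(lig.indices, pocket.indices)) == 0
        prot = protein_selection(st)
        assert set(pocket.indices).issubset(set(prot.indices))

    def test_unknown_element_rejected(self):
        with pytest.raises((ParseError, ValueError)):
            Atom(1, "Q1", "Qq", "LIG", 1, "A", [0, 0, 0])
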