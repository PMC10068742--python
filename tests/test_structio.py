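import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpart.core import EnsembleError, MoleculeTypeSpec
from scpart.partition import FreeEnergyProfile
from scpart.profiles import SliceGrid
from scpart.structio import (
    FormatError,
    LayerTable,
    compile_layer_table,
    read_dg_profile,
    read_gro_ensemble,
    read_layer_table,
    read_pdb_ensemble,
    read_solute_table,
    write_dg_profile,
    write_gro_ensemble,
    write_layer_table,
    write_pdb_ensemble,
    write_solute_table,
)
from scpart.synthetic import FixtureSpec, SoluteSetSpec, generate_bilayer_fixture, generate_solute_table

TWO_ATOM_GRO = """\
two atoms
    2
    1CER2    N1    1   1.000   2.000   3.000
    2SOL     OW    2   4.000   4.500   9.000
   5.00000   5.00000  10.00000
"""


# ---------------------------------------------------------------------- GRO

class TestGro:
    def test_two_atom_single_frame(self, tmp_path):
        p = tmp_path / "two.gro"
        p.write_text(TWO_ATOM_GRO)
        ens = read_gro_ensemble(p)
        assert ens.n_frames == 1
        assert ens.n_atoms == 2
        assert np.allclose(ens.boxes[0], [5.0, 5.0, 10.0])
        assert np.allclose(ens.coords[0, 0], [1.0, 2.0, 3.0])
        assert ens.molecule_types == ["CER2", "SOL"]
        assert ens.molecule_catalog["SOL"].role == "water"
        assert ens.molecule_catalog["CER2"].role == "lipid"
        # single-site water carries the full molecular mass
        assert ens.masses[1] == pytest.approx(18.015)

    def test_concatenated_frames(self, tmp_path):
        p = tmp_path / "two.gro"
        p.write_text(TWO_ATOM_GRO * 2)
        ens = read_gro_ensemble(p)
        assert ens.n_frames == 2
        assert np.array_equal(ens.coords[0], ens.coords[1])

    def test_roundtrip_against_generator(self, tmp_path):
        spec = FixtureSpec(
            lipid_counts={"CER2": 3, "CHOL": 3},
            waters_per_lipid=4,
            box=(4.0, 4.0, 10.0),
            n_frames=3,
            seed=11,
        )
        ens = generate_bilayer_fixture(spec)
        p = tmp_path / "fix.gro"
        write_gro_ensemble(ens, p)
        back = read_gro_ensemble(p)
        assert back.n_frames == 3
        # GRO stores 3 decimals -> 1e-3 nm tolerance
        assert np.abs(back.coords - ens.coords).max() <= 1e-3 + 1e-12
        assert back.molecule_types == ens.molecule_types
        assert np.array_equal(back.molecule_ids, ens.molecule_ids)

    def test_malformed_column_error_names_line(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text("t\n    1\n    1CER2    N1    1   1.0\n 5 5 5\n")
        with pytest.raises(FormatError, match="line 3"):
            read_gro_ensemble(p)

    def test_inconsistent_atom_counts(self, tmp_path):
        frame2 = TWO_ATOM_GRO.replace("    2\n", "    1\n", 1).split("\n")
        frame2 = "\n".join([frame2[0], frame2[1], frame2[2], frame2[4]]) + "\n"
        p = tmp_path / "bad.gro"
        p.write_text(TWO_ATOM_GRO + frame2)
        with pytest.raises(EnsembleError):
            read_gro_ensemble(p)


# ---------------------------------------------------------------------- PDB

class TestPdb:
    def test_angstrom_to_nm(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(
            "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1\n"
            "ATOM      1  C1  LIG     1      10.000   0.000   0.000  1.00  0.00"
            "           C\n"
            "END\n"
        )
        ens = read_pdb_ensemble(p)
        assert ens.n_frames == 1
        assert np.allclose(ens.coords[0, 0], [1.0, 0.0, 0.0])
        assert np.allclose(ens.boxes[0], [5.0, 5.0, 5.0])

    def test_two_model_blocks(self, tmp_path):
        atom = "ATOM      1  C1  LIG     1      10.000   0.000   0.000  1.00  0.00           C\n"
        p = tmp_path / "two.pdb"
        p.write_text(f"MODEL     1\n{atom}ENDMDL\nMODEL     2\n{atom}ENDMDL\nEND\n")
        ens = read_pdb_ensemble(p)
        assert ens.n_frames == 2

    def test_missing_cryst1_defers_error(self, tmp_path):
        from scpart.profiles import grid_for_ensemble

        p = tmp_path / "nobox.pdb"
        p.write_text(
            "ATOM      1  C1  LIG     1      10.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        ens = read_pdb_ensemble(p)  # reading succeeds
        with pytest.raises(Exception, match="no box"):
            grid_for_ensemble(ens)

    def test_cross_format_roundtrip(self, tmp_path):
        spec = FixtureSpec(
            lipid_counts={"CERO": 2, "LIGN": 2},
            waters_per_lipid=3,
            box=(4.0, 4.0, 12.0),
            n_frames=2,
            seed=5,
        )
        ens = generate_bilayer_fixture(spec)
        gro = tmp_path / "x.gro"
        write_gro_ensemble(ens, gro)
        from_gro = read_gro_ensemble(gro)
        pdb = tmp_path / "x.pdb"
        write_pdb_ensemble(from_gro, pdb)
        from_pdb = read_pdb_ensemble(pdb)
        assert np.abs(from_pdb.coords - from_gro.coords).max() <= 1e-4 + 1e-12
        assert from_pdb.molecule_types == from_gro.molecule_types


# --------------------------------------------------------------- layer table

def tiny_table():
    grid = SliceGrid(n=3, thickness=1.0, box_area=4.0)
    spec = MoleculeTypeSpec("X", 12.011, ("C",), "lipid")
    water = MoleculeTypeSpec("H2O", 18.015, ("O",), "water")
    return LayerTable(
        grid=grid,
        densities={"X": np.array([[0.0, 1.0, 0.0]]), "H2O": np.array([[0.5, 0.0, 0.5]])},
        catalog={"X": spec, "H2O": water},
        molecule_counts={"X": 1, "H2O": 4},
        system="tiny",
        n_frames=2,
    )


class TestLayerTable:
    def test_tiny_roundtrip_exact(self, tmp_path):
        table = tiny_table()
        p = tmp_path / "t.tsv"
        write_layer_table(table, p)
        back = read_layer_table(p)
        assert back.grid.n == 3
        assert back.system == "tiny"
        assert back.n_frames == 2
        np.testing.assert_array_equal(back.densities["X"], table.densities["X"])
        np.testing.assert_array_equal(back.densities["H2O"], table.densities["H2O"])
        assert back.molecule_counts == {"X": 1, "H2O": 4}

    def test_empty_molecule_list_errors(self, tmp_path):
        table = tiny_table()
        table.densities = {}
        with pytest.raises(FormatError, match="no molecule types"):
            write_layer_table(table, tmp_path / "t.tsv")

    def test_slice_count_mismatch(self, tmp_path):
        table = tiny_table()
        p = tmp_path / "t.tsv"
        write_layer_table(table, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")  # drop one body row
        with pytest.raises(FormatError, match="slices"):
            read_layer_table(p)

    def test_synthetic_fixture_roundtrip(self, tmp_path, small_bilayer):
        from scpart.profiles import build_slice_grid

        grid = build_slice_grid(np.array([4.0, 4.0, 10.37]), 0.1)
        assert grid.n == 104
        ens = small_bilayer
        # rebuild on the fixture's own grid (box_z must match within 1%)
        grid = build_slice_grid(ens.boxes.mean(axis=0), 0.1)
        table = compile_layer_table(ens, grid, system="HPm2-small", symmetrized=True)
        p = tmp_path / "layers.tsv"
        write_layer_table(table, p)
        back = read_layer_table(p)
        for mtype in table.densities:
            assert np.abs(back.densities[mtype] - table.densities[mtype]).max() < 1e-9
        assert back.grid.slice_volume == pytest.approx(grid.slice_volume, rel=1e-12)

    def test_water_profile_reconstruction(self, tmp_path):
        table = tiny_table()
        wp = table.water_profile()
        assert wp.n_w_tot == 4.0
        np.testing.assert_allclose(wp.x_w, [0.5, 0.0, 0.5])


# ------------------------------------------------------------- dG profiles

class TestDgProfile:
    def test_flat_profile(self, tmp_path):
        p = tmp_path / "dg.tsv"
        p.write_text("".join(f"{0.5 + i}\t0.0\n" for i in range(5)))
        prof = read_dg_profile(p)
        assert prof.n == 5
        assert np.all(prof.dg == 0.0)

    def test_non_uniform_spacing_rejected(self, tmp_path):
        p = tmp_path / "dg.tsv"
        p.write_text("0.0\t0.0\n1.0\t0.0\n2.0\t0.0\n4.0\t0.0\n")
        with pytest.raises(FormatError, match="non-uniform"):
            read_dg_profile(p)

    def test_angstrom_header(self, tmp_path):
        p = tmp_path / "dg.tsv"
        p.write_text("# z_unit: angstrom\n5.0\t1.0\n15.0\t2.0\n")
        prof = read_dg_profile(p)
        np.testing.assert_allclose(prof.z_centers, [0.5, 1.5])

    def test_generator_roundtrip(self, tmp_path, small_grid):
        from scpart.synthetic import DGProfileSpec, generate_dg_profile

        prof = generate_dg_profile(DGProfileSpec(well_depth=25.0, noise_sigma=1.0, seed=3), small_grid)
        p = tmp_path / "dg.tsv"
        write_dg_profile(prof, p)
        back = read_dg_profile(p)
        assert np.abs(back.dg - prof.dg).max() < 1e-9
        assert np.abs(back.z_centers - prof.z_centers).max() < 1e-9


# ------------------------------------------------------------ solute tables

class TestSoluteTable:
    def test_three_rows(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("name,log_klip_exp,log_kow\na,1.0,2.0\nb,0.5,1.0\nc,-0.1,0.2\n")
        records = read_solute_table(p)
        assert len(records) == 3
        assert records[0].log_kow == 2.0

    def test_duplicate_names_error(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("name,log_klip_exp,log_kow\na,1.0,2.0\na,0.5,1.0\n")
        with pytest.raises(FormatError, match="duplicate.*a"):
            read_solute_table(p)

    def test_missing_optional_flagged_not_dropped(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("name,log_klip_exp,log_kow,log_kow_pred\na,1.0,2.0,\nb,0.5,1.0,1.1\n")
        records = read_solute_table(p)
        assert len(records) == 2
        assert records[0].log_kow_pred is None
        assert records[1].log_kow_pred == 1.1

    def test_synthetic_64_roundtrip(self, tmp_path):
        recs = generate_solute_table(SoluteSetSpec(systems=("HPm2",), seed=9))
        p = tmp_path / "s.csv"
        write_solute_table(recs, p)
        back = read_solute_table(p)
        assert len(back) == 64
        for a, b in zip(recs, back):
            assert a.name == b.name
            assert b.log_kow == pytest.approx(a.log_kow, abs=1e-12)
            assert b.log_klip_exp == pytest.approx(a.log_klip_exp, abs=1e-12)
            assert b.log_klip_pred["HPm2"] == pytest.approx(a.log_klip_pred["HPm2"], abs=1e-12)


# --------------------------------------------------------------- properties

@st.composite
def layer_tables(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    n_types = draw(st.integers(min_value=1, max_value=3))
    grid = SliceGrid(n=n, thickness=draw(st.floats(0.05, 0.5)), box_area=draw(st.floats(1.0, 50.0)))
    densities, catalog, counts = {}, {}, {}
    for t in range(n_types):
        name = f"T{t}" if t else "H2O"
        n_atoms = 1 if name == "H2O" else draw(st.integers(min_value=1, max_value=4))
        raw = np.array(
            [[draw(st.floats(0.0, 1.0)) for _ in range(n)] for _ in range(n_atoms)]
        )
        raw += 1e-3  # avoid all-zero rows
        densities[name] = raw / raw.sum(axis=1, keepdims=True)
        if name == "H2O":
            catalog[name] = MoleculeTypeSpec(name, 18.015, ("O",), "water")
        else:
            catalog[name] = MoleculeTypeSpec(name, 12.011 * n_atoms, ("C",) * n_atoms, "lipid")
        counts[name] = draw(st.integers(min_value=1, max_value=500))
    return LayerTable(grid=grid, densities=densities, catalog=catalog,
                      molecule_counts=counts, system="prop", n_frames=1)


@settings(max_examples=25, deadline=None)
@given(layer_tables())
def test_layer_table_roundtrip_property(tmp_path_factory, table):
    path = tmp_path_factory.mktemp("lt") / "t.tsv"
    write_layer_table(table, path)
    back = read_layer_table(path)
    for mtype, dens in table.densities.items():
        assert np.abs(back.densities[mtype] - dens).max() < 1e-9
    assert back.grid.n == table.grid.n


@settings(max_examples=25, deadline=None)
@given(
    st.lists(st.floats(-400.0, 400.0), min_size=2, max_size=30),
    st.floats(0.01, 0.5),
)
def test_dg_profile_roundtrip_property(tmp_path_factory, dgs, dz):
    z = (np.arange(len(dgs)) + 0.5) * dz
    prof = FreeEnergyProfile(z_centers=z, dg=np.array(dgs))
    path = tmp_path_factory.mktemp("dg") / "p.tsv"
    write_dg_profile(prof, path)
    back = read_dg_profile(path)
    assert np.abs(back.dg - prof.dg).max() < 1e-9


def test_unit_discipline_tripwire():
    # coordinates beyond 1000 nm are treated as an Angstrom leak
    from conftest import make_ensemble

    with pytest.raises(EnsembleError, match="1000 nm"):
        make_ensemble(
            np.array([[[0.0, 0.0, 2000.0]]]), (1.0, 1.0, 3000.0), ["C"], [0], ["X"]
        )
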