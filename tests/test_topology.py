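"""Structure reading, bead classification, units and leaflet assignment."""

import logging

import numpy as np
import pytest

from lipidsites import (
    DEFAULT_SPECIES,
    assign_leaflets,
    classify_bead,
    read_system,
    read_trajectory,
    write_system,
)
from lipidsites.io import load_species_table
from lipidsites.system import Trajectory


def test_bead_classification_covers_all_species():
    for species, beads in DEFAULT_SPECIES.items():
        classes = [classify_bead(b) for b in beads]
        assert classes.count("phosphate") == 1
        assert classes[0] == "head"
        assert "tailA" in classes and "tailB" in classes
    assert len(DEFAULT_SPECIES["POPC"]) == 13
    assert len(DEFAULT_SPECIES["DPPC"]) == 12
    assert len(DEFAULT_SPECIES["POPE"]) == 13


def test_read_system_roundtrip(fixture_dir, small_run):
    system, traj, truth = small_run
    read = read_system(fixture_dir["pdb"])
    assert read.n_beads == system.n_beads
    assert list(read.bead_names) == list(system.bead_names)
    assert list(read.residue_ids) == list(system.residue_ids)
    assert read.n_lipids == system.n_lipids
    po4 = read.bead_classes[read.phosphate_indices]
    assert set(po4) == {"phosphate"}
    assert (read.molecule_kinds == "protein").sum() == len(
        system.protein_indices)


def test_unit_invariance_pdb_vs_gro(fixture_dir):
    """Angstrom-native and nm-native dialects give identical nm coordinates."""
    s_pdb = read_system(fixture_dir["pdb"])
    s_gro = read_system(fixture_dir["gro"])
    t_pdb = read_trajectory(fixture_dir["pdb"], s_pdb)
    t_gro = read_trajectory(fixture_dir["gro"], s_gro)
    assert np.allclose(t_pdb.coordinates, t_gro.coordinates, atol=1e-3)
    assert np.allclose(t_pdb.box, t_gro.box, atol=1e-4)


def test_read_trajectory_dcd(fixture_dir, small_run):
    system, traj, truth = small_run
    sysr = read_system(fixture_dir["pdb"])
    t = read_trajectory(fixture_dir["dcd"], sysr)
    assert t.n_frames == traj.n_frames
    assert t.n_beads == system.n_beads
    # DCD stores float32 Angstrom; nm round trip agrees to ~1e-5 nm
    assert np.allclose(t.coordinates, traj.coordinates, atol=1e-4)
    assert np.all(t.box > 0)


def test_atom_count_mismatch_rejected(fixture_dir, tmp_path):
    small = tmp_path / "one.pdb"
    small.write_text(
        "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  PO4 POPC    1       1.000   1.000   1.000  1.00  0.00\n"
        "END\n")
    sysr = read_system(str(small), {"POPC": ("PO4",)})
    with pytest.raises((ValueError, OSError)):
        read_trajectory(fixture_dir["dcd"], sysr)


def test_unknown_residues_classified_as_solvent_or_ion(tmp_path, caplog):
    pdb = tmp_path / "mixed.pdb"
    lines = []
    recs = [("W", "W", 1), ("NA", "NA", 2), ("XXX", "Q1", 3)]
    for i, (resname, atname, resid) in enumerate(recs, start=1):
        lines.append(
            f"ATOM  {i:5d} {atname:<4s} {resname:<4s}A{resid:4d}    "
            f"{1.0 * i:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00")
    pdb.write_text("CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1\n"
                   + "\n".join(lines) + "\nEND\n")
    with caplog.at_level(logging.WARNING):
        system = read_system(str(pdb))
    assert list(system.molecule_kinds) == ["solvent", "ion", "solvent"]
    assert "unrecognised" in caplog.text
    # degenerate: no protein beads is not an error
    assert len(system.protein_indices) == 0


def test_lipid_bead_mismatch_rejected(tmp_path):
    pdb = tmp_path / "bad.pdb"
    lines = []
    for i, name in enumerate(["CHO", "GL1"], start=1):  # PO4 missing
        lines.append(
            f"ATOM  {i:5d} {name:<4s} POPCA   1    "
            f"{1.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00")
    pdb.write_text("\n".join(lines) + "\nEND\n")
    with pytest.raises(ValueError, match="species table"):
        read_system(str(pdb))


def test_species_table_requires_phosphate(tmp_path):
    y = tmp_path / "species.yaml"
    y.write_text("FOO:\n  beads: [CHO, GL1]\n")
    with pytest.raises(ValueError, match="PO4"):
        load_species_table(str(y))
    y.write_text("FOO:\n  beads: [CHO, PO4, C1A]\n")
    table = load_species_table(str(y))
    assert table["FOO"] == ("CHO", "PO4", "C1A")


def test_triclinic_box_rejected(tmp_path, small_run):
    import MDAnalysis as mda
    system, traj, truth = small_run
    gro = tmp_path / "tri.gro"
    u = mda.Universe.empty(n_atoms=1, trajectory=True)
    u.add_TopologyAttr("names", ["PO4"])
    u.add_TopologyAttr("resnames", ["POPC"])
    u.atoms.positions = [[1.0, 1.0, 1.0]]
    u.dimensions = [50, 50, 50, 60, 90, 90]
    u.atoms.write(str(gro))
    sysr = read_system(str(gro), {"POPC": ("PO4",)})
    with pytest.raises(ValueError, match="riclinic"):
        read_trajectory(str(gro), sysr)


def test_leaflet_assignment_symmetric_pair():
    from conftest import hand_system
    sys2 = hand_system(n_lipids=2)
    coords = np.zeros((1, sys2.n_beads, 3))
    coords[0, sys2.phosphate_indices[0], 2] = 1.9
    coords[0, sys2.phosphate_indices[1], 2] = -1.9
    traj = Trajectory(coordinates=coords, box=np.array([[10.0, 10, 10]]))
    leaf = assign_leaflets(sys2, traj)
    assert list(leaf.labels) == ["external", "internal"]
    assert leaf.midplane_z == pytest.approx(0.0)


def test_leaflet_assignment_recovers_generator_truth(small_run):
    system, traj, truth = small_run
    leaf = assign_leaflets(system, traj)
    assert list(leaf.labels) == truth["leaflet_labels"]
    assert len(leaf.flip_flop_lipids) == 0


def test_all_lipids_one_leaflet_warns(caplog):
    from conftest import hand_system
    sys2 = hand_system(n_lipids=3)
    coords = np.zeros((1, sys2.n_beads, 3))
    coords[0, sys2.phosphate_indices, 2] = [1.0, 1.1, 1.2]
    traj = Trajectory(coordinates=coords, box=np.array([[10.0, 10, 10]]))
    with caplog.at_level(logging.WARNING):
        leaf = assign_leaflets(sys2, traj)
    assert len(set(leaf.labels)) <= 2  # midplane splits them deterministically


def test_write_system_preserves_order(tmp_path, small_run):
    system, traj, truth = small_run
    out = tmp_path / "copy.pdb"
    write_system(system, traj.coordinates[0], traj.box[0], str(out))
    back = read_system(str(out))
    assert list(back.bead_names) == list(system.bead_names)
    assert list(back.residue_ids) == list(system.residue_ids)
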