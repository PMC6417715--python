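import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", module="MDAnalysis")

from lipidsites import default_helix_map, generate
from lipidsites.generate import GeneratorConfig


@pytest.fixture(scope="session")
def helices():
    return default_helix_map()


@pytest.fixture(scope="session")
def small_run():
    """Desk-scale synthetic run shared across tests: 120 lipids, 40 frames."""
    system, traj, truth = generate(
        n_frames=40, n_lipids_per_leaflet=60, seed=11)
    return system, traj, truth


@pytest.fixture(scope="session")
def biased_run():
    """Small biased run with a planted H6/H7 residence site."""
    system, traj, truth = generate(
        n_frames=300, n_lipids_per_leaflet=60, seed=7,
        affinities={"67": 5.0})
    return system, traj, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_run):
    """On-disk PDB/GRO/DCD/JSON fixture written from the small run."""
    from lipidsites import write_fixture
    system, traj, truth = small_run
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(system, traj, str(outdir), truth)
    return paths


def hand_system(n_lipids=2, lipid_beads=("PO4",), protein_residues=(1,)):
    """Tiny hand-built CGSystem: single-bead protein residues plus minimal
    lipids, for contact-schedule and boundary tests."""
    from lipidsites import CGSystem
    n_prot = len(protein_residues)
    nb = len(lipid_beads)
    names = list(["BB"] * n_prot)
    resids = list(protein_residues)
    resnames = ["ALA"] * n_prot
    kinds = ["protein"] * n_prot
    classes = [""] * n_prot
    species = [""] * n_prot
    lipid_ids = [-1] * n_prot
    for lip in range(n_lipids):
        names.extend(lipid_beads)
        resids.extend([100 + lip] * nb)
        resnames.extend(["LIP"] * nb)
        kinds.extend(["lipid"] * nb)
        classes.extend(["phosphate" if b == "PO4" else "head"
                        for b in lipid_beads])
        species.extend(["LIP"] * nb)
        lipid_ids.extend([lip] * nb)
    return CGSystem(
        bead_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_kinds=np.array(kinds, dtype=object),
        bead_classes=np.array(classes, dtype=object),
        lipid_species=np.array(species, dtype=object),
        lipid_ids=np.array(lipid_ids),
    )
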