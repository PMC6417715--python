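"""Structure/trajectory reading and leaflet assignment.

File parsing is delegated to MDAnalysis (PDB, GRO, DCD, XTC dialects); this
module classifies beads into the package's :class:`~lipidsites.system.CGSystem`
topology and converts everything to nm.  MDAnalysis reports coordinates in
Angstrom regardless of the source format's native unit, so a single /10
conversion covers both Angstrom-native (PDB, DCD) and nm-native (GRO, XTC)
inputs.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .system import (
    CGSystem,
    DEFAULT_SPECIES,
    LeafletAssignment,
    PROTEIN_RESNAMES,
    Trajectory,
    classify_bead,
    _ION_NAMES,
    _SOLVENT_NAMES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_species_table",
    "read_system",
    "read_trajectory",
    "write_system",
    "assign_leaflets",
]

ANGSTROM_PER_NM = 10.0


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def load_species_table(path: Optional[str] = None) -> Mapping[str, Tuple[str, ...]]:
    """Load a species table (residue name -> ordered bead names) from YAML.

    Without a path the shipped POPC/DPPC/POPE defaults are returned.  The
    YAML schema is ``{SPECIES: {beads: [CHO, PO4, ...]}}`` or simply
    ``{SPECIES: [CHO, PO4, ...]}``.
    """
    if path is None:
        return dict(DEFAULT_SPECIES)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = {}
    for species, entry in raw.items():
        beads = entry["beads"] if isinstance(entry, Mapping) else entry
        table[str(species)] = tuple(str(b) for b in beads)
    for species, beads in table.items():
        if "PO4" not in beads:
            raise ValueError(f"species {species} has no PO4 bead")
    return table


def _check_orthorhombic(dimensions, where: str) -> np.ndarray:
    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        raise ValueError(f"{where}: missing or degenerate box")
    dims = np.asarray(dimensions, dtype=np.float64)
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise ValueError(
            f"{where}: triclinic box (angles {dims[3:6]}) not supported; "
            "orthorhombic boxes only")
    return dims[:3] / ANGSTROM_PER_NM


def read_system(structure_path: str,
                species_table: Optional[Mapping[str, Sequence[str]]] = None,
                ) -> CGSystem:
    """Read a PDB/GRO structure and classify every bead.

    Residues whose name appears in the species table become lipids (their
    bead names must match the table's ordered list and include exactly one
    PO4); standard amino-acid residue names become protein; known
    water/ion names become solvent/ion, as does anything unrecognised.
    """
    mda = _import_mda()
    if species_table is None:
        species_table = load_species_table()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(structure_path)

    n = len(u.atoms)
    bead_names = np.array([a.name for a in u.atoms], dtype=object)
    residue_ids = np.array([a.resid for a in u.atoms], dtype=np.int64)
    residue_names = np.array([a.resname.strip() for a in u.atoms], dtype=object)
    kinds = np.empty(n, dtype=object)
    classes = np.full(n, "", dtype=object)
    species = np.full(n, "", dtype=object)
    lipid_ids = np.full(n, -1, dtype=np.int64)

    next_lipid = 0
    for res in u.residues:
        idx = res.atoms.ix
        rname = res.resname.strip()
        if rname in species_table:
            expected = tuple(species_table[rname])
            got = tuple(bead_names[idx])
            if got != expected:
                raise ValueError(
                    f"lipid residue {rname} {res.resid}: bead names {got} do "
                    f"not match species table {expected}")
            kinds[idx] = "lipid"
            species[idx] = rname
            classes[idx] = [classify_bead(b) for b in got]
            lipid_ids[idx] = next_lipid
            next_lipid += 1
        elif rname in PROTEIN_RESNAMES:
            kinds[idx] = "protein"
        elif rname in _ION_NAMES:
            kinds[idx] = "ion"
        else:
            if rname not in _SOLVENT_NAMES:
                logger.warning("residue %s %d unrecognised; classified as solvent",
                               rname, res.resid)
            kinds[idx] = "solvent"

    return CGSystem(
        bead_names=bead_names,
        residue_ids=residue_ids,
        residue_names=residue_names,
        molecule_kinds=kinds,
        bead_classes=classes,
        lipid_species=species,
        lipid_ids=lipid_ids,
        source_path=structure_path,
    )


def read_trajectory(trajectory_path: str,
                    system: CGSystem,
                    frame_stride: int = 1) -> Trajectory:
    """Read a DCD/XTC/GRO/PDB trajectory into nm coordinates + per-frame box.

    The frame atom count must match ``system``; every frame must carry a
    strictly positive orthorhombic box.
    """
    mda = _import_mda()
    if system.source_path is None:
        raise ValueError("system has no source structure to use as topology")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(system.source_path, trajectory_path)
    if len(u.atoms) != system.n_beads:
        raise ValueError(
            f"atom-count mismatch: trajectory has {len(u.atoms)} atoms, "
            f"system has {system.n_beads} beads")
    coords = []
    boxes = []
    for ts in u.trajectory:
        coords.append(ts.positions / ANGSTROM_PER_NM)
        boxes.append(_check_orthorhombic(ts.dimensions,
                                         f"{trajectory_path} frame {ts.frame}"))
    return Trajectory(
        coordinates=np.asarray(coords, dtype=np.float64),
        box=np.asarray(boxes, dtype=np.float64),
        frame_stride=frame_stride,
    )


def write_system(system: CGSystem, coordinates_nm: np.ndarray,
                 box_nm: np.ndarray, path: str) -> None:
    """Write a single-frame structure (format from the file extension)."""
    mda = _import_mda()
    resid_breaks = np.flatnonzero(
        (np.diff(system.residue_ids) != 0)
        | (system.residue_names[1:] != system.residue_names[:-1])) + 1
    starts = np.concatenate(([0], resid_breaks))
    n_res = len(starts)
    atom_resindex = np.zeros(system.n_beads, dtype=np.int64)
    for i, s in enumerate(starts):
        atom_resindex[s:] = i
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=system.n_beads, n_residues=n_res,
            atom_resindex=atom_resindex, n_segments=1,
            residue_segindex=np.zeros(n_res, dtype=np.int64),
            trajectory=True)
        u.add_TopologyAttr("names", list(system.bead_names))
        u.add_TopologyAttr("resnames", list(system.residue_names[starts]))
        u.add_TopologyAttr("resids", list(system.residue_ids[starts]))
        u.atoms.positions = np.asarray(coordinates_nm, dtype=np.float64) * ANGSTROM_PER_NM
        u.dimensions = [box_nm[0] * 10, box_nm[1] * 10, box_nm[2] * 10, 90, 90, 90]
        u.atoms.write(path)


def assign_leaflets(system: CGSystem, traj: Trajectory,
                    reference_frame: int = 0,
                    flip_flop_fraction: float = 0.10) -> LeafletAssignment:
    """Assign every lipid to the external or internal leaflet.

    The midplane is the mean z of all phosphate beads in the reference
    frame; a lipid is external iff its phosphate sits above the midplane
    there.  Assignment is fixed for the whole trajectory; lipids whose
    frame-by-frame side differs from the assignment in more than
    ``flip_flop_fraction`` of frames are reported (and logged) as flip-flop
    suspects.
    """
    if system.n_lipids == 0:
        raise ValueError("no lipids present")
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError("reference_frame out of range")
    po4 = system.phosphate_indices
    z_ref = traj.coordinates[reference_frame, po4, 2]
    midplane = float(np.mean(z_ref))
    external = z_ref > midplane
    labels = np.where(external, "external", "internal").astype(object)
    if labels[0] == labels[-1] and len(set(labels)) == 1:
        logger.warning("all lipids assigned to the %s leaflet", labels[0])

    # flip-flop audit over all frames against per-frame midplanes
    z_all = traj.coordinates[:, po4, 2]
    mid_all = z_all.mean(axis=1, keepdims=True)
    side_all = z_all > mid_all
    mismatch = np.mean(side_all != external[None, :], axis=0)
    flip = np.flatnonzero(mismatch > flip_flop_fraction)
    for lip in flip:
        logger.warning("lipid %d changes leaflet side in %.0f%% of frames",
                       lip, 100 * mismatch[lip])
    return LeafletAssignment(labels=labels, midplane_z=midplane,
                             flip_flop_lipids=flip)
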