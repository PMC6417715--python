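"""Rigid-body superposition (Kabsch) and whole/per-helix RMSD profiles.

Frames are aligned once on the full protein bead selection; per-helix RMSD
is then measured on each helix's beads without refitting, so a helix that
moves rigidly relative to the aligned bundle shows up with its full
displacement.  CG beads are weighted equally (no masses).  RMSD is reported
in Angstrom, the structural-biology convention.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .system import CGSystem, HelixMap, Trajectory

__all__ = ["kabsch", "superpose", "rmsd", "per_helix_rmsd"]


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising
    ``|R @ mobile.T + t - reference.T|``; both point sets (n, 3).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise ValueError("selection cardinality differs between frame and reference")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def superpose(frame_coords: np.ndarray, reference: np.ndarray,
              selection: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Superpose one frame onto the reference using the selected beads.

    Returns ``(rotation, translation, aligned_coords)`` where the rigid
    transform is fitted on ``selection`` (bead indices) and applied to all
    beads of the frame.  At least 3 non-collinear selected beads are
    required for a well-defined rotation.
    """
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise ValueError("empty selection")
    sel_ref = np.asarray(reference, dtype=np.float64)[selection]
    sel_mob = np.asarray(frame_coords, dtype=np.float64)[selection]
    centered = sel_mob - sel_mob.mean(axis=0)
    if len(selection) < 3 or np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("need at least 3 non-collinear beads to superpose")
    R, t = kabsch(sel_mob, sel_ref)
    aligned = np.asarray(frame_coords, dtype=np.float64) @ R.T + t
    return R, t, aligned


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain root-mean-square deviation between two (n, 3) point sets."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def per_helix_rmsd(traj: Trajectory, reference: np.ndarray, system: CGSystem,
                   helices: HelixMap) -> pd.DataFrame:
    """Whole-protein and per-helix RMSD series (Angstrom) after global fit.

    ``reference`` is the full-system reference coordinate set in nm
    (typically frame 0 or the starting structure).  Each frame is fitted on
    all protein beads; RMSD is then evaluated on the whole protein
    ("all") and on each helix's beads without refitting.
    """
    pidx = system.protein_indices
    if len(pidx) == 0:
        raise ValueError("system has no protein beads")
    resids = system.residue_ids[pidx]
    prot_resid_set = set(int(r) for r in resids)
    helix_beads = {}
    for h in helices:
        for r in range(h.begin, h.end + 1):
            if r not in prot_resid_set:
                raise ValueError(
                    f"helix {h.helix_id} residue {r} outside protein residues")
        helix_beads[h.helix_id] = pidx[(resids >= h.begin) & (resids <= h.end)]
    ref = np.asarray(reference, dtype=np.float64)
    rows = []
    for f in range(traj.n_frames):
        _, _, aligned = superpose(traj.coordinates[f], ref, pidx)
        rows.append((f, "all", 10.0 * rmsd(aligned[pidx], ref[pidx])))
        for hid, beads in helix_beads.items():
            rows.append((f, str(hid), 10.0 * rmsd(aligned[beads], ref[beads])))
    return pd.DataFrame(rows, columns=["frame", "helix", "rmsd_A"])
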