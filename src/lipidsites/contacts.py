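"""Protein-lipid contact detection and contact-frequency maps.

A contact is a (protein bead, lipid bead) pair at minimum-image distance
strictly below the cutoff (0.5 nm by default, with 0.6 and 0.7 nm used for
sensitivity analysis).  Neighbor search is a vectorised cell-list grid in
float64, contractually identical to the all-pairs computation
(:func:`brute_force_pairs` is the slow reference used to validate it).

:func:`scan_contacts` runs the search over a whole trajectory with an
annular-shell prefilter: only lipids whose anchor bead lies within
``protein xy extent + lipid extent + cutoff`` of the protein in the membrane
plane can contribute a contact, so the exact bead-pair check is restricted
to that shell.  The prefilter bound follows from the triangle inequality on
the flat-torus metric and never discards a true contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .system import CGSystem, HelixMap, Trajectory, classify_bead

logger = logging.getLogger(__name__)

_KERNEL = None


def _static_kernel():
    # lazy import: numba compilation is deferred until a static-protein
    # trajectory is actually scanned; False when numba is unavailable
    global _KERNEL
    if _KERNEL is None:
        try:
            from ._kernels import static_contact_kernel
            _KERNEL = static_contact_kernel
        except ImportError:
            _KERNEL = False
    return _KERNEL


__all__ = [
    "periodic_pairs",
    "brute_force_pairs",
    "find_contacts",
    "scan_contacts",
    "ContactTable",
    "frequency_map",
    "cutoff_sensitivity",
]


def _check_cutoff(cutoff: float, box: np.ndarray) -> None:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > float(np.min(box)) / 2:
        raise ValueError(
            f"cutoff {cutoff} exceeds half the smallest box length "
            f"({np.min(box) / 2:.3f}); minimum-image convention violated")


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.rint(d / box)


def periodic_pairs(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                   cutoff: float) -> np.ndarray:
    """All (i, j) with minimum-image ``|a[i] - b[j]| < cutoff`` (strict).

    Cell-list grid on the orthorhombic box ``box`` (nm); exact float64
    distances decide membership.  Pairs are returned lexicographically
    sorted, shape (n_pairs, 2).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    box = np.asarray(box, dtype=np.float64)
    _check_cutoff(cutoff, box)
    if len(a) == 0 or len(b) == 0:
        return np.empty((0, 2), dtype=np.int64)

    aw = a - box * np.floor(a / box)
    bw = b - box * np.floor(b / box)
    ncell = np.maximum(1, (box / cutoff).astype(np.int64))
    width = box / ncell

    def cell_of(x):
        c = (x / width).astype(np.int64)
        return np.minimum(c, ncell - 1)

    def lin(c):
        return (c[:, 0] * ncell[1] + c[:, 1]) * ncell[2] + c[:, 2]

    la = lin(cell_of(aw))
    cb = cell_of(bw)
    order = np.argsort(la, kind="stable")
    la_sorted = la[order]

    # neighbor offsets, deduplicated modulo the cell grid (tiny boxes can
    # have fewer than 3 cells along an axis, making offsets coincide)
    offsets, seen = [], set()
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                key = (dx % ncell[0], dy % ncell[1], dz % ncell[2])
                if key not in seen:
                    seen.add(key)
                    offsets.append(key)
    need_dedupe = len(offsets) < 27

    cand_i: List[np.ndarray] = []
    cand_j: List[np.ndarray] = []
    nb_idx = np.arange(len(b), dtype=np.int64)
    for off in offsets:
        tc = (cb + np.asarray(off, dtype=np.int64)) % ncell
        lt = lin(tc)
        left = np.searchsorted(la_sorted, lt, side="left")
        right = np.searchsorted(la_sorted, lt, side="right")
        cnt = right - left
        tot = int(cnt.sum())
        if tot == 0:
            continue
        j = np.repeat(nb_idx, cnt)
        run = np.arange(tot, dtype=np.int64) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        i = order[np.repeat(left, cnt) + run]
        cand_i.append(i)
        cand_j.append(j)
    if not cand_i:
        return np.empty((0, 2), dtype=np.int64)
    i = np.concatenate(cand_i)
    j = np.concatenate(cand_j)
    if need_dedupe:
        key = i * len(b) + j
        _, keep = np.unique(key, return_index=True)
        i, j = i[keep], j[keep]
    d = _min_image(aw[i] - bw[j], box)
    inside = np.einsum("ij,ij->i", d, d) < cutoff * cutoff
    i, j = i[inside], j[inside]
    order2 = np.lexsort((j, i))
    return np.column_stack((i[order2], j[order2]))


def brute_force_pairs(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                      cutoff: float) -> np.ndarray:
    """O(N*M) all-pairs reference for :func:`periodic_pairs` (validation only)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    box = np.asarray(box, dtype=np.float64)
    _check_cutoff(cutoff, box)
    out = []
    cut2 = cutoff * cutoff
    for i0 in range(0, len(a), 512):
        d = a[i0:i0 + 512, None, :] - b[None, :, :]
        d = _min_image(d, box)
        ii, jj = np.nonzero((d * d).sum(axis=2) < cut2)
        out.append(np.column_stack((ii + i0, jj)))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.concatenate(out)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def find_contacts(frame_coords: np.ndarray, box: np.ndarray,
                  protein_beads: np.ndarray, lipid_beads: np.ndarray,
                  cutoff: float) -> np.ndarray:
    """Contacting (protein bead, lipid bead) global-index pairs in one frame."""
    protein_beads = np.asarray(protein_beads, dtype=np.int64)
    lipid_beads = np.asarray(lipid_beads, dtype=np.int64)
    local = periodic_pairs(frame_coords[protein_beads],
                           frame_coords[lipid_beads], box, cutoff)
    return np.column_stack((protein_beads[local[:, 0]],
                            lipid_beads[local[:, 1]]))


@dataclass
class ContactTable:
    """Accumulated contact counts and per-frame occupancy events.

    ``counts[species]`` has shape (n protein residues, n beads of species):
    total bead-pair contacts summed over frames.  ``events[f, l]`` records
    whether lipid ``l`` touches any protein bead in frame ``f`` (used by the
    site-network occupancy filter).  ``site_bits[f, l]`` is a bitmask of the
    helices the lipid touches (bit h-1 for helix h), present when the scan
    was given a helix map.
    """

    cutoff: float
    n_frames: int
    residue_ids: np.ndarray
    residue_names: np.ndarray
    counts: Dict[str, np.ndarray]
    bead_names: Dict[str, Tuple[str, ...]]
    events: np.ndarray
    site_bits: Optional[np.ndarray] = None

    def residue_totals(self) -> np.ndarray:
        """Total contact count per protein residue (all species, all beads)."""
        tot = np.zeros(len(self.residue_ids), dtype=np.int64)
        for mat in self.counts.values():
            tot += mat.sum(axis=1)
        return tot

    def per_class_counts(self, species: str) -> pd.Series:
        """Counts aggregated by lipid bead class for one species."""
        classes = [classify_bead(b) for b in self.bead_names[species]]
        per_bead = self.counts[species].sum(axis=0)
        return pd.Series(per_bead).groupby(classes).sum()

    def to_frame(self, helices: Optional[HelixMap] = None) -> pd.DataFrame:
        """Long-format table: residue x species x bead name -> count."""
        rows = []
        hel = (helices.residue_to_helix_array(self.residue_ids)
               if helices is not None else np.zeros(len(self.residue_ids), int))
        for species, mat in sorted(self.counts.items()):
            names = self.bead_names[species]
            for r, (resid, resname) in enumerate(
                    zip(self.residue_ids, self.residue_names)):
                for bcol, bname in enumerate(names):
                    rows.append((int(resid), str(resname),
                                 int(hel[r]) or None, species, bname,
                                 classify_bead(bname), self.cutoff,
                                 int(mat[r, bcol])))
        return pd.DataFrame(rows, columns=[
            "residue", "residue_name", "helix", "lipid_species", "bead_name",
            "bead_class", "cutoff", "count"])

    @staticmethod
    def merge(tables: Sequence["ContactTable"]) -> "ContactTable":
        """Pool replicate runs: counts summed, events concatenated in time."""
        first = tables[0]
        for t in tables[1:]:
            if t.cutoff != first.cutoff:
                raise ValueError("cannot merge tables with different cutoffs")
            if not np.array_equal(t.residue_ids, first.residue_ids):
                raise ValueError("cannot merge tables with different residues")
        counts = {sp: sum(t.counts[sp] for t in tables) for sp in first.counts}
        has_bits = all(t.site_bits is not None for t in tables)
        return ContactTable(
            cutoff=first.cutoff,
            n_frames=sum(t.n_frames for t in tables),
            residue_ids=first.residue_ids,
            residue_names=first.residue_names,
            counts=counts,
            bead_names=first.bead_names,
            events=np.concatenate([t.events for t in tables], axis=0),
            site_bits=(np.concatenate([t.site_bits for t in tables], axis=0)
                       if has_bits else None),
        )


def scan_contacts(traj: Trajectory, system: CGSystem, cutoff: float,
                  helices: Optional[HelixMap] = None,
                  chunk_frames: int = 256,
                  compute_counts: bool = True) -> ContactTable:
    """Accumulate protein-lipid contacts over every frame of a trajectory.

    Single pass, chunked over frames; produces bead-pair counts (unless
    ``compute_counts=False``), per-lipid any-contact events and, when a
    helix map is given, the per-frame helix-set bitmask that the
    site-network stage consumes.  Equivalent to calling
    :func:`find_contacts` frame by frame (asserted in the test suite).
    """
    pidx = system.protein_indices
    n_lip = system.n_lipids
    F = traj.n_frames

    res_ids = system.protein_residues()
    prot_resids_per_bead = system.residue_ids[pidx]
    res_pos = {int(r): k for k, r in enumerate(res_ids)}
    res_index_of_pbead = np.array(
        [res_pos[int(r)] for r in prot_resids_per_bead], dtype=np.int64)
    name_of_res = {}
    for bead, resid in zip(pidx, prot_resids_per_bead):
        name_of_res.setdefault(int(resid), str(system.residue_names[bead]))
    res_names = np.array([name_of_res[int(r)] for r in res_ids], dtype=object)

    events = np.zeros((F, n_lip), dtype=bool)
    site_bits = np.zeros((F, n_lip), dtype=np.uint16) if helices is not None else None
    helix_bits_of_pbead = None
    if helices is not None:
        hnum = helices.residue_to_helix_array(prot_resids_per_bead)
        helix_bits_of_pbead = np.where(
            hnum > 0, (1 << np.maximum(hnum - 1, 0)), 0).astype(np.uint16)

    # species groups: bead-index matrix per species (uniform bead count)
    species_of_lipid = system.species_of_lipid()
    groups = {}
    for sp in np.unique(species_of_lipid):
        lips = np.flatnonzero(species_of_lipid == sp)
        nb = int(system.lipid_counts[lips[0]])
        bead_mat = system.lipid_starts[lips][:, None] + np.arange(nb)[None, :]
        names = tuple(system.bead_names[bead_mat[0]])
        groups[str(sp)] = (lips, bead_mat, names)

    counts = {sp: np.zeros((len(res_ids), bead_mat.shape[1]), dtype=np.int64)
              for sp, (_, bead_mat, _) in groups.items()}
    bead_names = {sp: names for sp, (_, _, names) in groups.items()}

    if F == 0 or len(pidx) == 0 or n_lip == 0:
        return ContactTable(cutoff, F, res_ids, res_names, counts, bead_names,
                            events, site_bits)
    _check_cutoff(cutoff, traj.box.min(axis=0))
    cut2 = cutoff * cutoff
    _hbits_arr = (helix_bits_of_pbead if helix_bits_of_pbead is not None
                  else np.zeros(len(pidx), dtype=np.uint16))

    n_prot = len(pidx)

    def _record(sp, frames_abs, glipids, ic, ib, ij):
        """Fold true pairs (candidate ic, lipid bead ib, protein bead ij)
        into events / counts / helix site bits."""
        if len(ic) == 0:
            return
        events[frames_abs[ic], glipids[ic]] = True
        if compute_counts:
            np.add.at(counts[sp], (res_index_of_pbead[ij], ib), 1)
        if site_bits is not None:
            nc = len(frames_abs)
            pair_any = np.zeros((nc, n_prot), dtype=bool)
            pair_any[ic, ij] = True
            bits = np.bitwise_or.reduce(
                np.where(pair_any, helix_bits_of_pbead[None, :], 0),
                axis=1).astype(np.uint16)
            np.bitwise_or.at(site_bits, (frames_abs, glipids), bits)

    for f0 in range(0, F, chunk_frames):
        f1 = min(F, f0 + chunk_frames)
        box = traj.box[f0:f1]                                  # (C, 3)
        P = np.asarray(traj.coordinates[f0:f1][:, pidx], dtype=np.float64)
        # unwrap the protein around its first bead, then bound its xy extent
        # from the centroid of the unwrapped cloud
        p0 = P[:, 0, :]
        Q = p0[:, None, :] + _min_image(P - p0[:, None, :], box[:, None, :])
        pc = Q.mean(axis=1)                                    # (C, 3)
        rp_xy = np.sqrt(((Q[:, :, :2] - pc[:, None, :2]) ** 2)
                        .sum(-1)).max(axis=1)                  # (C,)

        # prefilter every species: candidate (frame, lipid) pairs whose
        # anchor bead is within protein-extent + lipid-extent + cutoff of
        # the protein center in the membrane plane.  Bounds are computed in
        # float32 with an epsilon pad (they only gate the exact float64
        # check, so rounding can never lose a contact).
        eps = 1e-3
        chunk_data = {}
        max_rl3 = 0.0
        for sp, (lips, bead_mat, _) in groups.items():
            Lc = np.ascontiguousarray(traj.coordinates[f0:f1][:, bead_mat])
            boxC = box.astype(Lc.dtype)
            # anchor = middle bead: minimises the lipid extent radius that
            # the exact check has to cover
            mid = bead_mat.shape[1] // 2
            anchorC = Lc[:, :, mid, :]
            dl = Lc - anchorC[:, :, None, :]                   # (C, nl, nb, 3)
            bhalf = boxC[:, None, None, :] / 2
            bad = np.abs(dl) > bhalf
            if bad.any():
                bfull = np.broadcast_to(boxC[:, None, None, :], dl.shape)[bad]
                dl[bad] -= bfull * np.rint(dl[bad] / bfull)
            dl2 = np.einsum("...k,...k->...", dl, dl)
            rl3 = np.sqrt(dl2.max(axis=2)) + eps               # (C, nl)
            rl_xy = np.sqrt(
                np.einsum("...k,...k->...", dl[..., :2], dl[..., :2])
                .max(axis=2)) + eps
            dxy = _min_image(anchorC[:, :, :2].astype(np.float64)
                             - pc[:, None, :2], box[:, None, :2])
            dist_xy = np.sqrt((dxy ** 2).sum(-1))              # (C, nl)
            ci, cl = np.nonzero(dist_xy < rp_xy[:, None] + rl_xy + cutoff)
            if len(ci):
                max_rl3 = max(max_rl3, float(rl3[ci, cl].max()))
            chunk_data[sp] = (ci, cl, Lc)

        # protein static across the chunk (and box constant): plain
        # distances against one wrapped + ghost-image protein set replace
        # the per-frame minimum-image computation; a BLAS inner product
        # does the anchor-level stage
        static = bool(np.all(P == P[0]) and np.all(box == box[0]))
        margin = cutoff + max_rl3
        if static and margin < float(box[0].min()) / 2:
            bx = box[0]
            Pw = Q[0] - bx * np.floor(Q[0] / bx)
            ghost_xyz = [Pw]
            ghost_src = [np.arange(n_prot, dtype=np.int64)]
            for sx in (-1, 0, 1):
                for sy in (-1, 0, 1):
                    for sz in (-1, 0, 1):
                        if (sx, sy, sz) == (0, 0, 0):
                            continue
                        near = np.ones(n_prot, dtype=bool)
                        for k, s in enumerate((sx, sy, sz)):
                            if s == 1:
                                near &= Pw[:, k] < margin
                            elif s == -1:
                                near &= Pw[:, k] > bx[k] - margin
                        if near.any():
                            shift = np.array([sx, sy, sz], dtype=np.float64)
                            ghost_xyz.append(Pw[near] + shift * bx)
                            ghost_src.append(np.flatnonzero(near))
            Pg = np.concatenate(ghost_xyz)
            gsrc = np.concatenate(ghost_src)
            pnorm2 = (Pg ** 2).sum(axis=1)
            Pg32 = Pg.astype(np.float32)
            pnorm2_32 = pnorm2.astype(np.float32)
        else:
            static = False

        kernel = _static_kernel() if static else False
        for sp, (lips, bead_mat, _) in groups.items():
            ci, cl, Lc = chunk_data[sp]
            if len(ci) == 0:
                continue
            mid = bead_mat.shape[1] // 2
            glip = lips[cl]
            sub = 8192 if static else 512
            for s0 in range(0, len(ci), sub):
                s1 = min(len(ci), s0 + sub)
                sci, scl = ci[s0:s1], cl[s0:s1]
                LB = Lc[sci, scl].astype(np.float64)          # (nc, nb, 3)
                a_raw = LB[:, mid, :]
                if static and kernel:
                    A0 = a_raw - bx * np.floor(a_raw / bx)     # (nc, 3)
                    dlc = _min_image(LB - a_raw[:, None, :], bx)
                    thr = (np.sqrt(np.einsum("ijk,ijk->ij", dlc, dlc)
                                   .max(axis=1)) + cutoff) ** 2
                    LBp = A0[:, None, :] + dlc
                    ev_out = np.zeros(len(sci), dtype=bool)
                    bits_out = np.zeros(len(sci), dtype=np.uint16)
                    kernel(LBp, A0, thr, Pg, gsrc, res_index_of_pbead,
                           _hbits_arr, cut2, counts[sp], compute_counts,
                           bits_out, ev_out)
                    hit = ev_out
                    if hit.any():
                        events[f0 + sci[hit], glip[s0:s1][hit]] = True
                        if site_bits is not None:
                            np.bitwise_or.at(
                                site_bits, (f0 + sci[hit], glip[s0:s1][hit]),
                                bits_out[hit])
                    continue
                if static:
                    # stage 1 (float32, padded threshold): anchors against
                    # the ghosted protein set; only gates the exact check
                    A0 = a_raw - bx * np.floor(a_raw / bx)     # (nc, 3)
                    dlc = _min_image(LB - a_raw[:, None, :], bx)
                    thr = (np.sqrt(np.einsum("ijk,ijk->ij", dlc, dlc)
                                   .max(axis=1)) + cutoff + eps) ** 2
                    A032 = A0.astype(np.float32)
                    d2a = ((A032 ** 2).sum(axis=1)[:, None]
                           + pnorm2_32[None, :] - 2.0 * (A032 @ Pg32.T))
                    hc, hj = np.nonzero(d2a < thr[:, None].astype(np.float32))
                    if len(hc) == 0:
                        continue
                    # stage 2: bead-level distances for near pairs only
                    LBp = A0[:, None, :] + dlc                 # (nc, nb, 3)
                    diff = LBp[hc] - Pg[hj][:, None, :]
                    d2 = np.einsum("ijk,ijk->ij", diff, diff)  # (nh, nb)
                    ih, ib = np.nonzero(d2 < cut2)
                    ic, ij = hc[ih], gsrc[hj[ih]]
                else:
                    PB = P[sci]                                # (nc, np, 3)
                    diff = LB[:, :, None, :] - PB[:, None, :, :]
                    diff = _min_image(diff, box[sci][:, None, None, :])
                    mask = np.einsum("icjk,icjk->icj", diff, diff) < cut2
                    ic, ib, ij = np.nonzero(mask)
                _record(sp, f0 + sci, glip[s0:s1], ic, ib, ij)
    return ContactTable(cutoff, F, res_ids, res_names, counts, bead_names,
                        events, site_bits)


def frequency_map(table: ContactTable) -> pd.DataFrame:
    """Per-residue contact frequency as a percentage of the most-contacted
    residue (the conventional yellow-to-red 0-100% coloring scale).

    Residues with zero contacts map to 0; when any contact exists the
    maximum is exactly 100.
    """
    totals = table.residue_totals()
    peak = totals.max() if len(totals) else 0
    if peak == 0:
        logger.warning("all-zero contact table; frequency map is all zeros")
        pct = np.zeros(len(totals))
    else:
        pct = 100.0 * totals / peak
    return pd.DataFrame({
        "residue": table.residue_ids.astype(int),
        "residue_name": table.residue_names,
        "count": totals,
        "frequency_pct": pct,
    })


def cutoff_sensitivity(traj: Trajectory, system: CGSystem,
                       cutoffs: Sequence[float] = (0.5, 0.6, 0.7),
                       helices: Optional[HelixMap] = None,
                       ) -> Tuple[Dict[float, pd.DataFrame], pd.DataFrame]:
    """Frequency maps at several cutoffs plus their Spearman rank agreement.

    Rank agreement is computed over residues with a nonzero count at the
    largest cutoff (a superset of the nonzero set at any smaller cutoff, by
    monotonicity of counts in the cutoff).
    """
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be sorted ascending")
    maps = {}
    for c in cutoffs:
        table = scan_contacts(traj, system, c, helices=helices)
        maps[c] = frequency_map(table)
    largest = maps[cutoffs[-1]]
    nonzero = largest["count"].to_numpy() > 0
    rows = []
    for i, c1 in enumerate(cutoffs):
        for c2 in cutoffs[i + 1:]:
            f1 = maps[c1]["frequency_pct"].to_numpy()[nonzero]
            f2 = maps[c2]["frequency_pct"].to_numpy()[nonzero]
            rho = spearmanr(f1, f2).statistic if nonzero.sum() > 1 else np.nan
            rows.append((c1, c2, rho))
    agreement = pd.DataFrame(rows, columns=["cutoff_a", "cutoff_b", "spearman_rho"])
    return maps, agreement
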