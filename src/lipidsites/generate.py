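"""Synthetic coarse-grained bilayer + helix-bundle trajectory generator.

Emulates the study systems at desk scale with known ground truth: a static
ring-shaped bundle of 8 ideal helices (one backbone bead per residue,
residue ranges of the GPCR helix table) spanning a two-leaflet bilayer of
12-13-bead lipids.  Lipids are kinematic: they perform lateral 2D Gaussian
random walks with periodic wrapping, are excluded from the protein core
disk, and linger near configured helix-combination sites (their step size
is divided by the site's residence-affinity multiplier inside an
interaction shell).  Head/phosphate/glycerol/tail beads ride at fixed
intra-lipid offsets, so the planted area per lipid, bilayer thickness and
leaflet labels are recovered exactly by the analysis modules.

Identical config + seed reproduces the trajectory bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .system import (
    CGSystem,
    DEFAULT_SPECIES,
    HelixMap,
    Trajectory,
    classify_bead,
    default_helix_map,
)

__all__ = ["GeneratorConfig", "build_protein", "simulate_lipids", "generate",
           "write_fixture"]

_RISE_PER_RESIDUE_NM = 0.25    # CG backbone rise along the helix axis
_TURN_DEG_PER_RESIDUE = 100.0  # alpha-helical twist


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic run.

    The defaults are the conditions exercised throughout: a pure POPC
    bilayer of 600 lipids (300 per leaflet) at 67.68 A^2 per lipid and
    42 A phosphate-phosphate thickness, 5000 saved frames of
    lateral diffusion.  ``affinities`` plants residence sites: e.g.
    ``{"67": 5.0}`` makes lipids inside the interaction shell of the
    H6/H7 face take 5x smaller diffusion steps.
    """

    species: str = "POPC"
    n_lipids_per_leaflet: int = 300
    area_per_lipid_A2: float = 67.68
    thickness_A: float = 42.0
    box_lz_nm: float = 9.0
    n_frames: int = 5000
    frame_stride: int = 10 ** 6          # saved-iteration interval (metadata)
    step_sigma_nm: float = 0.3           # lateral step std per saved frame
    affinities: Dict[str, float] = field(default_factory=dict)
    interaction_shell_nm: float = 0.7
    bundle_radius_nm: float = 1.4
    helix_radius_nm: float = 0.23
    exclusion_radius_nm: float = 1.6     # protein core disk lipids cannot enter
    min_spacing_nm: float = 0.55         # initial lipid-lipid spacing
    z_jitter_nm: float = 0.02            # per-frame whole-lipid z noise
    helix_tilts_deg: Dict[int, float] = field(default_factory=dict)
    helix_kink_bend_deg: Dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for label, mult in self.affinities.items():
            if mult < 1:
                raise ValueError(
                    f"affinity multiplier for site {label} must be >= 1")
        if self.species not in DEFAULT_SPECIES:
            raise ValueError(f"unknown lipid species {self.species!r}")

    @property
    def box_nm(self) -> np.ndarray:
        lx = np.sqrt(self.n_lipids_per_leaflet * self.area_per_lipid_A2) / 10.0
        return np.array([lx, lx, self.box_lz_nm])

    def helix_map(self) -> HelixMap:
        return default_helix_map()


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    a = np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def build_protein(config: GeneratorConfig
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static helix-bundle coordinates.

    Returns ``(coords_nm, residue_ids, helix_of_residue)``: one backbone
    bead per residue, helices placed on a ring of ``bundle_radius_nm``
    around the box center with per-helix tilt and optional post-kink bend
    applied about the helix's tangential axis (so segment tilt angles add).
    """
    helices = config.helix_map()
    box = config.box_nm
    center = np.array([box[0] / 2, box[1] / 2, box[2] / 2])
    coords, resids, helix_of = [], [], []
    n_hel = len(helices)
    for slot, h in enumerate(helices):
        n = h.n_residues
        k = np.arange(n)
        ang = np.radians(_TURN_DEG_PER_RESIDUE) * k
        local = np.column_stack([
            config.helix_radius_nm * np.cos(ang),
            config.helix_radius_nm * np.sin(ang),
            _RISE_PER_RESIDUE_NM * k,
        ])
        local[:, 2] -= local[:, 2].mean()
        phi = 2 * np.pi * slot / n_hel
        # bend/tilt about the local y axis; the final rotation by phi about
        # z maps it onto the tangential direction of the bundle ring
        tangent = np.array([0.0, 1.0, 0.0])
        bend = config.helix_kink_bend_deg.get(h.helix_id, 0.0)
        if bend:
            if h.kink is None:
                raise ValueError(
                    f"helix {h.helix_id} has a configured bend but no kink")
            kb, ke = h.kink
            i_kb = kb - h.begin
            anchor = local[i_kb]
            R = _rotation_about(tangent, bend)
            post = h.begin + k >= ke
            zone = (h.begin + k > kb) & (h.begin + k < ke)
            local[post] = anchor + (local[post] - anchor) @ R.T
            Rhalf = _rotation_about(tangent, bend / 2.0)
            local[zone] = anchor + (local[zone] - anchor) @ Rhalf.T
        tilt = config.helix_tilts_deg.get(h.helix_id, 0.0)
        if tilt:
            local = local @ _rotation_about(tangent, tilt).T
        # rotate the spiral phase with the slot azimuth so equal-length
        # helices are exact rotated copies (azimuthal symmetry)
        local = local @ _rotation_about(np.array([0.0, 0.0, 1.0]),
                                        np.degrees(phi)).T
        offset = center + config.bundle_radius_nm * np.array(
            [np.cos(phi), np.sin(phi), 0.0])
        pts = local + offset
        # overlap guard: helices must not interpenetrate laterally
        for prev in coords:
            d = np.linalg.norm(prev[:, None, :2] - pts[None, :, :2], axis=-1)
            if d.min() < 0.1:
                raise ValueError(f"helix {h.helix_id} overlaps a previous helix")
        coords.append(pts)
        resids.append(np.arange(h.begin, h.end + 1))
        helix_of.append(np.full(n, h.helix_id))
    return (np.concatenate(coords), np.concatenate(resids),
            np.concatenate(helix_of))


def _site_anchors(config: GeneratorConfig) -> Dict[str, np.ndarray]:
    """xy anchor point of each planted site: the mean direction of its
    member helices, at the protein exclusion radius."""
    helices = config.helix_map()
    box = config.box_nm
    center = box[:2] / 2
    slot_of = {h.helix_id: i for i, h in enumerate(helices)}
    anchors = {}
    for label in config.affinities:
        dirs = []
        for ch in label:
            phi = 2 * np.pi * slot_of[int(ch)] / len(helices)
            dirs.append([np.cos(phi), np.sin(phi)])
        v = np.mean(dirs, axis=0)
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError(f"site {label}: member helices are antipodal, "
                             "anchor direction undefined")
        anchors[label] = center + config.exclusion_radius_nm * v / norm
    return anchors


def _lipid_template(config: GeneratorConfig) -> Tuple[Tuple[str, ...], np.ndarray]:
    """Per-bead (dx, dy, dz) offsets from the lipid lateral center, for the
    external leaflet (internal is the z mirror).  The phosphate bead sits
    exactly at +thickness/2, so the planted thickness is recovered."""
    beads = DEFAULT_SPECIES[config.species]
    z_po4 = config.thickness_A / 20.0   # A -> nm, half thickness
    offsets = np.zeros((len(beads), 3))
    tail_a = [b for b in beads if classify_bead(b) == "tailA"]
    tail_b = [b for b in beads if classify_bead(b) == "tailB"]
    for i, b in enumerate(beads):
        cls = classify_bead(b)
        if cls == "head":
            offsets[i] = (0.0, 0.10, z_po4 + 0.30)
        elif cls == "phosphate":
            offsets[i] = (0.0, 0.0, z_po4)
        elif cls == "glycerol":
            gl_rank = int(b[-1]) - 1 if b[-1].isdigit() else 0
            offsets[i] = (0.05 * (-1) ** gl_rank, 0.0, z_po4 - 0.25 - 0.15 * gl_rank)
        elif cls == "tailA":
            rank = tail_a.index(b)
            offsets[i] = (0.15, 0.0, z_po4 - 0.65 - 0.33 * rank)
        else:
            rank = tail_b.index(b)
            offsets[i] = (-0.15, 0.0, z_po4 - 0.65 - 0.28 * rank)
    return beads, offsets


def _place_initial(config: GeneratorConfig, rng: np.random.Generator
                   ) -> np.ndarray:
    """Initial lateral centers for both leaflets, outside the core disk and
    at least ``min_spacing_nm`` apart within each leaflet."""
    box = config.box_nm
    center = box[:2] / 2
    n = config.n_lipids_per_leaflet
    placed_all = []
    for _leaflet in range(2):
        placed = np.empty((0, 2))
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 400 * n:
                raise ValueError(
                    "lipid density too high to place lipids without overlap")
            p = rng.uniform(0, 1, 2) * box[:2]
            d = p - center
            if np.hypot(*d) < config.exclusion_radius_nm:
                continue
            if len(placed):
                dd = placed - p
                dd -= box[:2] * np.rint(dd / box[:2])
                if np.min(np.hypot(dd[:, 0], dd[:, 1])) < config.min_spacing_nm:
                    continue
            placed = np.vstack([placed, p])
        placed_all.append(placed)
    return np.concatenate(placed_all)


def simulate_lipids(config: GeneratorConfig
                    ) -> Tuple[CGSystem, Trajectory, Dict]:
    """Generate the full synthetic system, trajectory and ground truth.

    Lipid order: external leaflet first, then internal; protein beads come
    first in the system.  Ground truth records leaflet labels, planted
    affinities and descriptors.
    """
    rng = np.random.default_rng(config.seed)
    box = config.box_nm
    center = box[:2] / 2
    prot_xyz, prot_resids, _helix_of = build_protein(config)
    bead_names_l, offsets = _lipid_template(config)
    nb = len(bead_names_l)
    n_lip = 2 * config.n_lipids_per_leaflet
    F = config.n_frames
    anchors = _site_anchors(config)
    anchor_xy = np.array(list(anchors.values())) if anchors else np.empty((0, 2))
    mults = np.array([config.affinities[k] for k in anchors], dtype=float)

    centers = _place_initial(config, rng)            # (n_lip, 2)
    centers_t = np.empty((F, n_lip, 2), dtype=np.float64)
    if F:
        centers_t[0] = centers
    pos = centers.copy()
    box2 = box[:2]
    shell2 = config.interaction_shell_nm ** 2
    excl2 = config.exclusion_radius_nm ** 2
    steps = rng.normal(0.0, 1.0, (max(F - 1, 0), n_lip, 2))
    for t in range(1, F):
        step = steps[t - 1] * config.step_sigma_nm
        if len(anchor_xy):
            # residence bias: inside a site's interaction shell the
            # diffusion step shrinks by the affinity multiplier, so the
            # lipid lingers near the site (slow escape from the shell)
            d = pos[:, None, :] - anchor_xy[None, :, :]
            d -= box2 * np.rint(d / box2)
            d2 = (d * d).sum(axis=2)
            eff = np.where(d2 < shell2, mults[None, :], 1.0).max(axis=1)
            step /= eff[:, None]
        new = (pos + step) % box2
        dc = new - center
        dc -= box2 * np.rint(dc / box2)
        blocked = (dc * dc).sum(axis=1) < excl2
        new[blocked] = pos[blocked]
        pos = new
        centers_t[t] = pos

    z_mid = box[2] / 2
    leaflet_sign = np.concatenate([
        np.ones(config.n_lipids_per_leaflet),
        -np.ones(config.n_lipids_per_leaflet)]).astype(np.float32)
    z_jit = (rng.normal(0.0, config.z_jitter_nm, (F, n_lip))
             if config.z_jitter_nm > 0 else np.zeros((F, n_lip)))

    n_prot = len(prot_xyz)
    coords = np.empty((F, n_prot + n_lip * nb, 3), dtype=np.float32)
    off32 = offsets.astype(np.float32)
    box32 = box2.astype(np.float32)
    zj32 = z_jit.astype(np.float32)
    c32 = centers_t.astype(np.float32)
    for f0 in range(0, F, 500):
        f1 = min(F, f0 + 500)
        coords[f0:f1, :n_prot] = prot_xyz[None, :, :]
        nfc = f1 - f0
        lip = np.empty((nfc, n_lip, nb, 3), dtype=np.float32)
        lip[..., :2] = (c32[f0:f1, :, None, :] + off32[None, None, :, :2]) % box32
        lip[..., 2] = (np.float32(z_mid)
                       + leaflet_sign[None, :, None] * off32[None, None, :, 2]
                       + zj32[f0:f1, :, None])
        coords[f0:f1, n_prot:] = lip.reshape(nfc, n_lip * nb, 3)

    system = _assemble_system(config, prot_resids, n_lip, bead_names_l)
    traj = Trajectory(
        coordinates=coords,
        box=np.tile(box, (F, 1)),
        frame_stride=config.frame_stride)
    truth = {
        "seed": config.seed,
        "species": config.species,
        "leaflet_labels": ["external"] * config.n_lipids_per_leaflet
                          + ["internal"] * config.n_lipids_per_leaflet,
        "affinities": dict(config.affinities),
        "area_per_lipid_A2": config.area_per_lipid_A2,
        "thickness_A": config.thickness_A,
        "box_nm": box.tolist(),
        "n_frames": F,
    }
    return system, traj, truth


def _assemble_system(config: GeneratorConfig, prot_resids: np.ndarray,
                     n_lip: int, bead_names_l: Tuple[str, ...]) -> CGSystem:
    n_prot = len(prot_resids)
    nb = len(bead_names_l)
    bead_names = np.concatenate([
        np.full(n_prot, "BB", dtype=object),
        np.tile(np.array(bead_names_l, dtype=object), n_lip)])
    residue_ids = np.concatenate([
        prot_resids,
        np.repeat(np.arange(1, n_lip + 1), nb)])
    residue_names = np.concatenate([
        np.full(n_prot, "ALA", dtype=object),
        np.full(n_lip * nb, config.species, dtype=object)])
    kinds = np.concatenate([
        np.full(n_prot, "protein", dtype=object),
        np.full(n_lip * nb, "lipid", dtype=object)])
    classes = np.concatenate([
        np.full(n_prot, "", dtype=object),
        np.tile(np.array([classify_bead(b) for b in bead_names_l],
                         dtype=object), n_lip)])
    species = np.concatenate([
        np.full(n_prot, "", dtype=object),
        np.full(n_lip * nb, config.species, dtype=object)])
    lipid_ids = np.concatenate([
        np.full(n_prot, -1, dtype=np.int64),
        np.repeat(np.arange(n_lip), nb)])
    return CGSystem(bead_names=bead_names, residue_ids=residue_ids,
                    residue_names=residue_names, molecule_kinds=kinds,
                    bead_classes=classes, lipid_species=species,
                    lipid_ids=lipid_ids)


def generate(config: Optional[GeneratorConfig] = None, **overrides
             ) -> Tuple[CGSystem, Trajectory, Dict]:
    """Convenience front end: build a config (defaults + overrides) and run."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    return simulate_lipids(config)


def write_fixture(system: CGSystem, traj: Trajectory, outdir: str,
                  truth: Optional[Mapping] = None) -> Dict[str, str]:
    """Write structure (PDB + GRO), trajectory (DCD) and ground-truth JSON.

    The structure carries frame 0 (or zeros for an empty trajectory); the
    returned dict maps artifact names to paths, all readable back through
    :mod:`lipidsites.io`.
    """
    from .io import write_system, ANGSTROM_PER_NM
    import warnings
    import MDAnalysis as mda

    os.makedirs(outdir, exist_ok=True)
    if traj.n_frames:
        frame0 = traj.coordinates[0]
        box0 = traj.box[0]
    else:
        frame0 = np.zeros((system.n_beads, 3))
        box0 = np.array([1.0, 1.0, 1.0])
    paths = {
        "pdb": os.path.join(outdir, "structure.pdb"),
        "gro": os.path.join(outdir, "structure.gro"),
        "dcd": os.path.join(outdir, "trajectory.dcd"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_system(system, frame0, box0, paths["pdb"])
    write_system(system, frame0, box0, paths["gro"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(paths["pdb"])
        with mda.Writer(paths["dcd"], system.n_beads) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[f] * ANGSTROM_PER_NM
                u.dimensions = [*(traj.box[f] * ANGSTROM_PER_NM), 90, 90, 90]
                w.write(u.atoms)
    with open(paths["truth"], "w") as fh:
        json.dump(dict(truth or {}), fh, indent=1, sort_keys=True)
    return paths
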