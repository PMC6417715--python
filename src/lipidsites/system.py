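"""Core data containers for coarse-grained membrane-protein systems.

A :class:`CGSystem` is the static topology (bead names, classes, residue and
molecule assignment), a :class:`Trajectory` holds per-frame coordinates in nm
with an orthorhombic box, and a :class:`HelixMap` maps helix ids (1-8 for a
GPCR-like bundle) to residue ranges, optionally with a kink that splits a
helix into two sub-segments separated by a torsion zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "BEAD_CLASSES",
    "CGSystem",
    "Helix",
    "HelixMap",
    "LeafletAssignment",
    "Trajectory",
    "DEFAULT_SPECIES",
    "classify_bead",
    "default_helix_map",
]

#: Recognised lipid bead classes.
BEAD_CLASSES = ("head", "phosphate", "glycerol", "tailA", "tailB")

# MARTINI-style bead lists for the three membrane species used throughout:
# a choline or ethanolamine head bead, one phosphate, two glycerol-ester
# beads and two acyl tails.  POPC/POPE carry an unsaturated D3B bead and a
# fifth B-tail bead; DPPC is fully saturated and one bead shorter.
DEFAULT_SPECIES: Mapping[str, Tuple[str, ...]] = {
    "POPC": ("CHO", "PO4", "GL1", "GL2",
             "C1A", "C2A", "C3A", "C4A",
             "C1B", "C2B", "D3B", "C4B", "C5B"),
    "DPPC": ("CHO", "PO4", "GL1", "GL2",
             "C1A", "C2A", "C3A", "C4A",
             "C1B", "C2B", "C3B", "C4B"),
    "POPE": ("NH3", "PO4", "GL1", "GL2",
             "C1A", "C2A", "C3A", "C4A",
             "C1B", "C2B", "D3B", "C4B", "C5B"),
}

_HEAD_NAMES = {"CHO", "NH3", "NC3", "NH3+"}
_SOLVENT_NAMES = {"W", "WAT", "SOL", "HOH", "TIP3", "PW"}
_ION_NAMES = {"ION", "NA", "CL", "NA+", "CL-", "K", "K+", "CA", "CA2+"}

# Three-letter amino-acid codes (plus generic CG backbone residue names).
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "BB",
}


def classify_bead(name: str) -> str:
    """Classify a lipid bead name into one of :data:`BEAD_CLASSES`."""
    if name in _HEAD_NAMES:
        return "head"
    if name == "PO4":
        return "phosphate"
    if name.startswith("GL"):
        return "glycerol"
    if name.endswith("A"):
        return "tailA"
    if name.endswith("B"):
        return "tailB"
    raise ValueError(f"cannot classify lipid bead name {name!r}")


@dataclass(frozen=True)
class Helix:
    """One helix: inclusive residue range, optional kink torsion zone.

    ``kink`` is a ``(kink_begin, kink_end)`` residue pair: the two
    sub-segments are ``begin..kink_begin`` and ``kink_end..end`` and residues
    strictly between them form the torsion zone, excluded from both.  A
    single residue ``k`` may be given and is treated as ``(k, k)``.
    """

    helix_id: int
    begin: int
    end: int
    kink: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        if self.begin > self.end:
            raise ValueError(f"helix {self.helix_id}: begin > end")
        if self.kink is not None:
            k = self.kink
            if isinstance(k, int):
                k = (k, k)
            kb, ke = int(k[0]), int(k[1])
            if kb > ke:
                raise ValueError(f"helix {self.helix_id}: kink_begin > kink_end")
            if not (self.begin < kb and ke < self.end):
                raise ValueError(
                    f"helix {self.helix_id}: kink {k} not strictly inside "
                    f"[{self.begin}, {self.end}]")
            object.__setattr__(self, "kink", (kb, ke))

    @property
    def n_residues(self) -> int:
        return self.end - self.begin + 1

    def segments(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """Residue ranges of the pre- and post-kink sub-segments."""
        if self.kink is None:
            raise ValueError(f"helix {self.helix_id} has no kink defined")
        return (self.begin, self.kink[0]), (self.kink[1], self.end)


class HelixMap:
    """Ordered collection of helices with pairwise-disjoint residue ranges."""

    def __init__(self, helices: Iterable[Helix]):
        hs = sorted(helices, key=lambda h: h.helix_id)
        ids = [h.helix_id for h in hs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate helix ids")
        ranges = sorted((h.begin, h.end) for h in hs)
        for (b1, e1), (b2, e2) in zip(ranges, ranges[1:]):
            if b2 <= e1:
                raise ValueError("helix residue ranges overlap")
        self.helices: Tuple[Helix, ...] = tuple(hs)
        self._by_id = {h.helix_id: h for h in hs}

    def __iter__(self):
        return iter(self.helices)

    def __len__(self):
        return len(self.helices)

    def __getitem__(self, helix_id: int) -> Helix:
        return self._by_id[helix_id]

    def helix_of_residue(self, resid: int) -> Optional[int]:
        """Helix id containing ``resid``, or None for loop/terminal residues."""
        for h in self.helices:
            if h.begin <= resid <= h.end:
                return h.helix_id
        return None

    def residue_to_helix_array(self, resids: np.ndarray) -> np.ndarray:
        """Vectorised helix lookup: 0 marks residues outside every helix."""
        out = np.zeros(len(resids), dtype=np.int64)
        for h in self.helices:
            out[(resids >= h.begin) & (resids <= h.end)] = h.helix_id
        return out


def default_helix_map() -> HelixMap:
    """The 8-helix µOR-like bundle used throughout.

    H1-H7 are the transmembrane helices, H8 the short intracellular helix.
    H5 carries a proline kink; its sub-segments are 226-240 and 244-257 with
    the 241-243 torsion zone excluded.
    """
    return HelixMap([
        Helix(1, 65, 95),
        Helix(2, 103, 130),
        Helix(3, 138, 169),
        Helix(4, 180, 204),
        Helix(5, 226, 257, kink=(240, 244)),
        Helix(6, 273, 304),
        Helix(7, 312, 340),
        Helix(8, 341, 352),
    ])


@dataclass
class CGSystem:
    """Static topology of a coarse-grained system.

    All per-bead arrays are parallel and indexed by bead index.  Beads of a
    lipid are required to be contiguous (one residue per lipid, as written
    by every structure format this package reads).
    """

    bead_names: np.ndarray          # str
    residue_ids: np.ndarray         # int
    residue_names: np.ndarray       # str
    molecule_kinds: np.ndarray      # 'protein' | 'lipid' | 'solvent' | 'ion'
    bead_classes: np.ndarray        # lipid bead class, '' for non-lipid beads
    lipid_species: np.ndarray       # species token, '' for non-lipid beads
    lipid_ids: np.ndarray           # 0..n_lipids-1, -1 for non-lipid beads
    source_path: Optional[str] = None

    def __post_init__(self):
        n = len(self.bead_names)
        for name in ("residue_ids", "residue_names", "molecule_kinds",
                     "bead_classes", "lipid_species", "lipid_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        self._validate_lipids()

    # -- lipid bookkeeping -------------------------------------------------
    def _validate_lipids(self):
        lid = self.lipid_ids
        lip_mask = self.molecule_kinds == "lipid"
        if np.any((lid >= 0) != lip_mask):
            raise ValueError("lipid_ids inconsistent with molecule_kinds")
        if not lip_mask.any():
            self._lipid_starts = np.empty(0, dtype=np.int64)
            self._lipid_counts = np.empty(0, dtype=np.int64)
            return
        ids = lid[lip_mask]
        uniq = np.unique(ids)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("lipid_ids must be 0..n_lipids-1")
        # contiguity: each lipid occupies one contiguous bead slice
        idx = np.flatnonzero(lip_mask)
        change = np.flatnonzero(np.diff(lid[idx]) != 0) + 1
        starts_in_idx = np.concatenate(([0], change))
        seen = lid[idx][starts_in_idx]
        if len(seen) != len(uniq) or not np.array_equal(np.sort(seen), uniq):
            raise ValueError("beads of each lipid must be contiguous")
        order = np.argsort(seen)
        counts = np.diff(np.concatenate((starts_in_idx, [len(idx)])))
        self._lipid_starts = idx[starts_in_idx][order]
        self._lipid_counts = counts[order]
        # exactly one phosphate bead per lipid
        for lip in range(len(uniq)):
            s, c = self._lipid_starts[lip], self._lipid_counts[lip]
            n_po4 = int(np.sum(self.bead_classes[s:s + c] == "phosphate"))
            if n_po4 != 1:
                raise ValueError(
                    f"lipid {lip} ({self.lipid_species[s]}) has {n_po4} "
                    "phosphate beads (exactly one required)")

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def n_lipids(self) -> int:
        return len(self._lipid_starts)

    @property
    def lipid_starts(self) -> np.ndarray:
        """First bead index of each lipid (indexed by lipid id)."""
        return self._lipid_starts

    @property
    def lipid_counts(self) -> np.ndarray:
        """Bead count of each lipid (indexed by lipid id)."""
        return self._lipid_counts

    @property
    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(self.molecule_kinds == "protein")

    @property
    def lipid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.molecule_kinds == "lipid")

    @property
    def phosphate_indices(self) -> np.ndarray:
        """Bead index of the PO4 bead of each lipid, ordered by lipid id."""
        out = np.empty(self.n_lipids, dtype=np.int64)
        for lip in range(self.n_lipids):
            s, c = self._lipid_starts[lip], self._lipid_counts[lip]
            out[lip] = s + int(np.flatnonzero(
                self.bead_classes[s:s + c] == "phosphate")[0])
        return out

    def species_of_lipid(self) -> np.ndarray:
        """Species token per lipid id."""
        return self.lipid_species[self._lipid_starts]

    def protein_residues(self) -> np.ndarray:
        """Unique protein residue ids, in order of appearance."""
        prot = self.residue_ids[self.protein_indices]
        _, first = np.unique(prot, return_index=True)
        return prot[np.sort(first)]


@dataclass
class Trajectory:
    """Per-frame bead coordinates (nm) with an orthorhombic box (nm)."""

    coordinates: np.ndarray   # (n_frames, n_beads, 3), nm
    box: np.ndarray           # (n_frames, 3), nm
    frame_stride: int = 1     # saved-iteration interval (metadata)

    def __post_init__(self):
        c = np.asarray(self.coordinates)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_beads, 3)")
        b = np.asarray(self.box, dtype=np.float64)
        if b.ndim != 2 or b.shape != (c.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if c.shape[0] and not np.all(b > 0):
            raise ValueError("box lengths must be strictly positive in every frame")
        self.coordinates = c
        self.box = b

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class LeafletAssignment:
    """Fixed per-trajectory leaflet membership of every lipid.

    ``labels[lipid_id]`` is ``"external"`` (phosphate above the midplane) or
    ``"internal"``; ``midplane_z`` is the mean phosphate z of the reference
    frame, in nm.
    """

    labels: np.ndarray          # str per lipid id
    midplane_z: float
    flip_flop_lipids: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    def lipids_in(self, leaflet: str) -> np.ndarray:
        return np.flatnonzero(self.labels == leaflet)
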