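"""Lipid site-transition networks.

Each frame, each annular lipid is labelled by the set of helices it touches
(canonical label: ascending helix digits, e.g. "167" = H1+H6+H7).  Lipids
must interact with the protein in at least 20% of frames to be retained
(occupancy filter).  Per lipid, frames with no helix contact are gaps that
neither emit a label nor break a run; runs of identical labels are then
collapsed to one occurrence, giving the lipid's path between sites.  Paths
are pooled per leaflet into a weighted graph: node weight = number of path
entries with that label, edge count = number of adjacent path pairs
(undirected by default).  Louvain community detection (resolution 0.8,
seeded) clusters the sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity

from .contacts import ContactTable, periodic_pairs
from .system import CGSystem, HelixMap, LeafletAssignment, Trajectory

__all__ = [
    "canonical_label",
    "label_from_bits",
    "occupancy_filter",
    "frame_site",
    "collapse_path",
    "LipidPath",
    "paths_from_table",
    "SiteNetwork",
    "build_network",
    "cluster_network",
    "write_gexf",
]


def canonical_label(helix_set: Iterable[int]) -> str:
    """Canonical site label: ascending concatenated helix digits.

    ``{7, 6, 1} -> "167"``; idempotent over re-parsing its own output.
    """
    ids = sorted(set(int(h) for h in helix_set))
    if not ids:
        raise ValueError("site label requires a non-empty helix set")
    for h in ids:
        if not 1 <= h <= 8:
            raise ValueError(f"helix id {h} outside 1-8")
    return "".join(str(h) for h in ids)


def label_from_bits(bits: int) -> Optional[str]:
    """Site label from a helix bitmask (bit h-1 = helix h); None if empty."""
    if bits == 0:
        return None
    return canonical_label(h + 1 for h in range(8) if bits >> h & 1)


def occupancy_filter(events: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """Lipid ids interacting with the protein in >= ``threshold`` of frames.

    The boundary is inclusive: a lipid in contact for exactly 20% of the
    frames is retained.  ``events`` is the (n_frames, n_lipids) any-contact
    boolean record.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    events = np.asarray(events, dtype=bool)
    if events.shape[0] == 0:
        raise ValueError("zero-frame trajectory")
    frac = events.mean(axis=0)
    return np.flatnonzero(frac >= threshold)


def frame_site(traj: Trajectory, system: CGSystem, helices: HelixMap,
               lipid_id: int, frame: int, cutoff: float = 0.5
               ) -> Optional[str]:
    """Site label of one lipid in one frame, or None if it touches no helix.

    A helix is in the label iff any bead of the lipid lies within the
    cutoff of any bead of a residue in that helix's range; loop and
    terminal residues contribute nothing.
    """
    s = system.lipid_starts[lipid_id]
    c = system.lipid_counts[lipid_id]
    lip = traj.coordinates[frame, s:s + c]
    pidx = system.protein_indices
    resids = system.residue_ids[pidx]
    touched = set()
    for h in helices:
        sel = pidx[(resids >= h.begin) & (resids <= h.end)]
        if len(sel) == 0:
            continue
        pairs = periodic_pairs(lip, traj.coordinates[frame, sel],
                               traj.box[frame], cutoff)
        if len(pairs):
            touched.add(h.helix_id)
    return canonical_label(touched) if touched else None


@dataclass(frozen=True)
class LipidPath:
    """Run-length-collapsed sequence of site labels visited by one lipid."""

    lipid_id: int
    leaflet: str
    sites: Tuple[str, ...]

    def __len__(self):
        return len(self.sites)


def collapse_path(site_sequence: Sequence[Optional[str]]) -> Tuple[str, ...]:
    """Drop gaps (None) and merge runs of identical labels.

    A gap does not break a run: [5, None, 5] collapses to (5,).  Idempotent
    under re-collapse.  Returns an empty tuple if nothing remains.
    """
    out: List[str] = []
    for label in site_sequence:
        if label is None:
            continue
        if not out or out[-1] != label:
            out.append(label)
    return tuple(out)


def paths_from_table(table: ContactTable, leaflets: LeafletAssignment,
                     occupancy: float = 0.20) -> List[LipidPath]:
    """Occupancy-filter, label and collapse every lipid of a scanned table.

    Requires the table to have been scanned with a helix map (site_bits).
    Lipids whose collapsed path is empty (retained by occupancy but never
    touching a helix) are excluded.
    """
    if table.site_bits is None:
        raise ValueError("contact table has no helix site record; "
                         "re-run scan_contacts with a helix map")
    retained = occupancy_filter(table.events, occupancy)
    paths = []
    for lip in retained:
        seq = [label_from_bits(int(b)) for b in table.site_bits[:, lip]]
        sites = collapse_path(seq)
        if not sites:
            continue
        paths.append(LipidPath(int(lip), str(leaflets.labels[lip]), sites))
    return paths


@dataclass
class SiteNetwork:
    """Leaflet-tagged transition network between protein sites.

    Conservation invariants hold exactly: the node weights sum to the total
    path length and the edge counts to the total number of transitions.
    """

    leaflet: str
    node_weights: Dict[str, int]
    edge_counts: Dict[Tuple[str, str], int]
    directed: bool = False
    clusters: Dict[str, int] = field(default_factory=dict)
    modularity_score: Optional[float] = None

    def graph(self) -> nx.Graph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        for node, w in sorted(self.node_weights.items()):
            g.add_node(node, weight=int(w))
        for (u, v), c in sorted(self.edge_counts.items()):
            g.add_edge(u, v, count=int(c))
        return g


def build_network(paths: Sequence[LipidPath], leaflet: str,
                  directed: bool = False) -> SiteNetwork:
    """Aggregate collapsed lipid paths into a site-transition network.

    Node weight counts path entries; edge count counts adjacent pairs.  By
    default edges are undirected ((a, b) stored with a <= b); pass
    ``directed=True`` to preserve transition order.
    """
    for p in paths:
        if p.leaflet != leaflet:
            raise ValueError(
                f"path of lipid {p.lipid_id} is from leaflet {p.leaflet!r}, "
                f"expected {leaflet!r}")
    nodes: Counter = Counter()
    edges: Counter = Counter()
    for p in paths:
        nodes.update(p.sites)
        for a, b in zip(p.sites, p.sites[1:]):
            key = (a, b) if directed else tuple(sorted((a, b)))
            edges[key] += 1
    return SiteNetwork(leaflet=leaflet, node_weights=dict(nodes),
                       edge_counts=dict(edges), directed=directed)


def cluster_network(net: SiteNetwork, resolution: float = 0.8,
                    seed: int = 0) -> SiteNetwork:
    """Louvain community detection on the edge-count-weighted graph.

    Deterministic under a fixed seed; cluster ids are renumbered by each
    community's lexicographically smallest node for stable output.  A
    single-node (or edgeless) network gets one cluster and modularity 0.
    """
    if not net.node_weights:
        raise ValueError("empty network")
    g = net.graph()
    if g.is_directed():
        g = g.to_undirected()
    if g.number_of_edges() == 0:
        net.clusters = {n: i for i, n in enumerate(sorted(g.nodes))}
        net.modularity_score = 0.0
        return net
    comms = louvain_communities(g, weight="count", resolution=resolution,
                                seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    net.clusters = {n: i for i, c in enumerate(comms) for n in c}
    net.modularity_score = float(modularity(
        g, [set(c) for c in comms], weight="count", resolution=resolution))
    return net


def write_gexf(net: SiteNetwork, path: str) -> None:
    """Gephi-compatible GEXF export (node weight/cluster, edge count).

    The writer's volatile last-modified date is pinned so identical inputs
    produce byte-identical files.
    """
    g = net.graph()
    for n in g.nodes:
        if net.clusters:
            g.nodes[n]["cluster"] = int(net.clusters.get(n, -1))
    nx.write_gexf(g, path)
    with open(path) as fh:
        text = fh.read()
    import re
    text = re.sub(r'lastmodifieddate="[^"]*"', 'lastmodifieddate="1970-01-01"',
                  text)
    with open(path, "w") as fh:
        fh.write(text)
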