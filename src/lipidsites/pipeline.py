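"""End-to-end orchestration: structure + trajectories in, report bundle out.

Stages: topology -> alignment -> contacts -> tilt -> site networks ->
membrane descriptors.  Replicate trajectories are pooled (counts summed,
paths pooled per leaflet) before normalisation and network construction;
per-replicate tables are written alongside for error bars.  Outputs are a
pure function of (inputs, config, seed): reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .align import per_helix_rmsd
from .contacts import ContactTable, cutoff_sensitivity, frequency_map, scan_contacts
from .io import assign_leaflets, load_species_table, read_system, read_trajectory
from .membrane import membrane_summary
from .network import build_network, cluster_network, paths_from_table, write_gexf
from .system import Helix, HelixMap, default_helix_map
from .tilt import tilt_profile, tilt_summary

__all__ = ["RunConfig", "run_all", "read_helix_table"]

_PKG_VERSION = "0.1.0"

STAGES = ("topology", "alignment", "contacts", "tilt", "network", "membrane")


def read_helix_table(path: str) -> HelixMap:
    """Read a helix-definition TSV: helix_id, begin, end[, kink_begin, kink_end]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    helices = []
    for _, row in df.iterrows():
        kink = None
        if "kink_begin" in df.columns and not pd.isna(row.get("kink_begin")):
            kink = (int(row["kink_begin"]), int(row["kink_end"]))
        helices.append(Helix(int(row["helix_id"]), int(row["begin"]),
                             int(row["end"]), kink=kink))
    return HelixMap(helices)


@dataclass
class RunConfig:
    """Validated pipeline configuration (echoed into the output bundle)."""

    structure: str
    trajectories: Sequence[str]
    outdir: str
    helix_table: Optional[str] = None      # TSV path; None = built-in 8-helix map
    species_table: Optional[str] = None    # YAML path; None = POPC/DPPC/POPE
    cutoff: float = 0.5
    sensitivity_cutoffs: Sequence[float] = (0.5, 0.6, 0.7)
    occupancy: float = 0.2
    resolution: float = 0.8
    seed: int = 0
    directed: bool = False

    def validate(self) -> None:
        if not os.path.exists(self.structure):
            raise FileNotFoundError(f"structure not found: {self.structure}")
        if not self.trajectories:
            raise ValueError("at least one trajectory required")
        for t in self.trajectories:
            if not os.path.exists(t):
                raise FileNotFoundError(f"trajectory not found: {t}")
        if not 0 < self.cutoff <= 2.0:
            raise ValueError("cutoff (nm) outside the documented (0, 2] range")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy threshold outside (0, 1]")
        if not 0 < self.resolution <= 5:
            raise ValueError("resolution outside the documented (0, 5] range")

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["trajectories"] = list(d["trajectories"])
        d["sensitivity_cutoffs"] = list(d["sensitivity_cutoffs"])
        return d


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig) -> Dict:
    """Execute every stage and write the report bundle.

    Returns the manifest dict (also written as manifest.json).  Any stage
    failure raises with the stage name attached.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    helices = (read_helix_table(config.helix_table) if config.helix_table
               else default_helix_map())
    species = load_species_table(config.species_table)
    manifest: Dict = {
        "package_version": _PKG_VERSION,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "outputs": [],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()

    def emit(df: pd.DataFrame, name: str) -> None:
        _write_tsv(df, os.path.join(config.outdir, name))
        manifest["outputs"].append(name)

    stage = "topology"
    try:
        system = read_system(config.structure, species)
        trajs = [read_trajectory(t, system) for t in config.trajectories]
        leaflets = assign_leaflets(system, trajs[0])
        manifest["stages"].append(stage)

        stage = "alignment"
        reference = trajs[0].coordinates[0]
        rmsd_frames = []
        for run_i, traj in enumerate(trajs):
            df = per_helix_rmsd(traj, reference, system, helices)
            df.insert(0, "run", run_i)
            rmsd_frames.append(df)
        emit(pd.concat(rmsd_frames, ignore_index=True), "rmsd.tsv")
        manifest["stages"].append(stage)

        stage = "contacts"
        tables = [scan_contacts(t, system, config.cutoff, helices=helices)
                  for t in trajs]
        pooled = ContactTable.merge(tables) if len(tables) > 1 else tables[0]
        long = pooled.to_frame(helices)
        emit(long, "contacts.tsv")
        for run_i, t in enumerate(tables):
            emit(frequency_map(t), f"frequency_map_run{run_i}.tsv")
        emit(frequency_map(pooled), "frequency_map.tsv")
        maps, agreement = cutoff_sensitivity(
            trajs[0], system, config.sensitivity_cutoffs, helices=helices)
        emit(agreement, "cutoff_sensitivity.tsv")
        manifest["stages"].append(stage)

        stage = "tilt"
        tilt_frames = []
        for run_i, traj in enumerate(trajs):
            df = tilt_profile(traj, system, helices)
            df.insert(0, "run", run_i)
            tilt_frames.append(df)
        all_tilt = pd.concat(tilt_frames, ignore_index=True)
        emit(all_tilt, "tilt.tsv")
        emit(tilt_summary(all_tilt), "tilt_summary.tsv")
        manifest["stages"].append(stage)

        stage = "network"
        all_paths = []
        for t in tables:
            all_paths.extend(paths_from_table(t, leaflets, config.occupancy))
        sp_name = "_".join(sorted(set(system.species_of_lipid()))) or "lipid"
        edge_rows = []
        for leaflet in ("external", "internal"):
            paths = [p for p in all_paths if p.leaflet == leaflet]
            net = build_network(paths, leaflet, directed=config.directed)
            if net.node_weights:
                net = cluster_network(net, config.resolution, config.seed)
            gexf = f"{sp_name}_{leaflet}.gexf"
            from .network import write_gexf as _wg
            _wg(net, os.path.join(config.outdir, gexf))
            manifest["outputs"].append(gexf)
            for (u, v), c in sorted(net.edge_counts.items()):
                edge_rows.append((leaflet, u, v, c))
        emit(pd.DataFrame(edge_rows,
                          columns=["leaflet", "site_a", "site_b", "count"]),
             "network_edges.tsv")
        manifest["stages"].append(stage)

        stage = "membrane"
        mem_frames = []
        for run_i, traj in enumerate(trajs):
            df = membrane_summary(traj, system, leaflets)
            df.insert(0, "run", run_i)
            mem_frames.append(df)
        emit(pd.concat(mem_frames, ignore_index=True), "membrane.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
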