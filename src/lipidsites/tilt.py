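"""Helix tilt from sliding-window local axes.

Local axes follow the HELANAL construction: for four consecutive backbone
beads p1..p4 the axis is the cross product of the successive second
differences, (p1 - 2 p2 + p3) x (p2 - 2 p3 + p4), which is exact for an
ideal helix of any radius and pitch.  For (near-)collinear windows, where
that cross product vanishes, the window chord direction is used instead.
Axes are sign-aligned along increasing residue order; tilt is the angle to
the membrane normal (the box z axis), folded into [0, 90] degrees because a
tilt has no sign.

The per-helix quantity reported is the maximum tilt over the helix's
windows; kinked helices are additionally measured on their two sub-segments
with the torsion-zone residues excluded from both.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .system import CGSystem, Helix, HelixMap, Trajectory

__all__ = ["local_axes", "max_tilt", "segment_tilts", "tilt_profile",
           "tilt_summary"]

Z_AXIS = np.array([0.0, 0.0, 1.0])
_DEGENERATE = 1e-12


def local_axes(helix_coords: np.ndarray, window: int = 4) -> np.ndarray:
    """One unit axis per sliding window of ``window`` consecutive beads.

    ``helix_coords`` are ordered backbone bead positions (n, 3) with
    ``n >= window``; returns (n - window + 1, 3) unit vectors with positive
    dot products between consecutive axes.
    """
    p = np.asarray(helix_coords, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("helix_coords must be (n, 3)")
    n = len(p)
    if n < window:
        raise ValueError(f"helix has {n} residues, shorter than window {window}")
    if window < 4:
        raise ValueError("window must be at least 4")
    n_win = n - window + 1
    axes = np.empty((n_win, 3))
    for i in range(n_win):
        w = p[i:i + window]
        # second differences within the window; each points from the helix
        # surface toward the local axis
        d2 = w[:-2] - 2 * w[1:-1] + w[2:]
        a = np.zeros(3)
        for k in range(len(d2) - 1):
            a = a + np.cross(d2[k], d2[k + 1])
        norm = np.linalg.norm(a)
        chord = w[-1] - w[0]
        if norm < _DEGENERATE:
            a = chord
            norm = np.linalg.norm(a)
            if norm < _DEGENERATE:
                raise ValueError(f"window {i} is degenerate (zero extent)")
        a = a / norm
        if np.dot(a, chord) < 0:
            a = -a
        axes[i] = a
    return axes


def max_tilt(axes: np.ndarray, reference_axis: np.ndarray = Z_AXIS) -> float:
    """Maximum angle (degrees, folded to [0, 90]) between any local axis and
    the reference axis (membrane normal by default)."""
    axes = np.atleast_2d(np.asarray(axes, dtype=np.float64))
    if axes.shape[0] == 0:
        raise ValueError("no axes given")
    ref = np.asarray(reference_axis, dtype=np.float64)
    nref = np.linalg.norm(ref)
    norms = np.linalg.norm(axes, axis=1)
    if nref < _DEGENERATE or np.any(norms < _DEGENERATE):
        raise ValueError("zero-length vector")
    cosang = np.abs(axes @ ref) / (norms * nref)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang.max())


def _helix_bead_coords(frame_coords: np.ndarray, system: CGSystem,
                       begin: int, end: int) -> np.ndarray:
    pidx = system.protein_indices
    resids = system.residue_ids[pidx]
    sel = pidx[(resids >= begin) & (resids <= end)]
    if len(sel) == 0:
        raise ValueError(f"no protein beads in residue range {begin}-{end}")
    return frame_coords[sel]


def segment_tilts(helix_coords_by_residue, helix: Helix, window: int = 4,
                  reference_axis: np.ndarray = Z_AXIS
                  ) -> Tuple[float, float]:
    """Maximum tilt of the pre-kink and post-kink sub-segments.

    ``helix_coords_by_residue`` maps the helix residue range begin..end to
    rows of an (n, 3) array; residues strictly inside the torsion zone are
    excluded from both sub-segments.
    """
    p = np.asarray(helix_coords_by_residue, dtype=np.float64)
    if len(p) != helix.n_residues:
        raise ValueError("coordinate count does not match helix residue range")
    (b1, e1), (b2, e2) = helix.segments()
    seg1 = p[b1 - helix.begin: e1 - helix.begin + 1]
    seg2 = p[b2 - helix.begin: e2 - helix.begin + 1]
    for name, seg in (("pre-kink", seg1), ("post-kink", seg2)):
        if len(seg) < window:
            raise ValueError(f"{name} sub-segment shorter than window {window}")
    t1 = max_tilt(local_axes(seg1, window), reference_axis)
    t2 = max_tilt(local_axes(seg2, window), reference_axis)
    return t1, t2


def tilt_profile(traj: Trajectory, system: CGSystem, helices: HelixMap,
                 window: int = 4,
                 reference_axis: np.ndarray = Z_AXIS) -> pd.DataFrame:
    """Per-frame maximum tilt of every helix (and kink sub-segments).

    Returns a tidy frame with columns frame, helix, segment
    ("whole" | "pre_kink" | "post_kink") and tilt_deg.
    """
    rows = []
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        for h in helices:
            p = _helix_bead_coords(coords, system, h.begin, h.end)
            rows.append((f, h.helix_id, "whole",
                         max_tilt(local_axes(p, window), reference_axis)))
            if h.kink is not None:
                t1, t2 = segment_tilts(p, h, window, reference_axis)
                rows.append((f, h.helix_id, "pre_kink", t1))
                rows.append((f, h.helix_id, "post_kink", t2))
    return pd.DataFrame(rows, columns=["frame", "helix", "segment", "tilt_deg"])


def tilt_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean and std over frames of the per-frame maximum tilt, per helix and
    segment — the usual per-helix tilt-table layout."""
    g = profile.groupby(["helix", "segment"])["tilt_deg"]
    out = g.agg(["mean", "std"]).reset_index()
    out.columns = ["helix", "segment", "tilt_mean_deg", "tilt_std_deg"]
    return out
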