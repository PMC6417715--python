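"""Numba kernel for the static-protein contact check.

Distances are exact float64; the anchor gate only skips protein beads that
the triangle-inequality bound proves are out of reach, so the result is
identical to the all-pairs computation.  Aggregation (counts, occupancy
events, helix bitmasks) happens in-kernel to avoid materialising the pair
list.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def static_contact_kernel(LBp, A0, thr, Pg, gsrc, resix, hbits, cut2,
                          counts, do_counts, bits_out, ev_out):
    """Candidate lipids against a static (ghost-augmented) protein set.

    LBp: (nc, nb, 3) candidate lipid bead coords, same image as A0.
    A0: (nc, 3) anchor bead; thr: (nc,) squared anchor gate radius.
    Pg: (ng, 3) wrapped+ghost protein beads; gsrc maps ghosts to original
    bead index; resix/hbits map protein beads to residue row / helix bit.
    """
    nc, nb, _ = LBp.shape
    ng = Pg.shape[0]
    for c in range(nc):
        t = thr[c]
        ax, ay, az = A0[c, 0], A0[c, 1], A0[c, 2]
        for g in range(ng):
            dx = ax - Pg[g, 0]
            dy = ay - Pg[g, 1]
            dz = az - Pg[g, 2]
            if dx * dx + dy * dy + dz * dz >= t:
                continue
            j = gsrc[g]
            for b in range(nb):
                bx = LBp[c, b, 0] - Pg[g, 0]
                by = LBp[c, b, 1] - Pg[g, 1]
                bz = LBp[c, b, 2] - Pg[g, 2]
                if bx * bx + by * by + bz * bz < cut2:
                    ev_out[c] = True
                    bits_out[c] |= hbits[j]
                    if do_counts:
                        counts[resix[j], b] += 1
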