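# lipidsites

Protein–lipid interaction analysis for coarse-grained membrane-protein
trajectories: contact counting and per-residue frequency maps, helix tilt
from sliding-window local axes, lipid site-transition networks with Louvain
clustering, and bilayer descriptors — plus a synthetic trajectory generator
with known ground truth so every stage is testable without any download.

## Who this is for

Researchers running MARTINI-style coarse-grained MD of α-helical membrane
proteins (GPCRs and the like) in lipid bilayers who want to answer: *which
residues does each lipid species touch, how tilted is each helix, and which
protein faces do the annular lipids occupy and exchange between?*

## The methods

**Contacts.** A contact is a (protein bead, lipid bead) pair with
minimum-image distance *d* < *c*, with *c* = 0.5 nm by default and 0.6/0.7
nm used for sensitivity analysis. Counts are aggregated per residue and
per lipid bead class (head CHO/NH3, phosphate PO4, glycerol GL, tails), and
the per-residue contact frequency map is normalised to the most-contacted
residue:

    f(r) = 100 · n(r) / max_r' n(r')      (percent, 0–100)

The neighbor search is a cell-list grid that is exactly equivalent to the
all-pairs computation (asserted against a brute-force oracle in the tests).

**Helix tilt.** For each sliding window of 4 backbone beads p₁..p₄ the
local axis is (p₁−2p₂+p₃) × (p₂−2p₃+p₄) — the HELANAL construction, exact
for an ideal helix of any radius — and the tilt is the angle between that
axis and the membrane normal (the box z axis), folded into [0°, 90°]. Per
helix the maximum over windows is reported; a kinked helix (H5 at its
proline) is additionally measured on its two sub-segments with the torsion
zone excluded.

**Site-transition networks.** Each lipid that contacts the protein in at
least 20% of frames is labelled per frame by the set of helices within 0.5
nm, written as ascending digits ("167" = H1+H6+H7). Frames with no helix
contact are gaps that neither emit a label nor break a run; runs of equal
labels collapse to one visit. Pooled per leaflet, the collapsed paths form
a weighted graph — node weight = visits, edge count = transitions — which
is clustered by Louvain community detection (resolution 0.8, seeded) and
exported as Gephi-compatible GEXF.

**Bilayer descriptors.** Area per lipid = Lx·Ly / (lipids in the larger
leaflet); thickness = |mean z of external PO4 − mean z of internal PO4|.

**Synthetic generator.** A static ring of 8 ideal helices (residue ranges
H1 65–95 … H8 341–352) spans a two-leaflet bilayer of 12–13-bead lipids
doing lateral Gaussian random walks with periodic wrapping; configurable
residence sites slow lipids down near chosen helix faces. Planted truth
(leaflet labels, area per lipid, thickness, site affinities, tilt/kink
angles) is recovered by the analysis modules and anchors the test suite.

## Worked example

```bash
python examples/04_site_network.py
```

builds a 600-lipid, 2000-frame bilayer with a 5× residence affinity planted
at the H6/H7 face and prints:

```
22 lipids pass the 20% occupancy filter
external: top sites [('67', 220), ('6', 171), ('7', 148), ('5', 33), ('3', 17)], 3 Louvain clusters, modularity 0.350
internal: top sites [('67', 155), ('7', 121), ('6', 113), ('5', 27), ('8', 27)], 3 Louvain clusters, modularity 0.388
```

Node "67" (lipids touching helices 6 and 7 simultaneously) is the heaviest
node in both leaflets: the analysis recovers the planted binding site from
coordinates alone. The other examples cover fixture generation (`01`),
contact/frequency maps with cutoff sensitivity (`02` — Spearman rank
agreement ≥ 0.94 between the 0.5 and 0.7 nm maps), tilt and kink recovery
(`03` — a planted 12° tilt + 3° post-kink bend reads back as 12.0°/15.0°),
and the end-to-end pipeline (`05`).

The same analyses are available from the shell:

```bash
lipidsites generate --out fixture --seed 0 --n-frames 500
lipidsites analyze --structure fixture/structure.pdb \
    --trajectory fixture/trajectory.dcd --out results \
    --cutoff 0.5 --occupancy 0.2 --resolution 0.8 --seed 0
```

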