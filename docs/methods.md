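# Methods

## Scope and data model

The package analyses coarse-grained (CG) trajectories of an α-helical
membrane protein embedded in a lipid bilayer. The static topology
(`CGSystem`) records bead names, MARTINI-style bead classes (head,
phosphate, glycerol, two tails), residue ids and molecule kinds; the
`Trajectory` holds per-frame coordinates in nm with a strictly positive
orthorhombic box. Structure files (PDB/GRO) and trajectories (DCD/XTC) are
read through MDAnalysis and converted to nm on input; triclinic boxes are
rejected. Built-in species tables describe POPC and POPE (13 beads, one
unsaturated D3B tail bead) and DPPC (12 beads, saturated); users can
supply their own YAML table. The helix map defaults to the 8-helix GPCR
bundle (H1 65–95, H2 103–130, H3 138–169, H4 180–204, H5 226–257 with kink
zone 240–244, H6 273–304, H7 312–340, H8 341–352).

## Leaflets

The midplane is the mean z of all phosphate (PO4) beads in a reference
frame (frame 0 by default); a lipid is *external* iff its PO4 lies above
it. Assignment is made once per trajectory — the network analysis treats
each lipid as belonging to one leaflet throughout — and lipids whose
frame-by-frame side disagrees with the assignment in more than 10% of
frames are logged as flip-flop suspects. PO4 is the anchor because it is
the one unambiguous per-lipid bead across species.

## Contacts

A contact is a (protein bead, lipid bead) pair with minimum-image distance
strictly below the cutoff. Strict `<` is the documented convention;
boundary cases have measure zero for real coordinates. The default cutoff
is 0.5 nm with 0.6 and 0.7 nm as sensitivity settings; cutoffs above half
the smallest box length are rejected (minimum-image violation). A "count"
is a bead pair per frame, so one residue–lipid pair can contribute several
counts per frame; occupancy (for the network filter) instead records one
boolean per lipid per frame.

The search itself is a vectorised float64 cell-list grid
(`periodic_pairs`), contractually identical to the all-pairs computation;
a brute-force reference implementation exists solely to validate it and
the test suite asserts exact set equality on hundreds of random periodic
systems. The whole-trajectory scanner (`scan_contacts`) adds an
annular-shell prefilter: a lipid can only contribute contacts if its
anchor bead lies within (protein xy extent + lipid extent + cutoff) of the
protein's lateral center; the bound follows from the triangle inequality
on the flat-torus metric, so no true contact is ever discarded. Prefilter
bounds are computed in float32 with a 10⁻³ nm pad (they only gate the exact
check); membership is always decided by exact float64 distances. When the
protein is static across a chunk of frames and the box constant — always
true for generator output — the exact check runs in a numba kernel against
a single wrapped protein set augmented with ghost images near the box
faces; otherwise a generic numpy minimum-image path is used. Both routes
are asserted equal to the frame-by-frame grid search.

Frequency maps divide each residue's total count by the maximum residue
total (×100). Cutoff sensitivity reports Spearman rank correlation between
the per-residue maps at each cutoff pair, over residues with a nonzero
count at the largest cutoff (a superset of every smaller cutoff's support,
by monotonicity). Replicate runs are pooled by summing counts before
normalisation; per-replicate maps are also written for error bars.

## Helix tilt

Local axes use a sliding window of four consecutive backbone beads. The
axis of window p₁..p₄ is the cross product of successive second
differences, (p₁−2p₂+p₃)×(p₂−2p₃+p₄), sign-aligned along increasing
residue order. This construction (HELANAL's) is exact for an ideal helix
of any radius and pitch; for degenerate (collinear) windows the chord
p₄−p₁ is used. We considered taking the window's leading principal
component instead, but PCA of four beads on a realistic CG spiral (radius
0.23 nm, 100°/residue) is biased from the true axis by tens of degrees, so
the second-difference form is used; it is cross-checked against the
MDAnalysis HELANAL implementation in the tests. The visualisation spline
some tools draw through the local axes does not change which window is
most tilted and is not computed.

Tilt is the angle between a local axis and the membrane normal, taken as
the box z axis (trajectories are built with the bilayer in the xy plane),
folded into [0°, 90°] since tilt has no sign. Per helix and frame the
maximum over windows is reported, and the summary is the mean ± std over
frames of that per-frame maximum. Kinked helices are additionally measured
on their two sub-segments; the kink is stored as a residue pair
(kink_begin, kink_end) so the torsion zone strictly between the
sub-segments is excluded from both (H5: segments 226–240 and 244–257,
zone 241–243).

## RMSD

Frames are superposed on the full protein bead selection by the Kabsch
algorithm (proper rotation enforced; at least 3 non-collinear beads
required), then RMSD is evaluated on the whole protein and on each helix's
beads *without refitting* — the "align once, measure locally" convention —
so a helix displaced rigidly relative to the aligned bundle shows its full
displacement. Beads are weighted equally (no masses in the CG model).
RMSD is reported in Å; a per-helix local refit can only lower the value,
and the suite asserts that inequality on random perturbations.

## Site-transition networks

For each lipid retained by the occupancy filter (≥ 20% of frames in
contact with any protein bead; the boundary is inclusive), each frame is
labelled by the set of helices with any bead–bead contact below 0.5 nm,
canonically written as ascending digits ("167" = H1+H6+H7). Residues
outside every helix range (loops, termini) contribute nothing to labels —
loop contacts still appear in the contact tables. Frames with no helix
contact are gaps: they neither emit a label nor break a run, because
breaking runs on every brief detachment would inflate self-transitions.
Runs of identical labels collapse to one visit; lipids whose collapsed
path is empty are excluded.

Paths are pooled per leaflet (and across replicate runs) into a network:
node weight = number of path entries with that label, edge count = number
of adjacent pairs. Two conservation laws hold exactly and are enforced in
tests: Σ node weights = Σ |path| and Σ edge counts = Σ(|path|−1). Edges
are undirected by default (transfer between two sites, no direction
stated); `directed=True` preserves order for users who want it.

Clustering is Louvain community detection on the edge-count-weighted graph
with resolution 0.8. We read the method description's "modularity
coefficient of 0.8" as the resolution parameter — the one free coefficient
Louvain exposes — rather than a reported modularity score; this is a
documented interpretation, not ground truth. The seed is explicit
(default 0) and fixed-seed runs are bit-reproducible; cluster ids are
renumbered by each community's smallest node for stable output. Networks
are exported as GEXF (node `weight`, `cluster`; edge `count`) with the
writer's volatile date stamp pinned, and as edge-list TSV.

## Membrane descriptors

Area per lipid = Lx·Ly / (lipid count of the larger leaflet), in Å². The
protein cross-section is *not* subtracted, so in protein-containing
systems the value is biased slightly high relative to a protein-free
membrane at the same true area per lipid; this keeps the number directly
comparable to standard membrane-builder reference values. Thickness is
the absolute difference of the mean PO4 z of the two leaflets, in Å. Both
are invariant to rigid translation and rotation about z (tested).

## Synthetic generator

The generator is kinematic — no forces, no thermostat; its purpose is
exercising the analysis with known ground truth, not physical realism.

Protein: one backbone bead per residue on ideal spirals (radius 0.23 nm,
100°/residue, rise 0.25 nm/residue — chosen so the tallest 32-residue
helix fits inside the 9 nm box), eight helices on a ring of radius 1.4 nm
around the box center, spiral phase rotated with the slot azimuth so
equal-length helices are exact rotated copies (azimuthal symmetry, which
the face-symmetry tests rely on). Per-helix tilt and post-kink bend are
rigid rotations about the tangential axis, so planted segment angles add
exactly and the tilt module recovers them to float precision.

Lipids: 300 per leaflet by default (600 total), placed by rejection
sampling outside a 1.6 nm exclusion disk with ≥ 0.55 nm spacing (an error
is raised if the density cannot be placed). The box is sized from the
planted area per lipid — default 67.68 Å², with Lz = 9 nm — and the
phosphate planes sit exactly at ± thickness/2 (default 42 Å) plus a small
whole-lipid z jitter (σ = 0.02 nm), so leaflet labels, area per lipid and
thickness are recovered essentially exactly. Beads ride at fixed
intra-lipid offsets (rigid internal geometry; tail flexibility is not
modelled since the analysis sees only coordinates). Lateral motion is a
2D Gaussian random walk (σ = 0.3 nm per saved frame, a desk-scale choice
giving multi-frame residence near the protein at the saved-frame cadence)
with periodic wrapping; steps into the exclusion disk are rejected
(the lipid waits). Leaflets never exchange.

Residence sites: an affinity map like `{"67": 5}` places an anchor at the
mean direction of the member helices on the exclusion circle; inside a
0.7 nm interaction shell the step size is divided by the multiplier, so
lipids linger at that face. Because the stationary density of a walk with
position-dependent step scales roughly with the square of the multiplier
and the occupancy filter further concentrates weight on trapped lipids,
collapsed visit weights grow much faster than linearly in the multiplier;
the generator therefore guarantees the *direction* of a planted bias (and
near-unity symmetry for equal multipliers), and the quantitative anchor is
the planted-site recovery study: with a 5× affinity at the H6/H7 face,
node "67" is the top-weight node in ≥ 95% of 40 seeded runs of the
600-lipid, 5000-frame condition.

Determinism: one `numpy` Generator seeded from the config; identical
config + seed reproduces the trajectory bit for bit.

## Pipeline

`run_all` executes topology → alignment → contacts → tilt → networks →
membrane, validates the configuration before any computation, pools
replicate trajectories per the rules above, and writes TSV/GEXF outputs
plus a manifest (package version, seed, config echo and hash). Outputs
are a pure function of (inputs, config, seed); the suite asserts two runs
are byte-identical.

## Problem sizes and numerical choices

Defaults exercised in tests and the verification script: 600 lipids ×
5000 frames for the recovery study (40 seeds), 500 frames for the
rank-stability fixture, smaller systems (120–160 lipids, tens of frames)
for unit tests. Distances are float64 at every membership decision;
float32 appears only in conservative prefilter bounds (padded by 10⁻³ nm)
and in generator storage, matching the precision of the trajectory
formats themselves. Ties: contacts use strict `<`; tilt folding uses
|cos|; Louvain ties are fixed by the seed and canonical node order.

## Limitations

- The generator's lipids are rigid and kinematic: no tail order
  parameters, no flip-flop, no protein conformational change. Passing
  tests demonstrate that the analysis recovers planted geometric and
  statistical structure, not that any particular real membrane behaves
  this way.
- Real CG trajectories have moving proteins; the scanner then takes the
  generic minimum-image path, which is exact but slower.
- Tilt uses the box normal as reference; for strongly undulating membranes
  a local normal would differ.
- Area per lipid ignores the protein cross-section (bias documented
  above).
- The occupancy filter, cutoff and resolution are exposed parameters;
  their defaults (0.20, 0.5 nm, 0.8) are the conventional choices for this
  kind of analysis, and the cutoff-sensitivity tool quantifies how little
  the relative contact map depends on the cutoff.
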