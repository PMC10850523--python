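# Methods

This note documents the models, parameter choices and numerical conventions
behind `greenet`, and what the synthetic study conditions do and do not
establish about real landscapes.

## Morphological segmentation (MSPA)

Foreground is the union of the configured green-space classes (default
forest, grassland, water).  The seven-class segmentation uses:

* **core** — foreground whose exact Euclidean distance to background
  exceeds `edge_width` cells (default 1; ties fall to non-core).  The area
  outside the raster counts as background; a one-cell background pad is
  sufficient because the nearest exterior cell of the infinite outside
  always lies in the first ring.
* **islet** — every cell of a foreground component (8-connected by
  default) containing no core.
* **boundary zone** — non-core cells of core-bearing components inside the
  `edge_width`-fold morphological dilation of core with the foreground
  neighbourhood.  They are **edge** when the nearest background within the
  edge width belongs to the outside (border-connected) background and
  **perforation** when it belongs to an enclosed hole; when both are
  equally near, edge wins.  Background holes use the dual connectivity
  (4-connected holes for 8-connected foreground).
* **connectors** — the remaining cells, grouped into 8-connected
  components.  A component whose halo touches ≥ 2 distinct core components
  is **bridge**; touching one core component at ≥ 2 disjoint contact zones
  is **loop**; otherwise **branch**.  Boundary cells are attributed to the
  core component of their nearest core cell for this counting.

Core/islet/edge/perforation follow the standard distance-transform
semantics exactly and are verified against a brute-force oracle on random
masks.  The connector subtypes are a simplified, fully documented stand-in
for geodesic-skeleton taxonomies: trunk cells of a connecting path are
labelled, but its attachment cells within the core's boundary zone remain
edge.  No bit-compatibility with morphological GIS toolboxes is claimed.

## Probability of connectivity and source screening

Direct dispersal between patches uses the negative-exponential kernel
p(d) = exp(ln(p₀)·d/d₀) calibrated through (d₀, p₀) = (2500 m, 0.5), the
standard mid-range terrestrial calibration.  Inter-patch distance is
edge-to-edge between nearest pixels (conservative for large patches, the
usual connectivity-software convention).  Maximum-product path
probabilities p* are all-pairs shortest paths on −log p weights, so
p*ᵢⱼ ≥ pᵢⱼ and p*ᵢᵢ = 1; the i = j terms are included in the PC double sum,
making a single patch filling the landscape reach PC = 1.  dPC removes one
patch at a time and re-solves the path problem from the direct kernel,
because removal can destroy stepping-stone routes.  A_L is the total
non-nodata raster area.

Patches are gated by area first (≥ 25 km²) and dPC (> 0.5) second; dPC is
computed among the area-passing patches.  This matches the screening order
of regional studies and keeps the per-patch removal loop cheap.

## Resistance surface and corridors

Each factor is graded 1–5 by exact 1-D least-squares natural breaks
(Fisher–Jenks dynamic programming).  Above 1500 samples the breaks are fit
on evenly spaced order statistics — deterministic, and accurate for the
smooth value distributions the generator produces.  Direction conventions:
NDVI, MNDWI and water-network density are inverted (high value → low
resistance); DEM, slope, population and road density are direct; the land
use factor is an ordinal class recode mapped straight to grades.  Factor
weights default to 1/8 each and are configurable — real applications should
substitute expert or AHP weights.

Accumulated cost uses an 8-connected lattice with step cost equal to the
mean of the two cell resistances times the step length (cell size, ×√2
diagonally), i.e. the minimum-cumulative-resistance model with the outer
function taken as identity, the standard choice.  Corridors are backtracked
predecessor paths from multi-source Dijkstra runs rooted at each patch.
The library extracts corridors for every source pair; the pipeline then
drops pairs whose path crosses a third source patch ("mediated" pairs,
already represented by their two member corridors).  Without this pruning
the deduplicated graph is complete whenever the surface is connected, which
makes every topology indicator degenerate and contradicts the sparse
corridor systems reported in regional practice.

## Gravity model and tiering

Node mass is the equal-weight mean of min–max standardized attributes
(default area and dPC) plus ε = 0.01 so no source has zero interaction.
The exponent is pair-specific, r = d/l (straight-line over corridor
length), read literally from the model's definition of r as that ratio and
clamped to [0.5, 3] to guard degenerate geometry; since l ≥ d the effective
exponent is ≤ 1, damping distance decay for sinuous corridors.  A constant
r is available (`r=1`).  Tier thresholds are the G terciles with ties going
to the higher tier, so an all-equal network is all primary; tiering depends
only on ranks.

## Network topology

Indicators are computed on the unweighted simple graph (parallel corridors
collapse to the min-cost edge).  Conventions: classic closeness within the
component; betweenness normalized by (n−1)(n−2)/2; eigenvector centrality
by power iteration on A + I (the shift prevents oscillation on bipartite
graphs) scaled so the maximum is 1; PageRank with damping 0.85 and
tolerance 1e-9; eccentricity and average path length per component, the
latter averaged over connected pairs; Louvain communities with a fixed seed
and labels canonicalized by smallest member id; modularity
Q = Σ(e_c/m − (d_c/2m)²) evaluated unweighted.  Isolated nodes report
closeness/eccentricity 0 with a flag.

## Carbon accounting

C_tot per cell is the four-pool density sum of its class (Mg/ha) times the
cell area in hectares.  The default density table is a configurable
placeholder plausible for a temperate North-China landscape (forest 166,
cropland 87.4, grassland 100.6, water 40.1, built 46.6, barren 30.7 Mg/ha
total) — real studies must substitute regionally calibrated values.  Buffer
profiles are cumulative disks (each buffer contains the previous one and
the geometry's own cells), matching the reading of "means decreasing with
buffer distance" as cumulative; ring buffers are intentionally not the
default.  Nodes default to source centroids; a node's scalar carbon value
is the mean of its buffer means.  Buffers clipped by the raster edge are
computed over the intersection and flagged.

## Landscape pattern indices

Class-level metrics (CA, LPI, LSI, COHESION, DIVISION, SPLIT) use
8-connected patches and cell-edge perimeters that count the window
boundary, so a single square patch has LSI exactly 1 and
DIVISION = 1 − 1/SPLIT holds identically.  Landscape-level CONTAG, SHDI and
SHEI use double-counted 4-neighbour adjacencies; a single-class window has
SHDI = SHEI = 0 and CONTAG = 100.  Note that CONTAG is minimized by
near-uniform pairwise adjacency distributions (random speckle), not by a
checkerboard, whose perfectly ordered cross-class adjacency scores 50.
The per-source analysis window is the patch's bounding clip masked to the
patch polygon; an optional margin widens it to include surroundings.

## Correlation screening and weak nodes

Pearson r with two-sided p from the t-transform; stars follow the
half-open intervals 0.01 ≤ p < 0.05 (*), 0.001 ≤ p < 0.01 (**),
p < 0.001 (***).  Missing rows are dropped pairwise and cells with < 3
complete pairs or a constant vector are reported NA.  No multiple-testing
correction is applied by default, mirroring the star-matrix convention.
Weak carbon-sink nodes require *strictly* decreasing buffer means for both
the node and its source; a non-increasing variant exists behind a flag, and
the pipeline falls back to it (then to a plain top-3 by difference) so that
degenerate landscapes still produce an optimization target.  Ranking is by
|node − source| carbon, descending, with node id as the deterministic
tie-break.

## Optimization and robustness

The plan adds, per weak node, edges to its k = 2 nearest non-adjacent
nodes (by corridor cost, else straight-line distance) and a stepping stone
at the geometric midpoint of incident corridors longer than 1.5 × the
median corridor length.  Stones split their edge into two half-cost edges.

Attack schedules remove ⌈fraction·N⌉ nodes: a seeded uniform permutation
(random) or descending initial degree with ascending-id ties (malicious;
static degrees keep schedules comparable before/after optimization).  The
default recovery rule recovers a node at its own removal step iff an
original neighbour currently sits in the giant component, restoring edges
to giant-component neighbours; always/never rules bound the behaviour.
D, E, R are evaluated after every step; recovery can push the printed
formulas above 1, so values are clamped to [0, 1] and the clamp is flagged
per row.  The before/after comparison aligns curves on the step index of
one shared schedule over the original nodes (added stones are never
attacked) and reports per-step deltas, the improved fraction, and the
mean-value (AUC) difference.

## Synthetic study conditions

The generator emulates a 200 × 200 grid of 1 km cells: per-class Gaussian
fields smoothed at a 4-cell clumping scale, argmax assignment with offsets
calibrated to the target proportions (cropland 0.30, forest 0.30, grass
0.15, water 0.05, built 0.15, barren 0.05 — green foreground ≈ 0.5), plus
12 compact forest massifs of 3–7 cells radius so the landscape always
contains source-grade core patches.  These conditions yield an MSPA core
share near 40% and, typically, 7–20 ecological sources — a fragmented
regional mosaic.  Factor fields are smooth (lag-1 autocorrelation > 0.5)
and anchored to the land-use pattern (NDVI to vegetation, population to
built cells, and so on).  All randomness derives from one integer seed via
fixed stream offsets; identical configs are bit-identical.

What the generator does **not** emulate: realistic spectral noise,
hydrologically consistent terrain, gravity-shaped population fields,
anisotropic road networks, or temporal change.  Green tests on these
fixtures establish the correctness of the algorithms and the internal
consistency of the pipeline — not the ecological validity of any specific
regional conclusion, which depends on real data and calibrated weights and
densities.

## Problem sizes and numerical tolerances

Oracle suites run at the sizes where exhaustive checking is exact: random
masks ≤ 8×8 (MSPA), patch systems n ≤ 6 (path enumeration), 15×15 grids
(Dijkstra), graphs n ≤ 7 (indicator definitions), 6×6 windows (landscape
formulas).  The end-to-end pipeline runs at the full default 200×200 in a
few seconds.  Floating-point equalities are asserted at 1e-9 relative
unless an exact integer identity applies; the eigenvector comparison uses
1e-5 against a dense eigendecomposition.

## Known limitations

* Connector subtypes (loop/bridge/branch) are approximate, as described.
* Corridors are single-cell-wide paths; no corridor width buffering or
  circuit-theory current maps.
* The gravity mass uses area and dPC, not a full ecosystem-service
  valuation.
* The recovery mechanism in the robustness statistics is a modelling
  choice; the shipped rules bound, but do not resolve, that ambiguity.
* Default weights, grades and carbon densities are placeholders standing
  in for unpublished calibration tables.
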