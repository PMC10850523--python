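# greenet

Green-space ecological network construction, carbon accounting and
attack-robustness analysis on categorical land-use rasters.

`greenet` is aimed at landscape ecologists and regional planners who want a
reproducible, scriptable version of the classic GIS workflow for ecological
security patterns: identify structurally important green patches, connect
them with least-cost corridors, read the result as a graph, relate its
topology and landscape pattern to carbon stocks, and test how much a
proposed optimization actually buys in resilience.

## What it computes

1. **MSPA segmentation.** A binary green-space foreground (forest, grass,
   water) is segmented into the seven morphological classes — core, islet,
   perforation, edge, loop, bridge, branch — using an exact Euclidean
   distance transform (core = foreground farther than the edge width from
   background) and connected-component rules for the connector subtypes.
2. **Source screening by probability of connectivity.** Core patches are
   scored with

   PC = ( Σᵢ Σⱼ aᵢ aⱼ p*ᵢⱼ ) / A_L²,  dPCₖ = (PC − PC_rem,k)/PC × 100

   where aᵢ are patch areas, A_L the landscape area and p*ᵢⱼ the best
   product of step probabilities over patch paths under a negative
   exponential dispersal kernel calibrated so p(2500 m) = 0.5.  Ecological
   sources are core patches with area ≥ 25 km² and dPC > 0.5.
3. **Resistance surface and corridors.** Eight factors (DEM, slope, NDVI,
   MNDWI, land use, population / water-network / road-network density) are
   graded 1–5 by Jenks natural breaks and combined as a weighted sum; the
   minimum cumulative resistance MCR = min Σ Dᵢⱼ × Rᵢ is accumulated on an
   8-connected lattice and corridors are backtracked least-cost paths
   between source pairs.
4. **Gravity tiering.** Pair interaction G = Mᵢ Mⱼ / dʳ (standardized
   masses, straight-line distance d, exponent r = d/l with corridor length
   l) splits corridors into primary/secondary/tertiary tiers by terciles.
5. **Network topology.** Sources become nodes, corridors edges; each node
   gets degree, clustering, closeness, betweenness, eccentricity,
   eigenvector centrality, PageRank and a Louvain community label, plus the
   graph-level average path length and modularity Q.
6. **Carbon stocks.** Per-cell C_tot = C_above + C_below + C_soil + C_dead
   (Mg/ha by land-use class, stock = density × cell area), with mean-carbon
   profiles over cumulative 500/1000/1500/2000 m buffers around every node
   and source.
7. **Screening and optimization.** Pearson correlation (with the usual
   */**/*** significance stars) relates topology and landscape-pattern
   indices (CA, LPI, LSI, COHESION, DIVISION, SPLIT, CONTAG, SHDI, SHEI,
   dPC) to carbon; nodes whose node *and* source buffer profiles decay with
   distance are ranked as weak carbon sinks; the optimizer adds corridors
   to their nearest non-adjacent nodes and stepping stones on long
   corridors.
8. **Robustness verification.** Under seeded random or degree-targeted
   attack schedules with a pluggable recovery rule, the package tracks
   D = 1 − (N_r − N_d)/N, E = 1 − (M_r − M_e)/M and R = C/(N − N_r)
   before and after optimization.

A synthetic-landscape generator (clumped categorical mosaics, smooth
correlated factor fields, configurable carbon-density table) provides the
study conditions, so the entire pipeline runs from a single seed with no
external data.

## Worked example

```python
from greenet.pipeline import RunConfig, run_all

manifest = run_all(RunConfig(seed=1), "out/")
print(manifest["results"])
```

prints (seed 1, default 200 × 200 km synthetic landscape at 1 km cells):

```
core_percent         40.385      # MSPA core share of the landscape
n_sources            7           # core patches passing area + dPC gates
n_corridors          8           # least-cost links between sources
modularity_Q         0.25        # Louvain modularity of the network
total_carbon_Mg      416291950.0 # landscape carbon stock, tonnes
auc_R_pre            0.924       # mean connectivity robustness under attack
auc_R_post           1.0         # ... after adding 2 corridors
auc_diff_R           0.076       # the optimization's robustness gain
```

So roughly 40% of this landscape is interior green space; seven patches are
both large and irreplaceable enough to act as ecological sources; and adding
two corridors around the weakest carbon-sink node lifts the network's mean
connectivity robustness under targeted attack by about 8 points.

The same run from the shell:

```bash
greenet run --config examples/default.yaml --outdir out/
```

writes GeoTIFF rasters (land use, MSPA classes, resistance, carbon), GeoJSON
sources and tiered corridors, GraphML networks (before/after optimization),
CSV indicator tables and a `manifest.json` whose per-stage checksums are
bit-identical across reruns of the same config.

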