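# pondnet

Circuit-theory landscape connectivity and community statistics for urban
pond networks, aimed at spatial ecologists studying how the urban matrix
shapes pond-breeding insects such as Odonata (dragonflies and damselflies).

Urban stormwater ponds can act as stepping stones between natural
wetlands — but only if the intervening land cover lets adults move.
`pondnet` implements the full analysis chain used to test that idea:

1. **Resistance surface** — a 10-class categorical land-cover raster is
   reclassified to movement resistance r ∈ {1, 10, 100} (wetlands/water
   low, semi-natural cover medium, settlement/transportation high).
2. **Circuit model** — the raster becomes a resistor network (4- or
   8-neighbourhood; conductance g = 1/(mean(rₐ, r_b)·d), d = √2 on
   diagonals). For focal nodes s, t the graph Laplacian system
   **L**v = e (e = +1 at s, −1 at t) is solved sparsely; per-cell
   current density cᵢ = ½ Σⱼ |g_ij (vᵢ − vⱼ)| is the circuit analogue of
   expected movement intensity, and the effective resistance is
   v(s) − v(t).
3. **Omnidirectional connectivity map** — to avoid edge artefacts the
   map is padded with a randomised buffer holding a representative
   low/medium/high mix (default 14.2%/34.8%/51.0%), nodes are scattered
   on the outer perimeter, and the per-cell densities of all C(n, 2)
   node pairs are averaged (50 nodes → 1225 pairs), then log10-scaled.
4. **Site metrics** — around each pond, at a taxon-specific radius
   derived from flight-distance literature (max mean daily distance
   rounded to 100 m: 900 m for Anisoptera, 300 m for Zygoptera), the
   mean and SD of current and the number of neighbouring habitat
   patches are extracted.
5. **Statistics** — per suborder: Gaussian linear models of abundance,
   Shannon diversity (nats) and richness against each predictor
   separately (12 models), log-likelihood screening of uninformative
   parameters, Hellinger-transformed redundancy analysis
   (y′ = √(y/row total); permutation F test, B = 999, p = (b+1)/(B+1);
   Ezekiel-adjusted R²), and Wilcoxon rank-sum comparisons of natural
   vs stormwater ponds.

A first-class synthetic-data module generates seeded urban mosaics,
pond networks and negative-binomial communities with the assumed
structure (dragonflies respond positively to connectivity, damselflies
weakly/negatively, one indicator dragonfly concentrated at
high-connectivity natural ponds), so the whole pipeline is testable
without any GIS downloads.

## Worked example

```python
from pondnet import (LandscapeConfig, generate_landscape, classify, add_buffer,
                     place_perimeter_nodes, build_graph, mean_current_map)

landcover = generate_landscape(LandscapeConfig(grid_rows=120, grid_cols=120, seed=11))
buffered = add_buffer(classify(landcover), width_m=300.0, seed=12)
graph = build_graph(buffered, neighbourhood=8)
cmap = mean_current_map(graph, place_perimeter_nodes(buffered, 30, seed=13))
print(cmap.n_pairs, cmap.values.min(), cmap.values.max())
```

Running `python examples/01_connectivity_map.py` (which wraps the
above) prints:

```
study area: 120x120 cells at 10 m; resistance mix low/medium/high = 14.2%/34.8%/51.0%
averaged 435 node pairs; log10 mean current over the study area spans -3.64 to -1.54 (median -2.42)
```

435 = C(30, 2) circuits were solved and averaged; cells near −1.5 are
the landscape's movement corridors, cells near −3.6 its dead zones.
`examples/02_site_metrics.py`, `03_community_analysis.py` and
`04_full_pipeline.py` walk the remaining capabilities, ending in the
12-model GLM table, the 4 constrained ordinations and a seeded,
checksummed run manifest. A thin CLI mirrors the stages
(`pondnet simulate|classify|buffer|current|metrics|stats|run`).

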