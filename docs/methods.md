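# Methods

## The model

`pondnet` treats a projected categorical land-cover raster as an
electrical network and equates connectivity with current density. Each
cell is a node; orthogonally and (in the default 8-neighbourhood)
diagonally adjacent cells are joined by a resistor. The conductance of
an edge between cells with resistances rₐ and r_b is

    g = 1 / (mean(rₐ, r_b) · d),  d = 1 (orthogonal), √2 (diagonal),

i.e. average-resistance coupling with a diagonal distance correction.
This rule is the package default and is deliberately stated rather than
inherited silently: an average-conductance rule is a defensible
alternative, and the graph builder is the single place where the choice
lives. Resistance values come from a ten-class scheme — wetlands and
water 1 (primary habitat), crop/pasture, grassland, large rivers, rock
barren, sand/gravel and wooded area 10 (usable but not habitat),
settlement and transportation 100 (hostile) — shipped as a packaged CSV
and overridable per run.

For one source/target pair, injecting a unit current gives the
Laplacian system **L**v = e. The system is solved on the reduced
Laplacian with one node grounded (sparse LU), which removes the
singular constant mode deterministically; the full-system relative
residual is checked against 1e-8. Per-cell current density is half the
sum of absolute edge currents at the cell (terminals carry the injected
unit by definition); effective resistance is the potential difference
per unit current. Current conservation, source/target reciprocity,
invariance under global resistance scaling, and agreement with a dense
deflated-inverse oracle are all enforced in the test suite.

### Edge correction and the mean map

Artificial map edges inflate apparent resistance, so before solving,
the raster is padded on all four sides with a buffer of iid draws from
{1, 10, 100} at a configurable "representative" ratio (default
14.2%/34.8%/51.0% low/medium/high). iid sampling is the simplest
construction that is both random and ratio-faithful; the pad is a
rectangular frame rather than a geodesic annulus because the grid is
already projected and only the ratio and width matter for edge
correction. Focal nodes are sampled uniformly without replacement from
the outermost one-cell ring ("around the perimeter" operationalised on
a grid). The connectivity surface is the per-cell mean density over
*all* C(n, 2) unordered node pairs — with the canonical 50 nodes, 1225
pairwise solves; one LU factorisation is shared across pairs, so the
cost per pair is a pair of triangular solves plus a sparse
matrix-vector product. A `pair_mode="nearest"` variant (each node
against its k nearest node neighbours) is available for sensitivity
analysis. Because mean densities span orders of magnitude, the map is
log10-transformed by default with a floor of 1e-12; the flag and floor
are recorded on the map object so downstream tables know which scale
they summarise.

The canonical buffer width is 15 km at 10 m resolution (1500 cells per
side). Demonstrations, tests and the acceptance script use study areas
of 20–200 cells a side with buffers of 2–30 cells and 8–50 nodes: the
solver contracts (residuals, conservation, oracle agreement) are
size-independent, and these sizes keep the full suite in minutes on one
CPU. Those problem sizes are the package's own test-design choice.

## Site metrics and scales

Zonal statistics use cell-centre-in-circle membership with an inclusive
boundary — the common zonal-statistics default, fixed here because
boundary conventions otherwise silently change neighbour counts. The SD
is the sample SD (ddof = 1, recorded). The focal pond's own water cells
are included in its buffer statistics; a masking option exists but is
off by default. Neighbour counts merge wetland/water patch centroids
(large rivers excluded — the species modelled breed in ponds, not
rivers) with active stormwater-facility points, de-duplicated within
half a cell; a point within half a cell of the focal pond is treated as
the pond itself and not counted.

Analysis radii are taxon-specific: the maximum mean daily flight
distance per suborder, rounded half-up to the nearest 100 m. With the
packaged (synthetic, literature-style) flight table this yields 900 m
for dragonflies and 300 m for damselflies. Only this final arithmetic
is implemented; the upstream systematic-review screening that produces
such a table is out of scope.

## Statistical battery

Responses per pond and suborder: total abundance, species richness
(count of species with positive counts) and Shannon diversity in nats
(base e matches the convention of the standard vegan implementation).
Each response is regressed on mean current and on neighbour count in
*separate* Gaussian OLS models because the two predictors are strongly
collinear; that yields 3 responses × 2 predictors × 2 suborders = 12
models. Residual diagnostics are reported as statistics (skewness and
the slope of squared residuals on fitted values) rather than plots. No
multiple-testing correction is applied by default.

An extra parameter (canonically the SD of current) is screened as
*uninformative* when adding it improves the Gaussian log-likelihood by
less than 1.92 — half the 95% point of χ²₁, equivalently the point at
which AIC stops preferring the smaller model. The threshold is a
parameter because "did not improve the log-likelihood" admits several
operationalisations; 1.92 is the documented default.

Composition is analysed by transformation-based RDA with a single
constraint: Hellinger transform y′ = √(y/row total) (zero rows stay
zero and are flagged), column centring, and the constrained variance
fraction R² from the per-species regression on the centred predictor.
Significance uses a permutation F test with the (b + 1)/(B + 1)
convention (B = 999 by default; p can never be 0) and a required seed;
the permutation F values are computed with a single matrix product, so
calibration studies with hundreds of replicates stay cheap. Adjusted R²
is Ezekiel's 1 − (1 − R²)(n − 1)/(n − m − 1). Species scores are
covariances of the transformed, centred species columns with the
constrained site axis, oriented along the predictor. The implementation
is cross-checked in the test suite against `vegan::rda` on a small
matrix (R², adjusted R², pseudo-F to 1e-8). Each suborder is analysed
at its own scale; that pairing is configurable.

Pond-type contrasts use the Wilcoxon rank-sum test with midranks:
exact enumeration when the combined sample is ≤ 12 without ties,
otherwise the normal approximation with tie and continuity corrections,
with the method recorded alongside W and p.

## Synthetic data: what it does and does not emulate

The landscape generator apportions cells to the ten classes by largest
remainder, draws roads as random straight polylines (stopping exactly
at the transportation quota), grows wetlands as contiguous clusters by
seeded region growing from random kernels, and scatters the remaining
classes iid. This reproduces the features the analysis is sensitive to
— wetland clustering, linear high-resistance barriers, a controllable
low/medium/high ratio (default mixture realises 14.2/34.8/51.0) — but
not real geography: no rivers with banks, no road networks with
topology, no pond age structure, no spatial autocorrelation beyond the
clusters. Natural ponds are placed in or beside wetland clusters and
stormwater ponds in settlement-dominated neighbourhoods (≥ 25% built
cover in a 7×7 window), mirroring the siting contrast of real pond
networks.

Communities are negative binomial (mean μ, size k; variance
μ + μ²/k; Poisson recovered for large k) with a log link on
connectivity z-scored across sites — z-scoring makes slopes comparable
across landscapes. All dragonflies share one slope except a single
indicator species with its own (larger) slope and an extra log-mean
bonus at natural ponds; the bonus defaults to the indicator slope so
that setting every slope to zero yields a genuinely null community —
an earlier fixed bonus coupled pond type to connectivity and silently
inflated null rejection rates, which is why the coupling is explicit.
Damselflies share one (typically non-positive) slope. Counts are drawn
per seasonal visit (two visits, each NB with mean μ/2) and aggregated
by sum (default) or max, since field protocols that record per-visit
maxima admit either convention. The distribution of real pond counts is
unknown; negative binomial is a standard ecological convenience choice,
not an inference from data. Consequently, passing calibration and
recovery tests shows the statistical machinery is correct and
well-sized *under this generative model*, not that real communities
follow it.

`generate_site_metrics` fabricates a two-scale metrics table directly
(natural ponds higher current and more neighbours, neighbour counts
positively tied to current) for simulation studies where the raster
stages are not under test; its location parameters are chosen to sit in
the empirical regime of urban pond surveys (log10 current around −0.7
at stormwater and −0.2 at natural ponds, neighbour counts of order 10
and 100 at 900 m).

## Numerical choices and degenerate inputs

- Zero or non-finite resistances are rejected at graph build; the
  scheme guarantees r ≥ 1.
- Disconnected focal pairs raise an error naming offending pairs
  (cannot occur on grid graphs, but the graph type admits general edge
  lists).
- `fit_glm` refuses constant predictors; on small demonstration maps a
  radius larger than the map makes neighbour counts constant, which is
  why demo configurations override the analysis scales.
- Rounding of flight distances is half-up (`floor(x/100 + 0.5)·100`),
  so 850 → 900.
- Majority resampling from a finer categorical grid breaks ties toward
  the smallest class code.
- Permutation and sampling seeds are explicit arguments everywhere; the
  pipeline derives per-stage seeds from one global seed via
  `SeedSequence.spawn`, and its manifest records seeds, timings and
  SHA-256 checksums of every artifact.

## Known limitations

- No CRS handling: inputs must already be projected in metres.
- Raster I/O is ESRI ASCII grid only; no GeoTIFF geo-tags.
- The solver is a direct sparse LU; very large rasters (the canonical
  15 km buffer at 10 m resolution implies ~10⁷ cells) would need an
  iterative or multigrid solver, which is out of scope.
- One constraint per RDA (matching the one-predictor-at-a-time design);
  multi-constraint partial RDA is not implemented.
- The indicator-species construction encodes the assumed ecology
  (connectivity-loving, natural-pond-concentrated); it is a synthetic
  stand-in, not an empirical species model.
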