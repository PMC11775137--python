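# Methods

`sedarange` analyses long-format plant community tables recovered from
multi-lake sedimentary-DNA (sedaDNA) metabarcoding records: read counts
per (lake, 1000-year time-slice, taxon), a lake coordinate registry and
a growth-form trait table. Its question is temporal: how does the
relationship between per-slice taxonomic richness and mean geographic
range size change through a deglaciation, and do biotic-interaction
proxies (cushion-plant vs. tree abundance) explain the change?

## Time convention

Ages are calendar years BP. Slice `k` covers the half-open interval
`((k−1)·W, k·W]` with slice width `W = 1000` y, so slice 1 is the most
recent and a 30,000-year record yields 30 slices. The half-open rule is
our choice — a sample dated exactly on a boundary joins the older
slice; no published convention exists for that tie. A "modern" 2000-year
unit is the union of slices {1, 2}, not a wider slice. Windows are
`width = 5` consecutive slices advancing by `step = 1` (26 windows for
30 slices), labelled by their old/young slice ages, e.g. `23–19ka`.

## Rarefaction

Read depth varies across lakes and slices, and richness estimates rise
with depth, so every (lake, slice) sample is rarefied to a common
`base_count = 5000` reads by multivariate hypergeometric subsampling
(without replacement — the standard community-ecology rarefaction; a
multinomial with-replacement variant exists behind a flag for
sensitivity runs). The procedure repeats for `n_iterations = 100`
independent iterations. Samples shallower than the base count are
excluded — not up-scaled — identically in every iteration, and logged;
exclusion is the conservative reading of equal-count standardisation.
Iteration `i` uses an RNG substream seeded `(rng_seed, i)`, making
iterations individually reproducible and order-independent.
Rarefaction is applied per lake-slice sample, not per pooled slice.
Downstream incidence (presence = rarefied count ≥ 1) feeds richness,
range sizes and turnover; whether the original study used rarefied or
raw incidences for turnover is not documented — rarefied is used here
for internal consistency.

## Range-size estimators

*AOO (area of occupancy)*: a taxon's range in a slice is the number of
lakes where it has a positive rarefied count, in lakes (1..n_lakes).

*EOO (extent of occurrence)*: lakes are projected with a spherical
Lambert azimuthal equal-area projection (authalic radius
6 371 007.181 m) centred on the mean lake position; over a regional
extent the projected distances agree with great-circle distances to
well under 1% (tested). A square grid with 200 km sides is anchored
half a cell below/left of the projected bounding box, so no lake sits
on a grid line at default precision; a point exactly on a boundary is
assigned to the cell with the smaller index (tested). A taxon's EOO is
the summed area (km², cell area 40 000 km²) of cells whose closed
square intersects the convex hull of its occupied lakes. Degenerate
cases follow explicit rules: one lake → the containing cell only; two
lakes or collinear sets → cells intersecting the connecting segment.
"Overlap" as closed-set intersection (boundary touch counts) is a
deliberate choice: it is deterministic and checkable against a
rasterisation oracle. With ≤ 16 lakes the per-taxon EOO reduces to a
lookup over the `2^n − 1` possible occupied-lake sets, making the
per-iteration computation a vectorised table lookup.

Per (iteration, slice) the summary is richness `S` (distinct taxa with
≥ 1 read in any lake) and the AOO and EOO means over exactly those `S`
taxa; empty slices carry missing means and contribute no window points.
On synthetic data the two estimators rank slices almost identically
(Spearman > 0.8 across slices, tested), so analyses default to AOO.

The same AOO logic applies to arbitrary point occurrences binned into
grid cells (`grid_cell_stats`) for spatial-domain richness/range
regressions against independent occurrence databases.

## Moving-window regression and sign classification

Within a window, each (iteration, member slice) pair with a defined
mean range contributes one point — 500 for a complete window. The OLS
fit is richness (response) on mean range size (predictor);
`σ̂² = RSS/(n−2)`. Uncertainty is propagated by posterior simulation:
per draw, `σ² = σ̂²(n−2)/χ²_{n−2}` and coefficients from
`N(β̂, σ²(XᵀX)⁻¹)`; a perfect fit degenerates to the point mass at β̂.
The default pools all points into one fit per window and simulates
draws from it; per-iteration fits are available through
`window_iteration_classes`. The sign classification uses Spearman's
rank correlation (average ranks, two-sided t-based p): positive if
R > 0.2, negative if R < −0.2, otherwise indeterminate — strict
inequalities, so R = 0.2 is indeterminate. Spearman rather than the
OLS slope is classified because it is symmetric in the axes and
invariant to monotone rescaling. Mixed-regime windows are classified
like any other; p-values are descriptive with no multiplicity
correction across overlapping windows.

## Turnover heterogeneity

Biotic heterogeneity per (iteration, slice) is the multiple-site
Jaccard turnover across lakes

    β_JTU = 2·Σ_{i<j} min(b_ij, b_ji)
            / [(Σ_i S_i − S_T) + 2·Σ_{i<j} min(b_ij, b_ji)]

(the replacement component of the Jaccard-family beta-diversity
partition), which isolates species replacement from richness
differences. Two sites reduce to `2·min(b₁₂,b₂₁)/(a + 2·min)`, the
closed form used as a test oracle. All-identical sites define
β_JTU = 0. Slices with fewer than two occupied lakes are missing.
Values are computed per iteration and summarised (median, quartiles)
and window-averaged for reporting. Nestedness and Sørensen-family
variants are out of scope.

## Interaction GLMs

Group abundance is the read-count share (%) of cushion-plant or tree
taxa in a unit (an incidence-share variant exists behind a flag). The
GLM unit is a (window, iteration) pair: its response is that
iteration's own 5-point relationship sign (indeterminate excluded),
its predictor the median group share across the window's member slices
in that iteration; a per-window pooled-unit alternative is supported.
The logistic fit is maximum likelihood via Newton/IRLS with
step-halving (log-likelihood non-decreasing; converged when the
largest coefficient update < 1e−8 within 50 iterations; final gradient
norm < 1e−6, tested).

Separation policy: no penalisation is ever applied. `fit_logistic_irls`
raises on complete separation. At the generator's default conditions
the classes *are* completely separated (glacial windows unanimously
positive with ~45% cushion share, Holocene windows unanimously negative
with ~12%), so the analysis wrapper reports a non-converged fit whose
slope is ±∞ with the mathematically determined sign — the direction in
which the likelihood diverges — rather than a spurious finite estimate.
Real records, with gradual group turnover and noisier classifications,
typically yield finite slopes (and do for some generator seeds).

## Co-occurrence network

Families with ≥ 10 reads summed over all slices and presence in ≥ 5
slices are retained; their abundance series (reads per slice, pooled
over lakes — 30 observations) are correlated all-pairs by Spearman.
P-values are Benjamini–Hochberg adjusted over all tested pairs (the
adjustment method is configurable; BH is the standard choice for
correlation screens). An undirected edge requires r > 0.6 *and*
adjusted p < 0.05; only positive associations are kept, and filtered
families remain as degree-0 nodes. Communities maximise Newman–Girvan
modularity: components with ≤ 12 nodes are solved exactly by
set-partition enumeration with incremental bookkeeping (optimal
partitions never merge disconnected components, so per-component
optima compose), larger components fall back to greedy agglomeration
with the method recorded. Each community reports node count, internal
edge count and its internal edges as a percentage of all network edges;
both counts appear explicitly because the percentage's natural
denominator is ambiguous (internal vs. all edges), so any convention
can be recomputed. A community is labelled glacial/Holocene by where
its members' summed reads concentrate — reporting convenience only.
Edges must not be read as direct interactions; indirect and
environmentally induced correlations are indistinguishable here.

## Synthetic community generator

The generator exists to exercise the *analysis*, not to model ecology
mechanistically. Defaults define the reference conditions: 7 lakes, 30
slices, regime boundary at slice 11, a 150-taxon pool over 20 families
(4 cushion, 2 tree), mean slice richness λ = 60 (Poisson, truncated
≥ 5), 20 000 reads per lake-slice, Dirichlet(1) within-slice relative
abundances, and a ×5 abundance boost of the regime-favoured group
(cushion in glacial, tree in Holocene slices). The core mechanism is a
logit coupling of occupancy to standardised richness: each present
taxon occupies `1 + Binomial(n_lakes − 1, p_t)` uniformly chosen lakes
with `logit(p_t) = a + b·(S_t − λ)/√λ`, `b = +0.6` (glacial) or `−0.6`
(Holocene). This is the minimal mechanism producing the
positive-then-negative richness/range correlation a facilitation→
competition shift would leave in such a record; effect sizes are tuning
choices exposed in `SimParams`, not empirical claims. A single RNG
stream per dataset (documented draw order) makes outputs reproducible;
the truth record stores the *realized* state recounted from the emitted
table, so truth and table can never disagree.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: temporal autocorrelation of composition
(each slice's taxa, abundances and occupancies are redrawn
independently), spatial autocorrelation among lakes, taphonomic decay
and DNA-damage gradients, depth-age uncertainty, and detection
differences among taxa. Two visible consequences: family abundance
series are noisy enough that the co-occurrence network is typically
edgeless at the r > 0.6 threshold under default settings (persistent
composition in real records is what sustains high rank correlations),
and the interaction GLM separates completely (see above). A detection
artefact worth knowing: at low read depth, richer slices dilute
per-taxon reads and depress *realized* occupancy, biasing the
richness–occupancy correlation negative; at the default 20 000
reads/sample the bias is negligible (tested against a zero-coupling
null).

## Numerical choices

- OLS via `numpy.linalg.lstsq`; tested to 1e−10 against extended-
  precision normal equations. Constant predictors raise.
- Logistic IRLS tested to 1e−4 against a brute-force likelihood-grid
  maximiser and cross-checked against an independent GLM fitter.
- Spearman via scipy (average ranks); |R| = 1 forces p = 0.
- EOO tested for exact cell-set equality against a hull-rasterisation
  oracle (1 km interior lattice; boundary handled by exact grid-line
  traversal so corner slivers thinner than any sampling pitch are
  detected).
- Exact modularity enumeration capped at 12-node components
  (≈ 4·10⁶ partitions); beyond that, greedy with the method recorded.
- Degenerate inputs have defined outcomes throughout: empty slices
  (richness 0, missing means), < 2 occupied lakes (missing turnover),
  all-identical sites (β_JTU = 0), σ̂ = 0 (point-mass posterior),
  single-class GLM response (error), edgeless network (trivial
  partition with warning).

## Problem sizes

Default runs — 7 lakes × 30 slices × 100 iterations, 150-taxon pool —
complete in a few seconds per dataset on one CPU; replicate studies in
the test-suite and the reproduction script use 10–20 seeded datasets.
These sizes are the package's reference conditions; everything scales
linearly in iterations and samples except exact modularity search.

## Known limitations

- No age–depth modelling, taxonomy assignment or sequence-level
  simulation; ages arrive pre-binned, taxa pre-assigned.
- No coverage-based (Chao-type) standardisation or extrapolation.
- No autocorrelation-corrected regression; windows overlap and share
  slices, so neighbouring window statistics are strongly dependent.
- No concave hulls or ellipsoidal area corrections in EOO.
- The heterogeneity proxy is biotic turnover only; abiotic
  heterogeneity (topography, soils) is out of scope.
- Network edges are associational; no deconfounding is attempted.
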