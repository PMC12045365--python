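# Methods

## The quantity being estimated

The pipeline asks whether marker-positive tumor cells (proliferating,
BrdU-incorporating cells in the motivating application) are spatially
biased toward stromal regions within a single histological cross-section,
and whether that bias differs between treatment groups or host models.
The per-cell statistic is the Euclidean distance to the nearest stroma
pixel; the per-sample effect sizes are the KS statistic between the
positive-cell and all-cell distance ECDFs and the observed-minus-null
median/mean distance of positives (Δ, µm).  Negative Δ means positives
concentrate peristromally.

## Distance definition and its discretization error

Distances are measured on the rasterized stroma geometry, pixel center to
pixel center: a cell at continuous position (x, y) belongs to pixel
(⌊y⌋, ⌊x⌋) and receives the exact Euclidean distance transform value of
that pixel times the pixel size.  Cells lying on stroma pixels get
distance 0 and are retained — rasterization coarsens class boundaries, and
dropping boundary cells would bias against the very peristromal signal
being measured.  Relative to a continuous point-to-polygon distance, the
pixel-center convention is off by at most pixel_size/√2; at sub-micron
scanner resolutions this is far below the effect sizes of interest.  The
transform must be exact (no chamfer approximation); the test suite
enforces equality with brute-force minimization over all stroma pixels.

Necrotic tissue is excluded from all analyses: cells on excluded pixels
are dropped, and by default stroma pixels inside the exclusion mask are
also removed as distance targets (`exclude_necrotic_stroma=True`).
Whether necrotic stroma should still attract distances is genuinely
ambiguous for platform exports; the opposite behavior is available behind
that flag.

## The avatar null

The null model holds every tumor-cell position and the stroma geometry
fixed and redistributes the K positive labels uniformly among the N
tumor cells.  Two estimators of null quantities are used:

- **Closed form.**  For a uniformly random size-K subset S,
  E[(1/K) Σ_{i∈S} 1(dᵢ ≤ t)] = (1/N) Σᵢ 1(dᵢ ≤ t): the expected
  positive-subset ECDF *is* the all-cell ECDF, exactly and for every K.
  Predicted (null) medians and means therefore use the all-cell summary —
  the R→∞ limit of avatar averaging — with zero Monte-Carlo noise.
- **Sampled ensembles.**  Where a null *distribution* is needed (95%
  bands, empirical p-values), R avatars are drawn.  Replicates use
  counter-based child seed streams, so replicate i is identical whether
  R = 100 or R = 1000 and ensembles are extensible.

The empirical p-value is the add-one estimator
p = (1 + #{null ≤ observed}) / (R + 1) for the left tail (proximity
bias); it is never 0 and its support is the grid {1/(R+1), …, 1}.  Ties
between the observed and null medians count as extreme, which makes the
estimator very slightly conservative (tie rates ~0.2% under the study
conditions below).

## Group-level inference

Within a group, "observed vs predicted" is a paired comparison per tumor;
it is computed as a one-sample two-tailed t-test on the per-tumor deltas,
which is algebraically the paired t-test.  All-zero deltas (e.g. every
sample has f = 1) return t = 0, p = 1 by convention; zero variance with
nonzero mean is flagged and reported at an underflow floor.

Between two host models, the pipeline fits a fixed-effects two-way ANOVA
on the long table (value ~ model + condition + model×condition, condition
∈ {observed, predicted}) and reports the interaction term.  No
repeated-measures error stratum is fitted.  A consequence worth knowing:
the observed and predicted values of one tumor share that tumor's
geometry noise, which cancels in the interaction contrast but still
inflates the residual mean square, so under the null the interaction
F-test is *conservative* (empirical rejection at α = 0.05 runs at ~0–3%
rather than 5% in the calibration studies).  Power against real
between-model differences remains high (≥ 90% joint recovery in the
simulated two-model scenario).  A paired/repeated-measures formulation
would be exact but is deliberately not the default; the fixed-effects
choice is isolated in `interaction_test` and easy to swap.

KS p-values use the asymptotic Kolmogorov distribution with effective
size n₁n₂/(n₁+n₂).  At histology scale (10⁴–10⁵ cells) they underflow,
so D itself is the reported effect size; the p-value is provided for
small-sample uses.  Medians use the midpoint convention for even n.

## Synthetic tissue: what it emulates and what it does not

The generator reproduces the *content* of a segmentation export, not the
image: strand-like stroma (persistent random walks of configurable
thickness, grown until the realized area fraction is within ±20% of
target), uniform cell placement over admissible pixels with sub-pixel
jitter (centroids are continuous, as platform exports are), a single
elliptical necrotic region, and marker labels drawn without replacement
with weights exp(−dᵢ/λ) so that exactly K = round(f·N) cells are
positive.  λ = ∞ gives uniform weights — i.e. exactly one avatar draw —
so unbiased synthetic tissue embeds the analysis null by construction.
Weighted sampling uses the Efraimidis–Spirakis key scheme in log space,
numerically stable for arbitrarily small λ.

Defaults are chosen once as plausible study conditions, since the
motivating experiments report neither stroma area fractions nor positive
fractions per tumor: 15% stroma, f = 0.1, 1 µm/pixel, 8-pixel
(≈ 8 µm) strands, 6 strand seeds, 256 × 256 grids with N = 2000 cells for
simulation studies (2048 × 2048 with N = 400,000 for the capacity run,
matching the upper end of real cross-sections).  What passing tests on
this tissue shows: the machinery is exact (distance transform,
enumeration-level null agreement), calibrated (type-I ≈ 5%, uniform
p-values) and sensitive (power ≈ 1 at λ = 10 µm, effect size monotone in
λ).  What it does not show: robustness to segmentation error, to
non-uniform cell density (cellularity gradients), to stroma
morphologies unlike strands, or to marker biases that are not
monotone-exponential in distance.  Real-data conclusions inherit the
platform's segmentation accuracy.

## Numerical and convention details

- Coordinates: origin top-left, x rightward, y downward; pixel (i, j)
  spans [j, j+1) × [i, i+1) with center (j+0.5, i+0.5).
- Rasterization of polygon stroma marks a pixel iff its center is inside
  or on the boundary of any polygon (boundary ties inside); invalid
  (self-intersecting) polygons are rejected, never silently repaired.
- Mask dialect: any nonzero value is foreground (platforms export 1 vs
  255 inconsistently).
- Cell tables round-trip exactly (`float_precision="round_trip"` when
  parsing); malformed coordinate rows are dropped and logged with file
  row numbers, unknown class/marker vocabulary is a hard error.
- All generators are `numpy.random.Generator`-based; identical
  configuration and seed give bit-identical outputs.  Seeds derived
  inside study drivers stay below 2³¹.

## Known limitations

- The asymptotic KS p-value is unreliable below ~25 effective samples;
  D is always reported alongside.
- The avatar null treats labels as fully exchangeable among tumor cells;
  spatially constrained permutations (e.g. within annuli) are out of
  scope.
- The fixed-effects interaction test is conservative under the null (see
  above).
- Stroma strands are the only synthetic morphology; blob- or
  sheet-dominated stroma must be supplied as real masks/polygons.
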