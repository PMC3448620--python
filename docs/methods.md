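# Methods

## The assignment model

A feather grown at location *s* is modelled as carrying an isotope triplet
x = (δ²H_f, δ¹³C_f, δ¹⁵N_f) drawn from a multivariate normal
MVN(μ(s), Σ), where μ(s) comes from feather-scale isoscapes and Σ is a
single covariance shared by all origins. Origins are discretized into K
isotopically distinct regions ("clusters"); each cluster k contributes its
zonal mean vector μ_k, and the posterior over clusters under equal priors
is

p_k(x) = f(x; μ_k, Σ) / Σ_j f(x; μ_j, Σ).

Because Σ is shared and priors are equal, argmax_k p_k(x) is the cluster
whose mean is nearest in Mahalanobis distance (x−μ_k)ᵀΣ⁻¹(x−μ_k); this
equivalence is oracle-checked in the tests. Probabilities are computed in
log space and normalized by log-sum-exp, so extreme separations cannot
underflow.

Assumptions worth stating: a common Σ across regions (the between-region
differences live entirely in the means); equal prior weight per region (no
area or abundance prior — an option allows priors ∝ region cell counts);
and independence between individuals.

## Covariance estimation with missing values (EM)

Σ and the grand mean are estimated from the feather sample itself by
maximum likelihood under MCAR missingness. The EM iteration, per record
with observed block *o* and missing block *m*:

- E-step: impute x̂_m = μ_m + Σ_mo Σ_oo⁻¹ (x_o − μ_o) and add the
  conditional covariance Σ_mm − Σ_mo Σ_oo⁻¹ Σ_om to the second-moment
  accumulator (records are grouped by missingness pattern);
- M-step: μ ← mean of completed records, Σ ← second moment minus μμᵀ
  (n divisor, matching the ML rather than the unbiased estimator).

Initialization is available-case means and diagonal available-case
variances; convergence when the largest absolute parameter change is
< 1e-8, capped at 1000 iterations (non-convergence flags the fit and any
use of it raises). A singular observed block gets a ridge of 1e-8·trace
with a warning. With complete data the first iteration already sits at the
closed-form MLE, which the tests assert to 1e-10.

Note the estimand: fitting the whole cohort pools within-region scatter
*and* between-region separation. That is the intended variance object for
the assignment likelihood, but it is deliberately conservative as a
measurement-error model (see the simulation covariance below).

## Simulation-based uncertainty

Each of n_sims replicates redraws every individual as
x\* ~ MVN(x, Σ_sim) — the observed triplet is the mean of its own
simulation distribution — reassigns x\* by highest likelihood, and tallies
per-cluster counts. Reported are per-individual assignment frequencies and
per-cluster mean ± SD counts (sample SD, n_sims − 1). Σ_sim defaults to
the EM estimate, the only variance object the pipeline constructs; it is
overridable (e.g. a diagonal, a scalar inflation, or a known within-region
covariance) because the default, containing between-region spread, is an
upper bound on per-feather measurement scatter: with a minority fraction p
and region separation L it inflates the along-separation variance by
p(1−p)L², which smears counts between adjacent regions by a few percent of
the cohort no matter how separated the regions are. Argmax ties break
toward the lowest cluster id; with Σ_sim = 0 every replicate reproduces
the point assignment exactly (a tested degenerate limit).

## Rasters, calibration and clustering

Grids are north-up, row-major, cell-center registered, square-celled.
ESRI ASCII is the reference format (values round-trip bit-exactly via
`repr`); GeoTIFF I/O goes through tifffile with the ModelPixelScale,
ModelTiepoint and GDAL_NODATA tags, float32 payload. No reprojection is
attempted; stacking requires a common lattice and crops to the overlap,
and a cell is valid only where every layer is valid.

Transfer functions are affine: the δ²H rainfall-to-feather calibration
(slope 1.42, intercept −6.77‰, from known-origin birds) and additive
discrimination offsets (+2‰ δ¹³C, +5‰ δ¹⁵N). Nodata cells pass through
untouched.

Regions are derived by k-means on the stacked layers, standardized per
layer to mean 0 / SD 1 over the valid mask (without this, δ²H's ~100‰
range would dominate the ~10‰ ranges of C and N). Ten random restarts
under a fixed seed; labels are canonicalized 1..K by descending cell count
(ties by ascending first-layer centroid) so ids are stable. Zonal
statistics use the population (n) divisor for SD: a zone's cells are the
entire population of interest, not a sample. Zonal means are unweighted
cell means; latitude-dependent cell-area weighting is not applied (cells
span equal degree increments, and the published workflow gives no
indication of area weighting) — a weighted variant would be the natural
extension.

## Single-isotope continuous surface

For δ²H-only data the posterior over cells is the normalized per-cell
normal likelihood N(δ²H_f; cell value, σ). σ has no canonical value and is
a required input; deriving it from the calibration residuals of
known-origin birds is the recommended practice. Regions are delineated by
an odds ratio against the MAP cell (default 2:1, a literature convention
rather than a value from the motivating study); region size is
monotonically non-decreasing in the ratio.

## Ring-recovery regression

Recovery longitude is regressed on ringing longitude by closed-form OLS
(longitudes in decimal degrees, east positive). The prediction interval
for a new recovery at x₀ is

ŷ(x₀) ± t_{(1+level)/2, n−2} · s · √(1 + 1/n + (x₀ − x̄)² / S_xx),

which is exact under normal errors; empirical coverage at the study-sized
n = 21 is verified by simulation (95.05% over 20k replicates; the shipped
test uses 2000 replicates with a ±1.5-point band). The band is intersected
with the cluster map by cell-center longitude.

## Cohort t statistics

Published hatch-year vs adult comparisons are recomputed from printed
mean ± SD and n only: pooled-variance t (df = n_a + n_b − 2) and Welch t
(Satterthwaite df). Values recomputed from summaries rounded to 0.1‰ can
differ from printed t values by a few percent; the δ¹³C comparison
reproduces to within the printed precision, the δ¹⁵N one to within the
rounding of its inputs.

## Synthetic data

The world generator builds each layer as an affine lon/lat trend, optional
constant per-region band offsets, and smooth noise (seeded white noise,
boxcar-smoothed over a configurable length, rescaled to the requested
sample SD — only smoothness matters here, not the precise field model).
Ground truth is the k-means partition of the noiseless layers. For
pure-gradient worlds the partition boundary runs through near-equidistant
cells, so exact recovery is only expected for worlds with distinct
constant regions (band offsets on); the noisy default world is recovered
to ~93%.

Cohorts draw memberships from a given distribution, triplets from
MVN(μ_k + year shift, Σ_true), and apply per-isotope MCAR masking (a draw
that would lose all three isotopes is re-masked, which depresses the
realized missingness rate by at most rate³). The default Σ_true uses
SDs ≈ 13 / 1.3 / 0.9 ‰ (δ²H / δ¹³C / δ¹⁵N) with mild positive
correlations — the scale of observed adult feather spreads, illustrative
rather than fitted. The default cohort size is 171 with years 2007–2009,
the scale of the motivating dataset. Ring recoveries use n = 21, slope
0.9, intercept 5°, residual SD 8° over ringing longitudes −10°..30°.

What the synthetic tests do **not** show: real African isoscapes are not
affine-plus-bands, real missingness is year-structured rather than MCAR
(two early seasons lacked C/N entirely), and real within-region covariance
need not be shared or normal. Passing here validates the machinery and its
statistical contracts, not the geographic conclusions for any real cohort.

## Numerical choices and problem sizes

Log-densities via Cholesky throughout; non-PD covariances are rejected
rather than repaired (except the EM ridge above). Tolerances: probability
rows sum to 1 within 1e-9; EM convergence 1e-8; OLS checked against an
independent solver at 1e-9. Default test/demo problem sizes — 40×40 to
60×60 worlds, cohorts of 171–500, 1000 replicates, 2000 coverage
datasets — keep the full suite under ~10 s while leaving Monte-Carlo
tolerances (3 SEs) meaningful.

## Known limitations

No reprojection or CRS awareness; no area-weighted priors by default;
cluster-level (not spatially continuous) three-isotope assignment; the
simulation covariance question — whether per-feather perturbations should
use the full fitted Σ or a within-region covariance — is surfaced as an
option rather than resolved, since the two choices answer different
questions (total-variance sensitivity vs measurement repeatability).
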