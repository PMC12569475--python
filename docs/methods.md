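# Methods

`isoniche` quantifies trophic competition between sympatric pelagic
predators (swordfish, blue shark, shortfin mako) from carbon and nitrogen
stable isotopes, standardized longline catch rates, and gridded
environmental drivers. This note documents the statistical models, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Isotopic niches (KUD)

The isotopic niche of a group (species within a region or a 1°×1° grid
cell) is the 95% highest-density region of a bivariate Gaussian kernel
density over (δ¹³C, δ¹⁵N). For points x₁…xₙ and bandwidth matrix H,

    f(x) = (1/n) Σᵢ N(x; xᵢ, H),

evaluated on a 256×256 grid. The niche region is the smallest
density-threshold superlevel set containing ≥ 95% of the estimated mass;
its area (‰²) is the niche width. The centroid is the arithmetic mean of
the raw points, because the competition index below is defined between
centroids of isotope values, not density modes.

Bandwidth modes:

- `plugin` (default): a diagonal matrix of squared per-axis two-stage
  direct plug-in bandwidths (Wand–Jones type, Gaussian kernel; pilot
  functionals ψ₆, ψ₈ started from the normal reference). Falls back to
  the reference rule if the pilot stage degenerates.
- `ref`: the bivariate normal-scale rule H = n^(−1/3) S with S the sample
  covariance.

Groups with fewer than `min_n` = 10 points are refused: a kernel niche on
a handful of individuals is not interpretable (the regional analysis
excludes an n = 2 group for the same reason). The evaluation grid is
padded 4 kernel SDs beyond the data range; with 3-SD padding the mass
escaping the window can exceed the 10⁻³ tolerance we impose on the
density integral, with 4 SDs the integral is exact to ~10⁻⁷.

Directional overlap between two niches is computed on a common union
grid: overlap(A→B) = 100 · area(A ∩ B)/area(A). It is asymmetric: a
narrow niche nested inside a broad one overlaps ~100% one way and much
less the other.

On large standard-normal samples the estimated 95% area converges to the
closed-form highest-density-region area π·χ²₂(0.95) ≈ 18.8; the test
suite checks agreement within 10% at n = 4000. The KDE area is biased
slightly upward (bandwidth convolution inflates the contour), which is
inherent to the estimator, not a defect.

## Competition indices

**CCD (distance to competitors' centroids).** For species i among N
competitors in the same spatial key,

    CCDᵢ = (1/N) Σₖ ‖Cᵢ − Cₖ‖₂,

with Cᵢ the (δ¹³C, δ¹⁵N) centroid. Low CCD means competitors sit close in
isotope space — similar resource use. CCD is translation-invariant,
scale-equivariant, and symmetric in the two-species case.

**ITP (intraspecific trophic pressure).**

    ITP = ln(nCPUE + 1) / KUD_area,

standardized abundance (individuals per 1000 hooks) over niche area.
Natural log by default; the base is configurable because the index is
conventionally written with an unspecified "log". Abundant species with
narrow niches (many conspecifics on few resources) score high.

**Group comparisons.** CCD and ITP distributions are compared across
species/regions behind a Shapiro–Wilk gate (α = 0.05): all groups normal
→ one-way ANOVA + Tukey HSD; otherwise Kruskal–Wallis + pairwise Wilcoxon
rank-sum. Groups with < 3 values cannot be normality-tested and force the
nonparametric branch. Raw bivariate isotope values are tested with a
two-way PERMANOVA on the Euclidean distance matrix: sequential (Type I)
sums of squares partitioned from the Gower-centred matrix, species
entered first (the SS type is a design choice; the data are near-balanced
so the ordering matters little), free permutation of rows, and
p = (1 + #{F\* ≥ F})/(1 + n_perm). An exact mode enumerates all n!
permutations for small fixtures and is tested against an independent
coordinate-space ANOVA oracle.

## CPUE standardization

Catch counts per longline set are standardized with a negative-binomial
(NB2, log link) additive model:

    log μ = log(hooks) + te(lon, lat) + gear + year + month + boat,

where te(·,·) is a tensor-product P-spline (8 B-spline basis functions
per margin, second-order difference penalty per margin), gear is a fixed
factor, and year/month/boat are ridge-penalized dummy blocks — the usual
working approximation to Gaussian random intercepts. Fitting is penalized
IRLS with step-halving; smoothing/ridge parameters minimize the deviance
GCV score n·D/(n − edf)², and the NB overdispersion α (var = μ + αμ²) is
profiled by maximum likelihood, alternating with the fit. Species/basin
strata with fewer than 10 positive catches are refused — a model on
essentially all-zero counts estimates nothing (this mirrors the
impossibility of a Mediterranean shortfin mako model).

Prediction is at cell centres with the offset fixed at 1000 hooks,
penalized factors at their population (zero) level, and gear handled by
averaging response-scale predictions over observed gear levels. Cells
outside the fitted bounding box are flagged missing rather than
extrapolated.

## Driver models

Cell-level CCD and ITP are strictly positive and right-skewed and are
modelled with gamma/log-link additive models built from the same engine:
linear terms, univariate P-spline smooths of drivers (productivity index
OPFish, mixed-layer depth, fishing effort, competitor abundance), a
species factor, and the spatial tensor smooth. Zero-ITP cells (zero
predicted abundance) conflict with gamma support; they are shifted by
10⁻³ times the smallest positive value, logged loudly.

Before fitting, drivers are screened pairwise by Spearman rank
correlation: for |ρ| > 0.8 the lower-priority layer is dropped (by
default Chl is sacrificed in favour of the productivity index it tracks).
Candidates are ranked by AIC (−2ℓ + 2·edf, scale/dispersion parameters
counted) with deviance explained reported alongside; ties break toward
fewer terms. Partial effects are centred (sum-to-zero constrained) with
pointwise Wald 95% bands from the penalized ("Bayesian") coefficient
covariance.

## Bayesian mixing model

Diet proportions p over K prey source groups are estimated from consumer
isotope values. Per isotope e,

    Xₑ ~ N( Σₖ pₖ(μₖₑ + Δₖₑ),  Σₖ pₖ²(σₖₑ² + σ_Δₖₑ²) + σₑ² ),

with (μ, σ) the source moments, (Δ, σ_Δ) the diet-tissue discrimination
factors, and σₑ a per-isotope residual scale — a deliberate simplification
of the residual×process error menu of full mixing-model frameworks, kept
because a single additive residual is identifiable here and the error
structure of the original analysis is not recorded. DTDFs can be constant
or diet-dependent (Δ = a·δ_source + b per isotope, coefficients supplied
in configuration). The "generalist" prior is Dirichlet(1,…,1); σₑ gets a
half-normal(3) prior.

Sampling is adaptive random-walk Metropolis on the additive-log-ratio
transform of p plus log σ (the Dirichlet prior with the ALR Jacobian
folds to Σₖ αₖ log pₖ), three independent chains. Defaults are 30 000
draws with 20 000 burn-in and thinning 10 — a desk-scale setting chosen
because the posterior here is a (K+1)-dimensional unimodal density for
which these lengths give R̂ < 1.01; the 300 000/200 000 compatibility
setting is one argument away. Convergence is checked with the
Gelman–Rubin potential scale reduction factor (flagged at 1.1) and the
Geweke early/late z-score with Bartlett-kernel long-run variances.

Model geometry is validated by mixing-polygon simulation: hull vertices
are the DTDF-shifted source means resampled from the combined
source+DTDF uncertainty; each observed consumer is tested for hull
membership per draw and flagged when inside fewer than 5% of draws. The
DTDF correction is applied once, on the source side.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
with defaults fixed at the study's own conditions:

- Isotope clouds: bivariate normal per species × region with the
  published sample sizes, means and SDs (e.g. Mediterranean blue shark
  n = 45, δ¹³C −17.49 ± 0.96, δ¹⁵N 11.29 ± 1.32). Marginal SDs only are
  published, so the default isotope correlation is ρ = 0 (configurable).
  Lengths are uniform over the published ranges, metadata only.
- Locations: Gaussian cluster mixtures inside three region bounding boxes
  (western Mediterranean, Portugal/Cádiz, Canary Islands) spanning
  several 1° cells each. No within-region isotope–space gradient by
  default (none is reported); an optional linear δ¹⁵N trend exists for
  sensitivity checks.
- Longline sets: 2534 sets by default; NB catches with mean
  hooks · exp(intensity + gear effect), five gear levels, 2015–2019
  year/month/boat structure.
- Driver fields: smooth positive random fields (Gaussian-filtered noise);
  in collinear mode Chl is a monotone transform of OPFish so that the
  Spearman screen has something real to catch (ρ > 0.8).
- Mixture consumers: drawn exactly from the mixing-model likelihood above
  for a known p, so posterior recovery is a well-posed check.
- Scenario quadrants: two species with configurable centroid separation
  and scalar abundance/productivity levels, emulating the conceptual
  productivity × abundance matrix.

What the generator does **not** emulate: real spatial autocorrelation of
ocean fields beyond smoothness, seasonal cycles, size/length effects on
isotopes, spatially varying isotopic baselines, and observation error in
coordinates. Tests passing on synthetic data therefore demonstrate that
the estimators recover the structure they model — not that the model
captures every feature of field data.

## Numerical choices and degenerate inputs

- Half-open grid cells [edge, edge + size): every in-extent point maps to
  exactly one 1° cell; edge points belong to the cell they open.
- Missing raster cells are explicit (absent rows / validity mask), never
  silently propagated NaN.
- KDE thresholds: HDR threshold from sorted cumulative mass on the grid;
  all-equal or collinear point sets are rejected as singular.
- PIRLS convergence: relative deviance change < 10⁻⁸, max 50 iterations,
  step-halving keeps the penalized deviance non-increasing; non-converged
  fits raise rather than return silently.
- GCV optimization: Nelder–Mead on log smoothing parameters (coarse
  tolerances — the GCV surface is flat near its optimum and the fits are
  insensitive to λ within a factor of ~2).
- Gelman–Rubin on constant chains is guarded to 1; Geweke on constant
  chains is 0.
- Exact PERMANOVA p includes the identity permutation in the reference
  set; sampled p uses the add-one convention, so the smallest attainable
  p with 999 permutations is 1/1000.

## Known limitations

- The KUD plug-in bandwidth is diagonal; strongly tilted niches are
  estimated slightly conservatively compared to a full plug-in matrix.
- Ridge-penalized factors approximate random effects; their variance is
  tuned by GCV, not REML, and uncertainty in λ is not propagated.
- The gamma driver models assume independent cells; no spatial residual
  correlation beyond the tensor smooth mean structure.
- The mixing model has no concentration (elemental C:N) weighting and no
  covariate effects on diet proportions.
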