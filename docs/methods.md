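# Methods

This note documents the models behind `urbansoilrisk`, the conventions
and defaults that matter, the numerical choices made where the
published methodology left the design open, and what the synthetic-data
tests do and do not demonstrate about real surveys.

## Baselines and univariate statistics

The upper baseline limit of an element is `UBL = median + 2·MAD`, where
MAD is the **raw** median absolute deviation — the 1.4826 normal
consistency factor is deliberately not applied. Published baseline
tables computed this way (e.g. Pb: 68.92 + 2·75.61 = 220.1) are only
reproducible with the raw MAD, and the raw form is the natural
outlier-resistant envelope when no normality claim is being made.
Kurtosis uses the Pearson convention (normal = 3), matching the
geochemical habit of quoting 3 as the normality reference; skewness and
kurtosis are bias-corrected sample moments. SD uses ddof = 1. All
internal computation is full precision; rounding happens only at
reporting time.

QC metrics follow laboratory convention: precision as the relative
percent difference of duplicate pairs, RPD = 100·|a−b|/((a+b)/2), and
accuracy as 100·|measured − certified|/certified.

Units are harmonized to mg/kg at ingest (μg/kg ÷ 1000, % × 10,000;
by convention Hg arrives in μg/kg and Fe in %). Values below a declared
detection limit are imputed as DL/2, the common geochemical practice;
both the limits and the imputation are configurable.

## Interpolation and singularity analysis

Ordinary IDW uses the k nearest samples (default 12) with weights
d^−p (default p = 2); a cell whose center lies within 1e−9 m of a
sample takes that sample's value exactly. Ties at the k-th neighbor are
broken by sample-id order so grids are reproducible. The study area is
the convex hull of the samples buffered by one cell; outside cells are
masked NaN. Default cell size is 50 m — roughly a tenth of the nominal
inter-sample spacing of a 1-per-0.25 km² survey, fine enough to resolve
kernels without inflating grids.

The multifractal correction assumes the field's window means scale as

    μ(L) = c · L^(α−2),   L = 2r + 1 cells (window edge length)

α and c are fitted per cell by OLS of log μ on log L over half-widths
r ∈ {1,…,5}, windows clipped at grid edges and masked cells excluded
via integral images. The MIDW estimate is the scaling law at the cell's
own scale, Z = c·L^(α−2) at L = 1, i.e. c itself. Design rationale: no reference
formulation of the correction is published, so the reconstruction is
pinned to the two behaviours the method exists for — on a non-singular
field (α = 2, e.g. any constant field) MIDW reduces exactly to IDW, and
at a local anomaly (α < 2) the cell-scale extrapolation lies **above**
the window means, enhancing the peak instead of smoothing it. Fitting
against window half-width and evaluating at the smallest window, the
other candidate convention, returns a predicted 3×3-window mean and
therefore smooths peaks; it was rejected on that ground. α is clamped
to [0.5, 3.5] to stabilize edge cells where few window sizes are
informative. Fields that take zero or negative values (index surfaces,
PCA scores, balance coordinates) are shifted positive before the fit
and shifted back, preserving the non-singular identity with IDW.

## Concentration–area classification

A(s) is the count of unmasked cells with value ≥ s, over the sorted
unique values s (counts and true areas differ by the constant cell
area, which cancels in slope fitting). `n_classes` straight segments
are fitted to the log–log curve by exact dynamic programming over
breakpoint placements (O(k·m²) with prefix-sum segment SSE; the support
is thinned to ≤ 512 points for large grids). The regression is oriented
as **log s on log A**: with the conventional orientation the unbounded
lower tail of log A dominates the SSE and every breakpoint migrates
into the steepest descent of the dominant population, whereas in the
swapped orientation each population contributes a bounded share and a
sparse concentration range between populations appears as a
high-variance vertical run that attracts the breakpoint — which is the
geochemical object of interest. Thresholds are geometric means of the
two concentrations flanking each optimal breakpoint. This global-SSE
search is a deterministic surrogate for the published practice of
picking "marked inflexion points" by eye; the full curve and
per-segment slope/intercept/SSE diagnostics are exported so a user can
override the thresholds.

Jenks natural breaks (for CCI/CCS dot maps, default 5 classes) are
computed by exact dynamic programming minimizing within-class sum of
squares, verified against exhaustive search at small n. Component-score
maps use breaks symmetric about zero at ±0.25·max|score| (scores near
zero carry no information); single-signed inputs fall back to quartile
breaks with a warning.

## Contamination indices

`ICI = (C_i/N_i)/(UBL_i/UBL_N)` with Fe the default normalizer, chosen
for its low CV; the normalizer is excluded from the indexed element set
but its UBL enters every denominator. CCI is the plain sum over the 15
PTEs, CCS counts elements with ICI ≥ 1 (the boundary counts as
contaminated), and CCD = CCI·CCS exactly. UBLs default to local
baselines computed from the survey being indexed; externally supplied
UBLs are accepted for regulatory comparisons. The CCD surface is MIDW
interpolated and classed by the C–A method; cells and samples with
CCS = 0 carry CCD = 0 and are excluded from the positive-support
log–log curve.

## Compositional analysis

All multivariate statistics operate on log-ratio coordinates: clr for
interpretation, ilr for estimation. The ilr basis is built either from
the canonical pivot partition or from a user SBP; a partition row
splitting r "+" parts from s "−" parts yields the contrast
√(r·s/(r+s))·ln(g₊/g₋). The balance normalizer is the standard
orthonormal form — it is the only coefficient that makes the basis
orthonormal, and the first default split (3 vs 2 parts) gives
√(6/5) ≈ 1.0954. The default partition orders (Be, Tl, Hg, Pb, Sn):
anthropogenic (Hg, Pb, Sn) against geogenic (Be, Tl), then Hg vs
Pb+Sn, Pb vs Sn, and Be vs Tl. Hg must be in mg/kg (harmonization
guarantees this) or balances involving it are meaningless.

Robust PCA estimates a MinCovDet location/scatter (75 % support,
deterministic seeding) on the ilr matrix with z-scored pH appended as
an external, non-compositional column, then eigendecomposes. The
covariance (not correlation) matrix is analyzed by default — ilr
coordinates share a common log scale, and a `robust=False` flag exposes
the classical path. Loadings are mapped back to clr through the basis
contrast matrix (the result is independent of which orthonormal basis
was used); the pH row passes through untouched. Per component, the
largest-magnitude loading is made positive, compositional clr loadings
sum to zero, and variable contributions 100·loading²/Σloading² are
flagged above the 100/D % cutoff (6.67 % for 15 parts; configurable,
e.g. to a rounded 6 %). Note FastMCD's subset search makes the robust
estimate exactly reproducible only for a fixed row order and
random_state; invariance under permutation or duplication is exact on
the classical path and holds to a fraction of a degree on the robust
path.

## Risk assessment

Ingestion dose: D = C·IR·AF·EF/BW (mg/kg/day), with EF = F·ED/AT and
AT = ED·365 for non-carcinogens (EF = F/365) or a 70-year lifetime for
carcinogens. Inhalation is assessed as an exposure concentration
C/PEF·AF·EF (mg/m³), body-weight-free, compared against RfC (and, in
μg/m³, against IUR) — the route where reference values are already
concentration-based. Threshold comparisons are inclusive throughout
(HQ ≥ 0.2 relevant, HI ≥ 1 unacceptable, ILCR ≥ 1e−6 above the
no-risk line), and per-organ HI sums only the HQs that survive the 0.2
screen; a single surviving contributor makes HI equal its HQ.

The stochastic path fits each element's concentrations with the best
of lognormal, gamma, Weibull and normal (positive-support families
pinned at location 0) by the Anderson–Darling statistic, falling back
to empirical resampling if every fit fails and to a point mass for
constant input. Elements are sampled independently per iteration —
no concentration copula is asserted. Certainty is
100·#{iterations ≥ threshold}/n_iter at the default 50,000 iterations,
reported with a 95 % binomial half-width; runs are bit-reproducible
given a seed.

Default exposure scenarios (child soil ingestion 2.0e−4 kg/day, BW
15 kg, F 350 d/y, ED 6 y; adult inhalation 20 m³/day, BW 70 kg, ED
24 y; PEF 1.36e9 m³/kg) and the packaged toxicity table are standard
residential screening values; both are plain-text files the user is
expected to replace with jurisdiction-specific values. Ingestion is
assessed for children only by default, reflecting their geophagy
predisposition. The dermal pathway is out of scope.

## Synthetic surveys

The generator draws jittered-regular sampling locations (one per
0.25 km² nominal density, 121 samples over a 4.7 × 4.7 km domain),
lognormal backgrounds per element with log-medians near reported urban
topsoil values and log-spreads giving CVs from ~17 % (Fe) to well over
100 % (Hg, Pb, Sb, Sn), multiplicative anomaly kernels with Gaussian
distance decay (smooth anomalies give the C–A curve distinct segments),
a low-CV lognormal Fe normalizer, and truncated-normal pH in
[4.5, 9.5]. Hg is written out in μg/kg and Fe in % so ingest
harmonization is exercised. What it does **not** emulate: analytical
error structure beyond optional duplicate pairs, spatially correlated
lithological background, detection-limit censoring, or inter-element
correlation beyond shared kernels. Tests passing on these surveys
demonstrate the machinery's correctness and recovery properties, not
that any particular real city matches the generative model.

## Known limitations

- The MIDW variant is a reconstruction pinned to its limiting
  behaviours, not a re-implementation of a published algorithm.
- C–A thresholds from global SSE can differ from an analyst's visual
  inflexion picks on curves without clear population gaps; the exported
  diagnostics exist for exactly that reason.
- Published survey-specific results (component variances, balance
  means, risk certainties) depend on unpublished raw data and
  toxicological tables and are not reproduction targets; the package
  verifies the published internal identities and all structural
  properties instead.
- Monte Carlo concentrations are independent across elements; joint
  exceedance probabilities for multi-element HIs are therefore
  approximate when elements are strongly co-located.
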