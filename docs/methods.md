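# Methods

This note documents the models, estimators and numerical choices behind
cogplast, and what the synthetic-cohort studies do and do not establish.

## Volumetric data model

Volumes are 3D scalar lattices (`VolumeGrid`) with strictly positive voxel
sizes and an optional 4x4 affine; 4D timeseries add a frame interval (TR).
Indexing is 0-based (x, y, z) and no reorientation is ever applied — world
coordinates exist only through the stored affine. Missing voxels propagate
as NaN and are excluded from every downstream statistic; a percentage-change
image flags voxels whose baseline magnitude is below `eps = 1e-6` (in
modality units) as missing rather than dividing by a near-zero baseline.
Round-trip NIfTI I/O is bitwise for float32 payloads.

Residualized change scores — change maps regressed voxel-wise on their
baseline, and behavioral gains regressed on baseline test scores — remove
baseline-associated variance before group inference and mediation. The
residualizer refuses rank-deficient designs and names the collinear columns.

## Connectivity centrality

Eigenvector centrality uses the similarity transform `A = (r + 1)/2` of the
Pearson correlation matrix. Because `A` is strictly positive, the dominant
eigenvector is unique and nonnegative (Perron–Frobenius), so power iteration
from a uniform start converges without sign ambiguity. The matrix–vector
product is computed implicitly, `A v = (Z (Z^T v)/(T-1) + 1 sum(v))/2` with
`Z` the row-standardized data, so memory is O(N T) rather than O(N^2).
Convergence is declared when consecutive unit-norm iterates differ by less
than `tol = 1e-6` in 2-norm (default `max_iter = 100`); non-convergence is
an error carrying the final delta, never a silent result. The alternative
transform `max(r, 0)` would not guarantee positivity and is intentionally
not the default.

Degree centrality sums correlations above a threshold `tau` (default 0:
positive correlations only; `tau = -1` gives the signed row sum), computed
in voxel blocks to bound memory. Fisher-z maps cap `|r| -> 1` at
`atanh(1 - 1e-7)` and report the capped fraction. Cluster parcellation
thresholds a z map at the within-mask mean plus `k_sd` SDs (default 2) and
labels connected components under 26-connectivity (6/18 selectable),
ordered by descending size.

## Permutation inference

Group inference on change maps uses the Aspin–Welch `v` statistic
(unpooled variances), appropriate for the 32-vs-16 unbalanced design
(Behrens–Fisher problem). Nuisance covariates (age, sex, and — via prior
voxel-wise residualization — the baseline map) are handled Freedman–Lane
style: residuals of the nuisance-only model are sign-flipped per subject and
the nuisance fit re-added; since the projector is idempotent, the identity
flip reproduces the observed statistic bit for bit. Sign flips are drawn
i.i.d. per subject; the two group labels act as the variance groups of the
statistic. The flip matrix carries the identity as its first row plus
`n_flips` random rows, so the FWE p-value
`(1 + #{flips with max >= t}) / (1 + n_flips)` is a single count over all
rows and can never be zero. For `n <= 20` subjects all `2^n` sign patterns
can be enumerated exactly.

TFCE integrates `e(h)^E h^H dh` over thresholds `h = dh .. max` with
`E = 0.5`, `H = 2`, `dh = max_observed / 100`; permuted maps reuse the
observed `dh` so enhancement is comparable across draws. Only positive
values are enhanced; the opposite direction is run as a separate contrast.
The implementation sweeps thresholds downward with a union-find over
activating voxels (O(active) per threshold, numba-compiled), which testing
verifies against a per-threshold connected-component labeling loop to
1e-9. One numerical subtlety: when `dh` is derived from an
equal-up-to-rounding copy of the map, the top threshold `dh * n_thr` can
exceed the map maximum by one ulp and would silently drop the peak's top
slab; the top threshold is therefore clamped to the map maximum.

The NPC mediation screen runs two partial tests under the *same* flip draws
(synchronized permutations): (1) the directional group effect on the map
(`v`, age/sex-adjusted) and (2) the directional slope of behavior on the
map, adjusting for age, sex and group (partial-correlation t). Each draw's
statistic is converted to a p-value by its rank within that voxel's own
permutation distribution (self counted, ties share the larger count, so
`p >= 1/n_draws`); the partials are combined with Fisher's
`T = -2 (ln p1 + ln p2)`, the T maps TFCE-enhanced, and max-statistic FWE
applied as above. A parametric conversion of the partial statistics would
also be defensible; rank conversion was chosen because it is exact under
the permutation null and monotone-invariant.

## Mediation

The parallel-mediator model fits `M_j = a_j X + cov + e` and
`Y = c' X + sum_j b_j M_j + cov + e'` by OLS, with HC4 sandwich standard
errors by default (HC0/HC3 selectable; HC4's leverage-adaptive discount
`delta_i = min(4, n h_i / p)` is suited to small samples). The indirect
effect `ab` gets a percentile-bootstrap CI: rows resampled with replacement
(unstratified by default, stratified optional), degenerate resamples with
constant treatment redrawn and counted; the partially standardized effect
`ab / SD(Y)` carries its own percentile CI. Mediation is claimed when the
95% CI excludes zero.

The robust variant downweights extreme cases with `w_i = min(1, c/d_i)`
where `d_i` are robust Mahalanobis distances over (M, Y[, covariates]) —
the binary treatment is excluded from the metric — and
`c = sqrt(chi2_{1-kappa, p})`, so about a fraction `kappa` (default 0.05) of
Gaussian cases would be downweighted. Location and scatter are estimated by
an iteratively reweighted mean/covariance started at the coordinate median,
a deterministic scheme cheap enough to recompute inside every bootstrap
draw; `kappa = 0` reproduces the ordinary estimates to 1e-8. Covariates are
excluded from the robust fit by default for comparability with the
covariate-free formulation of the originating procedure.

## Johnson–Neyman ANCOVA

Group regression lines of gain on baseline are compared at `K = 10` design
points: the 25th and 75th percentile of the pooled baseline
(linear-interpolation percentiles, the numpy default) and 8 evenly spaced
points between. The SE of the predicted difference at each point comes from
a case bootstrap within each group (`B = 5000` default), the statistic is
`(control - exercise)/SE` with a two-sided standard-normal p, and
simultaneous significance uses the infinite-df Studentized maximum modulus
critical value under independence, `c = Phi^{-1}((1 + (1-alpha)^{1/K})/2)`
(1.96 at K = 1, ~2.80 at K = 10). The normal reference and the
difference/SE convention jointly reproduce published design-point tables of
this form to printed precision.

## Fitness and cognition scoring

PWC targets are interpolated linearly between the bracketing
workload–heart-rate pairs and divided by body mass. Lactate curves are
least-squares cubics in workload; thresholds are found by bisection on the
fitted cubic restricted to the observed workload range (|dW| < 0.01 W),
which avoids spurious out-of-range cubic roots. The IAT ("1.5 mmol method")
anchors at the minimum fitted lactate over the observed range — the
source description of the method is not fully specified in the literature
this follows, so the anchor and offset are configurable. Body-weight
adjustment happens after threshold finding. The training-lactate check
averages samples within sessions, sessions within subjects, normalizes to
the subject's absolute IAT lactate, and tests the cohort mean against 100%
(one-sample t; `d = t/sqrt(n)`).

d2-R concentration performance defaults to the "literal" convention
(processed targets minus commission-plus-overlooking errors); the test
manual's variant (correct marks minus commission errors) is available via
`convention="manual"`. Welch comparisons report
`d = t sqrt(1/n1 + 1/n2)`, which reproduces published two-sample effect
sizes at 32 vs 16.

## Diffusion

The tensor is fit by OLS on `log(S/S0)` over the six unique elements
(`S0` = mean of the b=0 volumes); eigenvalues are sorted descending and
negative eigenvalues from noisy fits are flagged rather than silently
clamped (a clamped copy is available). FA, MD and radial diffusivity follow
the standard eigenvalue formulas. No weighted or robust tensor variants are
provided.

## Synthetic cohorts: what they emulate and what they do not

`CohortConfig` defaults define the study conditions: 32 exercise vs 16
control subjects, two sessions, a 16^3 grid with 200 frames (TR 1.4 s),
ages uniform 18–35, sex Bernoulli(0.6 female). Network voxels (hub block
plus two network blocks, disjoint) share one latent unit-variance signal
`g(t)`; voxel timeseries are `w g(t) + sigma eps(t)` with `sigma = 0.8`.
Exercise subjects gain hub mixing weight post-intervention,
`w_post = w_pre + effect_a * delta_i` with `delta_i ~ Exp(1)` (positive,
mean 1); controls are unchanged. Behavioral gain (percent) is
`5 - 0.05 (CP_pre - 180) + c' group + b * latent + noise(4)` with
`c' = 1`, `b = 6` per unit latent — the total group difference of ~7% gain
and gain SDs of 4–8% sit near values reported for two-week interventions of
this design, and the behavioral path runs through the *latent* change, so
EC measurement noise attenuates the observable mediator path realistically.
The BOLD noise level and the latent's exponential spread were chosen so
that the planted effect is strong but honestly attenuated: the measured
cluster-mean EC change correlates with the latent at roughly 0.7–0.8 within
the exercise group. With weaker noise the correlation between a voxel and
`g(t)` saturates near 1 and the EC response compresses, which
counterintuitively *hurts* mediator observability; `sigma = 0.8` keeps the
response approximately linear in `delta`.

Diffusion eigenvalue maps use gray-matter-like (1.0, 0.8, 0.6)e-3 mm^2/s and
white-matter-like (1.5, 0.5, 0.5)e-3 baselines with lognormal voxel noise;
the minor eigenvalues shrink by 5% post-intervention inside the
white-matter effect mask, exercise group only. GXT records follow the
25 W / 2 min step protocol with linear HR (terminating after the stage
reaching 170 bpm) and cubic lactate; training-session lactate for exercise
subjects averages ~140% of the subject's IAT lactate. d2-R line records are
constructed to score exactly to the planted CP.

All randomness flows from one root seed through `numpy.random.SeedSequence`
spawning: one cohort-level stream (demographics, latents, behavior), then
one child per subject split into per-modality streams — cohorts are bitwise
reproducible and modality subsets can be generated without disturbing the
rest.

The generator deliberately omits realistic MR artifacts (motion,
physiological noise, distortion, spatial autocorrelation of noise,
registration error) and any spatial smoothness in the noise. Passing
calibration and recovery studies therefore shows the *statistical machinery*
is correct and calibrated under its assumptions, not that the pipeline is
robust to real acquisition artifacts.

## Simulation studies and problem sizes

Two studies validate the inference chain end to end. The type-I study runs
200 null cohorts (all planted effects zero, 12^3 grid, BOLD only) through
EC change maps, baseline residualization and the TFCE-FWE GLM with 500
flips each; the family-wise false-positive rate must fall in the binomial
95% band [0.02, 0.09] around the nominal 0.05. The recovery study runs 25
default planted-effect cohorts through the full pipeline (NPC with 500
flips, mediation bootstrap B = 2000) and requires hub recovery (Dice > 0.3)
and a zero-excluding mediation CI in at least 80% of seeds each. These
sizes keep each study in the minutes range on a single core while leaving
the binomial bands meaningful; the flip and bootstrap counts are reduced
from the 5000/50000 production defaults, which only widens Monte-Carlo
noise, not bias.

## Known limitations

* EC assumes no zero-variance voxel inside the mask; such voxels are an
  error, not an imputation.
* The NPC behavior submodel permutes behavior residuals only; map-side and
  behavior-side exchangeability are not tested separately.
* The robust mediation's weighting metric is one member of the Huber-type
  family; with heavy contamination (> kappa) its breakdown is limited.
* The JN-ANCOVA uses the independence-based maximum-modulus critical value;
  with strongly correlated design points it is conservative.
* Percentage-change maps are undefined at near-zero baselines; the missing
  convention removes those voxels from inference rather than imputing.
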