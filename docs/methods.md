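# Methods

`symptomnet` implements the complete statistical workflow of a
questionnaire-based symptom-network study of insomnia: cohort descriptive
statistics, a regularized Gaussian graphical model (GGM) over the seven
Insomnia Severity Index (ISI) items, node centrality and predictability,
bootstrap accuracy/stability diagnostics, a permutation test for comparing
two group networks, and a synthetic-cohort generator that provides ground
truth for every stage.  This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic data
can show.

## The latent copula generator

Subjects are i.i.d. draws from a zero-mean multivariate normal
`Z ~ N(0, Σ)` whose precision `K = Σ⁻¹` carries the ground-truth graph:
the partial correlation between nodes i and j is
`ρ_ij = −K_ij / √(K_ii K_jj)`, and `ρ_ij = 0` exactly when the edge is
absent.  Each ordinal item is produced by cutting its latent coordinate at
fixed thresholds (standard-normal scale), giving scores 0–4; nodes without
thresholds (quality of life) are observed on the latent scale.  Because
thresholding is monotone, the copula — and hence everything the rank-based
pipeline estimates — is fully determined by `K`.

Construction: `ground_truth_from_partials` builds a unit-diagonal precision
`K = I − P` from a requested partial matrix `P`, which realizes the
requested partials exactly whenever `I − P` is positive definite.
`make_ground_truth` places `round(density · p(p−1)/2)` random edges with
weights drawn from a requested interval; if positive definiteness fails it
applies the one closed-form uniform shrink that restores a positive
spectral margin and rejects the configuration when that shrink would move
any weight more than 0.01 from its request.

**Default model.**  The 7-item graph is derived from a one-factor marginal
correlation structure with loadings 0.78–0.90 (the range reported in ISI
factor analyses) plus small residual correlations inside a nocturnal
cluster (items 1–3) and a dissatisfaction/daytime cluster (items 4–7);
this matrix is inverted to partials and entries below 0.02 are zeroed.
The implied population quantities: mean inter-item correlation ≈ 0.65,
mean latent nodewise R² ≈ 0.71, and expected-influence order
ISI2 > ISI7 > ISI1.  These magnitudes are modeling assumptions, not
estimates from any dataset.  With `include_qol=True` an eighth continuous
node is attached through negative partials −0.18 (ISI4), −0.12 (ISI7) and
−0.07 (ISI5), so the "flow" analysis has a planted ranking to recover.
Default item thresholds (0.55, 1.25, 1.95, 2.60) make low scores dominant,
as in community samples.

**Prevalence calibration.**  A common shift is subtracted from all item
thresholds so that `P(Σ items ≥ 8)` matches a target prevalence (default
0.189).  The shift is found by bisection against a fixed internal
calibration sample of 20,000 latent draws and accepted when the calibrated
prevalence is within 0.005 of the target.  A single common shift (rather
than per-item shifts) preserves the relative item-difficulty profile.
Realized cohort prevalence then varies around the target with binomial
noise (sd ≈ 0.012 at n = 1,101) plus the ≤0.005 calibration quantization.

**Covariates and outcomes.**  Covariates are drawn from marginal families
(Bernoulli/categorical/normal) whose default rates follow a published
multicenter caregiver cohort; they are independent of the symptom process
(only the marginals are emulated).  Outcome totals — depression (0–27),
anxiety (0–21), fatigue (0–10), QoL (2–10) — are linear-Gaussian in the
latent severity (the mean of the latent item values), then rounded and
clamped; QoL instead loads on the specific item latents that carry its
network edges, so the item–QoL dependence stays concentrated on ISI4, ISI7
and ISI5.  Slopes are set to produce realistic insomnia-vs-none contrasts
(e.g. depression ≈ +6 points in the insomnia group); intercepts sit at the
cohort means.

## Descriptive statistics

* Severity bands of the ISI sum: <8 none, 8–14 subthreshold, 15–21
  moderate, 22–28 severe; ≥8 defines insomnia symptoms.
* Binomial proportions use the Wilson score interval.  Among standard
  intervals it is the only one consistent with the published caregiver
  percentages, reproducing seven of the eight printed bounds exactly; the
  subthreshold upper bound computes to 16.4% where 16.5% was printed, and
  no standard interval reproduces all eight simultaneously.
* Chi-square tests are uncorrected Pearson statistics (matching the
  printed 2×2 values); t tests come in Welch (Satterthwaite df; used for
  age, whose printed df is fractional) and pooled-variance forms (integer
  df; used for QoL).
* Mann-Whitney U is reported as a signed, tie-corrected normal-deviate Z
  (positive when sample 1 ranks higher); `method="exact"` enumerates all
  `C(n1+n2, n1)` group assignments of the pooled ranks — the permutation
  distribution of U is symmetric about `n1·n2/2` even under ties, so the
  two-sided p sums both tails at the observed distance from that center.
* The ANCOVA group effect is the type-III F computed from incremental
  residual sums of squares; it equals the squared group-coefficient t in
  exact arithmetic and degrades gracefully to F = 0 when covariates absorb
  the outcome entirely.  With no covariates it is exactly the squared
  pooled two-sample t.
* Logistic regression is a Newton/IRLS maximum-likelihood fit (tolerance
  1e−8, ≤100 iterations) with Wald 95% intervals on the odds-ratio scale;
  study site enters as fixed-effect indicators (first site reference).
  Separation is detected (fitted probabilities at 0/1 with diverging
  coefficients) and reported as an error, not repaired.

## Gaussianization and adjustment

The nonparanormal transform maps each variable through average-tie ranks,
the shrunken empirical CDF `r/(n+1)` clipped to `[δn, 1−δn]` with
`δn = 1/(4 n^{1/4} √(π log n))`, and the standard-normal quantile
function, then standardizes to mean 0, sd 1.  The output is invariant
under strictly monotone relabelings of any variable.  Age adjustment
residualizes every transformed node on (intercept, age) and
re-standardizes, so the adjusted network keeps the original node set; the
choice (residualization rather than adding age as a node) is recorded in
the transform metadata.

A caveat that matters for interpreting simulations: with coarse ordinal
scales the rank-based correlations are attenuated relative to the latent
(polychoric) correlations — by roughly 10% for a latent correlation of
0.5 cut into 4 categories, and less as categories multiply.  Estimated
edge weights and nodewise R² on discretized data are therefore
systematically somewhat below their latent-scale population values
(e.g. observed mean predictability ≈ 0.57 against the default model's
latent 0.71).  Polychoric estimation is deliberately out of scope.

## Network estimation

The estimator maximizes
`log det K − tr(SK) − λ Σ_{i≠j} |K_ij|`
by block coordinate descent (lasso subproblems solved by cyclic coordinate
descent), with the penalty on off-diagonal entries only; convergence is
declared when the working covariance changes by less than 1e−6 in
max-absolute entry (hard failure after 10,000 sweeps).  The solver is
numba-compiled because the resampling stages perform tens of thousands of
solves on p ≤ 10 problems (~0.1 ms per 20-value path).  At λ = 0 the
solution equals the inverse correlation matrix; at
λ ≥ max|S_ij| it is diagonal; for p = 2 it has the closed soft-threshold
form — all three serve as test oracles, alongside an independent
cross-check against scikit-learn's implementation.

Model selection: λ path log-spaced over `n_lambda = 100` values from
λ_max (largest absolute off-diagonal correlation) down to
`λ_max · 0.01`, each solution scored by
`EBIC = −2L + E log n + 4 γ E log p` with `γ = 0.5`; the minimizer wins,
with exact ties broken toward the larger penalty (sparser model).  All
three settings are exposed as configuration.  The selected precision is
reported as partial correlations; entries below 1e−8 are stored as exact
zeros so edge counts are well-defined.  The main symptom network uses the
7 ISI nodes; the QoL "flow" analysis re-estimates an 8-node network
including QoL and reports only the edges incident to it, most negative
first (the point estimate from the 8-node model, not an average over
variants).

## Centrality, predictability, similarity

Expected influence is the signed one-step sum of incident weights (a
two-step variant is available but off by default); strength is the
absolute sum.  Predictability is the nodewise linear R² of each
transformed node on all others — a deliberate simplification of
mixed-graphical-model predictability, recorded as such in the output
metadata so the number is never presented as that package's quantity.
Similarity between two networks' centralities is the Spearman rank
correlation of their EI vectors.

## Stability and accuracy

The edge bootstrap resamples subjects with replacement (default B = 1000,
minimum 200), re-runs the entire transform-and-select pipeline per
resample, and reports percentile 95% intervals (percentile, not BCa,
matching the cited procedure and deterministic given the seed).  Resamples
that collapse an item to a constant are redrawn and counted.  The
difference test for two edges checks whether the percentile interval of
their bootstrap difference excludes zero.

Because the EBIC-selected penalty shrinks edge estimates toward zero,
percentile intervals are intervals for the *shrunken* estimand: in dense
graphs where every edge is supported the selected penalty is near zero and
coverage of the true partial is near-nominal (measured ≈93% at n = 2000),
but in sparse graphs the shrinkage bias can push coverage well below
nominal (measured ≈80% for an isolated 0.3 edge, lower on a chain).  This
is a property of regularized estimation, not of the bootstrap; the
intervals quantify sampling variability, not unbiased uncertainty about
unpenalized parameters.

Case-dropping stability: for each drop proportion q in {0.05, …, 0.75}
(step 0.05), B = 50 subsamples of size ⌈(1−q)n⌉ are drawn without
replacement, EI is recomputed and Pearson-correlated with the full-sample
EI (zero-variance vectors contribute correlation 0 by convention).  The
CS coefficient is the largest q at which ≥95% of correlations are ≥0.7;
above 0.25 is conventionally acceptable, above 0.5 preferable.  The
smallest retained subsample must be at least 3× the node count.

## Network comparison

The permutation test estimates both groups' networks with identical
settings and compares: M, the maximum absolute edge difference (structure
invariance); S, the absolute difference of global strengths (sums of
absolute upper-triangle weights); per-edge and per-node EI differences,
Holm-adjusted within their families.  The null distribution reassigns
pooled subjects to groups of the original sizes (default 1000
permutations, minimum 100); p-values use the add-one convention and so are
never exactly zero.  Degenerate permutations (an item constant within a
group) are counted as extreme, which is conservative.  Measured type-I
error for M at α = 0.05 is ≈0.055 over null simulations.

## Problem sizes used by the test suite

Simulation-based checks are sized to single-CPU runs: type-I error of the
comparison test uses 500 null simulations of n = 600 per group with 100
permutations and a 20-value penalty path; interval coverage uses 100
replicates of n = 2000 with B = 500; sparsistency uses 100 replicates at
n = 1,101; recovery checks use single draws of n = 5,000–20,000.  The
acceptance script runs the full pipeline once at the default study size
(n = 1,101, B = 1000, 1000 permutations).

## Known limitations

* The generator emulates marginal covariate rates only; covariate–symptom
  and covariate–covariate dependence (beyond outcomes driven by latent
  severity) is absent, so covariate coefficients in the logistic model are
  null in truth.
* Ordinal discretization attenuates rank-based estimates (above); ground
  truth is recovered up to that attenuation.
* Percentile bootstrap intervals inherit regularization bias (above).
* The permutation comparison test is slightly conservative under
  discreteness and for tied statistics.
* No graphical layout/rendering; outputs are tables (CSV) and metadata
  (JSON).
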