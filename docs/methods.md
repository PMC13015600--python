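# Methods

This note documents the models implemented in `ctrlcascade`, the design
choices made where conventions diverge, and what the synthetic cohorts do
and do not establish about real data.

## Network model and controllability

Brain dynamics are modeled as the noise-free linear discrete-time
time-invariant system `x(t+1) = A x(t) + B_K u_K(t)`, with *A* a per-subject
symmetric nonnegative structural connectivity matrix (mean quantitative
anisotropy per edge; zero diagonal). Edges with QA ≤ 0.001 are removed
before analysis; the comparison is strict (`> 0.001` retained), matching
the usual noise-floor convention for QA-weighted deterministic tractography.

**Stabilization.** The literature on linear network control of structural
connectomes does not fix a unique normalization; we divide by
`1 + λ_max(A)`. This guarantees spectral radius < 1, so `1 − λ_j² > 0` for
every mode and the Gramian series converges. The zero matrix is a fixed
point (an empty graph stays empty).

**Modal controllability.** `φ_i = Σ_j (1 − λ_j²) V_ij²` with *V* the
orthonormal eigenbasis of the symmetric normalized matrix. Orthonormality
resolves the scale ambiguity of eigenvectors, and φ is invariant to their
sign since V enters squared. Two consequences are used as internal checks:
the conservation identity `Σ_i φ_i = N − ‖A‖_F²` (asserted to 1e-8) and
permutation equivariance. For an isolated node (zero row), φ_i = 1 exactly.

**Gramian.** For a single control node k, `W = Σ_τ A^τ b_k b_k' (A^τ)'`
is computed as the solution of the discrete Lyapunov equation
`W = A W A' + b_k b_k'` (SciPy's solver), which equals the infinite series
whenever the spectral radius is below one; tests compare it against a
200-term truncated-series oracle. W is symmetrized and its minimum
eigenvalue reported (PSD up to 1e-10 roundoff).

**Network aggregation** is the unweighted mean of node φ within each of
the ten canonical networks; the aggregation rule is a package choice since
network-level controllability is commonly reported without one.

## Latent adversity factors

**QC.** Items with missingness > 50% are dropped (strict), as are items
failing the near-zero-variance screen: most-common/second-most-common
frequency ratio > 19 AND unique-value fraction < 10% (the defaults of the
common screening convention; both boundaries strict, so a 95/5 binary item
with ratio exactly 19 is retained). Constant items are always dropped.
Outliers on continuous items are cells beyond 4 × MAD from the median,
with MAD scaled by 1.4826 (consistency with the normal sd); flagged cells
are set missing and imputed. A zero MAD disables flagging with a warning.

**Imputation.** Chained equations with predictive mean matching
(statsmodels `MICEData`), ten completions of ten cycles by default,
averaged cell-wise into a single analysis matrix; observed cells are never
altered. PMM is donor-based, so binary items remain on their observed
support within each completion, though the cross-completion average of an
imputed binary cell can be fractional — accepted, as the averaged matrix
feeds a Pearson-correlation EFA. (PMM is used for binary items as well as
continuous ones; a logistic draw would change individual completions but
not the averaged analysis matrix in any way the EFA is sensitive to.)
`MICEData` draws from NumPy's global RNG; calls are wrapped in a local
seed guard so identical seeds give identical completions.

**Factorability.** Overall KMO (`Σr²/(Σr² + Σq²)` with anti-image partials
q from the inverse correlation matrix) and Bartlett's sphericity test
(`−(n−1−(2p+5)/6)·ln det R`, df p(p−1)/2). With p = 2 the partial equals
the correlation and KMO is exactly 0.5, a useful fixed point for testing.

**Extraction and rotation.** Principal axis factoring starts from
squared-multiple-correlation communalities and iterates the reduced-matrix
eigendecomposition until the communalities move less than 1e-4 (max 100
iterations); negative reduced eigenvalues are clipped; communalities above
one (Heywood) are clipped and flagged. Rotation is oblimin via the
gradient-projection algorithm with γ = 0 (direct quartimin) — γ is a free
parameter of the oblimin family and 0 is the standard default. Factor
order and sign are unidentified, so solutions are canonicalized (explained
variance descending, dominant sign positive), and solutions from different
samples are matched by maximal absolute Tucker congruence (Hungarian
assignment) with sign flips.

**Factor count.** Velicer's MAP (mean squared off-diagonal partial
correlation after removing k principal components, argmin over k) and VSS
(fit of the rotated loading matrix truncated to its largest `complexity`
entries per item). On clean five-factor synthetic cohorts MAP reaches its
minimum at 5 and VSS(c=1) peaks at 4–5.

**Scores and stability.** Regression (Thurstone) scores `Z R⁻¹ (ΛΦ)`
using the training sample's standardization, which makes out-of-sample
scoring well defined. Tenfold cross-validation trains fold models on 90%
of subjects and scores the held-out 10% (fold factors congruence-matched
to the full-sample solution first); stability is the per-factor Spearman
correlation between the concatenated out-of-sample scores and full-sample
scores. Whether out-of-sample scoring in the source convention is
regression-based is not fixed; regression scoring is adopted here.

## Associations

Outcome and predictor are z-scored (n−1 denominator), categorical
covariates dummy-coded dropping the first level alphabetically, and a site
random intercept is estimated by REML. Wald p-values use the default
normal approximation (no Satterthwaite correction) — an approximation,
adequate at cohort-scale n. When REML converges to the zero-variance
boundary the model *is* ordinary least squares and is refit as such, so
the degenerate reduction is exact rather than optimizer-slack-deep. BH-FDR
is applied within explicitly declared analysis families (e.g., factors ×
networks); the family boundaries are configuration, not inference.
Missing data are handled by listwise deletion per model.

## Mediation

Point estimates come from the three OLS regressions; for linear models on
one case set `c = c' + a·b` holds exactly (asserted to 1e-10). Bootstrap
is by case resampling (rows, jointly across equations), vectorized over
resamples via batched normal equations; structurally singular resamples
fall back to minimum-norm solutions. Intervals are **bias-corrected (BC),
not BCa**: the named convention of the standard macro's default. The bias
constant z₀ is the probit of the fraction of draws strictly below the
point estimate with ties counted half; endpoints are type-7 empirical
quantiles at Φ(2z₀ ± z_α). Proportion mediated is `indirect/(indirect +
c')` as a percentage; opposite-signed indirect and direct effects are
flagged inconsistent rather than reported as negative percentages.

PRS strata split at the 16th/84th percentiles (low ≤ p16 < medium ≤ p84 <
high), giving ≈16/68/16 — percentile cutpoints are authoritative even
though such splits are often described as 15/70/15. Moderated mediation
adds X·W and M·W products only (covariate×moderator terms are not
included); conditional indirect effects `(a + a_w w*)(b + b_w w*)` are
evaluated at within-stratum moderator means by default, with a
16th/50th/84th-percentile evaluation mode as the alternative reading of
"per-group" conditional effects.

## Cross-lagged panel models

Variables are covariate-residualized and z-scored per wave, then the two
wave-2 equations are fit by per-equation least squares with HC0 sandwich
errors. For a saturated observed-variable two-wave CLPM, ML point
estimates coincide with per-equation OLS, so the SEM machinery is not
re-implemented; the equivalence is enforced by an oracle test. Wave-1
covariance is free; the wave-2 residual correlation is the correlation of
the two equations' residuals. Missing follow-up rows are dropped listwise
(full-information ML for partially observed rows is out of scope). All
cross-lagged p-values across fitted models form one BH-FDR family;
autoregressive paths are reported uncorrected. The models describe
group-average temporal relations, not within-person causal effects.

## Synthetic cohorts

The generator emulates the *structure* of a multisite pediatric cohort,
not its content. Connectomes are stochastic-block graphs (within-network
edge probability 1.5× the target density, between-network probability
solved to hit the overall density) with log-normal weights at a QA-like
scale (median 0.02, σ_log 0.5). Indicators follow a simple-structure
measurement model: one dominant loading per item drawn from U(0.5, 0.8),
factor correlations 0.2, unique noise either completing unit total
variance (default) or unit-sd ("unit" mode); a configurable fraction of
items (default 40%) is median-split dichotomized; missingness is MCAR
(default 5%) — the real mechanism is unknown, so no MNAR structure is
claimed. Phenotypes plant the mediation cascade directly: the mediator is
generated from the latent factors (a = 0.3 on F4→MF), the outcome from
mediator and factors (b = 0.3, c' = 0.2) with a PRS×a-path interaction
(0.1), site intercepts (sd 0.3), small age/sex effects, and unit noise;
wave 2 follows autoregressive (0.5 brain, 0.6 behavior) and cross-lagged
(0.3 brain→behavior, 0 reverse) coefficients. The mediator is planted
directly rather than routed through edge weights because no closed form
maps edge perturbations to a target modal-controllability value; coupling
magnitudes are otherwise free parameters chosen at conventional
moderate-effect scale. Covariate marginals (age 9.47 ± 0.51, 52% male,
race and handedness frequencies, 22 sites) mirror a typical cohort of this
design.

Passing recovery tests on these cohorts therefore shows the *estimators*
are correct and calibrated under the planted model; it does not validate
distributional realism, informative missingness, measurement invariance,
or selection effects in real data.

## Problem sizes and tolerances

Closed-form and conservation checks run at N = 50 nodes, 100 random
matrices, tolerance 1e-8. Factor recovery and cross-validated stability
use n = 4000 subjects × 67 items. Bootstrap calibration uses 300
replicates at n = 1000 with 1000 resamples (95% BC coverage asserted in
[91%, 98%]; null rejection ≤ 8%, BC being mildly liberal). Moderated
mediation ordering uses 200 replicate cohorts at n = 4000 (point
estimates; ordering ≥ 90%). CLPM recovery uses n = 5000 with a 2-robust-SE
band and 1e-8 OLS-oracle agreement. Bootstrap results are bit-reproducible
under a fixed seed; per-stage seeds in the pipeline are spawned from one
master seed via NumPy's `SeedSequence` and recorded in the run manifest.

## Known limitations

* Wald inference in the mixed model ignores small-site degrees-of-freedom
  corrections; with 20+ sites the approximation is mild.
* BC (not BCa) intervals lack the acceleration correction; coverage is
  asserted empirically instead.
* The EFA path assumes Pearson correlations on the averaged imputed
  matrix; polychoric correlations and weighted least squares estimation
  for ordinal items are not implemented.
* Confirmatory factor analysis with absolute fit indices (CFI/RMSEA/SRMR)
  is out of scope; cross-validated score stability is the implemented
  overfitting check.
* The pipeline handles one mediator per model; multiple-mediator and
  sensitivity analyses are not provided.
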