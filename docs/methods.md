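# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical and design decisions a
maintainer would otherwise have to reverse-engineer.

## Data model

One person's data are an `n_obs × p` matrix of Likert ratings (integers
0–6, NaN for missing) at strictly increasing response timestamps.  A
prompt the person never answered is an all-NaN row; the long CSV format
keeps such rows via empty rating cells, so datasets round-trip exactly.

**Endorsement screen.** A symptom enters a person's models only if it
has at least `min_nonzero = 3` non-zero ratings **and** standard
deviation ≥ `min_sd = 0.1` rating units.  The two-part rule separates
"never endorsed" from "endorsed but nearly constant"; both are excluded,
reported distinctly from a modeled R² of zero.  Both thresholds are
configurable.

**Missingness.** Complete-case (listwise) deletion over the endorsed
symptoms, applied once, before the regression stage — so the detrending
residuals and both networks are estimated on identical rows.  A floor of
10 surviving rows (configurable) guards the regressions.

## Temporal basis

Seven columns: `t, t², t³` on elapsed hours since the person's first
observation, and `sin/cos` pairs at the 24-hr and 12-hr periods on
actual clock time-of-day.  Elapsed-study-time is used for trends (time
since injury is typically unknown, and the span of the cubic family is
invariant to any affine shift of the time axis, so R² does not depend on
the choice).  Clock time anchors the cycles because diurnal physiology
is anchored to the day; the sine+cosine pair makes the fit invariant to
phase, which the test suite verifies to 1e-8 under arbitrary clock
shifts.

All seven columns are standardized (mean 0, SD 1) before the LASSO and
before network embedding: `t³` reaches ~1.1×10⁸ hours³ over 20 days, and
a shared L1 penalty is meaningless across such scales.  Raw polynomials
are kept (not orthogonalized); the trend columns are therefore heavily
collinear (corr(t, t²) ≈ 0.97 on a uniform design).  The LASSO and the
graphical lasso remain well-defined under collinearity, but see the
limitation on embedded networks below.  Columns with zero variance
(e.g. every prompt at the same clock time) are dropped with a warning.

## Detrending (approach 2, steps 1–2)

Per symptom: minimize `(1/2n)·‖y − Xβ‖² + λ‖β‖₁` over a log-spaced λ
path, λ chosen at the 10-fold cross-validation minimum with folds from a
seeded shuffle (a contiguous-block CV option exists for
autocorrelation-robust folding).  `y` is standardized inside the fit.
Any subset of the seven columns may be retained — no hierarchy between
trends and cycles is imposed.  If n is too small for the folds the
selector falls back to BIC with a warning.

The reported R² comes from an **unpenalized OLS refit** on the retained
columns, so it measures the post-selection model, and the residuals are
exactly centered and orthogonal to every retained column (enforced to
1e-10 / 1e-8 in tests).  An empty retained set is reported as R² = 0.00
with residuals equal to the centered series — a state kept distinct from
"not endorsed" in every table and export (rendered `0.00` vs `–`; means
over persons include the zeros and exclude the dashes).

CV-minimum LASSO deliberately over-selects: in the pinned simulations at
n = 100 the false-selection rate under a pure-noise series is ≈ 0.3
(at least one spurious column retained), inflating the null R̂² by
≈ +0.02 and biasing R̂² upward by ≈ +0.03 overall.  This is the familiar
price of CV-min; the 1-SE rule or BIC would trade it for lower
sensitivity.

## Network estimation

Input is the Pearson correlation matrix of the node columns (Spearman
available; polychoric correlation is not implemented — residuals are
continuous, and Pearson keeps the estimator transparent).  The graphical
lasso maximizes `log det Θ − tr(SΘ) − λΣ_{i≠j}|θ_ij|` with the diagonal
unpenalized, solved by coordinate descent (the solver behind
`glasso_solve` is scikit-learn's `graphical_lasso`; at λ = 0 the closed
form Θ = S⁻¹ is used, which doubles as the oracle check against direct
inversion).  Convergence tolerance is 1e-4 on the dual gap with 200
iterations — ordinal data at n < p rarely support tighter tolerances,
and non-converged path points are recorded rather than warned
per-λ.  A non-PSD input (possible when n < p) is repaired to the nearest
correlation matrix with a warning.

λ is selected on a 100-point log-spaced path from
`λ_max = max_{i≠j}|S_ij|` (the empty graph) down to `0.01·λ_max` by
minimum EBIC, `−2ℓ + E·log n + 4γE·log p` with `ℓ = (n/2)(log det Θ −
tr(SΘ))`, E the number of nonzero upper-triangle entries, and γ = 0.5
(configurable 0–1; γ = 0 is BIC).  Edge weights are the partial
correlations `w_ij = −θ_ij/√(θ_ii θ_jj)`.

**Approach 1** estimates the network over endorsed symptoms plus the
seven standardized temporal columns, all edges penalized uniformly, so
node counts vary with endorsement (a person endorsing two symptoms gets
a 9-node network).  **Approach 2** estimates over the detrending
residuals only.  Fewer than two endorsed symptoms yields a degenerate
network; fewer than three makes centrality uninterpretable — both are
flagged, not raised, since they occur in realistic cohorts.

**EBIC sensitivity at weak edges.** At n = 100 and γ = 0.5, the per-edge
likelihood gain of a true partial correlation r is ≈ −(n/2)·log(1−r²),
which crosses the EBIC per-edge cost near |r| ≈ 0.3.  Selection is
therefore bimodal (empty-or-recovered) exactly at that strength: the
pinned chain-recovery simulations give sensitivity ≈ 0.43 at r = 0.3 but
1.0 at r = 0.4, with specificity > 0.97 throughout and the null network
empty in ≈ 99% of replicates.  This is a property of the criterion, not
the solver.

**Known limitation of embedded networks.** When strong symptom–temporal
edges are present, the single EBIC-selected λ is pulled far down the
path (the likelihood cost of shrinking strong edges dominates the
penalty saved on weak ones).  At that λ, symptom–symptom partials at the
sampling-noise scale (~1/√n) survive as weak spurious edges even when
the true residual precision is the identity.  A λ that zeroes the
symptom–symptom block while keeping the symptom–temporal edges exists on
the path, but a single global penalty selected by EBIC never chooses it.
Consequence: in the covariance-through-time scenario, approach 2
correctly returns an empty residual network (the reliable signature),
while approach 1 shows the temporal edges *plus* weak noise edges among
symptoms; interpret embedded-network symptom–symptom edges with their
weights, not their count.  Orthogonalizing the trend columns improves
the conditioning of the temporal block but does not remove this effect.

## Synthetic-data generator

Latent value per prompt = per-symptom mean structure (polynomial trend
on elapsed time rescaled to the study span, plus 24-hr and 12-hr
sinusoids with free amplitude and phase, phases drawn uniform on
[0, 2π)) + correlated Gaussian noise whose correlation is that of Ω⁻¹
for a chosen sparse positive-definite precision Ω, scaled by per-symptom
noise SD.  The latent state is evaluated at the *response* timestamp
(prompt time plus a uniform 0–90 min delay), so the analysis basis and
the generative process see the same clock.  Ratings discretize the
latent by thresholds — default: equal-probability bins over each
symptom's latent marginal, shifted upward per symptom (`floor_shift`) to
reproduce the floor effects that drive non-endorsement.  Whole prompts
are missing i.i.d. Bernoulli(0.27); the protocol is 20 days × 5 prompts
at 3-hour intervals on one of three preset daily schedules.

Mean-structure coefficients can be rescaled so each symptom's population
temporal R² over the realized schedule hits an exact target; the
generator returns realized R² and response rate as metadata, alongside
the latent matrix for latent-scale diagnostics.

What the generator does **not** emulate: informative (MNAR)
missingness, between-person multilevel structure, autocorrelated
residual dynamics (residuals are i.i.d. across prompts given the mean
structure), item-level skipping within an answered prompt, and
measurement reactivity.  Recovery results on these data therefore show
that the pipeline recovers the structure *its model class assumes*; they
do not certify behavior under lagged dynamics or non-random compliance.

The default 10-person cohort is heterogeneous (endorsement masks,
R² profiles, network densities) and always contains a two-symptom person
(person 5) and a person whose symptom covariation is carried entirely by
shared temporal structure (person 7), because those boundary cases
exercise the degenerate-network and empty-network code paths.

## Problem sizes and determinism

Simulation-based checks use n = 100 prompts per person (the protocol's
natural size), 100–200 replicates for recovery rates, and a 10-person
cohort for end-to-end runs — sizes at which the pinned Monte-Carlo
quantities are stable to a few percent.  All randomness (fold
assignment, simulation draws) flows from one master seed through
`numpy.random.SeedSequence` spawning; a rerun with the same inputs,
configuration and seed produces byte-identical result bundles, and the
bundle manifest records a SHA-256 per artifact.
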