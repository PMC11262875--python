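# Methods

This note records the statistical model behind each component, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Model and assumptions

Two-sample summary-level MR treats each instrument SNP *j* as an
instrumental variable: valid inference requires that the SNP is (1)
strongly associated with the exposure, (2) affects the outcome only
through the exposure (no horizontal pleiotropy), and (3) is independent of
confounders of the exposure–outcome relationship. The data model is

    γ̂ⱼ ~ N(γⱼ, σ_xj²),    Γ̂ⱼ ~ N(θ γⱼ + αⱼ, σ_yj²),

with θ the causal effect on the log-odds scale and αⱼ a pleiotropic
effect (zero for a valid instrument). The exposure and outcome samples
are assumed non-overlapping, so the two noise terms are independent.
Effects for binary traits are treated on the log-odds scale throughout;
odds ratios and 95% intervals are exp-transforms of β̂ ± 1.96·se.

## Estimators

* **Wald ratio** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order se σ_yj/|γ̂ⱼ|; an optional
  second-order (delta-method) se adds Γ̂ⱼ²σ_xj²/γ̂ⱼ⁴. First-order weights
  are the default everywhere, consistent with the F-statistic framing of
  instrument strength.
* **IVW**: inverse-variance-weighted mean of the ratios. Default is
  multiplicative random effects — the fixed-effect se scaled by
  max(1, √(Q/(J−1))) — so heterogeneity can widen but never narrow the
  interval; a fixed-effect flag is available.
* **MR-Egger**: weighted regression of Γ̂ on γ̂ with an intercept
  (weights 1/σ_y²) after re-orienting every instrument to γ̂ ≥ 0 (the
  standard identifiability convention). The intercept estimates the mean
  directional pleiotropic effect and requires pleiotropy independent of
  instrument strength (InSIDE). Standard errors are scaled by
  max(1, residual scale). The fit itself is delegated to statsmodels WLS;
  a test re-solves the normal equations independently. p-values use the
  normal reference like every other method here; users of R conventions
  should note the common alternative of a t reference on J−2 df.
* **Weighted median**: ratios ordered ascending, inverse-variance weights
  normalized, cumulative weight centered by half of each SNP's own mass,
  and the estimate interpolated at cumulative weight 0.5. It is consistent
  when valid instruments carry >50% of weight. The se comes from a
  parametric bootstrap (default 1,000 resamples, fixed recorded seed).
* **Maximum likelihood**: the per-SNP nuisance effects γⱼ are profiled out
  in closed form, leaving the one-dimensional profile log-likelihood
  −½ Σ (Γ̂ⱼ − θγ̂ⱼ)²/(σ_yj² + θ²σ_xj²), maximized by Brent search; the se
  is the inverse square root of the numerical curvature at the optimum.
  As σ_x → 0 this reduces exactly to fixed-effect IVW (tested).
* **RAPS**: solves Σ ψ(tⱼ)·∂tⱼ/∂θ = 0 with standardized profile residuals
  tⱼ = (Γ̂ⱼ − θγ̂ⱼ)/√(σ_yj² + θ²σ_xj² + τ²). Because exposure noise enters
  the denominator, the estimator does not attenuate under weak instruments
  (verified against IVW in simulation at per-SNP F ≈ 5). Overdispersion
  (τ², from the second-moment equation mean(tⱼ²) = 1, alternated with the
  θ root-solve) is enabled by default only for J ≥ 10 — with five
  instruments it is weakly identified. ψ is the identity for squared loss
  or the Huber clip (k = 1.345) for bounded influence; the se is the
  sandwich √B/|A| with A the numerical score slope.
* **BWMR**: the hierarchical model γⱼ ~ N(0, σ₀²), Γ̂ⱼ ~ N(θγⱼ, σ_yj²+τ²)
  makes each (γ̂ⱼ, Γ̂ⱼ) marginally bivariate normal. An EM loop alternates
  (a) maximizing the weighted marginal likelihood over (θ, τ², σ₀²) and
  (b) recomputing per-instrument weights as the posterior probability of
  the inlier component of a two-component scale mixture on standardized
  residuals (outlier variance 10× the inlier's, prior inlier probability
  0.99; both configurable). The reported se is the curvature of the
  weighted log-likelihood in θ at convergence; final weights are returned
  so flagged instruments are visible.

## Diagnostics

Cochran's Q uses first-order weights around the fitted model; df = J−1
for IVW and J−2 for Egger — the convention that simultaneously reproduces
both published p-values this package's acceptance checks pin (Q = 5.658,
df 4 → 0.226; Q = 4.857, df 3 → 0.183). I² = max(0, (Q−df)/Q).
Radial coordinates are x = √wⱼ, y = β̂ⱼ√wⱼ; the through-origin slope is
algebraically the IVW estimate and the per-SNP squared radial residuals
sum to Q, both asserted to 1e−8. Radial outliers use the χ²(1) quantile at
the Bonferroni-corrected level α/J (no rule is standard; this one is
conservative and deterministic).

The resampling outlier test builds the observed statistic from
leave-one-out residuals (SNP j against the IVW fit excluding j, weighted
by wⱼ) and simulates its null by redrawing Γ*ⱼ ~ N(θ̂₋ⱼγ̂ⱼ, σ_yj²) with
the full statistic recomputed per draw (vectorized). Defaults: 1,000
draws, significance 0.05, fixed recorded seed. Empirical p-values use
(1 + exceedances)/(1 + n_sim), so they are never zero; with no flagged
outliers the distortion test is not run (reported as absent). The
simulated null ignores the γ̂ noise in the observed residuals, which makes
the global p very slightly conservative for strong instruments; the
calibration test (KS against uniform over 100 seeded datasets) bounds the
effect.

## Harmonization and selection conventions

"Intermediate frequency" for palindromic SNPs is |EAF − 0.5| ≤ w with
default w = 0.08, the common harmonization default, exposed as a
parameter; non-intermediate palindromic SNPs are oriented by frequency
agreement, and a strict mode drops all of them. Matching is by rsID.
Clumping is greedy by ascending p with ties broken by smaller se then
rsID (deterministic); the distance window is measured from the index SNP
and inclusive at the boundary; pairs absent from the LD table count as
r² = 0. The F-statistic uses the unrounded R² and K = the number of
selected instruments by default (K is a parameter: with the five bundled
instruments both K = 5 and K = 1 reproduce the printed F column within
rounding, so the convention cannot be pinned further).

## Power

The closed form is the standard binary-outcome approximation used by the
mRnd-style online calculators. With the motivating study's inputs
(N = 36,792, 8,180 cases, R² = 0.049, OR = 1.2, α = 0.05) it yields
≈ 0.90. The source study reports 81% power for the same design without
stating the OR actually plugged in; no choice of printed input reproduces
that figure under this closed form, so the package reports only what it
computes and surfaces the formula in the output for traceability.

## Synthetic generator

`simulate_pair` draws per-instrument MAF ~ U(0.05, 0.5), true exposure
effects γⱼ ~ N(0, 0.15²), pleiotropy per mode (none / balanced /
directional / strength-correlated, with a configurable invalid fraction),
and observed effects with noise sd 1/√(2p(1−p)n) per study. Defaults
(n_exposure = 212,453; n_outcome = 36,792; effect spread 0.15) mirror the
motivating two-cohort design and put instrument F-statistics in the
strong regime. In the directional modes true γ are oriented positive
(instruments reported for the exposure-increasing allele), otherwise a
fixed-sign pleiotropic offset would cancel in expectation and directional
pleiotropy would be unrepresentable. Null SNPs carry zero effects; LD
blocks, when requested, group leading SNPs at nearby positions with a
shared pairwise r².

What it does not emulate: case-control ascertainment and the binary-trait
link (log-odds effects are treated with the standardized-trait noise
formula, matching the R² convention used for instrument strength), sample
overlap, LD beyond block-constant r², allele-frequency differences
between studies, and genotyping/imputation error. Passing recovery and
calibration tests on this generator therefore demonstrates correctness of
the estimators under the stated sampling model, not robustness to those
real-data complications.

## Numerical conventions and problem sizes

P-values are never allowed to underflow to zero (floored at the smallest
positive normal double) so genome-wide values survive file round-trips.
Tables are written with shortest-round-trip float formatting, making
bundles byte-reproducible for a fixed config and seed. All stochastic
components (bootstrap, resampling test, generator, BWMR restarts) take
explicit seeds recorded in their outputs. Statistical test sizes in the
suite follow the contracts they check: 2,000 replicates for type-I-error
and Q calibration, 200 for estimator recovery and robustness orderings,
100 random instances for the clumping oracle; these keep Monte-Carlo
error well inside the asserted bands while the whole suite runs in about
half a minute.

## Known limitations

No multivariable or bidirectional MR, no proxy-SNP lookup, no LD
computation from genotype panels (LD is consumed as a pairwise table),
no VCF ingestion, and no figure rendering (the radial table is plot-ready
coordinates). The BWMR weighting scheme follows the published method's
spirit with documented constants rather than reproducing any specific
implementation's internals.
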