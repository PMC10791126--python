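# Methods

This note documents the models, priors, numerical choices and
limitations of `empabayes`, in the order the pipeline uses them.

## Censored rating model

Ratings on a bounded 0–100 visual-analog scale pile up at the bounds
whenever the latent judgment exceeds the scale. We therefore model a
latent rating

y\*₍ij₎ = xᵢⱼ′β + zᵢⱼ′bᵢ + εᵢⱼ, εᵢⱼ ~ N(0, σᵢ²),

observed as yᵢⱼ = min(max(y\*ᵢⱼ, 0), 100). An observation exactly at a
bound is always treated as censored — we deliberately do not support an
"observed boundary" dialect, because a 0 or 100 response carries no
information about how far beyond the scale the judgment lay.
Interior observations contribute Normal densities; boundary observations
contribute Φ tail probabilities.

Design terms are ±1-coded factors and all their interactions
(Group × Session × Intensity for empathy-for-pain ratings;
Group × Content × Context for emotional-reactivity ratings). With this
coding, a two-level condition difference equals 2β
(`condition_difference`); a general contrast evaluator is also provided,
because the 2β reading of a three-way interaction is a *convention* (the
fully crossed double-difference contrast of a three-way term under ±1
coding is 8β, not 2β — users who want that contrast should use
`censored_model.contrast`).

Random effects bᵢ cover the within-subject terms plus an intercept. The
intercept is included because between-subject spread in overall scale
use is large in rating data and omitting it would push that variance
into the residuals. A per-subject residual SD σᵢ absorbs idiosyncratic
rating granularity (some subjects answer in steps of 10, others finely).

### Priors

All priors are explicit and configurable (`PriorSpec`), because every
Bayes factor depends on them:

| parameter | prior | default scale (rating units) |
|---|---|---|
| intercept | Normal(0, s) | 50 |
| other fixed effects | Normal(0, s) | 10 |
| random-effect SDs | half-Normal(0, s) | 20 |
| RE correlation | LKJ(η) | η = 2 |
| per-subject σᵢ | half-Normal(0, s), independent | 20 |

These are this package's own choices: weakly informative on the 0–100
scale (a non-intercept effect of ±20 points is ~2 prior SDs), mildly
regularizing on correlations. A Normal(0, 10) prior does shrink a very
large effect: at 12 subjects × 4 ratings/cell the posterior SE of a
strong effect is ≈1.3 rating units, giving an expected shrinkage of
β·SE²/(SE²+10²) ≈ 0.5 units on a 28-unit effect — visible in the
parameter-recovery suite and decaying quadratically with sample size.

### Estimation

Sampling is blocked Gibbs with truncated-normal data augmentation:

1. latent y\* for each censored observation from its truncated-normal
   full conditional (inverse-CDF draws, tail-guarded);
2. β from its Gaussian conditional **with the random effects integrated
   out** (Woodbury identity per subject) — collapsing removes the
   β–bᵢ coupling that makes naive Gibbs mix slowly on intercept-like
   terms (split-R̂ ≈ 1.00 and bulk ESS ≈ 0.9 per draw in our checks);
3. bᵢ per subject from its Gaussian conditional;
4. σᵢ by vectorized Metropolis on log σᵢ (target acceptance 0.44);
5. τ (RE SDs) by joint Metropolis on log τ, and the RE correlation
   matrix by a random-walk on its off-diagonals with positive-definite
   rejection (target acceptance 0.23); step sizes adapt by
   Robbins–Monro during warmup only.

Augmentation and the closed-form tail-probability likelihood
(`censored_loglik`) define the same posterior; the test suite fits a
small model both ways (Gibbs vs. an emcee ensemble sampler on the
direct likelihood) and checks the posteriors agree. We chose
augmentation as the primary route because every conditional is then
conjugate or a cheap scalar Metropolis step, which on one CPU is an
order of magnitude faster than ensemble sampling at realistic
dimensionality. Defaults are 4 chains × (1000 warmup + 1000 draws);
`fit_posterior` fails loudly if any fixed effect's split-R̂ exceeds
1.01.

## Bayes factors

* **Savage–Dickey**: BF₁₀ = prior density at 0 / posterior density at 0
  for a point null nested in the unrestricted model. The posterior
  density is estimated by a moment-matched Normal by default (fixed
  effects are near-Gaussian a posteriori); a Gaussian KDE alternative is
  available and the two are compared in tests. If the posterior density
  at 0 underflows, the result is flagged as a lower bound.
* **Sign-restricted**: BF(restricted vs. null) = [posterior sign mass /
  prior sign mass] × Savage–Dickey BF, the chain rule through the
  unrestricted model. For a symmetric prior the prior mass is ½.
* **JZS t-test**: Cauchy(0, √2/2) prior on the standardized effect δ;
  BF₁₀ = ∫ nct(t; ν, δ√N_eff) dΠ(δ) / t(t; ν) with
  N_eff = n₁n₂/(n₁+n₂). The integral is evaluated on the prior-CDF
  scale (adaptive quadrature for single values; fixed 256-node
  Gauss–Legendre, vectorized, for Monte-Carlo work — the two agree to
  ~1e-8 relative). One-sided tests truncate and renormalize the prior.
  The scale √2/2 is the conventional "medium" default and reproduces
  the reference group-comparison value in the acceptance suite.
* Evidence categories: H1 iff BF > 3, H0 iff BF < 1/3, the closed
  interval [1/3, 3] inclusive is inconclusive.

## Reliability

The behavioral test–retest reliability uses the variance-component
formula (see README) evaluated **per posterior draw** and then
summarized, so parameter uncertainty propagates into the ρ interval
rather than being collapsed to point estimates first. The formula
equals corr(b_I − b_I:S, b_I + b_I:S) under the random-effect
distribution; a seeded million-draw simulation confirms the identity to
<0.005 in the tests. Degenerate inputs (both variance components zero,
or |r| > 1) raise errors rather than returning NaN.

Neural reliability is the correlation between session-1 and session-2
subject-level contrast effects — by default the per-draw Pearson
correlation of the two random-effect vectors, optionally the model's
correlation parameter. Cross-task correlation tables report posterior
means above the diagonal and 95% intervals below it, mirroring the
field's tabular convention.

## Design analysis

* r → d: d = 2r/√(1−r²).
* Interaction power: the group-by-time interaction F in a 2 (between) ×
  2 (within) ANOVA has df₁ = (g−1)(m−1), df₂ = (N−g)(m−1) and, under
  effect d with repeated-measure correlation ρ, noncentrality
  λ = (d/2)²·N·m/(1−ρ) (the GPower 3.1 within-between convention).
  `required_n` scans even N. Under this convention d = 0.3 requires
  N = 90 and d = 0.396 gives power 0.960 at N = 90.
* BFDA: for each replicate, a two-group pre/post sample is drawn with
  unit marginal SDs, pre/post correlation ρ, and the raw effect d added
  to the experimental group's post score — so the standardized
  change-score effect is d/√(2(1−ρ)). A pooled two-sample t on change
  scores (raw scores for single-session designs) is converted to a
  one-sided JZS BF and classified. Whether the original analysis
  simulated at trial or subject level is not documented; we simulate
  subject-level summaries, which reproduces the published outcome grid
  within Monte-Carlo error. Each scenario reports Monte-Carlo standard
  errors; 10,000 repetitions by default.

## ROI model

Event boxcars on an oversampled grid (tr/16) are convolved with a
canonical double-gamma HRF (peak gamma: delay 6 s, dispersion 1 s —
mode at 5 s; undershoot: delay 16 s, ratio 1/6; unit-peak normalized)
and sampled at scan onsets. Low-frequency drift uses a discrete-cosine
basis with a 128 s cutoff.

The hierarchical fit concerns the two Other-condition stimulation
regressors (pain / no-pain). Their amplitudes carry the ±1-coded
Group × Session × Intensity fixed-effect structure plus three subject
random effects: a shared amplitude level and session-specific
pain-minus-no-pain contrast effects, whose cross-session correlation is
the neural reliability. All other design columns (cue and
self-condition regressors, rating events, drift, constant) are
projected out of each run before the fit — the ROI-level analogue of
standard high-pass filtering. This is a deliberate simplification: the
nuisance amplitudes are not themselves modeled hierarchically, and
projection slightly correlates the filtered noise, which the white
per-subject Gaussian noise model ignores. Observation noise is white by
design (no AR(1) by default). With noise-free data the per-run
amplitudes are recovered exactly; with one amplitude per run the model
reduces to the classical two-level summary-statistics GLM, and the
tests verify the group contrast matches per-run least squares within
Monte-Carlo error.

## Synthetic data

The generators produce exactly the structure the models assume:
±1-coded factors, correlated subject random effects, log-normal
per-subject residual SDs (strictly positive, heavy-ish tail; log-SD 0.4
around a median of 10 rating units), clamping with censoring flags.
Default sample sizes are 44 control / 45 experimental subjects; the
empathy task yields 8 ratings per condition per session (ratings follow
half of the 16 trials per condition), the reactivity task 4 (one per
picture block). Default generative effects mirror the magnitudes of the
published rating analyses (intensity 27.86, content 37.08 rating
units, intercept 45); the master seed spawns one child stream per
subject, so subject i's data are invariant to the number of subjects
requested.

What the generators deliberately do **not** emulate: ordinal/steppy
rating behavior, drift or serial dependence in ratings across trials,
session-order effects beyond the coded Session term, physiological fMRI
noise (cardiac/respiratory, motion spikes), scanner drift beyond smooth
DCT-removable trends, and dropout. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
real-data violations of it.

## Problem sizes used in the test suite

Tests run the full machinery at reduced but honest sizes chosen for a
single-core laptop: parameter-recovery/coverage at 12 subjects ×
4 ratings/cell over 100 replicates (nominal 95% coverage asserted with
three binomial SEs of slack), design-analysis grid cells at 2,500
Monte-Carlo repetitions (±0.03 assertions), the sampler cross-check at
4 subjects. The acceptance script uses the study-scale 44/45 design
with 10,000 repetitions.

## Known limitations

* The exact informed priors of the original analyses are not published
  in the main text; ours are stated above and all BF values depend on
  them. Reproduction of the published posterior tables would require
  the archived raw data.
* Bridge sampling (the reference implementation's BF route) is not
  implemented; Savage–Dickey plus sign-mass ratios is exact in the
  large-draw limit for these nested tests but relies on a density
  estimate at zero.
* The Gibbs sampler assumes the random-effect dimension is modest
  (≤ ~6) and subjects number in the tens to hundreds — the regime of
  these designs.
* The printed achieved-power triple (0.901/0.960/0.986 at N = 90) is
  internally inconsistent with any λ ∝ d² convention; our convention
  reproduces the middle value and the required N exactly, and gives
  0.899 and 0.987 for the outer two.
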