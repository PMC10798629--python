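# Methods

## The task and its generative model

The coin-catching task is a visuospatial estimation game.  Screen
coordinates are dimensionless, spanning −0.5 (left edge) to 0.5 (right
edge); all lengths below are in these screen units.  On each trial a hidden
coin position is drawn from a zero-mean Gaussian *prior* with standard
deviation σ_P, and five "splash" dots are scattered i.i.d. Gaussian around
the coin with single-dot dispersion σ_L (the *likelihood*).  The observer
places a net (width l = 0.02) at the estimated coin position; the coin
(diameter d = 0.01) is caught when the response is within half the catch
window L = l + d = 0.03.  Because the dot centroid μ_L is a sufficient
statistic for the coin given the cloud, the effective evidence variance is
σ_L²/n with n = 5 dots.

Two protocols are implemented:

* **exp1** — priors Pn (σ = 0.025) and Pw (σ = 0.085) crossed orthogonally
  with likelihoods Ln (σ = 0.06) and Lw (σ = 0.15).  400 learning trials
  (200 per trained combo; block-wise for the *serial* group, interleaved for
  *parallel*), then 180 transfer trials of one prior with both likelihoods
  (90 + 90), one pairing being novel.  Four counterbalance assignments cover
  the two orthogonal pairings × the two transfer priors.
* **exp2** — a single prior Pw with likelihoods Ln (σ = 0.024), Lm (σ =
  0.06) and Lw (σ = 0.15).  200 learning trials of two combos (100 + 100),
  then 75 transfer trials of each of the three.  The *interpolation* group
  trains Ln and Lw (novel: Lm, inside the trained range); *extrapolation*
  trains Ln and Lm (novel: Lw, outside it).  The narrow σ of 0.024 is
  config-exposed because the design is stated inconsistently at one place in
  the source material; 0.024 is the reading consistent with the figure-level
  design summary.

A likelihood-only pre-task (exp1: 80 trials, 40 per likelihood; exp2: 90
trials, 30 per likelihood over three 30-trial blocks) measures pure centroid
estimation.  Its generative cloud centres are drawn from a zero-mean
Gaussian with the design's widest prior σ; this choice is presentational
only, since the estimation below depends on response − centre, which is
independent of the centre.

"Interleaved/pseudorandom" orders are realized as a seeded proportional
draw without replacement, constrained so no condition runs longer than 6
consecutive trials; the rare dead ends at the sequence tail restart the
draw.  Positions are never clipped to the screen: with these σ values
excursions beyond ±0.5 are vanishingly rare for coins, and clipping the
occasional wide-likelihood dot would distort the Gaussian assumptions the
estimators rely on.

## Synthetic observers

Observers respond with additive Gaussian motor noise (σ_m, identical in
both tasks) around a strategy-dependent estimate:

* **bayes** — ŵ·μ_L with ŵ = σ̂_P²/(σ̂_P² + σ̂_L²/n) computed from
  *internal* dispersions σ̂, which may be miscalibrated.
* **likelihood_only** / **prior_only** — μ_L / the prior mean.
* **linear_map** — ŵ = β₀ + β₁/σ̂_P² + β₂/σ̂_L², clipped to [0, 1]; with
  β₁ = 0 this is a likelihood-only mapping learner.
* **exemplar** — stores every learning-phase coin-feedback position, and per
  trial resamples N of them uniformly with replacement, returning their
  likelihood-weighted mean (self-normalized importance sampling; weights use
  the single-dot σ_L by default, a centroid-σ variant is config-selectable).
  If all weights underflow, the unweighted sample mean is used.
* **rote** — learns the bayes weights during training but, facing a novel
  likelihood in transfer, re-uses the weight of the trained combo sharing
  the trial's prior (in exp2, the trained likelihood nearest in σ).  This is
  the zero-transfer baseline.

Cohorts draw internal dispersions per participant and label as
true σ × bias × exp(τ·z), z ~ N(0, 1): a systematic bias times log-normal
jitter.  The default bias_l = 0.7 shrinks internal likelihood σ, producing
the characteristic over-reliance on sensory evidence; bias 1 and τ = 0 give
ideal observers.  The default motor noise σ_m = 0.01 (half the net width)
is the package's realism choice for a cursor-placement response.  A master
seed fixes the entire cohort (schedules, internal parameters, responses),
so identical configurations are byte-identical on disk.

## Estimation chain

Per participant:

1. **Evidence proxy.**  σ_Li² = Σ(μ_Lest − μ_L)²/n_trials per likelihood
   level from the likelihood-only task (population divisor, exactly as
   defined), where μ_L is the generative cloud centre.  For a noiseless
   centroid estimator this equals σ_L²/5; motor and computation error add
   to it, which is what makes it subject-specific.
2. **Slopes.**  OLS of responses on centroids per combo, in presentation
   order, after discarding the first 50 (exp1) / 25 (exp2) trials of each
   learning combo to skip prior acquisition.  Transfer-phase and
   likelihood-only fits discard nothing.  A through-origin variant
   (β = Σxy/Σx²) is available for sensitivity analysis.
3. **Prior proxy.**  σ_Pi² = σ_Li²·slope/(1 − slope).  Slopes outside
   (0, 0.99) are flagged unreliable — near 1 the proxy diverges — and the
   (participant, combo) takes the exclusion path instead of propagating a
   wild value.  A logistic-pooling helper is provided as the alternative
   treatment of extreme slopes.
4. **Predicted transfer slope.**  σ_Pi²/(σ_Pi² + σ_Li,new²), one per
   trained combo sharing the novel combo's prior.

## Transfer score and screening

ts = (measured_new − learned)/(predicted_new − learned), with the learned
slope taken from the learning phase of the baseline combo.  In exp2 the two
trained combos give two scores, which are averaged per participant (the
ratio-of-averaged-changes alternative is deliberately not the default).
Denominators below 10⁻⁶ mark the score undefined.  The score is 1 for ideal
transfer and 0 for none, and — its defining property — it is invariant to
*consistent* internal miscalibration, because the subject's own proxies
appear in both numerator and denominator.

Outlier screening is staged 3-MAD exclusion (scaled MAD, normal-consistency
constant 1.4826) applied across participants, in order, to: slopes
(learning and transfer-new, per combo), σ_Pi² (per combo), predicted
slopes, and pooled scores.  A participant flagged at one stage does not
enter later stages; every stage's count is tallied in the outputs.  With
MAD = 0 only exact deviants from the median are excluded.

The optimality index for a trial is p_hit(x_net)/p_hit(μ_post), where
p_hit(x) = Φ((x + L/2 − μ)/σ) − Φ((x − L/2 − μ)/σ) under the true
generative posterior (variance (1/σ_P² + n/σ_L²)⁻¹).  It is 1 exactly at
the posterior mean and is used as a trend diagnostic (first vs last 10
transfer trials) for incremental learning after feedback removal.

## Strategy models and BIC

Candidate models, all conditioned on learning-phase estimates only:
**bayes** (modelled ts ≡ 1; k = 0 beyond the shared estimation stage),
**linear** (per-participant least squares of learning slopes on
(1, 1/σ_Pi², 1/σ_Li²); k = 3; with two learning combos the system is
rank-deficient and the minimum-norm solution is used, flagged once in the
log), **likelihood_only** (β₁ = 0; k = 2; exactly determined by two
combos), and **exemplar_N5/N20** (simulate transfer-new responses from the
participant's actual stored coin positions and trials, refit the slope;
k = 1).  Exemplar predictions average the refitted slope over 20 simulation
repetitions so the model is judged on its expected prediction rather than
one Monte-Carlo draw.

Each model's predicted transfer slope passes through the transfer-score
formula with the participant's own learned and Bayes-predicted slopes.
Models are ranked by the Gaussian-residual BIC, n·ln(RSS/n) + k·ln(n), over
participant-level (measured − modelled) score residuals, on the common set
of participants for which every model is defined; RSS = 0 reports −∞
("perfect fit").

## What the simulations do and do not show

The generator reproduces the protocol structure, reliability-based
weighting, internal miscalibration, motor noise, and the strategy classes —
enough to calibrate the chain end to end: ideal cohorts score ~1, rote
cohorts ~0, miscalibrated Bayesian cohorts stay near 1, and the generating
model is recovered by BIC in 3 of 4 recovery cells (the rote generator has
no counterpart in the candidate model space; its cell is won by the bayes
model and logged).  It does **not** emulate trial-by-trial prior
acquisition dynamics, sequential/history effects, lapses, or attention
drifts, so passing tests validate the estimators and statistics, not any
claim about how real participants learn.  Two quantitative footnotes:
(a) motor noise inflates σ_Li² relative to an ideal observer's internal
evidence variance, which biases ideal-cohort mean scores slightly above 1
(~+0.05 at σ_m = 0.01) — a property of the statistic itself, not of the
implementation; (b) exemplar observers at small N show shrinkage-biased
scores (~0.87 at N = 5), which is precisely what makes them separable from
bayes in model recovery.

Deliberate numerical choices: slope cap 0.99; ts-denominator tolerance
10⁻⁶; MAD constant 1.4826; interleaving max-run 6; population divisor in
σ_Li²; exemplar weighting uses single-dot σ_L.  Problem sizes used in the
calibration suite — 50-participant cohorts at the full published trial
counts (660 trials per exp1 participant) — were chosen as the smallest
cohorts at which cohort means are stable to well under the test tolerances.

## Known limitations

* Participants whose slopes saturate near 1 (easy in exp2, where optimal
  narrow-likelihood slopes are ≈0.98) are excluded by the slope cap; cohort
  attrition there is a property of the proxy algebra, and the package
  reports it rather than hiding it.
* The minimum-norm convention for the under-determined exp1 linear-mapping
  fit is one defensible choice among several; its predictions are poor by
  construction and flagged in output.
* Real-data ingestion is limited to the documented trial-table CSV dialect;
  no fitting to archival human data is attempted.
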