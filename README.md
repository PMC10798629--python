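# cointransfer

Tools for asking whether an observer in a probabilistic estimation task is
*actually* doing Bayesian computation — or just behaving Bayes-ish — by
measuring how well a learned prior transfers to sensory evidence it was
never paired with.

The package is built around the coin-catching task of Bayesian
psychophysics: on each trial a hidden coin position is drawn from a
zero-mean Gaussian prior (sd σ_P), five splash dots are scattered around it
with Gaussian likelihood noise (single-dot sd σ_L), and the observer places
a net at the estimated position.  The ideal observer weights the splash
centroid μ_L by

    w = σ_P² / (σ_P² + σ_L²/n),        n = 5 dots,

and that weight is measurable as the regression slope of responses on
centroids (1 = pure likelihood reliance, 0 = pure prior reliance).  Humans
are reliably *qualitatively* Bayesian but miscalibrated, so a slope alone
cannot tell flexible Bayesian computation from a memorised stimulus–
response policy.  The **transfer score** can: from each participant's own
variance proxies — σ_Li² from a centroid-only pre-task, and
σ_Pi² = σ_Li²·slope/(1 − slope) from the learning phase — it predicts the
slope an internally-consistent Bayesian would show on a *novel*
prior/likelihood pairing and normalises the measured slope change by the
predicted one:

    ts = (measured_new − learned) / (predicted_new − learned).

ts = 1 means full Bayesian transfer regardless of miscalibration; ts ≤ 0
means none (a rote policy).  The package simulates cohorts of known
strategies (ideal and miscalibrated Bayesian, rote, likelihood-only,
linear-mapping, exemplar-resampling observers), runs the full estimation
chain with staged 3-MAD outlier screening, computes per-trial optimality
indices, and compares Bayesian against heuristic strategy models with BIC.

Intended users: computational cognitive scientists designing or
re-analysing cue-integration and prior-learning experiments, and anyone who
needs a ground-truth-known testbed for transfer statistics.

## Worked example

Simulate 50 miscalibrated-but-Bayesian participants (internal likelihood
sigmas shrunk by the default bias 0.7 with log-normal jitter τ = 0.2 — the
kind of observers that over-rely on sensory evidence), then estimate,
score and model-compare in one run:

```bash
cointransfer run --n 50 --seed 42 --tau-l 0.2 --tau-p 0.2 --out demo
```

prints

```
{"n_included": 39, "mean_ts": 0.9764614146814071, "median_ts": 1.0021887388923876, ...}
```

and writes `demo/model_comparison.csv`:

```
       model_id  k  n       RSS     BIC  delta_BIC
          bayes  0 39     3.602 -92.904      0.000
likelihood_only  2 39   350.644  92.979    185.883
   exemplar_N20  1 39   538.632 106.057    198.961
    exemplar_N5  1 39   649.306 113.345    206.249
         linear  3 39 61147.809 297.933    390.836
```

Reading: although every simulated participant weights evidence too heavily
(slopes above optimal), the cohort's mean transfer score is ≈ 1 — the
statistic cancels subject-specific miscalibration, which is exactly its
point — and the Bayesian model wins the BIC comparison over the
linear-mapping, likelihood-only and exemplar alternatives, with 11 of 50
participants removed by the staged slope/proxy/score screening
(`demo/manifest.json` holds the per-stage tally).  A rote cohort
(`--strategy rote`) scores ≈ 0 instead.

Other subcommands (`simulate`, `estimate`, `score`, `compare`) expose the
stages separately; `score --input trials.csv` works on any externally
supplied trial table in the documented CSV dialect.  The library API
(`cointransfer.simulate_cohort`, `estimate_cohort`, `cohort_transfer`,
`compare_models`) gives the same results programmatically.

See `docs/methods.md` for the model, estimators, screening rules and their
caveats.

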