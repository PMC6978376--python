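# Methods

This note records the model, the numerical choices, the synthetic data
design, and the limitations of `riskaudit`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The unreliability score

The audit compares the risk model f(x) = ŷ against an alternate estimate
derived from the same training data, using only per-class summary
statistics. Per outcome class a multivariate normal (MVN) is fit to the
normalized features (sample mean, unbiased sample covariance, ridge `1e-6`
added to the diagonal so small or degenerate classes stay samplable).
Continuous features are affinely mapped to [0, 1] by schema ranges; binary
features enter the MVN as their raw 0/1 values.

The score-conditional likelihoods P^G(ŷ|y) are estimated by pushing
Monte-Carlo draws from each class MVN through f and histogramming the
scores at bin width 0.001 (1000 half-open bins, the last bin closed so a
score of exactly 1.0 is counted). Binary coordinates of each draw are
thresholded at 0.5 — with the Bernoulli-moment variance this approximately
preserves the fitted class frequency (a latent mean of 0.3 realizes a
frequency of 0.331) — and continuous coordinates are clipped to [0, 1],
the model's domain. Convergence is declared per class when a two-sample
Kolmogorov–Smirnov test of the previous score sample against the combined
sample fails to reject; the test is applied to the raw samples, not binned
counts, because the two-sample K–S statistic is defined on empirical CDFs.
Non-convergence after `max_iter` rounds is returned as a flag and logged,
never silent.

With β(ŷ) the per-bin mass ratio and π the training prevalence, the
alternate estimate is P^G(y=1|ŷ) = βπ/(βπ + 1 − π) and

U(x) = |P^G(y=1|ŷ) − ŷ|.

If f equals the generative posterior P^G(y=1|x), U converges to zero as
the batch grows (verified as an acceptance property); the converse fails —
U = 0 does not certify a prediction, so only *large* U is informative.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `batch` | 1e6 | generative draws per K–S round and class; the printed-protocol scale |
| `bin width` | 0.001 | score histogram resolution (fixed) |
| `alpha_ks` | 0.05 | K–S significance for the stopping rule; conventional level |
| `max_iter` | 20 | cap on K–S rounds; exhaustion flags `converged=False` |
| `pseudocount` | 1.0 | virtual samples added per bin per class; keeps β finite and positive on empty bins while perturbing occupied bins by ≲0.1% at 1e6 draws |
| `ridge` | 1e-6 | covariance diagonal regularizer |
| `n_boot`, `fraction` | 100, 0.2 | stratified bootstrap replicates of 20% of the test pool |
| trust `k`, `alpha` | 10, 0.05 | k-th-neighbor density filter; fraction of each class removed as outliers |
| β law | uniform (0, 10] | support for expected-unreliability curves; the qualitative shape under imbalance is insensitive to the bound |

Bayes' rule uses the training-summary prevalence by default (the method is
defined to need only training summaries); an override is accepted where a
deployment prevalence is known. Percentile cutoffs for flagged subgroups
are computed once on the full test pool and applied within bootstrap
replicates, so "the most unreliable subgroup" is a stable patient set;
ties at the threshold are included.

## Feature-space variant and mixed features

υ(x) = |P^G(y=1|x) − ŷ| evaluates the class densities at the patient's own
features. For mixed vectors the density factorizes by the
conditional-Gaussian chain rule in schema order; a binary coordinate
contributes the conditional probability that its latent Gaussian falls on
the observed side of 0.5, and subsequent coordinates condition on the
observed 0/1 value itself. This keeps the factorization Gaussian and is an
approximation: conditioning on the value rather than the half-line is
exact only when the binary coordinate is uncorrelated with what follows.
The same construction supplies the "Bayes-consistent" reference model used
in the null-behavior checks, which is therefore *near*-Bayes on mixed
features — a small genuine residual miscalibration that the no-false-alarm
tolerance absorbs.

## Evaluation protocol

Accuracy is the Brier score normalized by the null model that predicts the
subgroup's own event rate (B/B_null, which can exceed 1); discrimination is the
Mann–Whitney AUC; calibration uses fixed equal-width bins (centers
0.05…0.95, or 0.005/0.015/0.025 for very-low-rate models) plus a
Hosmer–Lemeshow test with (O−E)²/(E(1−E/n)) over decile-of-risk groups and
a χ²(g−2) reference. Bootstrap replicates resample positives and negatives
separately (sizes `round(fraction · class size)`); a replicate arm with a
single outcome class records its metrics as missing rather than imputing,
and more than 50% missing is an error. Paired two-sided t-tests compare
arms across replicates; identical vectors give p = 1 by convention, and
fewer than 10 replicates triggers a logged fragility warning. Metric error
bars are standard errors of the mean; calibration error bars are standard
deviations.

One estimator caveat, measured and designed around: on a bootstrap arm of
only ~50 patients the ratio B/B_null is biased upward by roughly +0.02, so
*null* contrasts (is a flagged subgroup actually no worse?) use the
pool-level point estimates, while detection contrasts — whose effect sizes
are an order of magnitude larger — use the protocol's bootstrap means.

## Synthetic registries

The real registries the method targets are access-restricted, so
`cohorts.py` generates seeded stand-ins: labels Bernoulli(π) first
(prevalence is an explicit knob), then class-conditional MVN features with
binary thresholding. The default "grace-like" cohort has 8 continuous + 3
binary features, π = 0.0715, n = 40,000, and class separation chosen once
so the Bayes-optimal AUC sits near 0.81, matching the discrimination level
reported for widely used acute-coronary-syndrome scores; a "stroke-like"
variant has π = 0.00511 for the rare-event regime. Risk models are
developed the way point-score nomograms are: linear per-feature point
tables (diagonal-LDA weights scaled to 0–100 points) with a univariate
logistic total-points-to-probability lookup fitted on training data;
`perturb_model` injects localized miscalibration (clip(m·ŷ) on a score
region). What the generator does **not** emulate: real covariate
skews/heavy tails, missingness, categorical features beyond binary, or
cohort heterogeneity over time — passing tests show the machinery recovers
injected miscalibration under MVN-faithful data, not that any particular
clinical model is reliable.

## Problem sizes in the shipped checks

The acceptance checks run end-to-end audits at batch 1e5 (100 repetitions
each for the detection and null studies, with fresh cohorts, summaries,
PDFs and 100-replicate bootstraps per repetition) and the two 1-D oracle
checks at batch 1e6; the expected-unreliability quadrature uses 1e5
trapezoid nodes (deterministic, so figure-level artifacts carry no seed).
The 1-D closed-form oracle is evaluated per histogram bin via normal CDF
differences — the analytic limit of the histogram estimator — on the
standard calibration-bin centers, where the predictive mixture carries the
cohort's mass; a per-bin dense grid would instead measure single-bin
Monte-Carlo noise at the steepest posterior bin.

## Known limitations

- Only large U is informative; small U does not validate a prediction
  whose features carry little outcome signal.
- The MVN generative family is a modeling choice; the interfaces accept
  any summaries-like object, but no kernel/mixture alternative is
  implemented.
- The trust baseline implements the binary distance-ratio form only, with
  Euclidean distance on normalized features and predicted classes assigned
  by thresholding at the cohort prevalence (a 0.5 threshold under 0.5–7%
  prevalence would predict one class almost always). Note that reports of
  this baseline's orientation differ between sources; here *untrustworthy*
  means the lowest percentile of trust scores.
- Missing features are not imputed; complete cases are assumed.
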