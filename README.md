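# riskaudit

**Generative-model audits of clinical risk models: find the patients whose
predictions should not be trusted.**

Clinical risk scores are validated with population-level metrics — accuracy,
AUC, calibration on a large registry. Those averages can hide patient
subgroups where a model is badly wrong, which matters when the prediction
drives decisions about myocardial infarction, stroke or death. `riskaudit`
implements a model-independent *unreliability score* that flags such
subgroups for any probabilistic classifier, needs only **summary statistics**
of the model's training data (no raw patient records, no retraining), and is
designed for the heavy class imbalance typical of clinical outcomes
(event rates from ~50% down to ~0.5%).

## The method

Let f(x) = ŷ ∈ [0, 1] be the risk model under audit and y ∈ {0, 1} the
outcome with prevalence π = P(y = 1). Fit one multivariate normal per
outcome class to the (normalized) training features — means, covariances and
π are the only artifacts retained. Pushing large Monte-Carlo samples from
each class model through f gives histogram estimates (bin width 0.001,
Kolmogorov–Smirnov-tested for convergence) of the score-conditional
likelihoods, whose ratio is the relative likelihood

    β(ŷ) = P^G(ŷ | y=1) / P^G(ŷ | y=0),

and Bayes' rule turns it into an alternate risk estimate
P^G(y=1 | ŷ) = βπ / (βπ + 1 − π). The unreliability score is the
disagreement between the model and this generative alternate:

    U(x) = | P^G(y=1 | ŷ) − ŷ |,

with a feature-space variant υ(x) = |P^G(y=1|x) − ŷ| available per patient.
U = 0 does not certify a prediction, but large U means the model's own
training data cannot be reconciled with its output. Under class imbalance,
expected unreliability rises with the predicted risk — the high-risk calls
are the ones to doubt.

The evaluation protocol quantifies what "unreliable" costs: subgroups
flagged by the top percentiles of U are compared against their complements
on the normalized Brier score B/B_null (B_null predicts the subgroup event
rate for everyone), the AUC, and fixed-bin calibration curves, with a
stratified 20% bootstrap and paired two-sided t-tests. A nearest-neighbor
*trust score* baseline (distance ratio to the two classes after outlier
filtering) is included for comparison.

## A worked example

Real acute-coronary-syndrome registries are access-restricted, so the
package ships a seeded synthetic registry generator with the same
structure (mixed continuous/binary features, ~7% mortality, a
nomogram-style risk model). `examples/01_audit_miscalibrated_model.py`
corrupts the model by tripling every score above 0.2 and audits it:

```
prevalence 0.0714; PDFs converged: True
median U 0.0024; 99th percentile U 0.5714
                     metric     mean      sem
  normalized_brier_subgroup 3.063534 0.085860
normalized_brier_complement 1.197410 0.003912
               auc_subgroup 0.569476 0.009727
             auc_complement 0.781176 0.001218
paired p-values: normalized Brier 3.35e-39, AUC 8.69e-39
```

The top-1%-unreliability subgroup has a normalized Brier of 3.06 — three
times worse than simply predicting the subgroup's event rate — and its AUC
collapses to 0.57 while the rest of the cohort sits at 0.78: the audit
found exactly the patients the corrupted model misleads. The other
examples show the expected-unreliability curves under imbalance, the
summary-statistics-only workflow, and the trust-score comparison.

A thin CLI wraps the same library calls:

```bash
riskaudit simulate --spec spec.json --out train.csv --label died
riskaudit fit --train train.csv --label died --schema schema.json --out summaries.json
riskaudit score --summaries summaries.json --model model.json --test test.csv \
    --label died --out scored.csv --with-trust --train train.csv
riskaudit evaluate --scored scored.csv --label died --out report.json --percentiles 50,1
riskaudit curve --prevalence 0.01 --out curve.csv
```

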