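# survtopic

Survival-supervised neural topic models for clinical event data.

## The problem

Electronic health records describe each patient as counts of binary
historical events — "white blood count in the bottom quintile",
"ever diagnosed with diabetes" — exactly the bag-of-words shape that
topic models were built for. Clinicians, however, usually want two
things at once: a *prediction* of a time-to-event outcome (death, ICU
discharge) from censored follow-up data, and an *explanation* of how
the many raw features relate. `survtopic` addresses both jointly: a
neural topic model summarizes each subject i as a distribution W_i over
k latent topics (an age group, a disorder, a severity profile), and a
survival model reads W_i — not the raw counts — to predict the outcome.
Because the two parts are trained together by minibatch gradient
descent, the topics are shaped to be prognostic, not merely descriptive.

## The model

With X̄_i the row-normalized event counts, an encoder network produces a
Gaussian approximate posterior over unnormalized topic weights W̃_i
(prior N(0, σ0² I), σ0² = (k−1)/(αk), the logistic-normal stand-in for a
symmetric Dirichlet(α)); W_i = softmax(W̃_i). A decoder maps W_i to a
distribution ζ_i over events — either an LDA mixture ζ = Wᵀ softmax(H)
or a SAGE form ζ = softmax(γ + WᵀH) of log-deviations from background
frequencies. The joint objective is

    L = L_topic + λ_survival · L_survival

where L_topic is reconstruction −Σ_v X̄_{i,v} log ζ_{i,v} plus the KL to
the prior, and L_survival is either the Cox negative log partial
likelihood for scores βᵀW (Breslow baseline for curves; larger β ⇒
shorter survival) or the censored log-logistic AFT likelihood for
locations μ + θᵀW (closed-form curves; larger θ ⇒ longer survival),
optionally with a concordance-oriented ranking penalty. The k-th topic's
coefficient is fixed at 0, making it a *background topic*. The four
combinations lda/sage × cox/aft are all supported, plus the naive
two-stage baseline (unsupervised topics, then Cox) for comparison.

Accuracy is the time-dependent concordance index C_td (fraction of
unambiguously ordered subject pairs whose predicted curves, evaluated at
the earlier event time, rank correctly), with percentile-bootstrap
confidence intervals. Interpretation is a filtered heatmap: topics as
columns sorted from shortest to longest associated survival, events as
rows filtered by prevalence and ranked by maximum topic probability.

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

Generate a synthetic cohort with planted topics and Cox survival
structure (n = 2000, d = 30 events, k = 3 topics, 30% censoring),
split it, train scholar lda-cox, evaluate, and draw the heatmap:

```bash
survtopic simulate --out data --seed 3
survtopic prepare --counts data/counts.mtx --vocab data/vocab.csv \
    --labels data/labels.csv --seed 3 --out splits
printf 'k: 3\nseed: 3\n' > cfg.yaml
survtopic train --config cfg.yaml --data-dir splits --out model
survtopic evaluate --model model --data splits/test --bootstrap 1000 --seed 3
survtopic interpret --model model --data splits/train \
    --min-frac 0 --max-frac 1 --out heatmap.png --table topics.csv
```

The evaluate step prints

```json
{
  "ctd": 0.582914204795156,
  "ci_lower": 0.5464475415022395,
  "ci_upper": 0.6193504850274146,
  "n_replicates_skipped": 0
}
```

a held-out C_td of 0.583 (95% bootstrap CI 0.546–0.619): the model
orders about 58% of comparable test pairs correctly, comfortably above
the 0.5 of random ordering and in line with what a linear topic-level
hazard can extract from this generator (topic weights are Dirichlet(1)
draws, so individual risks overlap heavily). The interpret step reports

```
30 features x 3 topics; coefficients [2.239, 0.0, -2.092]
```

three topic columns sorted by Cox coefficient — a high-risk topic
(β = 2.24), the background topic (β = 0), and a protective topic
(β = −2.09), matching the planted β* = (1, −1, 0) ordering up to the
scale freedom of topic-weight shrinkage. `topics.csv` lists each
topic's event probabilities; on this synthetic corpus every event is
common, so the example relaxes the prevalence filter that on real data
defaults to [2%, 50%].

The same pipeline is available as library calls
(`survtopic.simulate.generate`, `survtopic.training.train`,
`survtopic.evaluation.ctd_index`, `survtopic.interpretation.build_heatmap`).

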