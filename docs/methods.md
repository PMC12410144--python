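# Methods

## The model

`survtopic` fits joint survival–topic models to bag-of-events clinical
data. Each subject i is a "document": a count vector X_i over d binary
historical clinical events (continuous measurements are discretized into
empirical-quantile bins, so an event is e.g. "white blood count in the
bottom quintile"), together with a right-censored label (Y_i, δ_i) where
Y_i is the survival time if δ_i = 1 and the censoring time otherwise.

The generative story, for k topics:

1. unnormalized topic weights W̃_i ~ N(0, σ0² I) with
   σ0² = (k−1)/(αk), the logistic-normal approximation of a symmetric
   Dirichlet(α);
2. topic weights W_i = softmax(W̃_i);
3. events drawn from the word distribution ζ_i = f_word(W_i), where
   - **lda** decoder: ζ = Wᵀ A with topic rows A_g = softmax(H_g);
   - **sage** decoder: ζ = softmax(γ + Wᵀ H), topics as log-deviations
     from a shared background log-frequency vector γ (H_{g,v} = 3 means
     the event occurs e³ times its background frequency);
4. the outcome depends on W_i through a linear survival head whose
   k-th coefficient is fixed at 0, so the last topic is a *background
   topic* free to absorb survival-irrelevant structure:
   - **cox**: hazard h(t|W) = h0(t) exp(βᵀW); larger β ⇒ shorter
     survival; subject curves are powers of a Breslow-estimated
     baseline, Ŝ(t|W) = Ŝ0(t)^{exp(βᵀW)};
   - **aft** (log-logistic): log T = μ + θᵀW + σ ε with standard
     logistic ε, giving the closed form
     S(t|W) = 1/(1 + t^{1/σ} e^{−(μ+θᵀW)/σ}); larger θ ⇒ *longer*
     survival (note the sign convention is opposite to Cox).

Inference is amortized: an encoder MLP (one softplus hidden layer,
default width 100, batch-normalized embedding) maps the row-normalized
counts X̄_i to the mean and log-variance of a diagonal Gaussian
approximate posterior over W̃_i. Training minimizes, by minibatch
gradient descent with reparameterized sampling,

    L = L_topic + λ_survival · L_survival

where L_topic is the per-subject mean of the reconstruction term
−Σ_v X̄_{i,v} log ζ_{i,v} plus the closed-form Gaussian KL to the prior
(row normalization weights every subject equally regardless of how many
events they accumulated), and L_survival is the Cox negative log partial
likelihood (risk sets within the minibatch, ties by the plain
Y_j ≥ Y_i rule) or the censored log-logistic NLL, optionally plus
λ_ranking times a pairwise ranking surrogate whose negation lower-bounds
concordance. The SAGE decoder adds λ_small-deviation · ‖H‖²; no ℓ1
penalty is used anywhere, since sparsity tends to pick one of several
correlated clinical features and destroy exactly the co-occurrence
structure the topics are meant to expose.

All gradients flow through a small in-package reverse-mode autodiff
core (`survtopic.autodiff`) operating on float64 NumPy arrays; every
primitive and every composed loss is validated against central finite
differences (relative error < 1e−4) in the test suite.

## Numerical and design choices

- **KL term.** The standard diagonal-Gaussian KL is used:
  ½ Σ_g [(σ_g² + μ_g²)/σ0² − 1 + log(σ0²/σ_g²)], which is zero exactly
  at the prior. It is cross-checked against a 10⁶-sample Monte-Carlo
  estimate.
- **ζ floor.** Word probabilities are floored at 1e−10 before logs; the
  floor's gradient is masked.
- **Per-step topic-weight estimate.** Each training step feeds the
  decoder and the survival head the average of `n_train_samples`
  (default 10) reparameterized simplex samples rather than a single
  draw. With row-normalized reconstruction the per-subject information
  gain of an informative posterior is small (≈0.14 nats on the synthetic
  family) and single-sample gradients are noisy enough that training
  reliably collapses to the prior mode; averaging a few samples — the
  same estimator used for Ŵ at evaluation time, where the default is
  100 samples — removes the collapse without changing the objective's
  fixed points materially. This is the one deliberate departure from a
  pure single-sample ELBO estimator.
- **Optimizer.** Adam with β1 = 0.99 ("high momentum"), lr 1e−2
  decaying linearly to 10% over the run, batch size 256, 200 epochs by
  default. Batch normalization is applied to the encoder embedding;
  the decoders follow their exact functional forms above (so LDA's
  ζ = Wᵀ softmax-rows(H) stays a true mixture).
- **Restarts.** Amortized topic models occasionally land in a collapsed
  mode from an unlucky initialization (~1 in 10 runs on the synthetic
  family). `train` runs `n_restarts` (default 2) independent
  initializations and keeps the one with the best validation
  concordance — the same validation-C_td selection used for
  hyperparameters. Fixed seed ⇒ identical trajectory and selection.
- **Cox risk sets in minibatches.** The partial likelihood is computed
  within each minibatch during training (required for stochastic
  optimization); reported losses and the Breslow baseline use the full
  training set in evaluation mode.
- **AFT scale.** σ is parameterized as exp(logσ) with logσ initialized
  from N(0, 1e−4)-scale noise. Ranking-loss locations are θᵀW (μ
  cancels in pairwise differences).
- **Degenerate inputs.** Zero-count rows are rejected at corpus
  construction (the normalized reconstruction is undefined); all-censored
  data yield a warning and a zero Cox loss / unit baseline survival; a
  C_td request with no comparable pair raises; degenerate bootstrap
  replicates are skipped and counted.
- **Quantile bins.** Bin edges are empirical quantiles with duplicate
  edges merged (heavily tied values can reduce the effective bin
  count); missing values contribute zero counts rather than a "missing"
  event word.
- **Ties.** Survival-time ties are allowed everywhere: the Cox risk set
  includes all Y_j ≥ Y_i (Breslow-style); C_td treats (Y_i = Y_j,
  δ_i = 1, δ_j = 0) as comparable and credits exactly tied predicted
  curves 0.5.
- **Bootstrap percentiles** are nearest-rank order statistics
  (1-based rank ⌈p/100 · m⌉), so intervals are deterministic across
  platforms given the seed.

## Evaluation

Accuracy is the time-dependent concordance index C_td: among pairs
where subject i died at Y_i and subject j is known to have survived past
Y_i, a pair is concordant when Ŝ(Y_i|x_i) < Ŝ(Y_i|x_j), with ties worth
0.5. For proportional-hazards predictions this reduces to Harrell's
concordance of the risk scores, which is verified against an independent
implementation. 95% confidence intervals resample subjects with
replacement (default B = 1000); model comparisons use paired differences
of C_td on identical resamples.

## The synthetic-data generator

The generator plants exactly the structure the model assumes:
W_i ~ Dirichlet(α·1_k); counts ~ Multinomial(v_i, W_iᵀA*) with document
lengths v_i ~ U[10, 200] (emulating, at desk scale, the large
heterogeneity in events per subject seen in clinical corpora); survival
times from an exponential-baseline Cox model (default h0 = 0.1,
β* = (1, −1, 0) — the background topic carries no risk) or a
log-logistic AFT model; independent exponential censoring with the rate
calibrated by root-finding on a 20 000-subject pilot sample to hit the
target censoring fraction (default 0.3). The default planted topics
put 85% of their mass on disjoint blocks of d/k words.

The standard study conditions are n = 2000 subjects, d = 30 events,
k = 3 topics, 30% censoring, with an 80/20 train/test split and 20% of
the training data held out for validation. Recovery is scored as the
permutation-minimal mean total-variation distance between estimated and
planted topic rows, plus Kendall's τ between matched and planted
survival coefficients (background excluded).

**What the generator does not emulate:** real EHR missingness
mechanisms, time-varying covariates, competing risks, informative
censoring, or the correlated bin structure of discretized continuous
variables. Passing recovery tests therefore show that the estimator is
consistent with its own generative assumptions at realistic sizes — not
that learned topics on real clinical data are clinically valid, which
requires expert review of the heatmaps.

## Interpretation

Topic summaries are built *after* training (filtering features before
topic modeling has no demonstrated advantage and entangles preprocessing
with the model): events are kept when their prevalence (fraction of
subjects with at least one occurrence) lies in [2%, 50%] by default,
ranked by maximum probability across topics, grouped so all bins of one
variable sit adjacent to the variable's best bin, and optionally
truncated to ~`max_features` rows counted after grouping (whole variable
blocks are kept, so the count can slightly exceed the budget). Topic
columns are sorted so the leftmost column is associated with the
shortest survival (descending β for Cox, ascending θ for AFT). SAGE
topics are displayed as their induced single-topic distributions
softmax(γ + H_g) so heatmap cells remain probabilities; raw
log-deviations are exported alongside.

## Known limitations

- The unsupervised model (λ_survival = 0, the first stage of the naive
  baseline) genuinely prefers the collapsed posterior under the
  row-normalized objective; its topics are close to the corpus mean and
  its downstream Cox fit is weak. This mirrors the intended contrast
  with joint supervision rather than being a defect of the baseline
  implementation.
- Training cost is O(epochs · n · (d·hidden + k·d)) on one CPU core;
  the float64 NumPy implementation favors exactness and testability
  over speed and is sized for corpora up to tens of thousands of
  subjects, not millions.
- Hyperparameter defaults (λ_survival = 10, epochs, learning rate) were
  chosen on the synthetic family; real datasets should select them on
  validation concordance via `select_hyperparameters`.
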