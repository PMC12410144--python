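"""Joint training of topic and survival models.

The four supervised models — lda-cox, lda-aft, sage-cox, sage-aft —
all minimize the same composite objective

    L = L_topic + lambda_survival * L_survival,

by minibatch gradient descent: per step, one reparameterized sample of
each subject's topic weights feeds both the decoder (reconstruction)
and the survival head (stochastic supervision).  The Cox risk sets and
ranking-loss pairs are formed within each minibatch.  At evaluation
time topic weights are the Monte-Carlo posterior mean over multiple
samples, and for Cox models a Breslow baseline is fitted once on the
full training set.

Also provided: the naive two-stage baseline (unsupervised topic model,
then a Cox fit on the frozen topic weights) and validation-concordance
hyperparameter selection.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from . import autodiff as ad
from .autodiff import Tensor
from .corpus import CountsCorpus
from .evaluation import PredictionSet, UndefinedMetricError, ctd_index
from .scholar import ScholarModel, _topic_loss_t, estimate_topic_weights
from .survival import (
    AFTHead,
    BaselineSurvival,
    CoxHead,
    _aft_nll_t,
    _cox_loss_t,
    _ranking_loss_t,
    breslow_baseline,
    cox_survival_curve,
    linear_score,
    loglogistic_survival_curve,
)

__all__ = [
    "TrainingConfig",
    "TrainingFailure",
    "Adam",
    "joint_loss",
    "train",
    "extract_head",
    "fit_breslow",
    "predict",
    "fit_two_stage_naive",
    "select_hyperparameters",
]


class TrainingFailure(RuntimeError):
    """Raised when the loss diverges (NaN/inf) during training."""


@dataclasses.dataclass
class TrainingConfig:
    """Hyperparameters of one joint model.

    ``lambda_survival`` > 0 gives a supervised model; 0 trains the
    topic model alone (the unsupervised stage of the naive baseline).
    """

    k: int = 5
    alpha: float = 1.0
    decoder: str = "lda"  # "lda" | "sage"
    survival: str = "cox"  # "cox" | "aft"
    lambda_survival: float = 10.0
    lambda_ranking: float = 0.0  # AFT only
    lambda_small_deviation: float = 0.0  # SAGE only
    learning_rate: float = 1e-2
    momentum: float = 0.99  # first-moment decay of the adaptive optimizer
    batch_size: int = 256
    epochs: int = 200
    seed: int = 0
    hidden_dim: int = 100
    n_train_samples: int = 10  # reparameterized draws averaged per step
    n_weight_samples: int = 100  # posterior-mean samples at evaluation
    kl_warmup_epochs: int = 0  # linear ramp of the KL weight from 0 to 1
    lr_decay: float = 0.9  # fraction of the learning rate annealed away linearly
    n_restarts: int = 2  # independent initializations, best val-Ctd kept
    val_every: int = 1  # epochs between validation-concordance checks

    def __post_init__(self) -> None:
        if self.lambda_survival < 0 or self.lambda_ranking < 0 or self.lambda_small_deviation < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.decoder not in ("lda", "sage") or self.survival not in ("cox", "aft"):
            raise ValueError("decoder must be lda/sage and survival cox/aft")
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("need epochs >= 1 and batch_size >= 2")


class Adam:
    """Adam with a high first-moment decay (the ``momentum`` setting).

    High momentum together with batch normalization is what keeps the
    encoder from collapsing all topics onto one mode.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 2e-3,
                 beta1: float = 0.99, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def joint_loss(topic_term, survival_term, lambda_survival: float):
    """Composite objective: topic_term + lambda_survival * survival_term."""
    return topic_term + lambda_survival * survival_term


# ---------------------------------------------------------------------------
# forward pass pieces


def _survival_loss_t(
    model: ScholarModel, W: Tensor, Y: np.ndarray, delta: np.ndarray, config: TrainingConfig
) -> Tensor:
    """Minibatch survival loss from a (batch, k) topic-weight sample."""
    k = model.k
    W_free = W[:, np.arange(k - 1)]  # background topic carries no coefficient
    if config.survival == "cox":
        scores = W_free @ model.params["surv.beta"]
        return _cox_loss_t(scores, Y, delta)
    theta_scores = W_free @ model.params["surv.theta"]
    locations = theta_scores + model.params["surv.mu"]
    loss = _aft_nll_t(locations, model.params["surv.log_sigma"], Y, delta)
    if config.lambda_ranking > 0:
        loss = loss + config.lambda_ranking * _ranking_loss_t(theta_scores, Y, delta)
    return loss


def _step_loss_t(
    model: ScholarModel,
    xbar: np.ndarray,
    Y: np.ndarray,
    delta: np.ndarray,
    noise: np.ndarray,
    config: TrainingConfig,
    train: bool = True,
    kl_weight: float = 1.0,
) -> Tensor:
    mu, log_sigma_sq = model.encode_t(Tensor(xbar), train=train)
    sigma = ad.exp(0.5 * log_sigma_sq)
    # per-step topic-weight estimate: average of a few reparameterized
    # simplex samples (noise has shape (n_samples, batch, k)); averaging
    # tames the sampling noise that otherwise washes out the topics
    noise = np.asarray(noise, dtype=np.float64)
    if noise.ndim == 2:
        noise = noise[None]
    W = ad.softmax(mu + sigma * noise[0], axis=-1)
    for s in range(1, noise.shape[0]):
        W = W + ad.softmax(mu + sigma * noise[s], axis=-1)
    W = W * (1.0 / noise.shape[0])
    zeta = model.decode_t(W)
    lam_dev = config.lambda_small_deviation if model.decoder_kind == "sage" else 0.0
    loss = _topic_loss_t(
        Tensor(xbar), zeta, mu, log_sigma_sq, model.prior,
        H=model.params["dec.H"] if lam_dev > 0 else None,
        lambda_small_deviation=lam_dev,
        kl_weight=kl_weight,
    )
    if config.lambda_survival > 0:
        loss = joint_loss(loss, _survival_loss_t(model, W, Y, delta, config),
                          config.lambda_survival)
    return loss


# ---------------------------------------------------------------------------
# evaluation-mode prediction


def extract_head(model: ScholarModel) -> CoxHead | AFTHead:
    """Read the fitted survival head (background coefficient fixed at 0)."""
    if model.survival_kind == "cox":
        free = model.params["surv.beta"].value if model.k > 1 else np.zeros(0)
        return CoxHead.from_free(free)
    if model.survival_kind == "aft":
        free = model.params["surv.theta"].value if model.k > 1 else np.zeros(0)
        return AFTHead.from_free(
            free,
            float(model.params["surv.mu"].value),
            float(model.params["surv.log_sigma"].value),
        )
    raise ValueError("model has no survival head")


def fit_breslow(
    model: ScholarModel, corpus: CountsCorpus, n_samples: int = 100, seed: int = 0
) -> BaselineSurvival:
    """Breslow baseline from evaluation-mode topic weights on a corpus."""
    W = model.topic_weights(corpus.normalized(), n_samples=n_samples, seed=seed)
    scores = linear_score(W, extract_head(model))
    return breslow_baseline(scores, corpus.times, corpus.events)


def predict(
    model: ScholarModel,
    corpus: CountsCorpus,
    baseline: BaselineSurvival | None = None,
    n_samples: int = 100,
    seed: int = 0,
) -> PredictionSet:
    """Subject-specific survival curves for every subject in ``corpus``.

    Cox models require the Breslow ``baseline`` fitted on training
    data; AFT curves are closed-form.
    """
    W = model.topic_weights(corpus.normalized(), n_samples=n_samples, seed=seed)
    head = extract_head(model)
    scores = np.atleast_1d(linear_score(W, head))
    if model.survival_kind == "cox":
        if baseline is None:
            raise ValueError("Cox prediction requires a fitted Breslow baseline")
        curves = [cox_survival_curve(s, baseline) for s in scores]
    else:
        curves = [loglogistic_survival_curve(loc, head.sigma) for loc in scores]
    return PredictionSet(curves, corpus.times, corpus.events)


def _validation_ctd(
    model: ScholarModel,
    corpus_train: CountsCorpus,
    corpus_val: CountsCorpus,
    config: TrainingConfig,
    n_samples: int,
    seed: int,
) -> float:
    baseline = None
    if model.survival_kind == "cox":
        baseline = fit_breslow(model, corpus_train, n_samples=n_samples, seed=seed)
    preds = predict(model, corpus_val, baseline=baseline, n_samples=n_samples, seed=seed)
    try:
        return ctd_index(preds)
    except UndefinedMetricError:
        return float("nan")


# ---------------------------------------------------------------------------
# training loops


def train(
    corpus_train: CountsCorpus,
    corpus_val: CountsCorpus | None,
    config: TrainingConfig,
) -> tuple[ScholarModel, pd.DataFrame]:
    """Fit a joint survival-topic model by minibatch gradient descent.

    Randomness (initialization, batch order, reparameterization noise)
    derives from ``config.seed``; a fixed seed reproduces the parameter
    trajectory exactly.  When a validation corpus is supplied, the
    checkpoint with the best validation concordance is restored at the
    end; otherwise the final parameters are kept.

    Returns the fitted model and a per-epoch log with columns
    (epoch, train_loss, val_ctd).

    With ``n_restarts`` > 1 and a validation corpus, several
    independently initialized runs are trained and the one with the
    best validation concordance is returned — amortized topic models
    occasionally fall into a collapsed mode, which validation
    concordance detects reliably.
    """
    if corpus_train.n_subjects == 0:
        raise ValueError("training corpus is empty")
    restarts = max(1, config.n_restarts) if corpus_val is not None else 1
    if restarts > 1:
        best = None
        for r in range(restarts):
            sub = dataclasses.replace(
                config, seed=config.seed + 7919 * r, n_restarts=1
            )
            model, log = train(corpus_train, corpus_val, sub)
            score = log["val_ctd"].dropna().max() if config.lambda_survival > 0 else np.nan
            if not np.isfinite(score):
                score = -np.inf
            if best is None or score > best[0]:
                best = (score, model, log)
        return best[1], best[2]
    model = ScholarModel(
        n_events=corpus_train.n_events,
        k=config.k,
        alpha=config.alpha,
        decoder=config.decoder,
        survival=config.survival,
        hidden_dim=config.hidden_dim,
        seed=config.seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = Adam(model.params, lr=config.learning_rate, beta1=config.momentum)
    xbar = corpus_train.normalized()
    Y, delta = corpus_train.times, corpus_train.events
    n = corpus_train.n_subjects
    supervised = config.lambda_survival > 0

    log_rows = []
    best_ctd, best_state = -np.inf, None
    for epoch in range(1, config.epochs + 1):
        # KL warm-up: ramp the divergence term in over the first epochs so
        # the encoder learns an informative posterior before paying for it
        kl_weight = (
            min(1.0, epoch / config.kl_warmup_epochs) if config.kl_warmup_epochs else 1.0
        )
        # linear learning-rate decay stabilizes the final parameters
        opt.lr = config.learning_rate * (1.0 - config.lr_decay * (epoch - 1) / config.epochs)
        perm = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            if idx.size < 2:  # batch norm needs at least two subjects
                continue
            noise = rng.standard_normal((config.n_train_samples, idx.size, config.k))
            loss = _step_loss_t(model, xbar[idx], Y[idx], delta[idx], noise, config,
                                kl_weight=kl_weight)
            if not np.isfinite(loss.value):
                raise TrainingFailure(f"loss diverged at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        val_ctd = np.nan
        if corpus_val is not None and supervised and (
            epoch % config.val_every == 0 or epoch == config.epochs
        ):
            val_ctd = _validation_ctd(
                model, corpus_train, corpus_val, config,
                n_samples=min(20, config.n_weight_samples), seed=config.seed,
            )
            if np.isfinite(val_ctd) and val_ctd > best_ctd:
                best_ctd, best_state = val_ctd, model.state_dict()
        log_rows.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_ctd": val_ctd}
        )
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(log_rows)


def fit_two_stage_naive(
    corpus_train: CountsCorpus,
    config: TrainingConfig,
    corpus_val: CountsCorpus | None = None,
) -> tuple[ScholarModel, pd.DataFrame]:
    """Naive decoupled baseline: unsupervised topic model, then Cox.

    Stage 1 trains the topic model with no survival term (identical to
    a supervised run with lambda_survival = 0 and the same seed).
    Stage 2 freezes all topic parameters, computes evaluation-mode
    topic weights for the training subjects, and fits the Cox
    coefficients (background fixed at 0) on those fixed weights by
    quasi-Newton minimization of the partial-likelihood loss.
    """
    if config.survival != "cox":
        raise ValueError("the naive two-stage baseline is defined for Cox supervision")
    stage1 = dataclasses.replace(config, lambda_survival=0.0)
    model, log = train(corpus_train, None, stage1)

    W = model.topic_weights(
        corpus_train.normalized(), n_samples=config.n_weight_samples, seed=config.seed
    )
    W_free = W[:, : config.k - 1]
    Y, delta = corpus_train.times, corpus_train.events

    def value_and_grad(beta_free: np.ndarray):
        b = Tensor(beta_free, requires_grad=True)
        loss = _cox_loss_t(Tensor(W_free) @ b, Y, delta)
        loss.backward()
        return loss.item(), b.grad

    res = optimize.minimize(
        value_and_grad, np.zeros(config.k - 1), jac=True, method="L-BFGS-B"
    )
    model.params["surv.beta"].value = res.x
    return model, log


def select_hyperparameters(
    grid: list[TrainingConfig],
    corpus_train: CountsCorpus,
    corpus_val: CountsCorpus,
) -> tuple[TrainingConfig, list[float]]:
    """Pick the config with the best validation concordance.

    Each candidate is trained on the training corpus and scored on the
    validation corpus; exact ties keep the earlier grid entry.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    scores: list[float] = []
    for config in grid:
        model, _ = train(corpus_train, corpus_val, config)
        scores.append(
            _validation_ctd(
                model, corpus_train, corpus_val, config,
                n_samples=config.n_weight_samples, seed=config.seed,
            )
        )
    best = int(np.nanargmax(scores))
    return grid[best], scores
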