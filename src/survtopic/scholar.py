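"""Amortized-variational neural topic model (the "scholar" family).

The generative story for subject i with k topics:

1. draw unnormalized topic weights  W̃_i ~ N(mu0, diag sigma0²),
   a logistic-normal approximation of a symmetric Dirichlet(alpha);
2. set topic weights  W_i = softmax(W̃_i);
3. draw each of the subject's v_i events from the word distribution
   zeta_i = f_word(W_i).

Two decoders are supported:

* ``lda``:  zeta = W @ A with topic-word rows A_g = softmax(H_g);
* ``sage``: zeta = softmax(gamma + W @ H), topics as log-deviations H_g
  from a shared background log-frequency vector gamma.

Inference is amortized: an encoder MLP maps a subject's normalized
counts to the mean and log-variance of a diagonal-Gaussian approximate
posterior over W̃_i, trained by reparameterized sampling against the
evidence lower bound (reconstruction + KL to the prior).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "PriorConstants",
    "PosteriorStats",
    "ScholarModel",
    "encode",
    "sample_topic_weights",
    "estimate_topic_weights",
    "word_distribution",
    "kl_to_prior",
    "topic_loss",
]

ZETA_FLOOR = 1e-10  # floor on word probabilities before taking logs
BN_EPS = 1e-5
BN_MOMENTUM = 0.99  # running-statistic decay for batch norm


@dataclasses.dataclass(frozen=True)
class PriorConstants:
    """Logistic-normal prior matching a symmetric Dirichlet(alpha).

    The prior on unnormalized topic weights is N(0, sigma0² I) with
    sigma0² = (k - 1) / (alpha k), the Laplace-approximation variance of
    the softmax-basis Dirichlet.
    """

    k: int
    alpha: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def mu0(self) -> np.ndarray:
        return np.zeros(self.k)

    @property
    def sigma0_sq(self) -> np.ndarray:
        if self.k == 1:
            # degenerate single-topic prior; variance is irrelevant but must be > 0
            return np.ones(1)
        return np.full(self.k, (self.k - 1) / (self.alpha * self.k))


@dataclasses.dataclass
class PosteriorStats:
    """Per-subject approximate posterior N(mu, diag exp(log_sigma_sq))."""

    mu: np.ndarray
    log_sigma_sq: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.log_sigma_sq = np.asarray(self.log_sigma_sq, dtype=np.float64)
        if self.mu.shape != self.log_sigma_sq.shape:
            raise ValueError("mu and log_sigma_sq must have the same shape")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.log_sigma_sq).all()):
            raise ValueError("posterior statistics must be finite")

    @property
    def sigma_sq(self) -> np.ndarray:
        return np.exp(self.log_sigma_sq)


# ---------------------------------------------------------------------------
# the model container


class ScholarModel:
    """Encoder + decoder (+ survival head parameters) as named tensors.

    Parameters are float64 :class:`~survtopic.autodiff.Tensor` leaves;
    batch-norm running statistics are plain arrays updated in training
    mode and frozen in evaluation mode.
    """

    def __init__(
        self,
        n_events: int,
        k: int,
        alpha: float = 1.0,
        decoder: str = "lda",
        survival: str = "cox",
        hidden_dim: int = 100,
        seed: int = 0,
    ):
        if decoder not in ("lda", "sage"):
            raise ValueError(f"unknown decoder {decoder!r}")
        if survival not in ("cox", "aft", "none"):
            raise ValueError(f"unknown survival head {survival!r}")
        self.d = n_events
        self.prior = PriorConstants(k, alpha)
        self.decoder_kind = decoder
        self.survival_kind = survival
        self.hidden_dim = hidden_dim
        self.seed = seed
        rng = np.random.default_rng(seed)

        def glorot(shape):
            scale = np.sqrt(2.0 / sum(shape))
            return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)

        d, h = n_events, hidden_dim
        self.params: dict[str, Tensor] = {
            "enc.W1": glorot((d, h)),
            "enc.b1": Tensor(np.zeros(h), requires_grad=True),
            "enc.bn_gamma": Tensor(np.ones(h), requires_grad=True),
            "enc.bn_beta": Tensor(np.zeros(h), requires_grad=True),
            "enc.Wmu": glorot((h, k)),
            "enc.bmu": Tensor(np.zeros(k), requires_grad=True),
            "enc.Wsig": glorot((h, k)),
            "enc.bsig": Tensor(np.zeros(k), requires_grad=True),
            "dec.H": glorot((k, d)),
        }
        if decoder == "sage":
            self.params["dec.gamma"] = Tensor(np.zeros(d), requires_grad=True)
        if survival == "cox" and k > 1:
            self.params["surv.beta"] = Tensor(np.zeros(k - 1), requires_grad=True)
        elif survival == "aft":
            if k > 1:
                self.params["surv.theta"] = Tensor(np.zeros(k - 1), requires_grad=True)
            self.params["surv.mu"] = Tensor(np.zeros(()), requires_grad=True)
            self.params["surv.log_sigma"] = Tensor(
                rng.normal(0.0, 1e-2, ()), requires_grad=True
            )
        # batch-norm running statistics (not trained by gradient)
        self.bn_mean = np.zeros(h)
        self.bn_var = np.ones(h)

    # -- plumbing ------------------------------------------------------
    @property
    def k(self) -> int:
        return self.prior.k

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.value.copy() for name, p in self.params.items()}
        out["bn_mean"] = self.bn_mean.copy()
        out["bn_var"] = self.bn_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.params.items():
            p.value = np.array(state[name], dtype=np.float64)
        self.bn_mean = np.array(state["bn_mean"], dtype=np.float64)
        self.bn_var = np.array(state["bn_var"], dtype=np.float64)

    def save(self, model_dir: str | Path) -> None:
        """Checkpoint: JSON manifest + npz array archive."""
        out = Path(model_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_events": self.d,
            "k": self.k,
            "alpha": self.prior.alpha,
            "decoder": self.decoder_kind,
            "survival": self.survival_kind,
            "hidden_dim": self.hidden_dim,
            "seed": self.seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(out / "params.npz", **self.state_dict())

    @classmethod
    def load(cls, model_dir: str | Path) -> "ScholarModel":
        d = Path(model_dir)
        manifest = json.loads((d / "manifest.json").read_text())
        model = cls(
            n_events=manifest["n_events"],
            k=manifest["k"],
            alpha=manifest["alpha"],
            decoder=manifest["decoder"],
            survival=manifest["survival"],
            hidden_dim=manifest["hidden_dim"],
            seed=manifest["seed"],
        )
        with np.load(d / "params.npz") as state:
            model.load_state_dict(dict(state))
        return model

    # -- forward pieces (Tensor in, Tensor out) ------------------------
    def _batch_norm(self, x: Tensor, train: bool) -> Tensor:
        if train and x.shape[0] > 1:
            mean = x.mean(axis=0, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=0, keepdims=True)
            self.bn_mean = BN_MOMENTUM * self.bn_mean + (1 - BN_MOMENTUM) * mean.value[0]
            self.bn_var = BN_MOMENTUM * self.bn_var + (1 - BN_MOMENTUM) * var.value[0]
            xhat = (x - mean) / ad.sqrt(var + BN_EPS)
        else:
            xhat = (x - self.bn_mean) / np.sqrt(self.bn_var + BN_EPS)
        return xhat * self.params["enc.bn_gamma"] + self.params["enc.bn_beta"]

    def encode_t(self, xbar: Tensor, train: bool = False) -> tuple[Tensor, Tensor]:
        """Map normalized counts (batch, d) to posterior (mu, log sigma²)."""
        if xbar.shape[-1] != self.d:
            raise ValueError(f"expected {self.d} event columns, got {xbar.shape[-1]}")
        pi = ad.softplus(xbar @ self.params["enc.W1"] + self.params["enc.b1"])
        pi = self._batch_norm(pi, train=train)
        mu = pi @ self.params["enc.Wmu"] + self.params["enc.bmu"]
        log_sigma_sq = pi @ self.params["enc.Wsig"] + self.params["enc.bsig"]
        return mu, log_sigma_sq

    def decode_t(self, W: Tensor) -> Tensor:
        """Per-subject word distributions zeta from topic weights."""
        if self.decoder_kind == "lda":
            A = ad.softmax(self.params["dec.H"], axis=-1)
            return W @ A
        return ad.softmax(self.params["dec.gamma"] + W @ self.params["dec.H"], axis=-1)

    def topic_word_matrix(self) -> np.ndarray:
        """Rows are per-topic distributions over events.

        For the SAGE decoder these are the induced single-topic
        distributions softmax(gamma + H_g).
        """
        H = self.params["dec.H"].value
        if self.decoder_kind == "lda":
            return ad.softmax(Tensor(H), axis=-1).value
        return ad.softmax(Tensor(self.params["dec.gamma"].value + H), axis=-1).value

    # -- numpy-facing inference helpers --------------------------------
    def encode(self, xbar: np.ndarray, train: bool = False) -> PosteriorStats:
        mu, lss = self.encode_t(Tensor(np.atleast_2d(xbar)), train=train)
        if np.asarray(xbar).ndim == 1:
            return PosteriorStats(mu.value[0], lss.value[0])
        return PosteriorStats(mu.value, lss.value)

    def topic_weights(
        self, xbar: np.ndarray, n_samples: int = 100, seed: int = 0
    ) -> np.ndarray:
        """Evaluation-mode posterior-mean topic weights Ŵ."""
        post = self.encode(np.atleast_2d(xbar), train=False)
        W = estimate_topic_weights(post, n_samples=n_samples, seed=seed)
        return W[0] if np.asarray(xbar).ndim == 1 else W


# ---------------------------------------------------------------------------
# functional operations (accept plain arrays; used by training via Tensors)


def encode(xbar: np.ndarray, model: ScholarModel) -> PosteriorStats:
    """Evaluation-mode encoding of normalized counts."""
    return model.encode(xbar, train=False)


def sample_topic_weights(post: PosteriorStats, noise: np.ndarray) -> np.ndarray:
    """One reparameterized draw mapped to the simplex.

    ``softmax(mu + sigma * noise)`` with externally supplied standard
    normal ``noise`` so that all randomness is seeded by the caller.
    """
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != post.mu.shape:
        raise ValueError("noise must match the posterior shape")
    wt = post.mu + np.sqrt(post.sigma_sq) * noise
    return ad.softmax(Tensor(wt), axis=-1).value


def estimate_topic_weights(
    post: PosteriorStats, n_samples: int = 100, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo posterior mean of softmax(W̃), W̃ ~ q."""
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    mu = np.atleast_2d(post.mu)
    sig = np.sqrt(np.atleast_2d(post.sigma_sq))
    acc = np.zeros_like(mu)
    for _ in range(n_samples):
        noise = rng.standard_normal(mu.shape)
        acc += ad.softmax(Tensor(mu + sig * noise), axis=-1).value
    out = acc / n_samples
    return out[0] if post.mu.ndim == 1 else out


def word_distribution(W: np.ndarray, model: ScholarModel) -> np.ndarray:
    """Word distribution zeta for topic weights W (single vector or batch)."""
    W = np.asarray(W, dtype=np.float64)
    out = model.decode_t(Tensor(np.atleast_2d(W))).value
    return out[0] if W.ndim == 1 else out


def _kl_terms_t(mu: Tensor, log_sigma_sq: Tensor, prior: PriorConstants) -> Tensor:
    """Per-subject KL( N(mu, diag sigma²) || N(0, sigma0² I) ), shape (batch,)."""
    sigma_sq = ad.exp(log_sigma_sq)
    s0 = prior.sigma0_sq  # (k,)
    per_coord = 0.5 * ((sigma_sq + mu**2) / s0 - 1.0 + np.log(s0) - log_sigma_sq)
    return per_coord.sum(axis=-1)


def kl_to_prior(post: PosteriorStats, prior: PriorConstants) -> float:
    """Closed-form Gaussian KL of the posterior to the topic prior.

    Zero exactly when mu = 0 and sigma² = sigma0².
    """
    if np.any(post.sigma_sq <= 0):
        raise ValueError("posterior variances must be strictly positive")
    mu = Tensor(np.atleast_2d(post.mu))
    lss = Tensor(np.atleast_2d(post.log_sigma_sq))
    out = _kl_terms_t(mu, lss, prior).value
    return float(out[0]) if post.mu.ndim == 1 else out


def _topic_loss_t(
    xbar: Tensor,
    zeta: Tensor,
    mu: Tensor,
    log_sigma_sq: Tensor,
    prior: PriorConstants,
    H: Tensor | None = None,
    lambda_small_deviation: float = 0.0,
    kl_weight: float = 1.0,
) -> Tensor:
    # kl_weight < 1 is only used transiently for warm-up annealing during
    # early training; the reported loss always uses weight 1
    recon = -(xbar * ad.log(zeta.clip_min(ZETA_FLOOR))).sum(axis=-1)
    kl = _kl_terms_t(mu, log_sigma_sq, prior)
    loss = (recon + kl_weight * kl).mean()
    if lambda_small_deviation > 0:
        if H is None:
            raise ValueError("H is required for the small-deviation penalty")
        loss = loss + lambda_small_deviation * (H**2).sum()
    return loss


def topic_loss(
    xbar_batch: np.ndarray,
    zeta_batch: np.ndarray,
    posts: PosteriorStats,
    prior: PriorConstants,
    H: np.ndarray | None = None,
    lambda_small_deviation: float = 0.0,
) -> float:
    """Batch-mean ELBO loss: reconstruction + KL (+ SAGE H² penalty).

    ``lambda_small_deviation`` is only meaningful for the SAGE decoder,
    where it shrinks the log-deviation matrix H toward the background.
    """
    if lambda_small_deviation < 0:
        raise ValueError("lambda_small_deviation must be >= 0")
    xbar = np.atleast_2d(np.asarray(xbar_batch, dtype=np.float64))
    if xbar.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    return _topic_loss_t(
        Tensor(xbar),
        Tensor(np.atleast_2d(zeta_batch)),
        Tensor(np.atleast_2d(posts.mu)),
        Tensor(np.atleast_2d(posts.log_sigma_sq)),
        prior,
        H=None if H is None else Tensor(H),
        lambda_small_deviation=lambda_small_deviation,
    ).item()
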