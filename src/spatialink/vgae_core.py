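"""Adversarially regularized variational graph autoencoder for link prediction.

The model follows the VGAE lineage: a two-layer graph convolutional encoder
produces a diagonal-Gaussian posterior per cell,

    hidden = ReLU(A_norm X W0)
    mu        = A_norm hidden W1_mu
    log_sigma = A_norm hidden W1_logsigma
    q(h_i | X, A) = N(mu_i, diag(sigma_i^2))

with A_norm = D^{-1/2} (A + I) D^{-1/2}; the inner-product decoder scores
every cell pair as sigmoid(H H^T).  Training minimizes the negative evidence
lower bound (class-weighted reconstruction cross-entropy plus the closed-form
KL of the posterior against a standard-normal prior), regularized by an
adversarial multilayer perceptron trained to distinguish prior samples from
encoder samples, which pushes the aggregate posterior toward the prior.

Everything is implemented in numpy with analytic gradients (validated
against central finite differences in the test suite) and a self-contained
Adam optimizer, so the model runs anywhere numpy does, CPU only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .data_io import SpatialExpressionDataset, preprocess_expression
from .errors import NumericalError, ValidationError
from .spatial_graph import CellGraph, EdgeSplit

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "LatentEmbedding",
    "TrainResult",
    "normalize_adjacency",
    "encode",
    "decode",
    "elbo_loss",
    "kl_divergence",
    "discriminator_forward",
    "score_pairs",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1
LOGSIG_CLIP = 10.0


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters of the encoder, discriminator and training loop.

    Defaults: a 250-125 graph-convolutional encoder, a 125-150 fully
    connected discriminator, Adam with learning rate 4e-4, dropout 0.2 on the
    hidden layer, and an adversarial weight of 1 on the generator loss.
    """

    hidden1: int = 250
    latent: int = 125
    disc_h1: int = 125
    disc_h2: int = 150
    learning_rate: float = 4e-4
    epochs: int = 300
    dropout_rate: float = 0.2
    adversarial_weight: float = 1.0
    feature_scaling: str = "none"
    early_stopping: bool = False
    patience: int = 50
    eval_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden1, self.latent, self.disc_h1, self.disc_h2) <= 0:
            raise ValidationError("all layer dimensions must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.epochs < 0:
            raise ValidationError("epochs must be non-negative")


@dataclasses.dataclass
class ModelParameters:
    """All trainable arrays: encoder weights and discriminator weights/biases."""

    W0: np.ndarray
    W1_mu: np.ndarray
    W1_logsigma: np.ndarray
    Wd1: np.ndarray
    bd1: np.ndarray
    Wd2: np.ndarray
    bd2: np.ndarray
    Wd3: np.ndarray
    bd3: np.ndarray

    def encoder_items(self) -> dict[str, np.ndarray]:
        return {"W0": self.W0, "W1_mu": self.W1_mu, "W1_logsigma": self.W1_logsigma}

    def disc_items(self) -> dict[str, np.ndarray]:
        return {
            "Wd1": self.Wd1, "bd1": self.bd1,
            "Wd2": self.Wd2, "bd2": self.bd2,
            "Wd3": self.Wd3, "bd3": self.bd3,
        }

    def copy(self) -> "ModelParameters":
        return ModelParameters(**{
            k: v.copy() for k, v in {**self.encoder_items(), **self.disc_items()}.items()
        })


@dataclasses.dataclass
class LatentEmbedding:
    """Per-cell posterior mean, log standard deviation, and sampled vectors."""

    mu: np.ndarray
    log_sigma: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (("mu", self.mu), ("log_sigma", self.log_sigma), ("H", self.H)):
            if not np.all(np.isfinite(arr)):
                raise NumericalError(f"non-finite values in latent {name}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(n_genes: int, config: ModelConfig) -> ModelParameters:
    """Seeded Glorot-uniform initialization; biases start at zero."""
    rng = np.random.default_rng(config.seed)
    return ModelParameters(
        W0=_glorot(rng, n_genes, config.hidden1),
        W1_mu=_glorot(rng, config.hidden1, config.latent),
        W1_logsigma=_glorot(rng, config.hidden1, config.latent),
        Wd1=_glorot(rng, config.latent, config.disc_h1),
        bd1=np.zeros(config.disc_h1),
        Wd2=_glorot(rng, config.disc_h1, config.disc_h2),
        bd2=np.zeros(config.disc_h2),
        Wd3=_glorot(rng, config.disc_h2, 1),
        bd3=np.zeros(1),
    )


def normalize_adjacency(graph: CellGraph | np.ndarray) -> np.ndarray:
    """Symmetrically normalized adjacency with self-loops,
    D^{-1/2} (A + I) D^{-1/2}.  Self-loops guarantee positive degrees, so
    isolated cells are valid (their row is just [.. 1 ..])."""
    A = graph.adjacency() if isinstance(graph, CellGraph) else np.asarray(graph, float)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _encoder_forward(
    params: ModelParameters,
    X: np.ndarray,
    A_norm: np.ndarray,
    eps: Optional[np.ndarray] = None,
    drop_mask: Optional[np.ndarray] = None,
    keep_prob: float = 1.0,
) -> dict:
    """Deterministic encoder pass given explicit noise (eps) and dropout mask.

    ``eps=None`` gives the eval-mode embedding H = mu; ``drop_mask=None``
    disables dropout.  Returning all intermediates makes backprop (and the
    finite-difference gradient check) straightforward.
    """
    Z1 = A_norm @ X
    Hpre = Z1 @ params.W0
    Hrelu = np.maximum(Hpre, 0.0)
    Hdrop = Hrelu if drop_mask is None else Hrelu * drop_mask / keep_prob
    Z2 = A_norm @ Hdrop
    logsig_raw = Z2 @ params.W1_logsigma
    log_sigma = np.clip(logsig_raw, -LOGSIG_CLIP, LOGSIG_CLIP)
    mu = Z2 @ params.W1_mu
    sigma = np.exp(log_sigma)
    H = mu if eps is None else mu + sigma * eps
    return dict(
        Z1=Z1, Hpre=Hpre, Hrelu=Hrelu, Hdrop=Hdrop, Z2=Z2,
        mu=mu, logsig_raw=logsig_raw, log_sigma=log_sigma, sigma=sigma,
        H=H, eps=eps, drop_mask=drop_mask, keep_prob=keep_prob,
    )


def encode(
    X: np.ndarray,
    A_norm: np.ndarray,
    params: ModelParameters,
    dropout_rate: float = 0.0,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> LatentEmbedding:
    """Run the graph-convolutional encoder.

    In ``train`` mode, dropout is applied to the hidden layer and H is a
    reparameterized sample mu + sigma * eps; in ``eval`` mode, H = mu and the
    pass is deterministic.
    """
    if X.shape[1] != params.W0.shape[0]:
        raise ValidationError(
            f"X has {X.shape[1]} genes but W0 expects {params.W0.shape[0]}"
        )
    if mode == "train":
        if rng is None:
            rng = np.random.default_rng()
        eps = rng.standard_normal((X.shape[0], params.W1_mu.shape[1]))
        drop_mask = None
        keep = 1.0
        if dropout_rate > 0:
            keep = 1.0 - dropout_rate
            drop_mask = (
                rng.random((X.shape[0], params.W0.shape[1])) < keep
            ).astype(float)
        fwd = _encoder_forward(params, X, A_norm, eps=eps, drop_mask=drop_mask,
                               keep_prob=keep)
    elif mode == "eval":
        fwd = _encoder_forward(params, X, A_norm)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LatentEmbedding(mu=fwd["mu"], log_sigma=fwd["log_sigma"], H=fwd["H"])


def decode(H: np.ndarray) -> np.ndarray:
    """Inner-product decoder: sigmoid(H H^T), symmetric, diagonal included
    (the diagonal is reported but never enters losses or metrics)."""
    if not np.all(np.isfinite(H)):
        raise NumericalError("non-finite latent sample passed to decoder")
    return _sigmoid(H @ H.T)


def score_pairs(H: np.ndarray, pairs) -> np.ndarray:
    """Decoder probabilities for specific unordered pairs (no full matrix)."""
    idx = np.asarray(sorted(pairs) if isinstance(pairs, set) else list(pairs))
    dots = np.einsum("ij,ij->i", H[idx[:, 0]], H[idx[:, 1]])
    return _sigmoid(dots)


def kl_divergence(mu: np.ndarray, log_sigma: np.ndarray) -> float:
    """Mean per-cell KL(q || N(0, I)) for a diagonal Gaussian posterior:
    sum_d 0.5 (mu^2 + sigma^2 - 1 - 2 log sigma), averaged over cells."""
    sigma2 = np.exp(2.0 * log_sigma)
    per_cell = 0.5 * np.sum(mu**2 + sigma2 - 1.0 - 2.0 * log_sigma, axis=1)
    return float(per_cell.mean())


def _recon_weights(n_cells: int, n_edges: int) -> tuple[float, float]:
    """Class-balancing constants for the reconstruction cross-entropy over
    the n(n-1)/2 off-diagonal pairs: positives are up-weighted by
    (n_pairs - n_edges)/n_edges and the whole term scaled by
    n_pairs / (2 (n_pairs - n_edges))."""
    n_pairs = n_cells * (n_cells - 1) // 2
    if n_edges == 0 or n_edges >= n_pairs:
        raise ValidationError("reconstruction target must have 0 < edges < all pairs")
    pos_weight = (n_pairs - n_edges) / n_edges
    norm = n_pairs / (2.0 * (n_pairs - n_edges))
    return pos_weight, norm


def elbo_loss(
    probs: np.ndarray,
    A: np.ndarray,
    mu: np.ndarray,
    log_sigma: np.ndarray,
) -> float:
    """Negative ELBO: class-weighted reconstruction binary cross-entropy over
    all off-diagonal pairs plus the closed-form KL term (mean per cell)."""
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    a = A[iu]
    p = np.clip(probs[iu], 1e-12, 1 - 1e-12)
    pos_weight, norm = _recon_weights(n, int(a.sum()))
    bce = -(pos_weight * a * np.log(p) + (1 - a) * np.log(1 - p))
    recon = norm * bce.mean()
    return recon + kl_divergence(mu, log_sigma)


def discriminator_forward(
    h: np.ndarray, params: ModelParameters, return_cache: bool = False
):
    """MLP latent -> disc_h1 -> disc_h2 -> 1 with ReLU hidden activations and
    a sigmoid output: the probability that a latent sample came from the
    standard-normal prior rather than the encoder."""
    h = np.atleast_2d(h)
    z1 = h @ params.Wd1 + params.bd1
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params.Wd2 + params.bd2
    a2 = np.maximum(z2, 0.0)
    t = a2 @ params.Wd3 + params.bd3
    p = _sigmoid(t)[:, 0]
    if return_cache:
        return p, dict(h=h, z1=z1, a1=a1, z2=z2, a2=a2, t=t)
    return p


def _disc_backprop_to_input(
    dt: np.ndarray, cache: dict, params: ModelParameters
) -> np.ndarray:
    """Gradient of a scalar loss wrt the discriminator INPUT, given dL/dt."""
    da2 = dt @ params.Wd3.T
    dz2 = da2 * (cache["z2"] > 0)
    da1 = dz2 @ params.Wd2.T
    dz1 = da1 * (cache["z1"] > 0)
    return dz1 @ params.Wd1.T


def generator_loss_and_grads(
    params: ModelParameters,
    X: np.ndarray,
    A_norm: np.ndarray,
    A_target: np.ndarray,
    eps: Optional[np.ndarray],
    drop_mask: Optional[np.ndarray],
    keep_prob: float,
    adversarial_weight: float,
) -> tuple[float, dict[str, np.ndarray], dict[str, float]]:
    """Negative ELBO plus adversarial generator loss, with analytic gradients
    for the encoder weights (discriminator held fixed).

    All computations use logits for numerical stability; the randomness
    (reparameterization eps, dropout mask) is passed in explicitly so the
    function is deterministic, which the finite-difference check exploits.
    """
    n = X.shape[0]
    fwd = _encoder_forward(params, X, A_norm, eps=eps, drop_mask=drop_mask,
                           keep_prob=keep_prob)
    H, mu, log_sigma, sigma = fwd["H"], fwd["mu"], fwd["log_sigma"], fwd["sigma"]
    iu = np.triu_indices(n, 1)
    logits = H @ H.T
    z = logits[iu]
    a = A_target[iu]
    pos_weight, norm = _recon_weights(n, int(a.sum()))
    n_pairs = z.size
    recon = norm * (pos_weight * a * _softplus(-z) + (1 - a) * _softplus(z)).mean()
    kl = kl_divergence(mu, log_sigma)

    # dL/dz for each unordered pair, assembled into a symmetric matrix.
    s = _sigmoid(z)
    g = (norm / n_pairs) * (s * (1.0 + (pos_weight - 1.0) * a) - pos_weight * a)
    G = np.zeros((n, n))
    G[iu] = g
    G = G + G.T
    dH = G @ H

    adv = 0.0
    if adversarial_weight != 0.0:
        p_disc, cache = discriminator_forward(H, params, return_cache=True)
        t = cache["t"]
        adv = float(_softplus(-t).mean())  # -log D(H), labels "prior"
        dt = (_sigmoid(t) - 1.0) / n
        dH = dH + adversarial_weight * _disc_backprop_to_input(dt, cache, params)

    total = recon + kl + adversarial_weight * adv
    if not np.isfinite(total):
        raise NumericalError("non-finite generator loss")

    dmu = dH + mu / n
    eps_arr = np.zeros_like(mu) if eps is None else eps
    dlogsig = dH * eps_arr * sigma + (np.exp(2 * log_sigma) - 1.0) / n
    dlogsig = dlogsig * (np.abs(fwd["logsig_raw"]) < LOGSIG_CLIP)

    Z2, Z1 = fwd["Z2"], fwd["Z1"]
    dW1_mu = Z2.T @ dmu
    dW1_logsigma = Z2.T @ dlogsig
    dZ2 = dmu @ params.W1_mu.T + dlogsig @ params.W1_logsigma.T
    dHdrop = A_norm @ dZ2
    if drop_mask is not None:
        dHrelu = dHdrop * drop_mask / keep_prob
    else:
        dHrelu = dHdrop
    dHpre = dHrelu * (fwd["Hpre"] > 0)
    dW0 = Z1.T @ dHpre

    grads = {"W0": dW0, "W1_mu": dW1_mu, "W1_logsigma": dW1_logsigma}
    parts = {"recon": float(recon), "kl": float(kl), "adversarial": float(adv)}
    return float(total), grads, parts


def discriminator_loss_and_grads(
    params: ModelParameters, H_fake: np.ndarray, prior: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Binary cross-entropy of the discriminator on prior samples (label 1)
    vs encoder samples (label 0); gradients wrt discriminator weights only."""
    inputs = np.vstack([prior, H_fake])
    labels = np.concatenate([np.ones(len(prior)), np.zeros(len(H_fake))])
    _, cache = discriminator_forward(inputs, params, return_cache=True)
    t = cache["t"][:, 0]
    loss = float((labels * _softplus(-t) + (1 - labels) * _softplus(t)).mean())
    dt = ((_sigmoid(t) - labels) / len(labels))[:, None]
    da2 = dt @ params.Wd3.T
    dz2 = da2 * (cache["z2"] > 0)
    da1 = dz2 @ params.Wd2.T
    dz1 = da1 * (cache["z1"] > 0)
    grads = {
        "Wd3": cache["a2"].T @ dt, "bd3": dt.sum(axis=0),
        "Wd2": cache["a1"].T @ dz2, "bd2": dz2.sum(axis=0),
        "Wd1": cache["h"].T @ dz1, "bd1": dz1.sum(axis=0),
    }
    return loss, grads


class _Adam:
    """Minimal Adam optimizer over a dict of named arrays."""

    def __init__(self, shapes: dict[str, tuple], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            arrays[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclasses.dataclass
class TrainResult:
    params: ModelParameters
    embedding: LatentEmbedding
    log: list[dict]
    config: ModelConfig


def _auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    from .robustness import compute_auroc  # local import to avoid a cycle
    return compute_auroc(pos, neg)


def train(
    ds: SpatialExpressionDataset,
    split: EdgeSplit,
    config: ModelConfig,
) -> TrainResult:
    """Train the adversarially regularized VGAE on one tissue section.

    Only training-split edges enter the reconstruction target (held-out test
    edges are treated as non-edges during training).  Each epoch runs one
    discriminator step (prior vs encoder samples) followed by one
    encoder/decoder step on the negative ELBO plus the weighted adversarial
    generator loss.  The log records per-epoch loss components and,
    every ``eval_interval`` epochs, the held-out test AUROC from the
    eval-mode (deterministic) embedding.  Fully seeded.
    """
    if not split.train_pos:
        raise ValidationError("training positive edge set is empty")
    n = ds.n_cells
    X = preprocess_expression(ds.expression, config.feature_scaling)
    A_target = np.zeros((n, n))
    for i, j in split.train_pos:
        A_target[i, j] = A_target[j, i] = 1.0
    A_norm = normalize_adjacency(A_target)

    rng = np.random.default_rng(config.seed)
    params = init_parameters(ds.n_genes, config)
    opt_gen = _Adam({k: v.shape for k, v in params.encoder_items().items()},
                    config.learning_rate)
    opt_disc = _Adam({k: v.shape for k, v in params.disc_items().items()},
                     config.learning_rate)

    test_pairs = sorted(split.test_pos) + sorted(split.test_neg)
    n_test_pos = len(split.test_pos)

    val_pairs, n_val_pos = None, 0
    if config.early_stopping:
        from .spatial_graph import _sample_non_edges
        train_list = sorted(split.train_pos)
        n_val = max(1, round(0.05 * len(train_list)))
        vidx = rng.choice(len(train_list), size=n_val, replace=False)
        val_pos = [train_list[i] for i in vidx]
        forbidden = split.train_pos | split.test_pos | split.test_neg
        val_neg = sorted(_sample_non_edges(n, forbidden, n_val, rng))
        val_pairs, n_val_pos = val_pos + val_neg, len(val_pos)

    keep = 1.0 - config.dropout_rate
    log: list[dict] = []
    best_val, best_epoch, best_params = -np.inf, -1, None

    def _test_auroc(H_eval: np.ndarray) -> float:
        if not test_pairs or n_test_pos == 0:
            return float("nan")
        scores = score_pairs(H_eval, test_pairs)
        return _auroc(scores[:n_test_pos], scores[n_test_pos:])

    for epoch in range(config.epochs):
        eps = rng.standard_normal((n, config.latent))
        drop_mask = None
        if config.dropout_rate > 0:
            drop_mask = (rng.random((n, config.hidden1)) < keep).astype(float)
        fwd = _encoder_forward(params, X, A_norm, eps=eps, drop_mask=drop_mask,
                               keep_prob=keep)
        prior = rng.standard_normal((n, config.latent))
        disc_loss, disc_grads = discriminator_loss_and_grads(params, fwd["H"], prior)
        disc_arrays = params.disc_items()
        opt_disc.step(disc_arrays, disc_grads)

        try:
            total, gen_grads, parts = generator_loss_and_grads(
                params, X, A_norm, A_target, eps, drop_mask, keep,
                config.adversarial_weight,
            )
        except NumericalError as exc:
            raise NumericalError(
                f"training diverged at epoch {epoch}; last finite epoch "
                f"{epoch - 1}"
            ) from exc
        enc_arrays = params.encoder_items()
        opt_gen.step(enc_arrays, gen_grads)

        entry = dict(epoch=epoch, total=total, disc_loss=disc_loss, **parts)
        if (epoch + 1) % config.eval_interval == 0 or epoch == config.epochs - 1:
            emb = encode(X, A_norm, params, mode="eval")
            entry["test_auroc"] = _test_auroc(emb.H)
            if val_pairs is not None:
                vs = score_pairs(emb.H, val_pairs)
                entry["val_auroc"] = _auroc(vs[:n_val_pos], vs[n_val_pos:])
                if entry["val_auroc"] > best_val:
                    best_val, best_epoch = entry["val_auroc"], epoch
                    best_params = params.copy()
                elif epoch - best_epoch >= config.patience:
                    log.append(entry)
                    break
        log.append(entry)

    if config.early_stopping and best_params is not None:
        params = best_params
    embedding = encode(X, A_norm, params, mode="eval")
    return TrainResult(params=params, embedding=embedding, log=log, config=config)


def save_checkpoint(path: str | Path, result: TrainResult) -> None:
    """Single-archive checkpoint: config (JSON) + parameter arrays, versioned."""
    arrays = {**result.params.encoder_items(), **result.params.disc_items()}
    meta = json.dumps({
        "version": CHECKPOINT_VERSION,
        "config": dataclasses.asdict(result.config),
    })
    np.savez(path, _meta=np.array(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParameters, ModelConfig]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValidationError(f"unsupported checkpoint version {meta['version']}")
        params = ModelParameters(**{
            k: data[k] for k in
            ("W0", "W1_mu", "W1_logsigma", "Wd1", "bd1", "Wd2", "bd2", "Wd3", "bd3")
        })
    return params, ModelConfig(**meta["config"])
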