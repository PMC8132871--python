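"""Variational autoencoder over cos/sin dihedral features.

The encoder maps a 2D-dimensional feature row through N fully connected
PReLU layers (layer n has floor(2D/n) nodes) to two linear heads of size
k = floor(2D/(N+1)): the latent mean mu and log-variance ln sigma^2 of a
diagonal Gaussian.  The decoder mirrors the encoder (layers m = N..1 of
floor(2D/m) nodes, linear output of size 2D).  Training minimizes

    loss_model = (1 - w) * loss_mse + w * loss_kl

where both terms are per-sample sums averaged over the batch: loss_mse
sums squared reconstruction errors over the feature dimension, and
loss_kl is the closed-form KL divergence of the latent Gaussian from
N(0, I), 0.5 * sum_i (sigma_i^2 + mu_i^2 - ln sigma_i^2 - 1).  The sum
convention matters: it keeps the reconstruction term proportional to the
feature dimension (loss values in the hundreds at the start of training
on real-size systems), so with w = 0.1 reconstruction dominates and the
latent space does not collapse onto the prior.  Averaging the
reconstruction error over elements instead makes collapse the optimum on
well-separated two-basin data and the model learns nothing.

Everything is plain numpy with hand-written backpropagation: the networks
are a few hundred to a few thousand parameters, and having explicit
gradients lets the biasing module differentiate the encoder with respect
to its inputs exactly.  Optimization is Adam with decoupled weight decay,
a multi-step learning-rate schedule (equally spaced milestones, each
multiplying the rate by gamma), and early stopping that restores the best
parameters seen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ShapeError, TrainingDivergedError

__all__ = [
    "VAEConfig",
    "LatentGaussian",
    "TrainedVAE",
    "LossTrace",
    "build_vae",
    "encode",
    "decode",
    "reparameterize",
    "loss_mse",
    "reconstruction_mse",
    "loss_kl",
    "loss_model",
    "train",
]

_EPS_ADAM = 1e-8


@dataclass
class VAEConfig:
    """Architecture and optimization settings.

    Defaults follow the reference protocol: 7 hidden layers, KL weight
    w = 0.1, Adam(lr=1e-4, betas=(0.9, 0.999)) with decoupled weight decay
    0.01, 50 equally spaced LR milestones with gamma 0.99, batch size 512,
    up to 5000 epochs, early-stopping patience 250.
    """

    d_dihedrals: int
    n_hidden: int = 7
    w: float = 0.1
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    lr_milestones: int = 50
    lr_gamma: float = 0.99
    batch_size: int = 512
    max_epochs: int = 5000
    patience: int = 250
    validation_fraction: float = 0.0
    seed: int = 0

    @property
    def input_dim(self) -> int:
        return 2 * self.d_dihedrals

    @property
    def latent_dim(self) -> int:
        return self.input_dim // (self.n_hidden + 1)

    @property
    def encoder_widths(self) -> list[int]:
        return [self.input_dim // n for n in range(1, self.n_hidden + 1)]

    @property
    def decoder_widths(self) -> list[int]:
        return [self.input_dim // m for m in range(self.n_hidden, 0, -1)]

    def validate(self) -> "VAEConfig":
        problems = []
        if self.d_dihedrals < 1:
            problems.append("d_dihedrals must be >= 1")
        if not 0.0 <= self.w <= 1.0:
            problems.append("w must lie in [0, 1]")
        if self.latent_dim < 1:
            problems.append(
                f"latent_dim = floor({self.input_dim}/{self.n_hidden + 1}) < 1"
            )
        if self.d_dihedrals >= 1 and any(w < 1 for w in self.encoder_widths):
            problems.append("a hidden-layer width floors to 0; reduce n_hidden")
        if self.patience < 1:
            problems.append("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            problems.append("batch_size and max_epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            problems.append("validation_fraction must lie in [0, 1)")
        if problems:
            raise ConfigurationError("; ".join(problems))
        return self


@dataclass
class LatentGaussian:
    """Latent diagonal Gaussian(s): mean mu and log-variance ln sigma^2.

    Arrays are either (k,) for a single frame or (B, k) for a batch.
    """

    mean: np.ndarray
    ln_var: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.ln_var = np.asarray(self.ln_var, dtype=float)
        if self.mean.shape != self.ln_var.shape:
            raise ShapeError("mean and ln_var must have identical shapes")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.ln_var))):
            raise ValueError("latent parameters must be finite")

    @property
    def k(self) -> int:
        return self.mean.shape[-1]


@dataclass
class LossTrace:
    """Per-epoch training record: (epoch, loss_model, loss_mse, loss_kl, lr)."""

    epochs: list[int] = field(default_factory=list)
    loss_model: list[float] = field(default_factory=list)
    loss_mse: list[float] = field(default_factory=list)
    loss_kl: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def append(self, epoch, lm, lmse, lkl, lr):
        if self.epochs and epoch <= self.epochs[-1]:
            raise ValueError("epochs must be strictly increasing")
        self.epochs.append(int(epoch))
        self.loss_model.append(float(lm))
        self.loss_mse.append(float(lmse))
        self.loss_kl.append(float(lkl))
        self.learning_rate.append(float(lr))

    def extend(self, other: "LossTrace"):
        for row in zip(other.epochs, other.loss_model, other.loss_mse,
                       other.loss_kl, other.learning_rate):
            self.append(*row)

    def __len__(self):
        return len(self.epochs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("epoch\tloss_model\tloss_mse\tloss_kl\tlr\n")
            for row in zip(self.epochs, self.loss_model, self.loss_mse,
                           self.loss_kl, self.learning_rate):
                fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


# --------------------------------------------------------------------------
# parameter container
# --------------------------------------------------------------------------

def _init_linear(rng, n_out, n_in):
    bound = 1.0 / np.sqrt(n_in)
    W = rng.uniform(-bound, bound, size=(n_out, n_in))
    b = rng.uniform(-bound, bound, size=n_out)
    return W, b


def _init_params(config: VAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    prev = config.input_dim
    for i, width in enumerate(config.encoder_widths):
        p[f"enc_W{i}"], p[f"enc_b{i}"] = _init_linear(rng, width, prev)
        p[f"enc_a{i}"] = np.array([0.25])  # PReLU slope, one per layer
        prev = width
    k = config.latent_dim
    p["mu_W"], p["mu_b"] = _init_linear(rng, k, prev)
    p["lv_W"], p["lv_b"] = _init_linear(rng, k, prev)
    prev = k
    for i, width in enumerate(config.decoder_widths):
        p[f"dec_W{i}"], p[f"dec_b{i}"] = _init_linear(rng, width, prev)
        p[f"dec_a{i}"] = np.array([0.25])
        prev = width
    p["out_W"], p["out_b"] = _init_linear(rng, config.input_dim, prev)
    return p


def _prelu(x, a):
    return np.where(x > 0, x, a * x)


class TrainedVAE:
    """Parameter container + config; exposes deterministic encode/decode.

    "Trained" refers to the role in the sampling loop; a freshly built
    instance simply holds its seeded initialization.
    """

    def __init__(self, config: VAEConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config.validate()
        if params is None:
            params = _init_params(config, np.random.default_rng(config.seed))
        self.params = params
        self.n_training_epochs = 0  # cumulative, across retrainings
        self.best_loss: float | None = None

    # -- forward passes ----------------------------------------------------

    def _encode_forward(self, X):
        """Returns (mu, lnvar, cache); cache holds layer inputs and
        pre-activations for backprop."""
        p = self.params
        h = X
        cache = []
        for i in range(self.config.n_hidden):
            pre = h @ p[f"enc_W{i}"].T + p[f"enc_b{i}"]
            cache.append((h, pre))
            h = _prelu(pre, p[f"enc_a{i}"][0])
        mu = h @ p["mu_W"].T + p["mu_b"]
        lv = h @ p["lv_W"].T + p["lv_b"]
        return mu, lv, (cache, h)

    def _encode_backward_input(self, cache, dmu, dlv):
        """Vector-Jacobian product: gradients at (mu, lnvar) -> gradient at
        the input features.  Does not touch parameter gradients."""
        p = self.params
        layer_cache, h_last = cache
        dh = dmu @ p["mu_W"] + dlv @ p["lv_W"]
        for i in range(self.config.n_hidden - 1, -1, -1):
            _, pre = layer_cache[i]
            a = p[f"enc_a{i}"][0]
            dpre = dh * np.where(pre > 0, 1.0, a)
            dh = dpre @ p[f"enc_W{i}"]
        return dh

    def _decode_forward(self, Z):
        p = self.params
        h = Z
        cache = []
        for i in range(self.config.n_hidden):
            pre = h @ p[f"dec_W{i}"].T + p[f"dec_b{i}"]
            cache.append((h, pre))
            h = _prelu(pre, p[f"dec_a{i}"][0])
        y = h @ p["out_W"].T + p["out_b"]
        return y, (cache, h)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: config as JSON plus exact parameter arrays (npz)."""
        meta = json.dumps(asdict(self.config))
        arrays = {k: v for k, v in self.params.items()}
        np.savez(
            path,
            __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
            __epochs__=np.array([self.n_training_epochs]),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedVAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            meta["betas"] = tuple(meta["betas"])
            config = VAEConfig(**meta)
            params = {k: data[k].copy() for k in data.files if not k.startswith("__")}
            model = cls(config, params)
            model.n_training_epochs = int(data["__epochs__"][0])
        return model


def build_vae(config: VAEConfig) -> TrainedVAE:
    """Seeded construction of an untrained model with the mirrored
    encoder/decoder architecture."""
    return TrainedVAE(config)


# --------------------------------------------------------------------------
# encode / decode / losses
# --------------------------------------------------------------------------

def _as_batch(X, dim, what):
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != dim:
        raise ShapeError(f"{what}: expected width {dim}, got {X.shape[1]}")
    return X, single


def encode(model: TrainedVAE, features) -> LatentGaussian:
    """Deterministic encoder pass (no sampling).  Accepts one row or a batch."""
    X, single = _as_batch(features, model.config.input_dim, "encode")
    mu, lv, _ = model._encode_forward(X)
    if single:
        return LatentGaussian(mu[0], lv[0])
    return LatentGaussian(mu, lv)


def decode(model: TrainedVAE, z) -> np.ndarray:
    """Deterministic decoder pass: latent point(s) -> reconstructed features."""
    Z, single = _as_batch(z, model.config.latent_dim, "decode")
    y, _ = model._decode_forward(Z)
    return y[0] if single else y


def reparameterize(g: LatentGaussian, rng: np.random.Generator) -> np.ndarray:
    """z = mu + exp(ln_var / 2) * eps, eps ~ N(0, I) from the given stream."""
    eps = rng.standard_normal(g.mean.shape)
    return g.mean + np.exp(0.5 * g.ln_var) * eps


def loss_mse(y, y_hat) -> float:
    """Reconstruction loss: squared error summed over the feature dimension,
    averaged over samples (rows)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    if y.shape != y_hat.shape:
        raise ShapeError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.mean(np.sum((y - y_hat) ** 2, axis=1)))


def reconstruction_mse(y, y_hat) -> float:
    """Plain per-element mean squared error (diagnostic metric)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ShapeError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


def loss_kl(g: LatentGaussian) -> float:
    """KL(N(mu, diag sigma^2) || N(0, I)): 0.5 * sum_i (sigma_i^2 + mu_i^2
    - ln sigma_i^2 - 1) per sample, averaged over the batch."""
    var = np.exp(g.ln_var)
    per_sample = 0.5 * np.sum(var + g.mean**2 - g.ln_var - 1.0, axis=-1)
    return float(np.mean(per_sample))


def loss_model(mse: float, kl: float, w: float) -> float:
    """Composite training loss (1 - w) * mse + w * kl."""
    if not 0.0 <= w <= 1.0:
        raise ConfigurationError("w must lie in [0, 1]")
    return (1.0 - w) * mse + w * kl


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class _AdamW:
    """Adam with decoupled weight decay.  Decay is not applied to PReLU
    slopes or biases (matching common practice for 1-d parameters)."""

    def __init__(self, params, betas, weight_decay):
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            p = params[k]
            if p.ndim > 1 and self.wd:
                p -= lr * self.wd * p
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr * (m / c1) / (np.sqrt(v / c2) + _EPS_ADAM)


def _batch_step(model: TrainedVAE, X, rng):
    """One forward/backward pass.  Returns (losses, grads)."""
    p = model.params
    cfg = model.config
    B = X.shape[0]
    w = cfg.w

    mu, lv, enc_cache = model._encode_forward(X)
    eps = rng.standard_normal(mu.shape)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    y, dec_cache = model._decode_forward(z)

    var = np.exp(lv)
    mse = float(np.mean(np.sum((X - y) ** 2, axis=1)))
    kl = float(np.mean(0.5 * np.sum(var + mu**2 - lv - 1.0, axis=1)))
    total = loss_model(mse, kl, w)
    if not np.isfinite(total):
        raise TrainingDivergedError(f"non-finite loss: mse={mse}, kl={kl}")

    grads: dict[str, np.ndarray] = {}

    # reconstruction branch
    dy = (1.0 - w) * 2.0 * (y - X) / B
    layer_cache, h_last = dec_cache
    grads["out_W"] = dy.T @ h_last
    grads["out_b"] = dy.sum(axis=0)
    dh = dy @ p["out_W"]
    for i in range(cfg.n_hidden - 1, -1, -1):
        h_in, pre = layer_cache[i]
        a = p[f"dec_a{i}"][0]
        dpre = dh * np.where(pre > 0, 1.0, a)
        grads[f"dec_a{i}"] = np.array([np.sum(dh * np.where(pre > 0, 0.0, pre))])
        grads[f"dec_W{i}"] = dpre.T @ h_in
        grads[f"dec_b{i}"] = dpre.sum(axis=0)
        dh = dpre @ p[f"dec_W{i}"]
    dz = dh

    # combine reparameterization and KL contributions at (mu, ln_var)
    dmu = dz + w * mu / B
    dlv = dz * eps * 0.5 * std + w * 0.5 * (var - 1.0) / B

    layer_cache, h_last = enc_cache
    grads["mu_W"] = dmu.T @ h_last
    grads["mu_b"] = dmu.sum(axis=0)
    grads["lv_W"] = dlv.T @ h_last
    grads["lv_b"] = dlv.sum(axis=0)
    dh = dmu @ p["mu_W"] + dlv @ p["lv_W"]
    for i in range(cfg.n_hidden - 1, -1, -1):
        h_in, pre = layer_cache[i]
        a = p[f"enc_a{i}"][0]
        dpre = dh * np.where(pre > 0, 1.0, a)
        grads[f"enc_a{i}"] = np.array([np.sum(dh * np.where(pre > 0, 0.0, pre))])
        grads[f"enc_W{i}"] = dpre.T @ h_in
        grads[f"enc_b{i}"] = dpre.sum(axis=0)
        dh = dpre @ p[f"enc_W{i}"]

    return (total, mse, kl), grads


def _milestones(max_epochs: int, n_milestones: int) -> np.ndarray:
    """Equally spaced milestone epochs within [1, max_epochs]."""
    spacing = max(1, max_epochs // n_milestones)
    return np.arange(1, n_milestones + 1) * spacing


def train(
    model: TrainedVAE,
    data,
    rng: np.random.Generator | None = None,
    max_epochs: int | None = None,
    epoch_offset: int | None = None,
) -> tuple[TrainedVAE, LossTrace]:
    """Optimize the model in place; returns (model, per-epoch LossTrace).

    Shuffling and the reparameterization noise draw from `rng` (defaults to
    a generator seeded by config.seed + 1 so initialization and training use
    distinct streams).  Early stopping restores the parameters of the best
    epoch.  `max_epochs` overrides the config budget (used by the sampling
    loop's shorter retraining rounds); `epoch_offset` shifts the epoch column
    so traces concatenated across retrainings stay strictly increasing.
    """
    from .featurize import FeatureMatrix

    if isinstance(data, FeatureMatrix):
        data = data.features
    X = np.atleast_2d(np.asarray(data, dtype=float))
    cfg = model.config
    if X.shape[0] < 1:
        raise ValueError("training data is empty")
    if X.shape[1] != cfg.input_dim:
        raise ShapeError(f"training data width {X.shape[1]} != 2D = {cfg.input_dim}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n_epochs = cfg.max_epochs if max_epochs is None else int(max_epochs)
    offset = model.n_training_epochs if epoch_offset is None else int(epoch_offset)

    n_val = int(round(cfg.validation_fraction * X.shape[0]))
    if n_val > 0:
        perm = rng.permutation(X.shape[0])
        X_val, X_train = X[perm[:n_val]], X[perm[n_val:]]
    else:
        X_val, X_train = None, X
    n = X_train.shape[0]

    opt = _AdamW(model.params, cfg.betas, cfg.weight_decay)
    milestones = _milestones(n_epochs, cfg.lr_milestones)
    trace = LossTrace()
    best_loss = np.inf
    best_params = None
    since_best = 0

    for epoch in range(1, n_epochs + 1):
        lr = cfg.learning_rate * cfg.lr_gamma ** int(np.sum(milestones <= epoch))
        perm = rng.permutation(n)
        sums = np.zeros(3)
        for start in range(0, n, cfg.batch_size):
            batch = X_train[perm[start:start + cfg.batch_size]]
            losses, grads = _batch_step(model, batch, rng)
            opt.step(model.params, grads, lr)
            sums += np.array(losses) * batch.shape[0]
        lm, lmse, lkl = sums / n
        if X_val is not None:
            g = encode(model, X_val)
            y = decode(model, g.mean)
            lmse_v = loss_mse(X_val, y)
            lm = loss_model(lmse_v, loss_kl(g), cfg.w)
        trace.append(offset + epoch, lm, lmse, lkl, lr)
        if lm < best_loss:
            best_loss = lm
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    if best_params is not None:
        model.params = best_params
    model.best_loss = float(best_loss)
    model.n_training_epochs = offset + len(trace)
    return model, trace
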