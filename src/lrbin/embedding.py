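"""Variational autoencoder over per-barcode features, with abundance-
balanced weighted sampling.

The encoder maps the 536-dim concatenated feature vector through two
fully connected layers of 512 units (each followed by batch
normalization, LeakyReLU and dropout p=0.2) to two parallel 32-unit
heads producing mu and sigma of a diagonal Gaussian; the embedding Z is
sampled by reparameterization.  The mirrored decoder reconstructs the
two feature blocks, each renormalized by a softmax so the outputs are
probability vectors like the inputs.

The loss is the weighted sum of two cross-entropy reconstruction terms
and a KL term:

    L_A  = -sum X_A  ln(X^_A + 1e-9)
    L_T  = -sum X_T  ln(X^_T + 1e-9)
    L_KL = -sum 1/2 (1 + ln sigma - mu^2 - sigma)
    Loss = w_A L_A + w_T L_T + w_KL L_KL

with w_A = alpha/ln(dim X_A), w_T = (1-alpha)/ln(dim X_T) and
w_KL = beta/dim(Z); alpha=0.1, beta=0.015 by default.  The weights are
always recomputed from the actual dimensions.  ``as_printed=True``
drops the minus sign of the two reconstruction terms (the literal
formula, for audit); the default is true cross-entropy, minimized.

Training batches are drawn with replacement with probability
proportional to max(X_A)^2 per record, which over-samples barcodes from
low-abundance genomes, and stops early on a held-out split.

Everything runs on NumPy with hand-written backpropagation and Adam;
with a fixed seed a training run is bit-reproducible on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

_EPS = 1e-9  # pseudo-count inside the reconstruction logs


@dataclass(frozen=True)
class EmbedderConfig:
    """Architecture and optimization parameters of the embedder."""

    hidden_sizes: tuple[int, ...] = (512, 512)
    latent_dim: int = 32
    dropout_p: float = 0.2
    alpha: float = 0.1
    beta: float = 0.015
    batch_size: int = 256
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    as_printed: bool = False
    weighted_sampling: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")

    def loss_weights(self, dim_a: int, dim_t: int) -> tuple[float, float, float]:
        """(w_A, w_T, w_KL) recomputed from the feature dimensions."""
        return (
            self.alpha / np.log(dim_a),
            (1.0 - self.alpha) / np.log(dim_t),
            self.beta / self.latent_dim,
        )


@dataclass
class LossBreakdown:
    """The three loss components, their weighted total, and reconstructions."""

    l_a: float
    l_t: float
    l_kl: float
    total: float
    xhat_a: np.ndarray | None = None
    xhat_t: np.ndarray | None = None


def loss_components(
    x_a, x_t, xhat_a, xhat_t, mu, sigma, config: EmbedderConfig = EmbedderConfig()
) -> LossBreakdown:
    """Evaluate the loss terms for one sample or a batch.

    Reconstruction terms sum over feature dimensions (mean over the
    batch when 2-D input is given); the KL term is evaluated in sigma
    exactly as stated, vanishing at the prior (mu=0, sigma=1).
    """
    x_a, x_t = np.atleast_2d(x_a), np.atleast_2d(x_t)
    xhat_a, xhat_t = np.atleast_2d(xhat_a), np.atleast_2d(xhat_t)
    mu, sigma = np.atleast_2d(mu), np.atleast_2d(sigma)
    if x_a.shape != xhat_a.shape or x_t.shape != xhat_t.shape or mu.shape != sigma.shape:
        raise ValueError("shape mismatch between inputs and reconstructions")
    sign = 1.0 if config.as_printed else -1.0
    l_a = sign * float(np.mean(np.sum(np.log(xhat_a + _EPS) * x_a, axis=1)))
    l_t = sign * float(np.mean(np.sum(np.log(xhat_t + _EPS) * x_t, axis=1)))
    l_kl = float(np.mean(-np.sum(0.5 * (1.0 + np.log(sigma) - mu**2 - sigma), axis=1)))
    w_a, w_t, w_kl = config.loss_weights(x_a.shape[1], x_t.shape[1])
    return LossBreakdown(l_a, l_t, l_kl, w_a * l_a + w_t * l_t + w_kl * l_kl)


class WeightedSampler:
    """Draws record indices with replacement, probability ~ weight."""

    def __init__(self, weights: Sequence[float], seed: int = 0, uniform_fallback: bool = False):
        w = np.asarray(weights, dtype=np.float64)
        if w.size == 0:
            raise ValueError("cannot sample from zero records")
        if np.any(w < 0):
            raise ValueError("sampling weights must be non-negative")
        total = w.sum()
        if total == 0:
            if not uniform_fallback:
                raise ValueError(
                    "all sampling weights are zero; pass uniform_fallback=True "
                    "to draw uniformly instead"
                )
            w = np.ones_like(w)
            total = w.sum()
        self.p = w / total
        self.rng = np.random.default_rng(seed)

    def draw(self, n: int) -> np.ndarray:
        return self.rng.choice(self.p.size, size=n, replace=True, p=self.p)


def make_weighted_sampler(records, seed: int = 0, uniform_fallback: bool = False) -> WeightedSampler:
    """Sampler over feature records weighted by ``max(X_A)**2``."""
    return WeightedSampler([r.sampling_weight for r in records], seed, uniform_fallback)


# ---------------------------------------------------------------------------
# layers


class _Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._xc = x - mean
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.ggamma = (g * self._xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        dxhat = g * self.gamma
        if not self._train:
            return dxhat / self._std
        n = g.shape[0]
        dvar = np.sum(dxhat * self._xc, axis=0) * -0.5 / self._std**3
        dmean = -np.sum(dxhat, axis=0) / self._std + dvar * np.mean(-2.0 * self._xc, axis=0)
        return dxhat / self._std + dvar * 2.0 * self._xc / n + dmean / n

    def params(self):
        return [("gamma", self), ("beta", self)]


class _LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.slope * g)

    def params(self):
        return []


class _Dropout:
    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class VariationalEmbedder:
    """Encoder/decoder pair trained on the weighted loss above."""

    def __init__(self, dim_a: int, dim_t: int, config: EmbedderConfig):
        self.dim_a, self.dim_t = dim_a, dim_t
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        d_in = dim_a + dim_t
        h = config.hidden_sizes
        self.enc: list = []
        prev = d_in
        for width in h:
            self.enc += [_Linear(self.rng, prev, width), _BatchNorm(width),
                         _LeakyReLU(), _Dropout(config.dropout_p)]
            prev = width
        self.head_mu = _Linear(self.rng, prev, config.latent_dim)
        self.head_sigma = _Linear(self.rng, prev, config.latent_dim)
        self.dec: list = []
        prev = config.latent_dim
        for width in reversed(h):
            self.dec += [_Linear(self.rng, prev, width), _BatchNorm(width),
                         _LeakyReLU(), _Dropout(config.dropout_p)]
            prev = width
        self.out = _Linear(self.rng, prev, d_in)
        for layer in self.enc + self.dec:
            if isinstance(layer, _Dropout):
                layer.rng = self.rng
        self._adam: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward ----------------------------------------------------------

    def _encode(self, x: np.ndarray, train: bool):
        h = x
        for layer in self.enc:
            h = layer.forward(h, train)
        mu = self.head_mu.forward(h, train)
        sraw = self.head_sigma.forward(h, train)
        sigma = _softplus(sraw) + 1e-6
        return mu, sigma, sraw

    def _decode(self, z: np.ndarray, train: bool):
        h = z
        for layer in self.dec:
            h = layer.forward(h, train)
        logits = self.out.forward(h, train)
        return _softmax(logits[:, : self.dim_a]), _softmax(logits[:, self.dim_a :])

    def forward(self, x: np.ndarray, train: bool = False, sample: bool = False):
        """(xhat_a, xhat_t, mu, sigma, z); deterministic (z=mu) unless sampling."""
        mu, sigma, sraw = self._encode(x, train)
        if sample:
            eps = self.rng.standard_normal(mu.shape)
            z = mu + sigma * eps
        else:
            eps = None
            z = mu
        xhat_a, xhat_t = self._decode(z, train)
        return xhat_a, xhat_t, mu, sigma, z, sraw, eps

    def loss(self, x: np.ndarray, train: bool = False, sample: bool = False) -> LossBreakdown:
        xhat_a, xhat_t, mu, sigma, *_ = self.forward(x, train=train, sample=sample)
        lb = loss_components(
            x[:, : self.dim_a], x[:, self.dim_a :], xhat_a, xhat_t, mu, sigma, self.config
        )
        lb.xhat_a, lb.xhat_t = xhat_a, xhat_t
        return lb

    # -- backward ---------------------------------------------------------

    def _softmax_ce_grad(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        """d/d logits of -sum x ln(p + eps) per sample (exact, incl. eps)."""
        r = x * p / (p + _EPS)
        return p * r.sum(axis=1, keepdims=True) - r

    def train_step(self, x: np.ndarray) -> LossBreakdown:
        """One forward/backward/Adam update on a batch; returns the losses."""
        lb = self.loss_and_grads(x)
        self._adam_update()
        return lb

    def loss_and_grads(self, x: np.ndarray, eps: np.ndarray | None = None) -> LossBreakdown:
        """Forward + backward on a batch, leaving gradients on the layers.

        ``eps`` fixes the reparameterization noise (drawn from the model
        rng when omitted) so gradients can be checked numerically.
        """
        cfg = self.config
        b = x.shape[0]
        x_a, x_t = x[:, : self.dim_a], x[:, self.dim_a :]
        mu, sigma, sraw = self._encode(x, train=True)
        if eps is None:
            eps = self.rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        xhat_a, xhat_t = self._decode(z, train=True)
        lb = loss_components(x_a, x_t, xhat_a, xhat_t, mu, sigma, cfg)
        if not np.isfinite(lb.total):
            raise FloatingPointError(
                f"non-finite loss (L_A={lb.l_a}, L_T={lb.l_t}, L_KL={lb.l_kl}); "
                "reduce the learning rate or inspect the input features"
            )
        w_a, w_t, w_kl = cfg.loss_weights(self.dim_a, self.dim_t)
        # _softmax_ce_grad differentiates -sum x ln(p+eps); as_printed flips it
        ga = (w_a / b) * self._softmax_ce_grad(xhat_a, x_a)
        gt = (w_t / b) * self._softmax_ce_grad(xhat_t, x_t)
        if cfg.as_printed:
            ga, gt = -ga, -gt
        g_logits = np.concatenate([ga, gt], axis=1)
        g = self.out.backward(g_logits)
        for layer in reversed(self.dec):
            g = layer.backward(g)
        gz = g
        gmu = gz + (w_kl / b) * mu
        gsigma = gz * eps + (w_kl / b) * 0.5 * (1.0 - 1.0 / sigma)
        gsraw = gsigma / (1.0 + np.exp(-sraw))  # softplus' = logistic
        gh = self.head_mu.backward(gmu) + self.head_sigma.backward(gsraw)
        for layer in reversed(self.enc):
            gh = layer.backward(gh)
        return lb

    def _grad_pairs(self):
        for layer in self.enc + [self.head_mu, self.head_sigma] + self.dec + [self.out]:
            for name, owner in layer.params():
                grad = getattr(owner, {"W": "gW", "b": "gb", "gamma": "ggamma", "beta": "gbeta"}[name])
                yield (id(owner), name), owner, name, grad

    def _adam_update(self, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        lr = self.config.learning_rate
        for key, owner, name, grad in self._grad_pairs():
            m, v = self._adam.get(key, (np.zeros_like(grad), np.zeros_like(grad)))
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad**2
            self._adam[key] = (m, v)
            mhat = m / (1 - b1**self._adam_t)
            vhat = v / (1 - b2**self._adam_t)
            param = getattr(owner, name)
            setattr(owner, name, param - lr * mhat / (np.sqrt(vhat) + eps))

    # -- state ------------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        layers = self.enc + [self.head_mu, self.head_sigma] + self.dec + [self.out]
        for i, layer in enumerate(layers):
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, attr):
                    arrays[f"layer{i}.{attr}"] = getattr(layer, attr)
        return arrays

    def save(self, path) -> None:
        meta = json.dumps({"version": 1, "dim_a": self.dim_a, "dim_t": self.dim_t,
                           "config": asdict(self.config)})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "VariationalEmbedder":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
        model = cls(meta["dim_a"], meta["dim_t"], EmbedderConfig(**cfg_dict))
        for key, arr in model.state_arrays().items():
            arr[...] = data[key]
        return model


@dataclass
class EmbeddingResult:
    """Latent means for non-flagged records, plus what was excluded."""

    mu: np.ndarray
    barcodes: list[str]
    excluded: list[str] = field(default_factory=list)


def train_embedder(
    records,
    config: EmbedderConfig = EmbedderConfig(),
) -> tuple[VariationalEmbedder, list[dict]]:
    """Train on the non-flagged records; returns (embedder, per-epoch log).

    A 10% held-out split (at least one record) drives early stopping:
    training stops when the validation loss has not improved for
    ``patience`` epochs, and the best-validation weights are restored.
    The log records the train-loss breakdown and validation loss per
    epoch.
    """
    usable = [r for r in records if not r.flagged]
    if len(usable) < 2 * config.batch_size:
        raise ValueError(
            f"need at least 2*batch_size={2 * config.batch_size} non-flagged records, "
            f"got {len(usable)}; reduce batch_size"
        )
    dim_a, dim_t = usable[0].x_a.size, usable[0].x_t.size
    X = np.stack([r.concat for r in usable])

    split_rng = np.random.default_rng(config.seed + 1)
    perm = split_rng.permutation(len(usable))
    n_val = max(1, int(round(config.val_fraction * len(usable))))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    weights = [usable[i].sampling_weight for i in train_idx]
    if config.weighted_sampling:
        sampler = WeightedSampler(weights, seed=config.seed + 2)
    else:
        sampler = WeightedSampler(np.ones(len(train_idx)), seed=config.seed + 2)

    model = VariationalEmbedder(dim_a, dim_t, config)
    log: list[dict] = []
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    for epoch in range(config.max_epochs):
        draws = train_idx[sampler.draw(len(train_idx))]
        sums = np.zeros(4)
        n_batches = 0
        for lo in range(0, len(draws), config.batch_size):
            batch = draws[lo : lo + config.batch_size]
            if batch.size < 2:
                continue  # batch statistics need >= 2 samples
            lb = model.train_step(X[batch])
            sums += (lb.l_a, lb.l_t, lb.l_kl, lb.total)
            n_batches += 1
        val = model.loss(X[val_idx], train=False, sample=False)
        entry = dict(
            epoch=epoch,
            l_a=sums[0] / n_batches, l_t=sums[1] / n_batches,
            l_kl=sums[2] / n_batches, total=sums[3] / n_batches,
            val_total=val.total,
        )
        log.append(entry)
        if val.total < best_val - 1e-12:
            best_val = val.total
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        for key, arr in model.state_arrays().items():
            arr[...] = best_state[key]
    return model, log


def embed(model: VariationalEmbedder, records) -> EmbeddingResult:
    """Latent means (mu) per record, deterministically (no sampling/dropout).

    Flagged records (all-zero histogram) are excluded and reported in
    ``excluded``; row order follows the input order of the kept records.
    """
    kept = [r for r in records if not r.flagged]
    excluded = [r.barcode for r in records if r.flagged]
    if not kept:
        return EmbeddingResult(np.empty((0, model.config.latent_dim)), [], excluded)
    X = np.stack([r.concat for r in kept])
    mu, _, _ = model._encode(X, train=False)
    return EmbeddingResult(mu, [r.barcode for r in kept], excluded)
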