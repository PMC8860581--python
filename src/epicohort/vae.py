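"""MMD-regularized variational autoencoder for gene-profile embeddings.

The model is an InfoVAE-style autoencoder: a dense encoder emits a posterior
mean and log-variance per latent dimension, a sample is drawn via the
reparameterization z = mu + eps * exp(logvar / 2), and a mirrored dense
decoder reconstructs the profile. The per-batch loss is

    MSE(x, x_hat) + lambda * MMD(z_batch, prior_batch),

where MMD is the biased V-statistic estimate of squared maximum mean
discrepancy under a Gaussian kernel and the prior batch is drawn from
N(0, I_D). Activations follow the original protocol: selu on the first
encoder layer and the decoder output, relu elsewhere. Optimisation is Adam
(beta1 = 0.9, beta2 = 0.999) at learning rate 0.01 with the classic per-step
decay lr_t = lr / (1 + decay * t), decay = 0.01, for 250 epochs at batch
size 50 on an 85% training split.

Everything — split, initialisation, batching, reparameterization noise and
prior draws — flows from one seeded generator, so training is bit-for-bit
reproducible. The network is implemented directly on numpy arrays with
hand-written backpropagation; it is small enough (order 10^2 features,
10^3 genes) that this trains in seconds on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


# ---------------------------------------------------------------------------
# Maximum mean discrepancy
# ---------------------------------------------------------------------------

def _gaussian_gram(a: np.ndarray, b: np.ndarray,
                   bandwidth: float) -> np.ndarray:
    """Gram matrix of k(u, v) = exp(-||u - v||^2 / (2 sigma^2))."""
    d2 = (np.sum(a ** 2, axis=1)[:, None] + np.sum(b ** 2, axis=1)[None, :]
          - 2.0 * a @ b.T)
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * bandwidth))


def mmd(x: np.ndarray, y: np.ndarray, bandwidth: float) -> float:
    """Biased V-statistic estimate of squared MMD with a Gaussian kernel.

    mean k(x, x') + mean k(y, y') - 2 mean k(x, y); zero when the two
    samples are identical, symmetric in its arguments, never negative for
    the biased estimator.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise ValueError("both sample sets must be non-empty")
    if x.shape[1] != y.shape[1]:
        raise ValueError(
            f"dimension mismatch: {x.shape[1]} vs {y.shape[1]}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return float(_gaussian_gram(x, x, bandwidth).mean()
                 + _gaussian_gram(y, y, bandwidth).mean()
                 - 2.0 * _gaussian_gram(x, y, bandwidth).mean())


def _mmd_grad_x(x: np.ndarray, y: np.ndarray,
                bandwidth: float) -> tuple[float, np.ndarray]:
    """MMD value and its gradient with respect to the first sample set."""
    n, m = x.shape[0], y.shape[0]
    kxx = _gaussian_gram(x, x, bandwidth)
    kxy = _gaussian_gram(x, y, bandwidth)
    kyy_mean = _gaussian_gram(y, y, bandwidth).mean()
    value = kxx.mean() + kyy_mean - 2.0 * kxy.mean()
    # d k(u,v)/du = -k(u,v) (u - v) / sigma^2; the xx term appears twice
    # (as (i,j) and (j,i)) hence the factor 2/n^2.
    gxx = (kxx.sum(axis=1)[:, None] * x - kxx @ x) * (-2.0 / (n * n))
    gxy = (kxy.sum(axis=1)[:, None] * x - kxy @ y) * (2.0 / (n * m))
    return float(value), (gxx + gxy) / bandwidth


# ---------------------------------------------------------------------------
# Configuration and model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VAEConfig:
    latent_dim: int = 3
    hidden_sizes: tuple[int, ...] = (64, 32)
    epochs: int = 250
    batch_size: int = 50
    mmd_weight: float = 1.0
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    decay: float = 0.01
    decay_mode: str = "lr"          # "lr" (per-step lr decay) or "weight"
    train_fraction: float = 0.85
    kernel_bandwidth: float | None = None   # defaults to latent_dim
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")
        if min(self.learning_rate, self.beta1, self.beta2) <= 0:
            raise ValueError("optimizer rates must be positive")
        if self.decay_mode not in ("lr", "weight"):
            raise ValueError("decay_mode must be 'lr' or 'weight'")

    @property
    def bandwidth(self) -> float:
        return (self.kernel_bandwidth if self.kernel_bandwidth is not None
                else float(self.latent_dim))


def _selu(x):
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))


def _selu_grad(x):
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(float)


class _Dense:
    """A dense layer with Glorot-uniform init and cached backprop state."""

    def __init__(self, n_in: int, n_out: int, activation: str | None,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._x: np.ndarray | None = None
        self._pre: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        pre = x @ self.w + self.b
        if cache:
            self._x, self._pre = x, pre
        if self.activation == "selu":
            return _selu(pre)
        if self.activation == "relu":
            return _relu(pre)
        return pre

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.activation == "selu":
            grad_out = grad_out * _selu_grad(self._pre)
        elif self.activation == "relu":
            grad_out = grad_out * _relu_grad(self._pre)
        self.gw = self._x.T @ grad_out
        self.gb = grad_out.sum(axis=0)
        return grad_out @ self.w.T

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


@dataclass
class VAEModel:
    """Trained encoder/decoder with the loss history of every epoch."""
    config: VAEConfig
    feature_names: list[str]
    layers: dict = field(repr=False)
    history: pd.DataFrame = field(repr=False)  # epoch x train/val loss parts

    def encode_mean(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers["enc"]:
            h = layer.forward(h, cache=False)
        return self.layers["mu"].forward(h, cache=False)

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = z
        for layer in self.layers["dec"]:
            h = layer.forward(h, cache=False)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decode(self.encode_mean(x))


@dataclass
class LatentEmbedding:
    """Posterior-mean latent codes per gene."""
    codes: pd.DataFrame          # genes x D

    @property
    def dims(self) -> list[str]:
        return list(self.codes.columns)

    def mean_sd(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.codes.mean(axis=0),
                             "sd": self.codes.std(axis=0, ddof=0)})


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, layers, config: VAEConfig):
        self.cfg = config
        self.slots = []
        for layer in layers:
            for arr, gname in layer.params():
                self.slots.append((layer, arr, gname, np.zeros_like(arr),
                                   np.zeros_like(arr)))
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        if c.decay_mode == "lr":
            lr = c.learning_rate / (1.0 + c.decay * (self.t - 1))
        else:
            lr = c.learning_rate
        for layer, arr, gname, m, v in self.slots:
            g = getattr(layer, gname)
            if c.decay_mode == "weight":
                g = g + c.decay * arr
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1 ** self.t)
            vhat = v / (1 - c.beta2 ** self.t)
            arr -= lr * mhat / (np.sqrt(vhat) + 1e-8)


def _build_layers(n_features: int, config: VAEConfig,
                  rng: np.random.Generator) -> dict:
    hidden = list(config.hidden_sizes)
    enc, n_in = [], n_features
    for i, h in enumerate(hidden):
        enc.append(_Dense(n_in, h, "selu" if i == 0 else "relu", rng))
        n_in = h
    mu = _Dense(n_in, config.latent_dim, None, rng)
    logvar = _Dense(n_in, config.latent_dim, None, rng)
    # start with a small posterior spread (SD ~ e^-2) so early reconstruction
    # gradients are not drowned by reparameterization noise
    logvar.b[:] = -4.0
    dec, n_in = [], config.latent_dim
    for h in reversed(hidden):
        dec.append(_Dense(n_in, h, "relu", rng))
        n_in = h
    dec.append(_Dense(n_in, n_features, "selu", rng))
    return {"enc": enc, "mu": mu, "logvar": logvar, "dec": dec}


def _forward_loss(layers: dict, x: np.ndarray, config: VAEConfig,
                  rng: np.random.Generator, sample: bool = True
                  ) -> tuple[float, float, dict]:
    h = x
    for layer in layers["enc"]:
        h = layer.forward(h)
    mu = layers["mu"].forward(h)
    logvar_raw = layers["logvar"].forward(h)
    logvar = np.clip(logvar_raw, -10.0, 3.0)
    eps = rng.standard_normal(mu.shape) if sample else np.zeros_like(mu)
    z = mu + eps * np.exp(0.5 * logvar)
    out = z
    for layer in layers["dec"]:
        out = layer.forward(out)
    mse = float(np.mean((x - out) ** 2))
    prior = rng.standard_normal(z.shape)
    mmd_val, mmd_gz = _mmd_grad_x(z, prior, config.bandwidth)
    cache = {"mu": mu, "logvar": logvar, "eps": eps, "z": z, "out": out,
             "x": x, "mmd_gz": mmd_gz,
             "logvar_open": (logvar_raw > -10.0) & (logvar_raw < 3.0)}
    return mse, mmd_val, cache


def _backward(layers: dict, cache: dict, config: VAEConfig) -> None:
    x, out = cache["x"], cache["out"]
    grad_out = 2.0 * (out - x) / out.size
    g = grad_out
    for layer in reversed(layers["dec"]):
        g = layer.backward(g)
    gz = g + config.mmd_weight * cache["mmd_gz"]
    g_mu = gz
    g_logvar = (gz * 0.5 * cache["eps"] * np.exp(0.5 * cache["logvar"])
                * cache["logvar_open"])
    gh = (layers["mu"].backward(g_mu)
          + layers["logvar"].backward(g_logvar))
    for layer in reversed(layers["enc"]):
        gh = layer.backward(gh)


def train_vae(profiles: ProfileMatrix, config: VAEConfig | None = None
              ) -> VAEModel:
    """Train the MMD-VAE on a scaled profile matrix.

    Raises on NaN loss with the offending step's diagnostics. The returned
    history has one row per epoch with train/validation loss and its MSE and
    MMD components.
    """
    config = config or VAEConfig()
    if not profiles.is_scaled:
        raise ValueError("profiles must be min-max scaled before training")
    x_all = profiles.data.to_numpy(dtype=float)
    n = x_all.shape[0]
    if n < 2 * config.batch_size:
        raise ValueError(
            f"need at least {2 * config.batch_size} genes, got {n}")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = max(int(round(config.train_fraction * n)), 1)
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    x_train, x_val = x_all[train_idx], x_all[val_idx]

    layers = _build_layers(x_all.shape[1], config, rng)
    all_layers = layers["enc"] + [layers["mu"], layers["logvar"]] \
        + layers["dec"]
    opt = _Adam(all_layers, config)

    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        mse_sum = mmd_sum = 0.0
        n_batches = 0
        for start in range(0, n_train, config.batch_size):
            batch = x_train[order[start:start + config.batch_size]]
            mse, mmd_val, cache = _forward_loss(layers, batch, config, rng)
            loss = mse + config.mmd_weight * mmd_val
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(lr step {opt.t}, mse={mse}, mmd={mmd_val})")
            _backward(layers, cache, config)
            opt.step()
            mse_sum += mse
            mmd_sum += mmd_val
            n_batches += 1
        row = {"epoch": epoch,
               "train_mse": mse_sum / n_batches,
               "train_mmd": mmd_sum / n_batches}
        row["train_loss"] = (row["train_mse"]
                             + config.mmd_weight * row["train_mmd"])
        if len(val_idx):
            vmse, vmmd, _ = _forward_loss(layers, x_val, config, rng)
            row.update(val_mse=vmse, val_mmd=vmmd,
                       val_loss=vmse + config.mmd_weight * vmmd)
        rows.append(row)

    return VAEModel(config, list(profiles.data.columns), layers,
                    pd.DataFrame(rows).set_index("epoch"))


def encode(model: VAEModel, profiles: ProfileMatrix) -> LatentEmbedding:
    """Posterior-mean latent codes (no sampling; deterministic)."""
    if list(profiles.data.columns) != model.feature_names:
        extra = set(profiles.data.columns) - set(model.feature_names)
        miss = set(model.feature_names) - set(profiles.data.columns)
        raise ValueError(
            f"feature mismatch: unexpected {sorted(extra)[:5]}, "
            f"missing {sorted(miss)[:5]}")
    codes = model.encode_mean(profiles.data.to_numpy(dtype=float))
    return LatentEmbedding(pd.DataFrame(
        codes, index=profiles.data.index,
        columns=[f"z{d}" for d in range(codes.shape[1])]))


def sweep_latent_dims(profiles: ProfileMatrix,
                      dims: list[int] | range = range(1, 33),
                      seeds: list[int] = (0,),
                      base_config: VAEConfig | None = None) -> pd.DataFrame:
    """Final validation reconstruction loss per (latent_dim, seed)."""
    from dataclasses import replace
    base = base_config or VAEConfig()
    rows = []
    for d in dims:
        for seed in seeds:
            cfg = replace(base, latent_dim=d, seed=seed,
                          kernel_bandwidth=base.kernel_bandwidth)
            model = train_vae(profiles, cfg)
            last = model.history.iloc[-1]
            rows.append({"latent_dim": d, "seed": seed,
                         "val_mse": last.get("val_mse", np.nan),
                         "train_mse": last["train_mse"]})
    return pd.DataFrame(rows)
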