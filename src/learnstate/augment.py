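"""GAN-based class balancing on feature vectors, with Wasserstein diagnostics.

One generative adversarial network is trained per class on that class's
feature vectors (features min-max scaled to [-1, 1] to match the generator's
tanh output).  The generator maps a 100-dimensional standard-normal noise vector
through hidden layers of 128, 256 and 512 leaky-rectifier units to a
feature-space vector; the discriminator mirrors that layout (512, 256, 128)
with dropout 0.3 after each hidden layer and a sigmoid output.  Both are
trained with binary cross-entropy under Adam (learning rate 2e-4, beta1 0.5),
the generator with the non-saturating form (fake samples scored against the
"real" target).

The empirical 1-d Wasserstein distance serves as the post-hoc similarity
diagnostic between real and synthetic marginals; GAN training itself uses the
BCE minimax objective (a Wasserstein-critic training mode is deliberately out
of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .features import LabeledDataset


@dataclass
class GanConfig:
    noise_dim: int = 100
    gen_hidden: tuple[int, ...] = (128, 256, 512)
    disc_hidden: tuple[int, ...] = (512, 256, 128)
    leaky_slope: float = 0.2
    dropout: float = 0.3
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 1000
    init_sd: float = 0.02  # weight-init scale conventional for this optimizer setup
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.gen_hidden + self.disc_hidden):
            raise ValueError("all layer sizes must be positive")
        if not self.learning_rate > 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


class _Adam:
    """Adam optimizer state for one list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


class _Net:
    """Small dense net with leaky-ReLU hidden units (weights stored row-major:
    W[l] has shape (out, in))."""

    def __init__(self, sizes: tuple[int, ...], slope: float, out_act: str, rng, init_sd=0.02):
        self.slope = slope
        self.out_act = out_act  # "tanh" | "sigmoid"
        self.W = [
            rng.normal(0.0, init_sd, size=(sizes[l + 1], sizes[l]))
            for l in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X, drop_rate=0.0, rng=None):
        """Returns (output, cache) where cache holds per-layer inputs, pre-acts
        and dropout masks for the backward pass."""
        a = X
        cache = {"a": [X], "z": [], "mask": []}
        last = len(self.W) - 1
        for l, (w, bb) in enumerate(zip(self.W, self.b)):
            z = a @ w.T + bb
            cache["z"].append(z)
            if l < last:
                a = np.where(z > 0, z, self.slope * z)
                if drop_rate > 0:
                    mask = (rng.random(a.shape) >= drop_rate) / (1 - drop_rate)
                    a = a * mask
                    cache["mask"].append(mask)
                else:
                    cache["mask"].append(None)
            else:
                a = np.tanh(z) if self.out_act == "tanh" else 1 / (1 + np.exp(-z))
                cache["mask"].append(None)
            cache["a"].append(a)
        return a, cache

    def backward(self, cache, dout):
        """Backprop from d(loss)/d(output); returns (param grads, d(loss)/d(input))."""
        last = len(self.W) - 1
        z = cache["z"][last]
        out = cache["a"][last + 1]
        if self.out_act == "tanh":
            delta = dout * (1 - out**2)
        else:
            delta = dout * out * (1 - out)
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for l in range(last, -1, -1):
            gW[l] = delta.T @ cache["a"][l]
            gb[l] = delta.sum(axis=0)
            delta = delta @ self.W[l]
            if l > 0:
                if cache["mask"][l - 1] is not None:
                    delta = delta * cache["mask"][l - 1]
                zprev = cache["z"][l - 1]
                delta = delta * np.where(zprev > 0, 1.0, self.slope)
        return gW + gb, delta


@dataclass
class FeatureScaler:
    """Per-feature affine map between feature units and the tanh range [-1, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    def to_tanh(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return 2.0 * (X - self.lo) / span - 1.0

    def from_tanh(self, Z: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return (Z + 1.0) / 2.0 * span + self.lo


@dataclass
class GanModel:
    generator: _Net
    discriminator: _Net
    scaler: FeatureScaler
    config: GanConfig
    n_features: int
    gen_losses: list[float] = field(default_factory=list)
    disc_losses: list[float] = field(default_factory=list)
    #: per-epoch discriminator accuracy on a frozen real batch vs fresh fakes;
    #: drifts toward 0.5 as the generator catches up
    probe_accuracy: list[float] = field(default_factory=list)

    def discriminate(self, X_scaled: np.ndarray) -> np.ndarray:
        """Probability that each (scaled) row is real."""
        out, _ = self.discriminator.forward(np.atleast_2d(X_scaled))
        return out.ravel()


def _bce(p: np.ndarray, target: float) -> float:
    p = np.clip(p, 1e-8, 1 - 1e-8)
    return float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())


def _bce_grad(p: np.ndarray, target: float) -> np.ndarray:
    p = np.clip(p, 1e-8, 1 - 1e-8)
    return (-(target / p) + (1 - target) / (1 - p)) / p.size


def train_gan(class_samples: np.ndarray, cfg: Optional[GanConfig] = None) -> GanModel:
    """Train one GAN on the feature vectors of a single class.

    Alternates one discriminator step (real batch scored toward 1, generated
    batch toward 0) with one generator step (generated batch scored toward 1)
    per minibatch.  Deterministic under ``cfg.seed``.
    """
    cfg = cfg or GanConfig()
    X = np.atleast_2d(np.asarray(class_samples, dtype=float))
    n, d = X.shape
    if n < 8:
        raise ValueError(f"class has only {n} rows; too few to train a GAN")
    batch = min(cfg.batch_size, n)
    rng = np.random.default_rng(cfg.seed)
    scaler = FeatureScaler(lo=X.min(axis=0), hi=X.max(axis=0))
    Xs = scaler.to_tanh(X)
    gen = _Net((cfg.noise_dim, *cfg.gen_hidden, d), cfg.leaky_slope, "tanh", rng, cfg.init_sd)
    disc = _Net((d, *cfg.disc_hidden, 1), cfg.leaky_slope, "sigmoid", rng, cfg.init_sd)
    opt_g = _Adam(gen.params, cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_d = _Adam(disc.params, cfg.learning_rate, cfg.beta1, cfg.beta2)
    model = GanModel(gen, disc, scaler, cfg, d)
    probe_real = Xs[: min(64, n)]
    probe_z = rng.standard_normal((probe_real.shape[0], cfg.noise_dim))
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        ep_d, ep_g, nb = 0.0, 0.0, 0
        for start in range(0, n, batch):
            real = Xs[order[start : start + batch]]
            m = real.shape[0]
            z = rng.standard_normal((m, cfg.noise_dim))
            fake, _ = gen.forward(z)
            # --- discriminator step ---
            p_real, cache_r = disc.forward(real, cfg.dropout, rng)
            p_fake, cache_f = disc.forward(fake, cfg.dropout, rng)
            d_loss = 0.5 * (_bce(p_real.ravel(), 1.0) + _bce(p_fake.ravel(), 0.0))
            g_r, _ = disc.backward(cache_r, 0.5 * _bce_grad(p_real, 1.0))
            g_f, _ = disc.backward(cache_f, 0.5 * _bce_grad(p_fake, 0.0))
            opt_d.step(disc.params, [a + b for a, b in zip(g_r, g_f)])
            # --- generator step (non-saturating BCE: fakes toward "real") ---
            z = rng.standard_normal((m, cfg.noise_dim))
            fake, cache_g = gen.forward(z)
            p_fake, cache_d = disc.forward(fake)  # no dropout when scoring for G
            g_loss = _bce(p_fake.ravel(), 1.0)
            _, dfake = disc.backward(cache_d, _bce_grad(p_fake, 1.0))
            g_grads, _ = gen.backward(cache_g, dfake)
            opt_g.step(gen.params, g_grads)
            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(
                    f"GAN training produced a non-finite loss (D={d_loss}, G={g_loss})"
                )
            ep_d += d_loss
            ep_g += g_loss
            nb += 1
        model.disc_losses.append(ep_d / nb)
        model.gen_losses.append(ep_g / nb)
        probe_fake, _ = gen.forward(probe_z)
        acc = 0.5 * (
            (model.discriminate(probe_real) > 0.5).mean()
            + (model.discriminate(probe_fake) <= 0.5).mean()
        )
        model.probe_accuracy.append(float(acc))
    return model


def sample_synthetic(gan: GanModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` synthetic feature vectors (inverse-scaled to feature units)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, gan.config.noise_dim))
    fake, _ = gan.generator.forward(z)
    return gan.scaler.from_tanh(fake)


def balance_dataset(
    ds: LabeledDataset, gans: dict[int, GanModel], seed: int = 0
) -> LabeledDataset:
    """Top every minority class up to the majority count with GAN samples.

    Real rows are untouched; added rows carry ``synthetic=True`` metadata.
    """
    counts = ds.class_counts()
    target = counts.max()
    deficits = {c: int(target - counts[c]) for c in range(len(counts)) if counts[c] < target}
    if not deficits:
        return ds
    missing = [c for c in deficits if c not in gans]
    if missing:
        raise ValueError(f"no trained GAN for deficient class(es) {missing}")
    X_new, y_new, meta_new = [ds.X], [ds.y], []
    base_meta = ds.meta
    if base_meta is None:
        base_meta = pd.DataFrame(index=range(ds.n_samples))
    base_meta = base_meta.copy()
    if "synthetic" not in base_meta.columns:
        base_meta["synthetic"] = False
    for c, k in deficits.items():
        Xc = sample_synthetic(gans[c], k, seed=seed + c)
        X_new.append(Xc)
        y_new.append(np.full(k, c, dtype=int))
        add = pd.DataFrame(
            {col: [None] * k for col in base_meta.columns if col != "synthetic"},
            index=range(k),
        )
        add["synthetic"] = True
        meta_new.append(add)
    meta = pd.concat([base_meta, *meta_new], ignore_index=True)
    return replace(
        ds, X=np.vstack(X_new), y=np.concatenate(y_new), meta=meta, normalization=None
    )


def wasserstein_1d(a: np.ndarray, b: np.ndarray) -> float:
    """Empirical 1-d Wasserstein-1 distance (area between the two ECDFs).

    Computed from the pooled breakpoints: sum over consecutive pooled values
    of |F_a - F_b| times the gap.  Symmetric, non-negative, zero iff the
    empirical distributions coincide.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    allv = np.concatenate([a, b])
    allv.sort(kind="mergesort")
    deltas = np.diff(allv)
    cdf_a = np.searchsorted(a, allv[:-1], side="right") / a.size
    cdf_b = np.searchsorted(b, allv[:-1], side="right") / b.size
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def augmentation_report(real: np.ndarray, synthetic: np.ndarray) -> pd.DataFrame:
    """Per-feature table of Wasserstein-1, mean difference and sd ratio."""
    real = np.atleast_2d(np.asarray(real, dtype=float))
    synthetic = np.atleast_2d(np.asarray(synthetic, dtype=float))
    if real.shape[1] != synthetic.shape[1]:
        raise ValueError(
            f"dimension mismatch: real has {real.shape[1]} features, "
            f"synthetic has {synthetic.shape[1]}"
        )
    rows = []
    for j in range(real.shape[1]):
        sd_r = real[:, j].std()
        sd_s = synthetic[:, j].std()
        rows.append(
            {
                "feature": j,
                "wasserstein_1": wasserstein_1d(real[:, j], synthetic[:, j]),
                "mean_difference": float(synthetic[:, j].mean() - real[:, j].mean()),
                "sd_ratio": float(sd_s / sd_r) if sd_r > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
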