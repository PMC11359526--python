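"""Data augmentation, conditional generative synthesis, and the Deep
Generative Ensemble (DGE).

Augmentation adds Gaussian noise and random amplitude scaling to positive
windows.  Synthetic windows come from either a label-conditioned GAN over
flattened 16-step sequences (two-layer MLP generator and discriminator,
non-saturating adversarial loss, hand-written gradients) or a deterministic
``bootstrap`` surrogate that resamples real windows per class with jitter —
the latter keeps the DGE logic exercisable when adversarial training is too
slow or flaky at desk scale.

DGE trains K classifiers on K disjointly-seeded synthetic datasets and
averages their predicted probabilities.  An optional outer homogeneous
ensemble averages M independently trained DGEs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .model import Hyperparams, TrainedClassifier, train
from .preprocess import WindowedDataset

__all__ = [
    "AugmentConfig",
    "GenerativeModel",
    "DGEnsemble",
    "OuterEnsemble",
    "augment_windows",
    "fit_generator",
    "sample_synthetic",
    "dge_train",
    "dge_predict",
    "save_ensemble",
    "load_ensemble",
    "dge_outer_ensemble",
]


@dataclass(frozen=True)
class AugmentConfig:
    noise_sd: float = 0.05  # standardized units
    scale_min: float = 0.8
    scale_max: float = 1.2
    n_augment_per_positive: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.scale_min <= self.scale_max:
            raise ValueError("need 0 < scale_min <= scale_max")
        if self.n_augment_per_positive < 0:
            raise ValueError("n_augment_per_positive must be >= 0")


def augment_windows(
    windows: np.ndarray, config: AugmentConfig, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """scale * window + noise, one scale draw per copy, noise i.i.d. per point."""
    windows = np.asarray(windows, dtype=float)
    if windows.size == 0:
        raise ValueError("augment_windows requires a non-empty window array")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    copies = []
    for _ in range(config.n_augment_per_positive):
        scales = rng.uniform(config.scale_min, config.scale_max,
                             size=(len(windows), 1, 1))
        noise = rng.normal(0.0, config.noise_sd, size=windows.shape) \
            if config.noise_sd > 0 else 0.0
        copies.append(scales * windows + noise)
    if not copies:
        return np.empty((0,) + windows.shape[1:])
    return np.concatenate(copies)


# ---------------------------------------------------------------------------
# conditional generator
# ---------------------------------------------------------------------------

def _leaky(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _MLP:
    """Two-layer perceptron with leaky-ReLU hidden layer and linear output."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator):
        s1 = np.sqrt(2.0 / n_in)
        s2 = np.sqrt(2.0 / n_hidden)
        self.W1 = rng.normal(0, s1, (n_hidden, n_in))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0, s2, (n_out, n_hidden))
        self.b2 = np.zeros(n_out)

    def forward(self, x: np.ndarray):
        a1 = x @ self.W1.T + self.b1
        h1 = _leaky(a1)
        out = h1 @ self.W2.T + self.b2
        return out, (x, a1, h1)

    def backward(self, cache, dout: np.ndarray):
        x, a1, h1 = cache
        grads = {
            "W2": dout.T @ h1,
            "b2": dout.sum(axis=0),
        }
        dh1 = dout @ self.W2
        da1 = dh1 * _leaky_grad(a1)
        grads["W1"] = da1.T @ x
        grads["b1"] = da1.sum(axis=0)
        dx = da1 @ self.W1
        return grads, dx

    def arrays(self):
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


class _MLPAdam:
    def __init__(self, mlp: _MLP, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in mlp.arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in mlp.arrays().items()}

    def step(self, mlp: _MLP, grads: dict) -> None:
        self.t += 1
        for k, p in mlp.arrays().items():
            g = grads[k]
            self.m[k] = 0.9 * self.m[k] + 0.1 * g
            self.v[k] = 0.999 * self.v[k] + 0.001 * g * g
            mh = self.m[k] / (1 - 0.9**self.t)
            vh = self.v[k] / (1 - 0.999**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + 1e-8)


def _onehot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), 2))
    out[np.arange(len(labels)), labels.astype(int)] = 1.0
    return out


@dataclass
class GenerativeModel:
    """Class-conditional window generator (``cgan`` or ``bootstrap``)."""

    kind: str
    window_shape: tuple[int, int]  # (T, channels)
    latent_dim: int
    training_seed: int
    condition_labels: tuple[int, int] = (0, 1)
    generator: _MLP | None = None
    class_pools: dict[int, np.ndarray] | None = None  # bootstrap source windows
    jitter_sd: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    training_log: list = field(default_factory=list)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.kind}:{self.latent_dim}:{self.training_seed}".encode())
        if self.generator is not None:
            for arr in self.generator.arrays().values():
                h.update(np.ascontiguousarray(arr).tobytes())
        if self.class_pools is not None:
            for cls in sorted(self.class_pools):
                h.update(np.ascontiguousarray(self.class_pools[cls]).tobytes())
        return h.hexdigest()[:16]

    def sample(self, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        labels = np.asarray(labels, dtype=int)
        T, C = self.window_shape
        if self.kind == "cgan":
            z = rng.normal(size=(len(labels), self.latent_dim))
            flat, _ = self.generator.forward(
                np.concatenate([z, _onehot(labels)], axis=1))
            return flat.reshape(len(labels), T, C)
        # bootstrap: parametric resampling of real windows with jitter
        out = np.empty((len(labels), T, C))
        for k, lab in enumerate(labels):
            pool = self.class_pools[int(lab)]
            src = pool[rng.integers(len(pool))]
            scale = rng.uniform(*self.scale_range)
            out[k] = scale * src + rng.normal(0.0, self.jitter_sd, size=src.shape)
        return out


def fit_generator(
    dataset: WindowedDataset,
    latent_dim: int = 16,
    epochs: int = 200,
    rng_seed: int = 0,
    kind: str = "cgan",
    hidden: int = 64,
    lr: float = 1e-3,
    batch_size: int = 64,
) -> GenerativeModel:
    """Train a class-conditional generator on real windows.

    ``kind="cgan"`` runs adversarial training with the non-saturating
    generator loss; ``kind="bootstrap"`` just stores class-conditional pools
    for jittered resampling (no optimization).
    """
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("generator training requires both classes")
    T, C = dataset.windows.shape[1:]
    rng = np.random.default_rng(rng_seed)

    if kind == "bootstrap":
        pools = {int(c): dataset.windows[labels == c].copy() for c in (0, 1)}
        return GenerativeModel(kind, (T, C), latent_dim, rng_seed,
                               class_pools=pools)
    if kind != "cgan":
        raise ValueError("kind must be 'cgan' or 'bootstrap'")

    d = T * C
    gen = _MLP(latent_dim + 2, hidden, d, rng)
    disc = _MLP(d + 2, hidden, 1, rng)
    g_opt = _MLPAdam(gen, lr)
    d_opt = _MLPAdam(disc, lr)
    x_flat = dataset.windows.reshape(len(dataset), d)
    log = []
    for epoch in range(epochs):
        order = rng.permutation(len(x_flat))
        d_losses, g_losses = [], []
        for start in range(0, len(order), batch_size):
            sel = order[start : start + batch_size]
            real = x_flat[sel]
            y = labels[sel]
            onehot = _onehot(y)
            B = len(sel)

            # --- discriminator step ---
            z = rng.normal(size=(B, latent_dim))
            fake, _ = gen.forward(np.concatenate([z, onehot], axis=1))
            d_in = np.concatenate(
                [np.concatenate([real, onehot], axis=1),
                 np.concatenate([fake, onehot], axis=1)])
            logit, d_cache = disc.forward(d_in)
            logit = logit[:, 0]
            target = np.concatenate([np.ones(B), np.zeros(B)])
            p = _sigmoid(logit)
            d_loss = float(np.mean(
                np.maximum(logit, 0) - logit * target
                + np.log1p(np.exp(-np.abs(logit)))))
            dlogit = ((p - target) / len(target))[:, None]
            d_grads, _ = disc.backward(d_cache, dlogit)
            d_opt.step(disc, d_grads)

            # --- generator step (non-saturating: maximize log D(fake)) ---
            z = rng.normal(size=(B, latent_dim))
            g_in = np.concatenate([z, onehot], axis=1)
            fake, g_cache = gen.forward(g_in)
            logit, d_cache = disc.forward(np.concatenate([fake, onehot], axis=1))
            logit = logit[:, 0]
            p = _sigmoid(logit)
            g_loss = float(np.mean(
                np.maximum(logit, 0) - logit
                + np.log1p(np.exp(-np.abs(logit)))))
            dlogit = ((p - 1.0) / B)[:, None]
            _, d_fake = disc.backward(d_cache, dlogit)
            g_grads, _ = gen.backward(g_cache, d_fake[:, :d])
            g_opt.step(gen, g_grads)
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        log.append((epoch, float(np.mean(d_losses)), float(np.mean(g_losses))))

    return GenerativeModel(kind, (T, C), latent_dim, rng_seed, generator=gen,
                           training_log=log)


def sample_synthetic(
    gen: GenerativeModel, n_per_class: int, rng_seed: int | np.random.Generator = 0
) -> WindowedDataset:
    """Balanced synthetic windows, flagged as synthetic provenance."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    labels = np.repeat(np.array(gen.condition_labels), n_per_class)
    windows = gen.sample(labels, rng)
    n = len(labels)
    return WindowedDataset(
        windows=windows,
        labels=labels,
        window_start_s=np.full(n, -1.0),
        subject_ids=np.array(["synthetic"] * n, dtype=object),
        synthetic=np.ones(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Deep Generative Ensemble
# ---------------------------------------------------------------------------

@dataclass
class DGEnsemble:
    """K classifiers trained on disjointly seeded synthetic merges."""

    members: list[tuple[int, TrainedClassifier]]  # (seed, classifier)
    generator_fingerprints: list[str]
    threshold: float = 0.5

    @property
    def K(self) -> int:
        return len(self.members)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        if not self.members:
            raise ValueError("ensemble has no trained members")
        probs = np.stack([clf.predict_proba(windows) for _, clf in self.members])
        return probs.mean(axis=0)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return (self.predict_proba(windows) >= self.threshold).astype(int)

    def manifest(self) -> dict:
        return {
            "K": self.K,
            "member_seeds": [s for s, _ in self.members],
            "generator_fingerprints": self.generator_fingerprints,
            "member_fingerprints": [c.config_fingerprint for _, c in self.members],
        }


def dge_train(
    real_train: WindowedDataset,
    K: int = 5,
    augment_config: AugmentConfig | None = None,
    model_hyperparams: Hyperparams | None = None,
    rng_seed: int = 0,
    generator_kind: str = "cgan",
    n_synthetic_per_class: int | None = None,
    generator_epochs: int = 200,
    latent_dim: int = 16,
) -> DGEnsemble:
    """Fit the Deep Generative Ensemble.

    Per member k: fit a generator with its own seed, sample a synthetic
    dataset, merge it with the real windows plus noise/scale-augmented
    positives (mixing ratio about 1:1:1 for the positive class by default),
    then train one classifier.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    cfg = augment_config or AugmentConfig()
    hp = model_hyperparams or Hyperparams()
    n_pos = int(real_train.labels.sum())
    if n_synthetic_per_class is None:
        n_synthetic_per_class = max(n_pos, 1)

    member_seeds = [int(s.generate_state(1)[0] % (2**31))
                    for s in np.random.SeedSequence(rng_seed).spawn(K)]
    members, gen_fps = [], []
    for seed in member_seeds:
        gen = fit_generator(real_train, latent_dim=latent_dim,
                            epochs=generator_epochs, rng_seed=seed,
                            kind=generator_kind)
        synth = sample_synthetic(gen, n_synthetic_per_class, rng_seed=seed)
        parts = [real_train, synth]
        pos = real_train.windows[real_train.labels == 1]
        if len(pos) and cfg.n_augment_per_positive > 0:
            aug = augment_windows(pos, cfg, rng_seed=seed)
            parts.append(WindowedDataset(
                windows=aug,
                labels=np.ones(len(aug), dtype=int),
                window_start_s=np.full(len(aug), -1.0),
                subject_ids=np.array(["augmented"] * len(aug), dtype=object),
                synthetic=np.ones(len(aug), dtype=bool),
            ))
        merged = WindowedDataset.concatenate(parts)
        clf = train(merged, hp, rng_seed=seed)
        members.append((seed, clf))
        gen_fps.append(gen.fingerprint())
    return DGEnsemble(members, gen_fps, threshold=hp.threshold)


def dge_predict(ensemble: DGEnsemble, windows: np.ndarray) -> np.ndarray:
    """Arithmetic mean of member probabilities per window."""
    return ensemble.predict_proba(windows)


def save_ensemble(ensemble: DGEnsemble, outdir) -> None:
    """Directory checkpoint: one NPZ per member + a JSON manifest."""
    from pathlib import Path

    from .model import save_classifier

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for k, (seed, clf) in enumerate(ensemble.members):
        save_classifier(clf, out / f"member_{k}.npz")
    manifest = {**ensemble.manifest(), "threshold": ensemble.threshold}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(indir) -> DGEnsemble:
    from pathlib import Path

    from .model import load_classifier

    src = Path(indir)
    manifest = json.loads((src / "manifest.json").read_text())
    members = [
        (seed, load_classifier(src / f"member_{k}.npz"))
        for k, seed in enumerate(manifest["member_seeds"])
    ]
    return DGEnsemble(members, manifest["generator_fingerprints"],
                      threshold=manifest.get("threshold", 0.5))


@dataclass
class OuterEnsemble:
    """Homogeneous outer ensemble of M independently seeded DGEs."""

    members: list[DGEnsemble]
    threshold: float = 0.5

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        if not self.members:
            raise ValueError("ensemble has no trained members")
        return np.stack([m.predict_proba(windows) for m in self.members]).mean(axis=0)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return (self.predict_proba(windows) >= self.threshold).astype(int)


def dge_outer_ensemble(
    real_train: WindowedDataset, M: int = 5, rng_seed: int = 0, **dge_kwargs
) -> OuterEnsemble:
    """DGE wrapped in an outer M-seed homogeneous classifier ensemble."""
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence((rng_seed, 1)).spawn(M)]
    members = [dge_train(real_train, rng_seed=s, **dge_kwargs) for s in seeds]
    threshold = members[0].threshold if members else 0.5
    return OuterEnsemble(members, threshold=threshold)
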