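"""Conditional variational autoencoder classifier on 33-feature vectors.

A Gaussian encoder maps a feature vector x ∈ [0,1]^33 to a diagonal
posterior q(z|x) = N(μ(x), diag σ²(x)); the decoder reconstructs x from a
latent sample with the class label injected by concatenation onto the
activations of its second layer, so the reconstruction distribution is
conditioned on both z and the label.  Training minimizes the negative ELBO

    L = BCE(x, x̂) + KL( q(z|x) ‖ N(0, I) )

by minibatch SGD with momentum, with the reparameterization z = μ + σ·ε.
Hidden activations are ReLU; the encoder's final layer is linear (mean and
log-variance heads) and the decoder's final layer is a sigmoid, matching the
Bernoulli reconstruction likelihood of min-max scaled features.

Classification rule: the label is the free input of the decoder, so a test
vector is scored once per candidate label with z fixed at the posterior mean,
and the label whose conditional ELBO is smallest is returned.

The implementation is a self-contained numpy network with hand-derived
gradients; everything is seeded and deterministic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

N_FEATURES = 33
LABELS = ("benign", "malignant")
_EPS_CLIP = 1e-7


@dataclass
class CVAEConfig:
    h1: int = 64
    h2: int = 32
    z_dim: int = 8
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 200

    def __post_init__(self) -> None:
        if min(self.h1, self.h2, self.z_dim) < 1:
            raise ValueError("layer sizes must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class CVAEParams:
    """Encoder (φ) and decoder (θ) weights plus the feature scaler ranges."""

    weights: dict[str, np.ndarray]
    config: CVAEConfig
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    trained: bool = False
    seed: int = 0


@dataclass(frozen=True)
class LatentPosterior:
    mean: np.ndarray
    logvar: np.ndarray


@dataclass(frozen=True)
class ELBOBreakdown:
    total: float
    recon: float
    kl: float


def _init_weights(config: CVAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, (n_in, n_out))

    h1, h2, z = config.h1, config.h2, config.z_dim
    n_lab = len(LABELS)
    return {
        "We1": glorot(N_FEATURES, h1), "be1": np.zeros(h1),
        "We2": glorot(h1, h2), "be2": np.zeros(h2),
        "Wmu": glorot(h2, z), "bmu": np.zeros(z),
        "Wlv": glorot(h2, z), "blv": np.zeros(z),
        "Wd1": glorot(z, h2), "bd1": np.zeros(h2),
        "Wd2": glorot(h2 + n_lab, h1), "bd2": np.zeros(h1),
        "Wd3": glorot(h1, N_FEATURES), "bd3": np.zeros(N_FEATURES),
    }


def init_params(config: CVAEConfig | None = None, seed: int = 0) -> CVAEParams:
    config = config or CVAEConfig()
    rng = np.random.default_rng(seed)
    return CVAEParams(weights=_init_weights(config, rng), config=config, seed=seed)


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))


def _one_hot(labels) -> np.ndarray:
    labels = np.atleast_1d(labels)
    idx = np.empty(labels.size, dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r}; expected one of {LABELS}")
            idx[i] = LABELS.index(lab)
        else:
            if int(lab) not in (0, 1):
                raise ValueError(f"unknown label {lab!r}; expected 0/1 or {LABELS}")
            idx[i] = int(lab)
    out = np.zeros((labels.size, len(LABELS)))
    out[np.arange(labels.size), idx] = 1.0
    return out


def encode(x: np.ndarray, params: CVAEParams) -> LatentPosterior:
    """Deterministic forward pass to the diagonal Gaussian posterior."""
    w = params.weights
    X = np.atleast_2d(np.asarray(x, dtype=np.float64))
    h1 = _relu(X @ w["We1"] + w["be1"])
    h2 = _relu(h1 @ w["We2"] + w["be2"])
    mu = h2 @ w["Wmu"] + w["bmu"]
    lv = h2 @ w["Wlv"] + w["blv"]
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
        raise FloatingPointError("non-finite encoder activations")
    if np.asarray(x).ndim == 1:
        mu, lv = mu[0], lv[0]
    return LatentPosterior(mean=mu, logvar=lv)


def decode(z: np.ndarray, label, params: CVAEParams) -> np.ndarray:
    """Label-conditioned reconstruction; output strictly inside (0, 1)."""
    w = params.weights
    Z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    lab = _one_hot([label] * Z.shape[0] if np.isscalar(label) or isinstance(label, str)
                   else label)
    d1 = _relu(Z @ w["Wd1"] + w["bd1"])
    cat = np.concatenate([d1, lab], axis=1)
    d2 = _relu(cat @ w["Wd2"] + w["bd2"])
    recon = _sigmoid(d2 @ w["Wd3"] + w["bd3"])
    recon = np.clip(recon, _EPS_CLIP, 1.0 - _EPS_CLIP)
    if np.asarray(z).ndim == 1:
        recon = recon[0]
    return recon


def elbo_loss(x: np.ndarray, recon: np.ndarray,
              posterior: LatentPosterior) -> ELBOBreakdown:
    """Negative ELBO of one sample: Bernoulli cross-entropy + closed-form KL."""
    x = np.asarray(x, dtype=np.float64)
    r = np.asarray(recon, dtype=np.float64)
    if x.shape != r.shape:
        raise ValueError("x and recon shapes differ")
    if np.any(r <= 0.0) or np.any(r >= 1.0):
        raise ValueError("reconstruction values must lie strictly in (0, 1)")
    rec = float(-(x * np.log(r) + (1.0 - x) * np.log(1.0 - r)).sum())
    mu = np.asarray(posterior.mean, dtype=np.float64)
    lv = np.asarray(posterior.logvar, dtype=np.float64)
    kl = float(-0.5 * (1.0 + lv - mu ** 2 - np.exp(lv)).sum())
    return ELBOBreakdown(total=rec + kl, recon=rec, kl=kl)


def _forward_backward(w: dict, X: np.ndarray, onehot: np.ndarray,
                      eps: np.ndarray) -> tuple[dict, float, float]:
    """One minibatch forward + manual backward pass.

    Returns (gradients of the mean per-sample loss, mean recon, mean kl).
    """
    B = X.shape[0]
    a1 = X @ w["We1"] + w["be1"]; h1 = _relu(a1)
    a2 = h1 @ w["We2"] + w["be2"]; h2 = _relu(a2)
    mu = h2 @ w["Wmu"] + w["bmu"]
    lv = np.clip(h2 @ w["Wlv"] + w["blv"], -20, 20)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    ad1 = z @ w["Wd1"] + w["bd1"]; d1 = _relu(ad1)
    cat = np.concatenate([d1, onehot], axis=1)
    ad2 = cat @ w["Wd2"] + w["bd2"]; d2 = _relu(ad2)
    logits = d2 @ w["Wd3"] + w["bd3"]
    r = _sigmoid(logits)
    rc = np.clip(r, _EPS_CLIP, 1.0 - _EPS_CLIP)

    recon = float(-(X * np.log(rc) + (1 - X) * np.log(1 - rc)).sum() / B)
    kl = float(-0.5 * (1 + lv - mu ** 2 - np.exp(lv)).sum() / B)

    g = {}
    dlogits = (r - X) / B
    g["Wd3"] = d2.T @ dlogits; g["bd3"] = dlogits.sum(0)
    dd2 = (dlogits @ w["Wd3"].T) * (ad2 > 0)
    g["Wd2"] = cat.T @ dd2; g["bd2"] = dd2.sum(0)
    dcat = dd2 @ w["Wd2"].T
    dd1 = dcat[:, : d1.shape[1]] * (ad1 > 0)
    g["Wd1"] = z.T @ dd1; g["bd1"] = dd1.sum(0)
    dz = dd1 @ w["Wd1"].T
    dmu = dz + mu / B
    dlv = dz * eps * 0.5 * std + 0.5 * (np.exp(lv) - 1.0) / B
    g["Wmu"] = h2.T @ dmu; g["bmu"] = dmu.sum(0)
    g["Wlv"] = h2.T @ dlv; g["blv"] = dlv.sum(0)
    dh2 = (dmu @ w["Wmu"].T + dlv @ w["Wlv"].T) * (a2 > 0)
    g["We2"] = h1.T @ dh2; g["be2"] = dh2.sum(0)
    dh1 = (dh2 @ w["We2"].T) * (a1 > 0)
    g["We1"] = X.T @ dh1; g["be1"] = dh1.sum(0)
    return g, recon, kl


def train(X: np.ndarray, y: np.ndarray, config: CVAEConfig | None = None,
          seed: int = 0) -> tuple[CVAEParams, dict[str, list[float]]]:
    """Train by minibatch SGD with momentum; returns params and loss history.

    ``X`` must already be scaled to [0, 1] (see :func:`fit_minmax`); the
    history holds per-epoch means of total/recon/kl per sample.
    """
    config = config or CVAEConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"X must be (n, {N_FEATURES})")
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError("X must be scaled to [0, 1] before training")
    if len(np.unique(y)) != 2:
        raise ValueError("training requires both classes")
    onehot = _one_hot(y)
    rng = np.random.default_rng(seed)
    params = init_params(config, seed=seed)
    w = params.weights
    vel = {k: np.zeros_like(v) for k, v in w.items()}
    history: dict[str, list[float]] = {"total": [], "recon": [], "kl": []}
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_rec, ep_kl, n_batches = 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            eps = rng.standard_normal((idx.size, config.z_dim))
            g, rec, kl = _forward_backward(w, X[idx], onehot[idx], eps)
            if not np.isfinite(rec + kl):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            for k in w:
                vel[k] = config.momentum * vel[k] - config.learning_rate * g[k]
                w[k] = w[k] + vel[k]
            ep_rec += rec
            ep_kl += kl
            n_batches += 1
        history["recon"].append(ep_rec / n_batches)
        history["kl"].append(ep_kl / n_batches)
        history["total"].append((ep_rec + ep_kl) / n_batches)
    params.trained = True
    return params, history


def classify(x: np.ndarray, params: CVAEParams) -> tuple[str, dict[str, float]]:
    """Label whose conditional ELBO (z at the posterior mean) is smallest."""
    if not params.trained:
        raise ValueError("classify requires trained parameters")
    post = encode(x, params)
    scores = {}
    for lab in LABELS:
        recon = decode(post.mean, lab, params)
        scores[lab] = elbo_loss(x, recon, post).total
    label = min(scores, key=scores.get)
    return label, scores


def classify_batch(X: np.ndarray, params: CVAEParams) -> np.ndarray:
    """Vectorized argmin-ELBO labels (0 = benign, 1 = malignant)."""
    if not params.trained:
        raise ValueError("classify requires trained parameters")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    post = encode(X, params)
    totals = []
    for lab in LABELS:
        recon = decode(post.mean, [lab] * X.shape[0], params)
        rec = -(X * np.log(recon) + (1 - X) * np.log(1 - recon)).sum(axis=1)
        kl = -0.5 * (1 + post.logvar - post.mean ** 2
                     - np.exp(post.logvar)).sum(axis=1)
        totals.append(rec + kl)
    return np.argmin(np.stack(totals), axis=0)


# ---------------------------------------------------------------------------
# Feature scaling and persistence
# ---------------------------------------------------------------------------


def fit_minmax(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise (min, max) for scaling features into [0, 1]."""
    X = np.asarray(X, dtype=np.float64)
    return X.min(axis=0), X.max(axis=0)


def apply_minmax(X: np.ndarray, x_min: np.ndarray, x_max: np.ndarray) -> np.ndarray:
    span = np.where(x_max > x_min, x_max - x_min, 1.0)
    return np.clip((np.asarray(X, dtype=np.float64) - x_min) / span, 0.0, 1.0)


def save_params(params: CVAEParams, path: str | os.PathLike) -> None:
    """Archive weights (npz) with a JSON sidecar of sizes/scaler/seed."""
    np.savez(path, **params.weights,
             **({"x_min": params.x_min, "x_max": params.x_max}
                if params.x_min is not None else {}))
    sidecar = {
        "config": asdict(params.config),
        "trained": params.trained,
        "seed": params.seed,
        "has_scaler": params.x_min is not None,
    }
    with open(f"{os.fspath(path)}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_params(path: str | os.PathLike) -> CVAEParams:
    archive = f"{os.fspath(path)}" if os.fspath(path).endswith(".npz") else f"{path}.npz"
    if not os.path.exists(archive):
        archive = os.fspath(path)
    data = np.load(archive)
    with open(f"{os.fspath(path)}.json") as fh:
        sidecar = json.load(fh)
    weights = {k: data[k] for k in data.files if k not in ("x_min", "x_max")}
    return CVAEParams(
        weights=weights,
        config=CVAEConfig(**sidecar["config"]),
        x_min=data["x_min"] if sidecar["has_scaler"] else None,
        x_max=data["x_max"] if sidecar["has_scaler"] else None,
        trained=sidecar["trained"],
        seed=sidecar["seed"],
    )


# ---------------------------------------------------------------------------
# Hyperparameter tuning via the hybrid optimizer
# ---------------------------------------------------------------------------

DEFAULT_TUNE_SPACE = {
    "log10_lr": (-3.0, -1.0),
    "z_dim": (2, 16),
    "h1": (16, 96),
    "h2": (8, 48),
}


def tune_hyperparams(train_set: tuple[np.ndarray, np.ndarray],
                     val_set: tuple[np.ndarray, np.ndarray],
                     space: dict[str, tuple[float, float]] | None = None,
                     tune_epochs: int = 30, pop_size: int = 6,
                     t_max: int = 8, seed: int = 0) -> CVAEConfig:
    """Search (learning rate, z, h1, h2) by minimizing validation total loss.

    The optimizer works in the unit box and each coordinate is mapped
    affinely into its range, so degenerate (singleton) ranges are allowed.
    """
    space = dict(DEFAULT_TUNE_SPACE if space is None else space)
    if not space:
        raise ValueError("empty hyperparameter space")
    names = list(space.keys())
    los = np.array([space[n][0] for n in names], dtype=np.float64)
    his = np.array([space[n][1] for n in names], dtype=np.float64)
    Xtr, ytr = train_set
    Xva, yva = val_set

    def to_config(u: np.ndarray) -> CVAEConfig:
        vals = dict(zip(names, los + np.clip(u, 0, 1) * (his - los)))
        return CVAEConfig(
            h1=int(round(vals.get("h1", 64))),
            h2=int(round(vals.get("h2", 32))),
            z_dim=int(round(vals.get("z_dim", 8))),
            learning_rate=float(10.0 ** vals.get("log10_lr", -2.0)),
            epochs=tune_epochs,
        )

    def objective(u: np.ndarray) -> float:
        cfg = to_config(u)
        params, _ = train(Xtr, ytr, cfg, seed=seed)
        post = encode(Xva, params)
        recon = decode(post.mean, yva, params)
        rec = -(Xva * np.log(recon) + (1 - Xva) * np.log(1 - recon)).sum(axis=1)
        kl = -0.5 * (1 + post.logvar - post.mean ** 2
                     - np.exp(post.logvar)).sum(axis=1)
        return float((rec + kl).mean())

    from hybridpath.optimize import OptConfig, hybrid_optimize

    opt = OptConfig(pop_size=pop_size, dim=len(names), bounds=(0.0, 1.0),
                    t_max=t_max, seed=seed, mode="hybrid")
    result = hybrid_optimize(objective, opt)
    return to_config(result.best_position)
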