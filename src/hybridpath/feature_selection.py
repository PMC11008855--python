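"""Binary wrapper feature selection over the 33-feature vector.

The continuous hybrid optimizer searches [−4, 4]^33; positions are mapped to
selection bits through a sigmoid (S-shaped) transfer with stochastic
thresholding, and each candidate subset is scored by the cross-validated
error of a small k-NN classifier plus a sparsity penalty:

    fitness = α·err + (1 − α)·(n_selected / 33),   α = 0.99 by default.

The transfer draw for a given position is derived deterministically from the
position's bits and the run seed, so the objective is a pure function and a
run is exactly reproducible from its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from hybridpath.features import FAMILY_SLICES
from hybridpath.optimize import OptConfig, OptResult, hybrid_optimize

N_FEATURES = 33


@dataclass(frozen=True)
class SelectionMask:
    bits: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bits).astype(np.uint8)
        if b.shape != (N_FEATURES,):
            raise ValueError(f"selection mask must have length {N_FEATURES}")
        if b.sum() < 1:
            raise ValueError("selection mask must select at least one feature")
        object.__setattr__(self, "bits", b)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def family_counts(self) -> dict[str, int]:
        """Selected-feature counts per family (geometric/directional/intensity)."""
        return {fam: int(self.bits[sl].sum()) for fam, sl in FAMILY_SLICES.items()}


@dataclass
class FSConfig:
    alpha_w: float = 0.99        # weight of the error term vs the sparsity penalty
    knn_k: int = 5
    cv_folds: int = 3
    transfer: str = "s"          # "s" sigmoid or "v" |tanh| transfer
    optimizer: OptConfig = field(default_factory=lambda: OptConfig(
        pop_size=20, dim=N_FEATURES, bounds=(-4.0, 4.0), t_max=40, seed=0,
        mode="hybrid"))

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_w < 1.0:
            raise ValueError("alpha_w must be in (0, 1)")
        if self.transfer not in ("s", "v"):
            raise ValueError("transfer must be 's' or 'v'")


def _position_rng(position: np.ndarray, seed: int) -> np.random.Generator:
    """Deterministic generator keyed on (position bits, seed)."""
    digest = zlib.crc32(np.ascontiguousarray(position, dtype=np.float64).tobytes())
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


def transfer_binarize(position: np.ndarray, rng: np.random.Generator,
                      transfer: str = "s") -> SelectionMask:
    """Map a continuous position to selection bits via a transfer function.

    S-shaped: bit_j = 1 iff rand_j < sigmoid(x_j).  V-shaped: probability
    |tanh(x_j)|.  An all-zero draw is repaired by switching on the bit with
    the largest transfer probability.
    """
    x = np.asarray(position, dtype=np.float64)
    if x.shape != (N_FEATURES,):
        raise ValueError(f"position must have length {N_FEATURES}")
    if transfer == "s":
        prob = 1.0 / (1.0 + np.exp(-x))
    else:
        prob = np.abs(np.tanh(x))
    bits = (rng.random(N_FEATURES) < prob).astype(np.uint8)
    if bits.sum() == 0:
        bits[int(np.argmax(prob))] = 1
    return SelectionMask(bits=bits)


def fs_fitness(mask: SelectionMask, X: np.ndarray, y: np.ndarray,
               config: FSConfig) -> float:
    """Wrapper objective: α·(CV error of k-NN on selected columns) + sparsity."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"X must have {N_FEATURES} columns")
    cols = mask.bits.astype(bool)
    Xs = X[:, cols]
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.optimizer.seed)
    errs = []
    for tr, te in skf.split(Xs, y):
        clf = KNeighborsClassifier(n_neighbors=config.knn_k)
        clf.fit(Xs[tr], y[tr])
        errs.append(1.0 - float(np.mean(clf.predict(Xs[te]) == y[te])))
    err = float(np.mean(errs))
    return config.alpha_w * err + (1.0 - config.alpha_w) * mask.n_selected / N_FEATURES


def select_features(X: np.ndarray, y: np.ndarray,
                    config: FSConfig | None = None
                    ) -> tuple[SelectionMask, OptResult]:
    """Run the hybrid optimizer over subset space; return best mask and trace."""
    config = config or FSConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(y) < 30:
        raise ValueError("need at least 30 samples for wrapper selection")
    if len(np.unique(y)) != 2:
        raise ValueError("wrapper selection requires exactly two classes")
    seed = config.optimizer.seed

    def objective(position: np.ndarray) -> float:
        mask = transfer_binarize(position, _position_rng(position, seed),
                                 config.transfer)
        return fs_fitness(mask, X, y, config)

    result = hybrid_optimize(objective, config.optimizer)
    best_mask = transfer_binarize(result.best_position,
                                  _position_rng(result.best_position, seed),
                                  config.transfer)
    return best_mask, result
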