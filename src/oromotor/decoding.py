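"""Decoding tongue direction from population firing rates.

Two decoders mirror the analysis protocol:

* **KNN classification** — per-neuron z-scored firing rates, Euclidean
  K = 7 nearest-neighbour vote, stratified 80/20 train/test splits repeated
  100 times, with a fresh random 28-neuron subsample per iteration when the
  population is larger. Identical split seeds are reused when populations
  are compared (verified by recorded split hashes), and mixed-population
  runs replace a random 25-neuron subset of the first population with
  neurons from the second.
* **LSTM regression** — a recurrent network regresses the direction angle
  (continuous left-right angle for feeding; −45/0/45° spout targets for
  drinking) from z-scored binned counts, five-fold cross-validated on 85/15
  splits over five random 28-neuron groups; performance is mean R².
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from ._lstm import LSTMRegressor

__all__ = [
    "DecodeConfig",
    "DecodeResult",
    "KNNDirectionDecoder",
    "knn_decode",
    "mixed_population_decode",
    "feeding_to_three_classes",
    "rnn_decode",
    "performance_model",
]

#: Spout regression targets in degrees (left, middle, right).
SPOUT_ANGLES = {"L": -45.0, "M": 0.0, "R": 45.0}


@dataclass
class DecodeConfig:
    """Decoder configuration; defaults follow the standard protocol."""

    algorithm: str = "knn"
    k: int = 7
    n_neurons: int | None = 28
    train_frac: float = 0.8
    iterations: int = 100
    folds: int = 5
    hidden_units: int = 400
    epochs: int = 50
    n_groups: int = 5
    rnn_train_frac: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("K must be odd and >= 1")
        if not 0.0 < self.train_frac < 1.0 or not 0.0 < self.rnn_train_frac < 1.0:
            raise ValueError("train fractions must lie in (0, 1)")
        if self.iterations < 1 or self.folds < 2:
            raise ValueError("iterations >= 1 and folds >= 2 required")


@dataclass
class DecodeResult:
    """Per-iteration accuracies (%) or per-fold R² with configuration."""

    values: np.ndarray
    metric: str
    config: dict
    split_hashes: list[str] = field(default_factory=list)
    population: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _split_seeds(seed: int, iterations: int) -> np.ndarray:
    """Per-iteration split seeds derived only from (seed, iteration).

    Populations compared under the same config seed therefore share
    identical train/test partitions.
    """
    return np.random.SeedSequence(seed).generate_state(iterations) % (2 ** 31)


def _zscore_train(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


class KNNDirectionDecoder(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbour direction classifier on z-scored rates.

    ``fit``/``predict`` provide the plain single-split estimator (z-scoring
    parameters estimated on the training data only); :meth:`evaluate` runs
    the full iterated protocol and returns a :class:`DecodeResult`.
    """

    def __init__(self, k: int = 7, n_neurons: int | None = 28,
                 train_frac: float = 0.8, iterations: int = 100, seed: int = 0):
        self.k = k
        self.n_neurons = n_neurons
        self.train_frac = train_frac
        self.iterations = iterations
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNDirectionDecoder":
        X = np.asarray(X, dtype=float)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._knn = KNeighborsClassifier(n_neighbors=self.k)
        self._knn.fit((X - self._mu) / self._sd, y)
        self.classes_ = self._knn.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._knn.predict((np.asarray(X, dtype=float) - self._mu) / self._sd)

    def evaluate(self, X: np.ndarray, y: np.ndarray,
                 columns_per_iteration: list[np.ndarray] | None = None
                 ) -> DecodeResult:
        """Iterated stratified-split evaluation; accuracy in percent.

        ``columns_per_iteration`` overrides the per-iteration neuron
        subsample (used by the mixed-population protocol).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, cls_counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        if cls_counts.min() < 2:
            raise ValueError("need at least two trials per class")
        seeds = _split_seeds(self.seed, self.iterations)
        col_rng = np.random.default_rng(np.random.SeedSequence((self.seed, 9173)))
        accs = np.empty(self.iterations)
        hashes = []
        idx_all = np.arange(X.shape[0])
        for it in range(self.iterations):
            tr_idx, te_idx = train_test_split(
                idx_all, train_size=self.train_frac,
                random_state=int(seeds[it]), stratify=y)
            if columns_per_iteration is not None:
                cols = columns_per_iteration[it]
            elif self.n_neurons is not None and X.shape[1] > self.n_neurons:
                cols = col_rng.choice(X.shape[1], size=self.n_neurons, replace=False)
            else:
                cols = np.arange(X.shape[1])
            Xtr, Xte = _zscore_train(X[np.ix_(tr_idx, cols)], X[np.ix_(te_idx, cols)])
            knn = KNeighborsClassifier(n_neighbors=self.k)
            knn.fit(Xtr, y[tr_idx])
            accs[it] = 100.0 * np.mean(knn.predict(Xte) == y[te_idx])
            hashes.append(hashlib.sha1(np.sort(te_idx).astype(np.int64).tobytes())
                          .hexdigest()[:12])
        return DecodeResult(values=accs, metric="accuracy_pct",
                            config={"k": self.k, "n_neurons": self.n_neurons,
                                    "train_frac": self.train_frac,
                                    "iterations": self.iterations, "seed": self.seed},
                            split_hashes=hashes)


def knn_decode(rates: np.ndarray, labels: np.ndarray,
               cfg: DecodeConfig | None = None) -> DecodeResult:
    """Run the iterated KNN protocol with a :class:`DecodeConfig`."""
    cfg = cfg or DecodeConfig()
    cfg.validate()
    dec = KNNDirectionDecoder(k=cfg.k, n_neurons=cfg.n_neurons,
                              train_frac=cfg.train_frac,
                              iterations=cfg.iterations, seed=cfg.seed)
    return dec.evaluate(rates, labels)


def mixed_population_decode(rates_a: np.ndarray, rates_b: np.ndarray,
                            labels: np.ndarray, replace: int = 25,
                            cfg: DecodeConfig | None = None
                            ) -> dict[str, DecodeResult]:
    """Replace ``replace`` random neurons of population A with B neurons.

    Each of the configured iterations swaps a fresh random subset; the
    baseline decodes the full first population on identical train/test
    splits. Returns ``{"baseline": ..., "mixed": ...}``.
    """
    cfg = cfg or DecodeConfig()
    cfg.validate()
    na, nb = rates_a.shape[1], rates_b.shape[1]
    if replace > na or replace > nb:
        raise ValueError(f"replace={replace} exceeds a population size ({na}, {nb})")
    if rates_a.shape[0] != rates_b.shape[0]:
        raise ValueError("populations must share trials")
    dec = KNNDirectionDecoder(k=cfg.k, n_neurons=None, train_frac=cfg.train_frac,
                              iterations=cfg.iterations, seed=cfg.seed)
    baseline = dec.evaluate(rates_a, labels)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 40717)))
    X = np.concatenate([rates_a, rates_b], axis=1)
    cols = []
    for _ in range(cfg.iterations):
        drop = rng.choice(na, size=replace, replace=False)
        keep_a = np.setdiff1d(np.arange(na), drop)
        add_b = na + rng.choice(nb, size=replace, replace=False)
        cols.append(np.concatenate([keep_a, add_b]))
    mixed = dec.evaluate(X, labels, columns_per_iteration=cols)
    assert baseline.split_hashes == mixed.split_hashes
    return {"baseline": baseline, "mixed": mixed}


def feeding_to_three_classes(lr_angles: np.ndarray) -> np.ndarray:
    """Tripartition of the left-right angle range into 20° bands.

    left: [−30°, −10°), middle: [−10°, 10°), right: [10°, 30°); angles
    outside [−30°, 30°) map to ``None`` (excluded).
    """
    a = np.asarray(lr_angles, dtype=float)
    out = np.full(a.shape, None, dtype=object)
    out[(a >= -30.0) & (a < -10.0)] = "left"
    out[(a >= -10.0) & (a < 10.0)] = "middle"
    out[(a >= 10.0) & (a < 30.0)] = "right"
    return out


def rnn_decode(counts: np.ndarray, targets: np.ndarray,
               cfg: DecodeConfig | None = None) -> pd.DataFrame:
    """LSTM regression of direction angle from binned counts.

    ``counts`` is (intervals, neurons) in time order, ``targets`` the
    direction angle per interval (degrees). For each of ``cfg.n_groups``
    random 28-neuron groups (with replacement), the interval sequence is
    split into ``cfg.folds`` contiguous folds; per fold the network trains
    on the remaining intervals (z-scored with training statistics) and
    predicts the held-out fold stepwise. Returns a tidy DataFrame with one
    R² per (group, fold).
    """
    cfg = cfg or DecodeConfig(algorithm="rnn")
    cfg.validate()
    X = np.asarray(counts, dtype=float)
    yt = np.asarray(targets, dtype=float)
    T, N = X.shape
    if T < cfg.folds:
        raise ValueError("fewer intervals than folds")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 5521)))
    n_sel = min(cfg.n_neurons or N, N)
    fold_edges = np.array_split(np.arange(T), cfg.folds)
    rows = []
    for grp in range(cfg.n_groups):
        # neuron groups are drawn with replacement when subsampling a larger
        # population; a group spanning the whole population keeps every neuron
        cols = rng.choice(N, size=n_sel, replace=n_sel < N)
        Xg = X[:, cols]
        for fold, te_idx in enumerate(fold_edges):
            tr_mask = np.ones(T, dtype=bool)
            tr_mask[te_idx] = False
            Xtr, Xte = _zscore_train(Xg[tr_mask], Xg[te_idx])
            net = LSTMRegressor(n_hidden=cfg.hidden_units, epochs=cfg.epochs,
                                seed=int(rng.integers(2 ** 31)))
            net.fit(Xtr, yt[tr_mask])
            pred = net.predict(Xte)
            rows.append({"group": grp, "fold": fold,
                         "r2": r2_score(yt[te_idx], pred)})
    return pd.DataFrame(rows)


def performance_model(results: pd.DataFrame, response: str = "accuracy",
                      factors: tuple[str, ...] = ("behavior", "region",
                                                  "subject", "condition")):
    """OLS with pairwise interactions comparing decoding performance.

    Factors with a single observed level are dropped. Returns the fitted
    statsmodels results object (coefficient table with p-values).
    """
    import statsmodels.formula.api as smf

    usable = [f for f in factors if f in results.columns
              and results[f].nunique() >= 2]
    if not usable:
        raise ValueError("need at least one factor with >= 2 levels")
    terms = " + ".join(f"C({f})" for f in usable)
    formula = f"{response} ~ ({terms})**2" if len(usable) > 1 else f"{response} ~ {terms}"
    return smf.ols(formula, data=results).fit()
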