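"""Training loop, splits, cross-validated grid search, AUC and model comparison.

Protocol: a stratified 8:2 train/test split, five-fold cross-validation
on the training portion for hyperparameter tuning, per-epoch validation
AUC bookkeeping (up to 30 epochs) with the best (configuration, epoch)
pair chosen by the five-fold mean AUC, then retraining on the full
training set for that many epochs.  AUC is the rank-based (Mann-Whitney)
statistic with ties counted 1/2; paired model comparison uses the
two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata, wilcoxon
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoding import EncodedSequence
from .model import Batch, ModelConfig, TSANNModel, VariantSpec, cross_entropy, pad_batch

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "Hyperparams",
    "HyperGrid",
    "full_grid",
    "desk_grid",
    "make_splits",
    "auc",
    "compare_models",
    "train",
    "evaluate",
    "grid_search_cv",
    "lr_features",
    "train_lr",
]


@dataclass
class SplitPlan:
    """Deterministic stratified 8:2 split plus 5-fold partition of the train ids."""

    train_ids: list[int]
    test_ids: list[int]
    folds: list[tuple[np.ndarray, np.ndarray]]  # (fold-train, fold-val) positions into train_ids
    seed: int


@dataclass(frozen=True)
class Hyperparams:
    learning_rate: float = 0.001
    l2: float = 0.0001
    batch_size: int = 32
    activation: str = "leaky_relu"
    batch_norm: bool = False
    optimizer: str = "adam"
    max_epochs: int = 30
    class_weight: tuple[float, float] = (1.0, 1.0)


@dataclass
class HyperGrid:
    learning_rate: list[float] = field(default_factory=lambda: [0.0005, 0.001, 0.005, 0.01])
    l2: list[float] = field(default_factory=lambda: [0.0001, 0.0005, 0.001])
    batch_size: list[int] = field(default_factory=lambda: [32, 64, 128])
    activation: list[str] = field(default_factory=lambda: ["relu", "leaky_relu"])
    batch_norm: list[bool] = field(default_factory=lambda: [True, False])
    optimizer: list[str] = field(default_factory=lambda: ["rmsprop", "adam"])
    max_epochs: int = 30

    def points(self) -> list[Hyperparams]:
        combos = itertools.product(
            self.learning_rate, self.l2, self.batch_size,
            self.activation, self.batch_norm, self.optimizer,
        )
        return [
            Hyperparams(lr, l2, bs, act, bn, opt, self.max_epochs)
            for lr, l2, bs, act, bn, opt in combos
        ]


def full_grid() -> HyperGrid:
    """The complete tuning grid of the emulated protocol (288 points)."""
    return HyperGrid()


def desk_grid(max_epochs: int = 10) -> HyperGrid:
    """A restricted grid for desk-scale runs: one optimizer, two learning rates."""
    return HyperGrid(
        learning_rate=[0.001, 0.005], l2=[0.0001], batch_size=[64],
        activation=["leaky_relu"], batch_norm=[False], optimizer=["adam"],
        max_epochs=max_epochs,
    )


# ---------------------------------------------------------------------- #
# splits & metrics

def make_splits(labels: np.ndarray, seed: int, test_size: float = 0.2,
                n_folds: int = 5) -> SplitPlan:
    """Stratified 8:2 split and stratified K-fold partition, deterministic in seed."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to build splits")
    idx = np.arange(len(labels))
    train_ids, test_ids = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=labels
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr, va) for tr, va in skf.split(train_ids, labels[train_ids])]
    return SplitPlan(train_ids.tolist(), test_ids.tolist(), folds, seed)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count one half.

    Equals the probability that a random case outscores a random control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compare_models(auc_samples_a, auc_samples_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired AUC samples."""
    a = np.asarray(auc_samples_a, dtype=float)
    b = np.asarray(auc_samples_b, dtype=float)
    if a.shape != b.shape or len(a) < 5:
        raise ValueError("paired samples of equal length >= 5 required")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; returning p = 1")
        return 1.0
    return float(wilcoxon(a, b).pvalue)


# ---------------------------------------------------------------------- #
# optimizers

class _Optimizer:
    def __init__(self, params: dict, lr: float):
        self.params = params
        self.lr = lr
        self.state = {k: {} for k in params}
        self.t = 0

    def step(self):
        raise NotImplementedError


class _Adam(_Optimizer):
    def step(self, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            st = self.state[k]
            st.setdefault("m", np.zeros_like(p.data))
            st.setdefault("v", np.zeros_like(p.data))
            st["m"] = b1 * st["m"] + (1 - b1) * p.grad
            st["v"] = b2 * st["v"] + (1 - b2) * p.grad**2
            mhat = st["m"] / (1 - b1**self.t)
            vhat = st["v"] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)


class _RMSprop(_Optimizer):
    def step(self, rho=0.9, eps=1e-8):
        for k, p in self.params.items():
            if p.grad is None:
                continue
            st = self.state[k]
            st.setdefault("v", np.zeros_like(p.data))
            st["v"] = rho * st["v"] + (1 - rho) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(st["v"]) + eps)


_OPTIMIZERS = {"adam": _Adam, "rmsprop": _RMSprop}


# ---------------------------------------------------------------------- #
# training

def train(
    model: TSANNModel,
    train_data: list[EncodedSequence],
    val_data: list[EncodedSequence] | None,
    hyper: Hyperparams,
    seed: int = 0,
) -> tuple[TSANNModel, list[float]]:
    """Mini-batch training with an L2 penalty on all parameters.

    Records the validation AUC after each epoch (empty history when no
    validation set is supplied).  Raises on non-finite loss.
    """
    opt = _OPTIMIZERS[hyper.optimizer](model.params, hyper.learning_rate)
    rng = np.random.default_rng(seed)
    history: list[float] = []
    n = len(train_data)
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, hyper.batch_size):
            batch = pad_batch([train_data[j] for j in order[start:start + hyper.batch_size]])
            for p in model.params.values():
                p.grad = None
            logits, _ = model.forward(batch, training=True)
            loss = cross_entropy(logits, batch.labels, hyper.class_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss.data}")
            loss.backward()
            if hyper.l2 > 0:  # l2 penalty for all parameters
                for p in model.params.values():
                    if p.grad is not None:
                        p.grad += 2.0 * hyper.l2 * p.data
            opt.step()
        if val_data:
            history.append(auc(model.predict_proba(val_data), [s.label for s in val_data]))
    return model, history


def evaluate(model: TSANNModel, data: list[EncodedSequence]) -> tuple[np.ndarray, float]:
    """Score a dataset; returns (scores, AUC)."""
    scores = model.predict_proba(data)
    return scores, auc(scores, [s.label for s in data])


def grid_search_cv(
    data: list[EncodedSequence],
    plan: SplitPlan,
    grid: HyperGrid,
    variant: VariantSpec,
    config: ModelConfig,
    vocab_size: int,
    seed: int = 0,
) -> dict:
    """Five-fold grid search with best-epoch selection.

    For each grid point, trains on each fold's train portion and records
    the fold-out AUC per epoch; selects the (point, epoch) maximizing
    the 5-fold mean AUC, then retrains on the full training set with
    that configuration for that many epochs.  Returns a dict with keys
    ``best_hyper``, ``best_epoch`` (1-based), ``best_mean_auc``,
    ``cv_table`` (point -> fold x epoch AUC array), ``model``,
    ``test_auc`` and ``test_scores``.
    """
    points = grid.points()
    if not points:
        raise ValueError("empty hyperparameter grid")
    train_set = [data[i] for i in plan.train_ids]
    cv_table: dict[Hyperparams, np.ndarray] = {}
    best = (-np.inf, None, None)
    for hp in points:
        fold_aucs = np.zeros((len(plan.folds), hp.max_epochs))
        for f, (tr, va) in enumerate(plan.folds):
            cfg = replace(config, activation=hp.activation, batch_norm=hp.batch_norm)
            m = TSANNModel(variant, cfg, vocab_size, seed=seed + f)
            _, hist = train(
                m, [train_set[i] for i in tr], [train_set[i] for i in va], hp, seed=seed + f
            )
            fold_aucs[f, : len(hist)] = hist
        cv_table[hp] = fold_aucs
        means = fold_aucs.mean(axis=0)
        e = int(np.argmax(means))
        if means[e] > best[0]:
            best = (float(means[e]), hp, e + 1)
    best_mean, best_hp, best_epoch = best
    logger.info("best grid point %s at epoch %d (mean CV AUC %.4f)", best_hp, best_epoch, best_mean)
    cfg = replace(config, activation=best_hp.activation, batch_norm=best_hp.batch_norm)
    final = TSANNModel(variant, cfg, vocab_size, seed=seed)
    train(final, train_set, None, replace(best_hp, max_epochs=best_epoch), seed=seed)
    test_set = [data[i] for i in plan.test_ids]
    scores, test_auc = evaluate(final, test_set)
    return {
        "best_hyper": best_hp,
        "best_epoch": best_epoch,
        "best_mean_auc": best_mean,
        "cv_table": cv_table,
        "model": final,
        "test_auc": test_auc,
        "test_scores": scores,
    }


# ---------------------------------------------------------------------- #
# logistic-regression baseline (bag-of-codes features)

def lr_features(data: list[EncodedSequence], vocab_size: int,
                use_time: bool = False) -> np.ndarray:
    """Frequency features for the LR baseline.

    Without time: counts of each code over the window.  With time, each
    code is crossed with the month bucket of its visit's gap (month as
    the time unit), expanding the feature space to vocab x 13 buckets.
    """
    n_buckets = 13 if use_time else 1
    X = np.zeros((len(data), vocab_size * n_buckets))
    for r, seq in enumerate(data):
        for idxs, gap in seq.visits:
            b = min(gap // 30, 12) if use_time else 0
            for i in idxs:
                X[r, b * vocab_size + i] += 1.0
    return X


def _oversample(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random minority oversampling (duplication with replacement) to 1:1."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    need = counts.max() - counts.min()
    if need == 0:
        return X, y
    pick = rng.choice(np.flatnonzero(y == minority), size=need, replace=True)
    return np.vstack([X, X[pick]]), np.concatenate([y, y[pick]])


def train_lr(
    train_data: list[EncodedSequence],
    vocab_size: int,
    use_time: bool = False,
    oversample: str | None = "random",
    seed: int = 0,
    C: float = 1.0,
) -> tuple[LogisticRegression, callable]:
    """Fit the logistic-regression baseline; returns (model, scoring function)."""
    X = lr_features(train_data, vocab_size, use_time)
    y = np.asarray([s.label for s in train_data])
    if oversample == "random":
        X, y = _oversample(X, y, seed)
    clf = LogisticRegression(max_iter=2000, C=C, random_state=seed)
    clf.fit(X, y)

    def score(data: list[EncodedSequence]) -> np.ndarray:
        return clf.predict_proba(lr_features(data, vocab_size, use_time))[:, 1]

    return clf, score
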