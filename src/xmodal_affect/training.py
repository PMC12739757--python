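"""Training protocol and cross-validated evaluation.

Models are trained with mini-batch Adam on the sum of cross-entropy and
an L2 penalty, and assessed by stratified k-fold cross-validation with a
fresh, fold-seeded model per fold.  Accuracy is correct/total (in the
binary case (TP+TN)/(TP+TN+FP+FN)); per-fold confusion matrices and
training histories are kept in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold

from .model import CrossAttentionClassifier, ModelConfig

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CVReport",
    "FeaturizedDataset",
    "QUADRANT_NAMES",
    "compute_loss",
    "binarize_deap_labels",
    "deap_quadrant_labels",
    "kfold_split",
    "fit",
    "fold_from_predictions",
    "evaluate",
    "run_cv",
]

logger = logging.getLogger(__name__)

#: Canonical valence/arousal quadrant order (high/low arousal x valence).
QUADRANT_NAMES = ("HAHV", "HALV", "LAHV", "LALV")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, lr 0.001, batch 64, CE + L2 loss."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    l2_lambda: float = 1e-4
    optimizer: str = "adam"
    n_folds: int = 5
    seed: int = 0
    task: str = "valence"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class FoldResult:
    """Evaluation artifacts for one cross-validation fold."""

    fold_index: int
    predictions: np.ndarray
    truths: np.ndarray
    accuracy: float
    confusion: np.ndarray
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "predictions": self.predictions.tolist(),
            "truths": self.truths.tolist(),
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "history": self.history,
        }


@dataclass
class CVReport:
    """Aggregated cross-validation outcome."""

    folds: list[FoldResult]
    mean_accuracy: float
    sd_accuracy: float
    per_subject_accuracy: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "per_subject_accuracy": self.per_subject_accuracy,
            "folds": [f.to_dict() for f in self.folds],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


@dataclass
class FeaturizedDataset:
    """Aligned feature tensors for every trial: [N, T, F] per modality + labels."""

    X_eeg: np.ndarray
    X_peri: np.ndarray
    y: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X_eeg = np.asarray(self.X_eeg, dtype=float)
        self.X_peri = np.asarray(self.X_peri, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.X_eeg) == len(self.X_peri) == len(self.y)):
            raise ValueError("modalities and labels must have equal trial counts")
        if self.X_eeg.shape[1] != self.X_peri.shape[1]:
            raise ValueError("EEG and peripheral sequences must have equal window counts")

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# Loss and labels
# ---------------------------------------------------------------------------

def compute_loss(probabilities: np.ndarray, truths: np.ndarray,
                 weights=(), l2_lambda: float = 0.0) -> float:
    """Mean cross-entropy over the batch plus ``l2_lambda * sum(w**2)``.

    A zero probability at the true class is clamped to 1e-12 (and
    logged) rather than producing an infinite loss.
    """
    probs = np.asarray(probabilities, dtype=float)
    truths = np.asarray(truths, dtype=int)
    p_true = probs[np.arange(len(truths)), truths]
    if np.any(p_true < 1e-12):
        logger.warning("zero probability at true class clamped to 1e-12")
    ce = -float(np.mean(np.log(np.clip(p_true, 1e-12, None))))
    l2 = sum(float(np.sum(np.asarray(w) ** 2)) for w in weights)
    return ce + l2_lambda * l2


def binarize_deap_labels(ratings: np.ndarray, dimension: str = "valence") -> np.ndarray:
    """High/low split of 1-9 self-assessment ratings: rating > 5 is high (1)."""
    if dimension not in ("valence", "arousal"):
        raise ValueError(f"dimension must be 'valence' or 'arousal', got {dimension!r}")
    r = np.asarray(ratings, dtype=float)
    if np.any((r < 1) | (r > 9)):
        raise ValueError("ratings must lie in [1, 9]")
    return (r > 5).astype(int)


def deap_quadrant_labels(valence: np.ndarray, arousal: np.ndarray) -> np.ndarray:
    """Four-class valence-arousal quadrants, ordered (HAHV, HALV, LAHV, LALV)."""
    v = binarize_deap_labels(valence, "valence")
    a = binarize_deap_labels(arousal, "arousal")
    return 2 * (1 - a) + (1 - v)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def kfold_split(n_samples: int, n_folds: int, labels: np.ndarray | None = None,
                seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold indices, stratified by label where class counts allow."""
    if n_samples < n_folds:
        raise ValueError(f"cannot split {n_samples} samples into {n_folds} folds")
    if labels is not None:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() >= n_folds:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            return [(tr, te) for tr, te in splitter.split(np.zeros(n_samples), labels)]
        logger.warning("class counts too small for stratification; plain k-fold used")
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n_samples))]


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class _Adam:
    """Adam with bias correction (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def fit(model: CrossAttentionClassifier,
        train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
        config: TrainConfig) -> list[dict]:
    """Mini-batch training; returns the per-epoch (loss, accuracy) history.

    The epoch shuffling RNG is seeded from ``config.seed`` and dropout
    from the model's own seed, so identical seeds give identical final
    weights.  A NaN loss aborts with a diagnostic.
    """
    X_eeg, X_peri, y = train_data
    if len(y) == 0:
        raise ValueError("training data must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = model.forward(X_eeg[idx], X_peri[idx], mode="train",
                                         update_stats=True, rng=model._dropout_rng)
            loss = model.loss(probs, y[idx], config.l2_lambda)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at epoch {epoch}, batch start {start}"
                )
            grads = model.backward(cache, y[idx], config.l2_lambda)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
            correct += int(np.sum(np.argmax(probs, axis=1) == y[idx]))
        history.append({
            "epoch": epoch,
            "loss": epoch_loss / len(y),
            "accuracy": correct / len(y),
        })
    return history


def fold_from_predictions(predictions: np.ndarray, truths: np.ndarray, n_classes: int,
                          fold_index: int = 0,
                          history: list[dict] | None = None) -> FoldResult:
    """Accuracy and confusion matrix from prediction/truth vectors.

    Accuracy is correct/total, i.e. (TP+TN)/(TP+TN+FP+FN) in the binary
    case, and always equals the confusion-matrix trace over its total.
    """
    preds = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    conf = confusion_matrix(truths, preds, labels=np.arange(n_classes))
    accuracy = float(np.trace(conf) / conf.sum())
    return FoldResult(fold_index, preds, truths, accuracy, conf, history or [])


def evaluate(model: CrossAttentionClassifier,
             test_data: tuple[np.ndarray, np.ndarray, np.ndarray],
             fold_index: int = 0, history: list[dict] | None = None) -> FoldResult:
    """Accuracy (correct/total) and confusion matrix on held-out trials."""
    X_eeg, X_peri, y = test_data
    if len(y) == 0:
        raise ValueError("test data must be non-empty")
    preds = model.predict(X_eeg, X_peri)
    return fold_from_predictions(preds, y, model.config.n_classes, fold_index, history)


def run_cv(dataset: FeaturizedDataset, model_config: ModelConfig,
           train_config: TrainConfig, *, shuffle_train_labels: bool = False) -> CVReport:
    """Stratified k-fold cross-validation with a fresh model per fold.

    Features are z-scored per fold using training-fold statistics.  Each
    fold's model is re-initialized from a fold-specific seed so no state
    leaks between folds.  ``shuffle_train_labels`` permutes the training
    labels within each fold (test labels untouched) — a leakage control
    that must drive accuracy to chance.
    """
    splits = kfold_split(len(dataset), train_config.n_folds, dataset.y,
                         seed=train_config.seed)
    folds: list[FoldResult] = []
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(train_config.seed, spawn_key=(97,)))
    for fold_index, (train_idx, test_idx) in enumerate(splits):
        stats = []
        norm = {}
        for name, X in (("eeg", dataset.X_eeg), ("peri", dataset.X_peri)):
            mu = X[train_idx].mean(axis=(0, 1))
            sd = X[train_idx].std(axis=(0, 1))
            norm[name] = (mu, np.maximum(sd, 1e-8))
        Xe = (dataset.X_eeg - norm["eeg"][0]) / norm["eeg"][1]
        Xp = (dataset.X_peri - norm["peri"][0]) / norm["peri"][1]

        y_train = dataset.y[train_idx].copy()
        if shuffle_train_labels:
            shuffle_rng.shuffle(y_train)

        fold_model_config = dataclasses.replace(
            model_config, seed=model_config.seed + 1000 * (fold_index + 1))
        fold_train_config = dataclasses.replace(
            train_config, seed=train_config.seed + 1000 * (fold_index + 1))
        model = CrossAttentionClassifier(fold_model_config,
                                         dataset.X_eeg.shape[2], dataset.X_peri.shape[2])
        history = fit(model, (Xe[train_idx], Xp[train_idx], y_train), fold_train_config)
        fold = evaluate(model, (Xe[test_idx], Xp[test_idx], dataset.y[test_idx]),
                        fold_index, history)
        logger.info("fold %d: accuracy %.4f", fold_index, fold.accuracy)
        folds.append(fold)

    accs = np.array([f.accuracy for f in folds])
    per_subject: dict[str, float] = {}
    if dataset.subjects is not None:
        subj = np.asarray(dataset.subjects)
        correct = np.zeros(len(dataset), dtype=bool)
        for fold, (_, test_idx) in zip(folds, splits):
            correct[test_idx] = fold.predictions == fold.truths
        for s in np.unique(subj):
            per_subject[str(s)] = float(correct[subj == s].mean())
    return CVReport(folds, float(accs.mean()), float(accs.std()), per_subject)
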