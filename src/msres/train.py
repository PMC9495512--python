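"""Training protocol and binary-classification evaluation suite.

Training follows the published protocol: Adam (lr 0.001), batch size 128,
binary cross-entropy on a single sigmoid output, 50 epochs by default, with
stratified 5-fold cross-validation as the headline evaluation.  The metric
suite computes the confusion matrix, precision/recall/accuracy/F1 and
threshold-swept PR and ROC curves from first principles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balance import BalanceConfig, balance_training_set
from .model.config import MsResConfig
from .model.network import MsResNet, _sigmoid, build_model
from .preprocess import SegmentSet, make_folds

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "EvalReport",
    "bce_loss",
    "confusion",
    "metrics",
    "curves",
    "train_model",
    "evaluate_model",
    "cross_validate",
    "CVResult",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 50
    optimizer: str = "adam"  # adam | adadelta | adagrad
    seed: int = 0
    threshold: float = 0.5
    validation_fraction: float = 0.0  # history-only validation split
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer not in ("adam", "adadelta", "adagrad"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# losses and metrics
# ---------------------------------------------------------------------------

def bce_loss(y: np.ndarray, yhat: np.ndarray, eps: float = _EPS) -> float:
    """Mean binary cross-entropy, -mean[y log p + (1-y) log(1-p)].

    Predicted probabilities are clipped to [eps, 1-eps] so perfect (0/1)
    predictions stay finite.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs yhat {yhat.shape}")
    p = np.clip(yhat, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/FN/TN of binary predictions (positive class = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 entries")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionMatrix(tp, fp, fn, tn)


def metrics(cm: ConfusionMatrix) -> dict:
    """Precision, recall, accuracy, F1 from a confusion matrix.

    A degenerate denominator (no predicted positives, no true positives,
    or an undefined F1) reports the affected metric as 0.0 and records a
    flag instead of raising, so fold aggregation never aborts.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, flags = 0.0, flags + ["precision_undefined"]
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, flags = 0.0, flags + ["recall_undefined"]
    accuracy = (cm.tp + cm.tn) / cm.total
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, flags = 0.0, flags + ["f1_undefined"]
    return {
        "precision": precision,
        "recall": recall,
        "accuracy": accuracy,
        "f1": f1,
        "flags": tuple(flags),
    }


def curves(y_true: np.ndarray, scores: np.ndarray):
    """Threshold-swept PR and ROC curves plus the trapezoidal ROC AUC.

    Thresholds sweep every unique score (descending).  The ROC curve is
    returned as (fpr, tpr) pairs from (0, 0) to (1, 1); the PR curve as
    (recall, precision) pairs starting at recall 0.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("curves undefined: y_true contains a single class")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied score block
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps, fps = tps[last], fps[last]
    tpr = tps / n_pos
    fpr = fps / n_neg
    roc = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    precision = tps / (tps + fps)
    recall = tpr
    pr = np.column_stack([np.r_[0.0, recall], np.r_[1.0, precision]])
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return pr, roc, auc


@dataclass(frozen=True)
class EvalReport:
    """Scalar metrics plus curve points for one evaluation."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    confusion: ConfusionMatrix
    pr_points: np.ndarray | None = None
    roc_points: np.ndarray | None = None
    auc: float | None = None
    flags: tuple[str, ...] = ()

    def to_dict(self, include_curves: bool = False) -> dict:
        out = {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "fn": self.confusion.fn, "tn": self.confusion.tn,
            },
            "flags": list(self.flags),
        }
        if include_curves and self.pr_points is not None:
            out["pr_points"] = self.pr_points.tolist()
            out["roc_points"] = self.roc_points.tolist()
        return out


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


class Adagrad:
    def __init__(self, params, lr=0.001, eps=1e-8):
        self.params, self.lr, self.eps = params, lr, eps
        self.g2 = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, g2 in zip(self.params, self.g2):
            g2 += p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(g2) + self.eps)


class Adadelta:
    def __init__(self, params, lr=1.0, rho=0.95, eps=1e-6):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.g2 = [np.zeros_like(p.data) for p in params]
        self.dx2 = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, g2, dx2 in zip(self.params, self.g2, self.dx2):
            g2 *= self.rho
            g2 += (1 - self.rho) * p.grad**2
            dx = -np.sqrt(dx2 + self.eps) / np.sqrt(g2 + self.eps) * p.grad
            dx2 *= self.rho
            dx2 += (1 - self.rho) * dx**2
            p.data += self.lr * dx


def _make_optimizer(name: str, params, lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "adagrad":
        return Adagrad(params, lr=lr)
    return Adadelta(params)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(
    model: MsResNet,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> list[dict]:
    """Fit the model in place; returns the per-epoch history.

    Each epoch reshuffles (seeded), iterates full batches plus the trailing
    short batch, and records mean training loss and accuracy (and a
    validation pair when ``validation_fraction > 0``).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=np.float64)
    if len(X) == 0:
        raise ValueError("training set is empty")
    if len(np.unique(y)) < 2:
        import warnings

        warnings.warn("training data contain a single class; metrics will degenerate")
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_fraction * len(X)))
    if n_val > 0:
        perm = rng.permutation(len(X))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X, y = X[train_idx], y[train_idx]
    opt = _make_optimizer(config.optimizer, model.parameters(), config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(X))
        loss_sum = 0.0
        correct = 0
        for lo in range(0, len(X), config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb, train=True, rng=rng)
            probs = _sigmoid(logits.astype(np.float64))
            loss = bce_loss(yb, probs)
            model.zero_grad()
            model.backward((probs - yb) / len(yb))
            opt.step()
            loss_sum += loss * len(yb)
            correct += int(np.sum((probs >= config.threshold) == (yb == 1)))
        entry = {
            "epoch": epoch + 1,
            "loss": loss_sum / len(X),
            "accuracy": correct / len(X),
        }
        if n_val > 0:
            p_val = model.predict_proba(X_val)
            entry["val_loss"] = bce_loss(y_val, p_val)
            entry["val_accuracy"] = float(np.mean((p_val >= config.threshold) == (y_val == 1)))
        if config.verbose:
            print(
                "epoch {epoch:3d}  loss {loss:.4f}  acc {accuracy:.4f}".format(**entry)
                + ("  val_loss {val_loss:.4f}  val_acc {val_accuracy:.4f}".format(**entry)
                   if n_val > 0 else "")
            )
        history.append(entry)
    return history


def evaluate_model(
    model: MsResNet, X: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Confusion matrix, scalar metrics and PR/ROC curves on held-out data."""
    scores = model.predict_proba(X)
    y = np.asarray(y)
    cm = confusion(y, (scores >= threshold).astype(int))
    m = metrics(cm)
    flags = list(m["flags"])
    pr = roc = auc = None
    if len(np.unique(y)) == 2:
        pr, roc, auc = curves(y, scores)
    else:
        flags.append("curves_undefined_single_class")
    return EvalReport(
        precision=m["precision"], recall=m["recall"], accuracy=m["accuracy"],
        f1=m["f1"], confusion=cm, pr_points=pr, roc_points=roc, auc=auc,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class CVResult:
    fold_reports: tuple[EvalReport, ...]
    fold_histories: tuple[tuple, ...]
    mean: dict
    excluded_folds: tuple[int, ...] = ()


def cross_validate(
    segments: SegmentSet,
    k: int = 5,
    model_config: MsResConfig | None = None,
    train_config: TrainConfig | None = None,
    balance_config: BalanceConfig | None = None,
    seed: int = 0,
    balance_before_split: bool = False,
    verbose: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Each fold is held out exactly once.  By default the oversampler runs on
    the training folds only, so synthetic points never reach the held-out
    fold; ``balance_before_split=True`` reproduces the alternative order
    (balance the whole population, then fold) at the cost of synthetic
    points derived from test segments leaking into training.
    A held-out fold with a single class is flagged and excluded from the
    mean.
    """
    model_config = model_config or MsResConfig()
    train_config = train_config or TrainConfig()
    ss = np.random.SeedSequence(seed)
    fold_seed, balance_seed, *fold_seeds = [int(s) for s in ss.generate_state(2 + 2 * k)]
    X_all, y_all = segments.matrix, segments.labels
    if balance_before_split and balance_config is not None:
        X_bal, y_bal = balance_training_set(
            X_all, y_all,
            BalanceConfig(balance_config.method, balance_config.k_neighbors,
                          balance_config.sampling_strategy, balance_config.jitter_sd,
                          balance_seed),
        )
        extra = len(X_bal) - len(X_all)
        segments = SegmentSet(
            X_bal,
            y_bal,
            np.concatenate([segments.sources, np.array(["synthetic"] * extra, dtype=object)]),
            np.concatenate([segments.starts, np.zeros(extra, dtype=np.int64)]),
        )
        X_all, y_all = segments.matrix, segments.labels
    folds = make_folds(segments, k=k, seed=fold_seed)
    reports: list[EvalReport] = []
    histories = []
    excluded = []
    for f in range(k):
        test_mask = folds == f
        X_tr, y_tr = X_all[~test_mask], y_all[~test_mask]
        X_te, y_te = X_all[test_mask], y_all[test_mask]
        if balance_config is not None and not balance_before_split:
            cfg = BalanceConfig(balance_config.method, balance_config.k_neighbors,
                                balance_config.sampling_strategy, balance_config.jitter_sd,
                                fold_seeds[2 * f])
            X_tr, y_tr = balance_training_set(X_tr, y_tr, cfg)
        model = build_model(model_config, seed=fold_seeds[2 * f + 1])
        fold_train = TrainConfig(
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            epochs=train_config.epochs,
            optimizer=train_config.optimizer,
            seed=fold_seeds[2 * f],
            threshold=train_config.threshold,
            validation_fraction=train_config.validation_fraction,
            verbose=train_config.verbose,
        )
        history = train_model(model, X_tr, y_tr, fold_train)
        report = evaluate_model(model, X_te, y_te, threshold=train_config.threshold)
        if len(np.unique(y_te)) < 2:
            import warnings

            warnings.warn(f"fold {f}: held-out fold has a single class; excluded from mean")
            excluded.append(f)
        reports.append(report)
        histories.append(tuple(history))
        if verbose:
            print(f"fold {f}: f1 {report.f1:.4f}  acc {report.accuracy:.4f}")
    keep = [r for i, r in enumerate(reports) if i not in excluded]
    mean = {
        key: float(np.mean([getattr(r, key) for r in keep])) if keep else float("nan")
        for key in ("precision", "recall", "accuracy", "f1")
    }
    return CVResult(tuple(reports), tuple(histories), mean, tuple(excluded))
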