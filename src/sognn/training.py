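"""Training protocol and leave-one-subject-out evaluation.

Training uses Adam (learning rate 1e-5, weight decay 1e-4, mini-batch 16 by
default) and monitors the macro one-vs-rest AUC on the training set once per
epoch in eval mode; the run stops at the first epoch whose AUC reaches the
0.99 threshold, or at ``max_epochs``.  LOSO trains one fresh model per
subject; the held-out subject's samples form the validation set of that
fold.  Per-fold metrics are accuracy, macro-F1, macro one-vs-rest AUC and
the confusion matrix; model comparison across subjects uses the two-sided
Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

from .features import BandFeatureTensor, apply_statistics, normalize_per_subject, subject_statistics
from .model import SOGNN, SOGNNConfig, sognn_loss

__all__ = [
    "TrainConfig",
    "FoldResult",
    "LOSOReport",
    "Adam",
    "loso_split",
    "train_sognn",
    "evaluate",
    "run_loso",
    "signed_rank_compare",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    batch_size: int = 16
    auc_stop_threshold: float = 0.99
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.weight_decay, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning rate, weight decay, batch size, max_epochs must be positive")
        if not (0.5 < self.auc_stop_threshold <= 1.0):
            raise ValueError("auc_stop_threshold must lie in (0.5, 1]")


@dataclass
class FoldResult:
    held_out_subject: str
    accuracy: float
    macro_F1: float
    macro_AUC: float
    per_class_F1: list
    confusion: np.ndarray
    epochs_trained: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = np.asarray(self.confusion).tolist()
        return d


@dataclass
class LOSOReport:
    folds: list
    mean_accuracy: float = 0.0
    std_accuracy: float = 0.0
    mean_macro_F1: float = 0.0
    mean_macro_AUC: float = 0.0

    def __post_init__(self):
        accs = [f.accuracy for f in self.folds]
        self.mean_accuracy = float(np.mean(accs))
        self.std_accuracy = float(np.std(accs))
        self.mean_macro_F1 = float(np.mean([f.macro_F1 for f in self.folds]))
        self.mean_macro_AUC = float(np.mean([f.macro_AUC for f in self.folds]))

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_macro_F1": self.mean_macro_F1,
            "mean_macro_AUC": self.mean_macro_AUC,
            "folds": [f.to_dict() for f in self.folds],
        }


class Adam:
    """Adam with additive (L2) weight decay on every parameter."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def loso_split(subject_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per subject: (train indices, validation indices).

    Validation sets are pairwise disjoint and jointly exhaustive; subjects
    are iterated in sorted order for determinism.
    """
    subject_ids = np.asarray(subject_ids)
    subjects = sorted(set(subject_ids.tolist()))
    if len(subjects) < 2:
        raise ValueError(f"LOSO needs >= 2 subjects, got {len(subjects)}")
    folds = []
    idx = np.arange(len(subject_ids))
    for s in subjects:
        val = idx[subject_ids == s]
        train = idx[subject_ids != s]
        folds.append((train, val))
    return folds


def _stack(samples: list[BandFeatureTensor]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.values for s in samples])
    y = np.array([s.label for s in samples])
    return X, y


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def _macro_auc(y: np.ndarray, proba: np.ndarray) -> float:
    """Macro one-vs-rest AUC; classes missing from y are skipped."""
    present = np.unique(y)
    if present.size < 2:
        return float("nan")
    aucs = []
    for c in present:
        aucs.append(roc_auc_score((y == c).astype(int), proba[:, c]))
    return float(np.mean(aucs))


def train_sognn(
    train_samples: list[BandFeatureTensor],
    model_config: SOGNNConfig,
    train_config: TrainConfig,
) -> tuple[SOGNN, list[dict]]:
    """Train a fresh model; returns (model, per-epoch log).

    The epoch-end AUC is computed on the full training set with dropout off;
    training stops as soon as it reaches the configured threshold.
    """
    if len(train_samples) < train_config.batch_size:
        raise ValueError(
            f"{len(train_samples)} training samples < batch size {train_config.batch_size}"
        )
    X, y = _stack(train_samples)
    if np.unique(y).size < 2:
        raise ValueError("training labels cover fewer than 2 classes")
    Y = _one_hot(y, model_config.n_classes)
    rng = np.random.default_rng(train_config.seed)
    model = SOGNN(model_config, rng=np.random.default_rng(train_config.seed))
    opt = Adam(model.trainable(), train_config.learning_rate, train_config.weight_decay)
    log: list[dict] = []
    n = len(train_samples)
    bs = train_config.batch_size
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            batch = order[start : start + bs]
            model.zero_grad()
            probs = model.forward(X[batch], train=True, rng=rng)
            loss = sognn_loss(probs, Y[batch], kind=model_config.loss_kind)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        proba = model.predict_proba(X)
        auc = _macro_auc(y, proba)
        log.append({"epoch": epoch, "loss": epoch_loss / n, "train_auc": auc})
        if np.isfinite(auc) and auc >= train_config.auc_stop_threshold:
            break
    return model, log


def evaluate(model: SOGNN, samples: list[BandFeatureTensor]) -> FoldResult:
    """Accuracy, macro-F1, macro one-vs-rest AUC and confusion counts."""
    if not samples:
        raise ValueError("no samples to evaluate")
    X, y = _stack(samples)
    proba = model.predict_proba(X)
    pred = proba.argmax(axis=1)
    labels = np.arange(model.config.n_classes)
    acc = float((pred == y).mean())
    per_class = f1_score(y, pred, labels=labels, average=None, zero_division=0)
    macro_f1 = float(np.mean(per_class))
    macro_auc = _macro_auc(y, proba)
    conf = confusion_matrix(y, pred, labels=labels)
    return FoldResult(
        held_out_subject="",
        accuracy=acc,
        macro_F1=macro_f1,
        macro_AUC=macro_auc,
        per_class_F1=[float(v) for v in per_class],
        confusion=conf,
    )


def run_loso(
    samples: list[BandFeatureTensor],
    model_config: SOGNNConfig,
    train_config: TrainConfig,
    normalize: str = "per-subject",
    collect_adjacency: bool = False,
) -> LOSOReport | tuple[LOSOReport, list[list[np.ndarray]]]:
    """Leave-one-subject-out evaluation.

    ``normalize``: "per-subject" standardizes every subject with its own
    statistics before splitting (the dataset convention); "train-only"
    standardizes each fold with pooled training-subject statistics only;
    "none" leaves features untouched.  Each fold trains from a fresh
    initialization with seed = global seed + fold index.

    With ``collect_adjacency`` the validation-set average dense adjacency of
    each branch is also returned, one [branch0, branch1, branch2] list per
    fold.
    """
    subject_ids = [s.subject_id for s in samples]
    folds = loso_split(subject_ids)
    if normalize == "per-subject":
        samples = normalize_per_subject(samples)
    elif normalize not in ("train-only", "none"):
        raise ValueError(f"unknown normalization mode {normalize!r}")
    results = []
    adjacencies: list[list[np.ndarray]] = []
    for fold_index, (train_idx, val_idx) in enumerate(folds):
        train = [samples[i] for i in train_idx]
        val = [samples[i] for i in val_idx]
        if normalize == "train-only":
            stats = subject_statistics(train)
            pooled_mean = np.mean([m for m, _ in stats.values()], axis=0)
            pooled_std = np.mean([s for _, s in stats.values()], axis=0)
            all_ids = {s.subject_id for s in train} | {s.subject_id for s in val}
            pooled = {sid: (pooled_mean, pooled_std) for sid in all_ids}
            train = apply_statistics(train, pooled)
            val = apply_statistics(val, pooled)
        fold_cfg = TrainConfig(**{**asdict(train_config), "seed": train_config.seed + fold_index})
        try:
            model, log = train_sognn(train, model_config, fold_cfg)
            result = evaluate(model, val)
        except Exception as exc:
            raise RuntimeError(
                f"LOSO fold {fold_index} (held-out subject "
                f"{val[0].subject_id!r}) failed"
            ) from exc
        result.held_out_subject = val[0].subject_id
        result.epochs_trained = len(log)
        results.append(result)
        if collect_adjacency:
            Xv, _ = _stack(val)
            _, adj = model.forward(Xv, return_adjacency=True)
            adjacencies.append([a["dense"].mean(axis=0) for a in adj])
    report = LOSOReport(folds=results)
    if collect_adjacency:
        return report, adjacencies
    return report


def signed_rank_compare(acc_a, acc_b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-subject accuracies.

    Zero differences are dropped; if every pair is tied the result is an
    explicit no-difference verdict (statistic NaN, p-value 1).
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired accuracy vectors must be 1-D and equal length")
    if a.size < 5:
        raise ValueError("signed-rank comparison needs >= 5 pairs")
    diff = a - b
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return {"statistic": float("nan"), "W_plus": 0.0, "W_minus": 0.0,
                "p_value": 1.0, "n_effective": 0, "verdict": "no difference"}
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    res = sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided",
                       method="exact" if nonzero.size <= 25 else "approx")
    return {
        # signed statistic: positive when a tends to exceed b
        "statistic": w_plus - w_minus,
        "W_plus": w_plus,
        "W_minus": w_minus,
        "p_value": float(res.pvalue),
        "n_effective": int(nonzero.size),
        "verdict": "significant at 0.05" if res.pvalue < 0.05 else "not significant",
    }
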