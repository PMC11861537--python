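"""Training loops and evaluation metrics for the three downstream tasks.

Metrics: per-class and overall accuracy, participant-averaged accuracy,
root-mean-square error, and dynamic time warping (classic dynamic
programming with steps (1,0), (0,1), (1,1)); the normalized DTW divides
the alignment cost by the sequence length (a path-length variant is
available).  Training uses Adam with early stopping on validation loss
and restores the best-validation parameters; everything is deterministic
under the configured seed on one device.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .dataset import DatasetSplit
from .model import ABLATION_VARIANTS, ModelConfig, SWCTNet, build_variant
from .nn import Adam, log_softmax, max_norm_constraint

__all__ = [
    "TrainConfig", "EvaluationReport", "TrainResult",
    "accuracy", "average_accuracy", "rmse", "dtw", "normalized_dtw",
    "classification_arrays", "regression_arrays",
    "train", "train_classifier", "train_regressor", "train_generator",
    "evaluate_classifier", "ablation_suite",
]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    patience: int = 10
    seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be nonnegative")


@dataclass
class EvaluationReport:
    """Evaluation results for one model on one subset."""

    per_class_accuracy: dict = field(default_factory=dict)
    average_accuracy: float | None = None
    overall_accuracy: float | None = None
    per_feature_rmse: dict = field(default_factory=dict)
    per_sequence_dtw: list = field(default_factory=list)
    normalized_dtw: float | None = None
    group: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrainResult:
    model: SWCTNet
    history: pd.DataFrame
    best_epoch: int
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------- metrics

def accuracy(preds, labels):
    """Per-class and overall accuracy in percent.

    Returns ``(per_class, overall)`` where ``per_class`` maps each label
    value to the percentage of its samples predicted correctly.
    """
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.size == 0:
        raise ValueError("cannot compute accuracy of empty predictions")
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    per_class = {}
    for c in np.unique(labels):
        mask = labels == c
        per_class[int(c)] = 100.0 * float(np.mean(preds[mask] == c))
    overall = 100.0 * float(np.mean(preds == labels))
    return per_class, overall


def average_accuracy(per_subject: dict | list) -> float:
    """Arithmetic mean of per-participant accuracies (percent)."""
    vals = list(per_subject.values()) if isinstance(per_subject, dict) else list(per_subject)
    if not vals:
        raise ValueError("no per-subject accuracies given")
    return float(np.mean(vals))


def rmse(y, y_hat) -> float:
    """Root-mean-square error between two equal-length arrays."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("rmse of empty arrays is undefined")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def _local_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.ndim == 1:
        return np.abs(a[:, None] - b[None, :])
    # vector series: Euclidean local distance
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def dtw(a, b, return_path_length: bool = False):
    """Dynamic time warping distance between two sequences.

    Local distance is ``|a_i - b_j|`` for scalar series and Euclidean for
    vector series (rows = time steps).  Allowed warping steps are
    (1,0), (0,1) and (1,1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW of an empty sequence is undefined")
    d = _local_distances(a, b)
    n, m = d.shape
    D = np.full((n, m), np.inf)
    D[0, 0] = d[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + d[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + d[i, 0]
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, m):
            row[j] = d[i, j] + min(row_prev[j], row[j - 1], row_prev[j - 1])
    dist = float(D[n - 1, m - 1])
    if not return_path_length:
        return dist
    # backtrack the optimal path to measure its length
    i, j, steps = n - 1, m - 1, 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            k = int(np.argmin([D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]]))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        steps += 1
    return dist, steps


def normalized_dtw(a, b, norm: str = "length") -> float:
    """DTW distance normalized for comparability across sequence pairs.

    ``norm="length"`` (default) divides by the sequence length n (the
    longer one when lengths differ); ``norm="path"`` divides by the
    number of steps on the optimal warping path.
    """
    if norm == "length":
        n = max(np.asarray(a).shape[0], np.asarray(b).shape[0])
        return dtw(a, b) / n
    if norm == "path":
        dist, steps = dtw(a, b, return_path_length=True)
        return dist / steps
    raise ValueError(f"unknown DTW normalization {norm!r}")


# ----------------------------------------------------- dataset -> arrays

def classification_arrays(split: DatasetSplit):
    """Stack (X, y, participant) arrays for each subset."""
    out = {}
    for name, samples in split.subsets().items():
        X = np.stack([s.imu_window for s in samples])
        y = np.array([s.movement_label for s in samples])
        pid = np.array([s.participant_id for s in samples])
        out[name] = (X, y, pid)
    return out


def regression_arrays(split: DatasetSplit):
    """Stack (X, features, envelope RMS) arrays for each subset."""
    out = {}
    for name, samples in split.subsets().items():
        X = np.stack([s.imu_window for s in samples])
        Y = np.stack([s.features.ravel() for s in samples])
        env = (np.stack([s.envelope_rms for s in samples])
               if samples[0].envelope_rms is not None else None)
        out[name] = (X, Y, env)
    return out


# ----------------------------------------------------------- training core

def _check_finite(loss: float, epoch: int) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged (non-finite loss at epoch {epoch})")


def _run_epochs(model, cfg, step_train, eval_val, verbose):
    """Shared epoch loop: optimize, early-stop on val loss, restore best."""
    opt = Adam(model.parameters(), lr=cfg.lr)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    rows = []
    wait = 0
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        tr_loss = step_train(opt, epoch)
        _check_finite(tr_loss, epoch)
        model.eval()
        val_loss = eval_val()
        rows.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:3d}  train {tr_loss:.4f}  val {val_loss:.4f}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return pd.DataFrame(rows), best_epoch


def _minibatches(n, batch_size, rng):
    idx = rng.permutation(n)
    for a in range(0, n, batch_size):
        yield idx[a:a + batch_size]


def train_classifier(model: SWCTNet, split: DatasetSplit,
                     cfg: TrainConfig | None = None) -> TrainResult:
    """Cross-entropy training of the classification head."""
    cfg = cfg or TrainConfig()
    data = classification_arrays(split)
    Xtr, ytr, _ = data["train"]
    Xva, yva, _ = data["val"]
    rng = np.random.default_rng(cfg.seed)
    model.reset_rng(cfg.seed)

    def step_train(opt, epoch):
        losses = []
        for batch in _minibatches(len(Xtr), cfg.batch_size, rng):
            model.zero_grad()
            fused = model.encode(Xtr[batch])
            logits = model.classification_logits(fused)
            logp = log_softmax(logits, axis=-1)
            nll = -logp[np.arange(len(batch)), ytr[batch]]
            loss = nll.mean()
            loss.backward()
            opt.step()
            max_norm_constraint(model.constrained_parameters(),
                                model.config.max_norm)
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def eval_val():
        probs = predict_in_batches(model, Xva)
        logp = np.log(np.clip(probs, 1e-12, None))
        return float(-logp[np.arange(len(yva)), yva].mean())

    history, best = _run_epochs(model, cfg, step_train, eval_val, cfg.verbose)
    return TrainResult(model, history, best)


def train_regressor(model: SWCTNet, split: DatasetSplit,
                    cfg: TrainConfig | None = None) -> TrainResult:
    """MSE training of the feature-regression head.

    Targets are z-scored with training-set statistics; the scaler is
    returned in ``extra`` so predictions can be mapped back to feature
    units.
    """
    cfg = cfg or TrainConfig()
    data = regression_arrays(split)
    Xtr, Ytr, _ = data["train"]
    Xva, Yva, _ = data["val"]
    mu = Ytr.mean(axis=0)
    sd = np.maximum(Ytr.std(axis=0), 1e-8)
    Ztr, Zva = (Ytr - mu) / sd, (Yva - mu) / sd
    rng = np.random.default_rng(cfg.seed)
    model.reset_rng(cfg.seed)

    def step_train(opt, epoch):
        losses = []
        for batch in _minibatches(len(Xtr), cfg.batch_size, rng):
            model.zero_grad()
            fused = model.encode(Xtr[batch])
            pred = model.regression_head(fused)
            loss = ((pred - Tensor(Ztr[batch])) ** 2).mean()
            loss.backward()
            opt.step()
            max_norm_constraint(model.constrained_parameters(),
                                model.config.max_norm)
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def eval_val():
        pred = predict_in_batches(model, Xva)
        return float(np.mean((pred - Zva) ** 2))

    history, best = _run_epochs(model, cfg, step_train, eval_val, cfg.verbose)
    return TrainResult(model, history, best,
                       extra={"target_mu": mu, "target_sd": sd})


def train_generator(model: SWCTNet, sequences: dict,
                    cfg: TrainConfig | None = None) -> TrainResult:
    """Teacher-forced MSE training of the sequence-generation decoder.

    ``sequences``: dict with keys train/val/test, each a list of
    ``(X_seq, Y_seq, meta)`` tuples where ``X_seq`` is (T, N_ch, N_L)
    IMU windows along a repetition and ``Y_seq`` is (T, gen_dim)
    feature-vector targets (already normalized).
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    model.reset_rng(cfg.seed)
    train_seqs, val_seqs = sequences["train"], sequences["val"]

    def step_train(opt, epoch):
        losses = []
        order = rng.permutation(len(train_seqs))
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_seqs[i] for i in order[start:start + cfg.batch_size]]
            T = min(x.shape[0] for x, _, _ in batch)
            X = np.stack([x[:T] for x, _, _ in batch])
            Y = np.stack([y[:T] for _, y, _ in batch])
            B = X.shape[0]
            model.zero_grad()
            fused = model.encode(X.reshape(B * T, *X.shape[2:]))
            memory = fused.reshape(B, T, *fused.shape[1:])
            pred = model.generation_decoder(memory, horizon=T, teacher=Y)
            loss = ((pred - Tensor(Y)) ** 2).mean()
            loss.backward()
            opt.step()
            max_norm_constraint(model.constrained_parameters(),
                                model.config.max_norm)
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def eval_val():
        losses = []
        for X_seq, Y_seq, _ in val_seqs:
            T = X_seq.shape[0]
            fused = model.encode(X_seq)
            memory = fused.reshape(1, T, *fused.shape[1:])
            pred = model.generation_decoder(memory, horizon=T)
            losses.append(float(np.mean((pred.data[0] - Y_seq) ** 2)))
        return float(np.mean(losses))

    history, best = _run_epochs(model, cfg, step_train, eval_val, cfg.verbose)
    return TrainResult(model, history, best)


def train(model: SWCTNet, data, cfg: TrainConfig | None = None) -> TrainResult:
    """Dispatch on the model's configured task."""
    task = model.config.task
    if task == "classification":
        return train_classifier(model, data, cfg)
    if task == "regression":
        return train_regressor(model, data, cfg)
    return train_generator(model, data, cfg)


def predict_in_batches(model: SWCTNet, X: np.ndarray,
                       batch_size: int = 256) -> np.ndarray:
    """Eval-mode head outputs for a (N, C, L) array, batched for memory."""
    was_training = model.training
    model.eval()
    outs = []
    for a in range(0, len(X), batch_size):
        fused = model.encode(X[a:a + batch_size])
        if model.config.task == "classification":
            outs.append(model.classification_head(fused).data)
        else:
            outs.append(model.regression_head(fused).data)
    model.train(was_training)
    return np.concatenate(outs, axis=0)


def evaluate_classifier(model: SWCTNet, X: np.ndarray, y: np.ndarray,
                        participant_ids: np.ndarray | None = None
                        ) -> EvaluationReport:
    """Accuracy report on one subset; participant-averaged when ids exist."""
    probs = predict_in_batches(model, X)
    preds = probs.argmax(axis=1)
    per_class, overall = accuracy(preds, y)
    if participant_ids is not None and len(np.unique(participant_ids)) > 1:
        per_subj = {int(p): accuracy(preds[participant_ids == p],
                                     y[participant_ids == p])[1]
                    for p in np.unique(participant_ids)}
        avg = average_accuracy(per_subj)
    else:
        avg = average_accuracy(list(per_class.values()))
    return EvaluationReport(per_class_accuracy=per_class,
                            overall_accuracy=overall,
                            average_accuracy=avg)


def ablation_suite(split: DatasetSplit, base_cfg: ModelConfig,
                   train_cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Train and evaluate the four ablation variants under one budget.

    Returns a table with variant name, parameter count and test accuracy.
    """
    train_cfg = train_cfg or TrainConfig()
    data = classification_arrays(split)
    Xte, yte, pte = data["test"]
    rows = []
    for variant in ABLATION_VARIANTS:
        model = build_variant(base_cfg, variant)
        try:
            train_classifier(model, split, train_cfg)
        except Exception as exc:
            raise RuntimeError(f"ablation variant {variant} failed: {exc}") from exc
        report = evaluate_classifier(model, Xte, yte, pte)
        rows.append({"variant": variant,
                     "n_parameters": model.n_parameters(),
                     "test_accuracy": report.overall_accuracy,
                     "average_accuracy": report.average_accuracy})
    return pd.DataFrame(rows)
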