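"""Tversky loss, patient-level data splits, and the training loop.

Tumor pixels are a small minority of each slice, and a missed tumor pixel
(false negative) is clinically worse than a false alarm. The Tversky
index generalizes Dice with separate weights for false positives (alpha)
and false negatives (beta); beta > alpha pushes the optimizer toward
recall. Defaults alpha = 0.25, beta = 0.75.

Splits operate on patient ids, never on slices, so no patient contributes
slices to both sides of a split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acrnet import ACRNet
from .nn import Adam


@dataclass(frozen=True)
class TverskyParams:
    """alpha penalizes false positives, beta false negatives; epsilon
    stabilizes the ratio when both masks are empty."""
    alpha: float = 0.25
    beta: float = 0.75
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 460
    batch_size: int = 8
    seed: int = 0
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# Tversky index / loss
# ---------------------------------------------------------------------------

def _check_pair(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def tversky_index(pred: np.ndarray, truth: np.ndarray,
                  params: TverskyParams = TverskyParams()) -> float:
    """T = sum(p*q) / (sum(p*q) + alpha*sum(p*(1-q)) + beta*sum(q*(1-p)) + eps).

    ``pred`` holds probabilities in [0, 1]; ``truth`` is binary. With
    alpha = beta = 0.5 this is exactly the (soft) Dice coefficient.
    """
    pred, truth = _check_pair(pred, truth)
    tp = float((pred * truth).sum())
    fp = float((pred * (1.0 - truth)).sum())
    fn = float((truth * (1.0 - pred)).sum())
    return tp / (tp + params.alpha * fp + params.beta * fn + params.epsilon)


def tversky_loss(pred: np.ndarray, truth: np.ndarray,
                 params: TverskyParams = TverskyParams()) -> float:
    """1 - Tversky index: 0 for a perfect prediction, 1 for a disjoint one."""
    return 1.0 - tversky_index(pred, truth, params)


def tversky_loss_grad(pred: np.ndarray, truth: np.ndarray,
                      params: TverskyParams = TverskyParams()
                      ) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to ``pred``.

    With numerator N = sum(pq) and denominator D = N + a*FP + b*FN + eps,
    dT/dp_i = (q_i * D - N * (q_i + a*(1-q_i) - b*q_i)) / D^2 and the loss
    gradient is its negation.
    """
    pred, truth = _check_pair(pred, truth)
    a, b = params.alpha, params.beta
    num = (pred * truth).sum()
    den = num + a * (pred * (1.0 - truth)).sum() \
        + b * (truth * (1.0 - pred)).sum() + params.epsilon
    d_num = truth
    d_den = truth + a * (1.0 - truth) - b * truth
    grad = -(d_num * den - num * d_den) / den ** 2
    return 1.0 - num / den, grad


# ---------------------------------------------------------------------------
# patient-level splits
# ---------------------------------------------------------------------------

def split_patients(patient_ids, spec: SplitSpec = SplitSpec()
                   ) -> tuple[list, list]:
    """Seeded disjoint train/test partition of patient ids.

    Train size is round(train_fraction * n); e.g. 210 ids at 0.7 give
    147 train / 63 test.
    """
    ids = list(dict.fromkeys(patient_ids))  # unique, order-preserving
    if len(ids) < 2:
        raise ValueError("need at least two patients to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(spec.train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def kfold_patients(patient_ids, spec: SplitSpec = SplitSpec()) -> list[list]:
    """Seeded k-fold partition of patient ids; fold sizes differ by <= 1."""
    ids = list(dict.fromkeys(patient_ids))
    if len(ids) < spec.k_folds:
        raise ValueError(f"{len(ids)} patients cannot fill {spec.k_folds} folds")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in sorted(chunk)]
            for chunk in np.array_split(perm, spec.k_folds)]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _dsc_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = float(np.logical_and(pred, truth).sum())
    total = float(pred.sum() + truth.sum())
    if total == 0:
        return 1.0
    return 2.0 * inter / total


def evaluate_dsc(model: ACRNet, images: np.ndarray, masks: np.ndarray,
                 threshold: float = 0.5, batch_size: int = 8) -> float:
    """Mean per-slice Dice of thresholded single-pass predictions."""
    scores = []
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        probs = model.forward(batch[:, None, :, :])[:, 0]
        for p, q in zip(probs >= threshold, masks[start:start + batch_size]):
            scores.append(_dsc_binary(p, q.astype(bool)))
    return float(np.mean(scores))


def train(model: ACRNet, train_images: np.ndarray, train_masks: np.ndarray,
          val_images: np.ndarray | None = None,
          val_masks: np.ndarray | None = None,
          tcfg: TrainConfig = TrainConfig(),
          params: TverskyParams = TverskyParams()) -> list[dict]:
    """Train in place with Adam on the Tversky loss; returns the epoch log.

    Each log record holds (epoch, loss, val_dsc, seconds). When a
    validation set and a checkpoint directory are given, the weights with
    the best validation Dice are saved to ``best.npz`` (and restored into
    the model at the end); ``last.npz`` always holds the final weights.

    Images are (N, H, W) normalized to [0, 1]; masks are (N, H, W) binary.
    Fully seeded: identical configs and data reproduce identical logs.
    """
    if len(train_images) == 0:
        raise ValueError("empty training set")
    if train_images.shape != train_masks.shape:
        raise ValueError("images and masks must align")
    opt = Adam(model.params(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    log: list[dict] = []
    best_dsc = -1.0
    ckpt = Path(tcfg.checkpoint_dir) if tcfg.checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)

    n = len(train_images)
    for epoch in range(tcfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            x = train_images[idx][:, None, :, :]
            q = train_masks[idx][:, None, :, :].astype(np.float64)
            opt.zero_grad()
            p = model.forward(x)
            loss, gp = tversky_loss_grad(p, q, params)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss!r} at epoch {epoch}, step {start}")
            model.backward(gp)
            opt.step()
            losses.append(loss)
        val_dsc = (evaluate_dsc(model, val_images, val_masks)
                   if val_images is not None and len(val_images) else float("nan"))
        seconds = time.perf_counter() - t0
        log.append(dict(epoch=epoch, loss=float(np.mean(losses)),
                        val_dsc=val_dsc, seconds=seconds))
        if ckpt and np.isfinite(val_dsc) and val_dsc > best_dsc:
            best_dsc = val_dsc
            model.save(ckpt / "best.npz")
    if ckpt:
        model.save(ckpt / "last.npz")
        if best_dsc >= 0:
            model.load_state_dict(ACRNet.load(ckpt / "best.npz").state_dict())
    if tcfg.log_path:
        import pandas as pd
        pd.DataFrame(log).to_csv(tcfg.log_path, index=False)
    return log
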