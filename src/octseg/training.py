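"""Training: combined CE + soft-Dice loss, cyclic SGD, early stopping, HPT.

The loss is ``lambda_ce * CE + lambda_dice * (1 - soft Dice)`` with the
soft Dice averaged over all four classes (background included) and an
``eps = 1e-5`` smoothing term.  Optimisation is SGD with momentum and
weight decay; learning rate follows a triangular cyclic schedule between
``lr_base`` and ``lr_max`` while momentum cycles inversely (it falls while
the learning rate rises).  Training stops early when the validation loss
fails to improve (strictly) for ``patience`` consecutive epochs; the
checkpoint with the smallest validation loss is retained.

The 3-stage manual hyper-parameter search fixes each stage's winner before
sweeping the next group: learning-rate range (including a constant-LR
control at 5e-3.5), then momentum range, then weight decay.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad

from .evaluation import aggregate, evaluate_pair
from .models.nn import log_softmax, softmax, tree_map

DICE_EPS = 1e-5

# Stage grids of the manual search.  Learning-rate ranges couple the base
# to a tenth of the max (the final range is the printed exception); the
# lone scalar is the constant-LR control at 5e-3.5.
STAGE1_LR_GRID = [
    (5e-5, 5e-4),
    (5e-4, 5e-3),
    5 * 10**-3.5,
    (5e-3, 5e-2),
    (5e-2, 5e-1),
    (5e-1, 1.5),
]
STAGE2_MOMENTUM_GRID = [(0.80, 0.90), (0.80, 0.95), (0.85, 0.97), (0.85, 0.99)]
STAGE3_WD_GRID = [1e-6, 1e-5, 1e-4, 1e-3, 1e-2]


@dataclass
class TrainConfig:
    lambda_ce: float = 0.5
    lambda_dice: float = 0.5
    lr_base: float = 5e-3
    lr_max: float = 5e-2
    momentum_base: float = 0.80
    momentum_max: float = 0.95
    weight_decay: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 6
    cycle_epochs: int = 10  # epochs per half-cycle of the triangular schedule
    seed: int = 0

    def __post_init__(self):
        if self.lambda_ce < 0 or self.lambda_dice < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lr_base > self.lr_max:
            raise ValueError("lr_base must be <= lr_max")
        if self.momentum_base > self.momentum_max:
            raise ValueError("momentum_base must be <= momentum_max")
        if self.patience < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("patience, max_epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    epochs: list  # per-epoch dicts: train_loss, val_loss, dice_IRF/SRF/PED
    best_epoch: int  # 1-based epoch with minimal validation loss
    best_val_loss: float
    best_params: object
    stopped_early: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, H, W) int -> (N, C, H, W) float32 one-hot (plain numpy)."""
    g = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        g[:, c] = target == c
    return g


def combined_loss(logits, target, lambda_ce: float = 0.5, lambda_dice: float = 0.5):
    """``lambda_ce * CE + lambda_dice * (1 - mean soft Dice)``.

    ``logits`` is (N, C, H, W) (a single image may omit the batch axis);
    ``target`` holds integer labels in [0, C).  The soft Dice term uses
    softmax probabilities against the one-hot target, summed per image and
    class, and averages over all classes including background.
    """
    if logits.ndim == 3:
        logits = logits[None]
        target = np.asarray(target)[None]
    n, c, h, w = logits.shape
    if np.asarray(target).shape != (n, h, w):
        raise ValueError("target shape does not match logits")
    g = one_hot(np.asarray(target), c)
    logp = log_softmax(logits, axis=1)
    ce = -anp.sum(g * logp) / (n * h * w)
    p = softmax(logits, axis=1)
    # eps smooths numerator and denominator so a correctly predicted
    # absent class scores a perfect 1 and the loss can reach 0
    num = 2.0 * anp.sum(p * g, axis=(2, 3)) + DICE_EPS
    den = anp.sum(p**2, axis=(2, 3)) + anp.sum(g**2, axis=(2, 3)) + DICE_EPS
    dice_loss = 1.0 - anp.mean(num / den)
    return lambda_ce * ce + lambda_dice * dice_loss


def cyclic_schedule(step: int, steps_per_half_cycle: int, low: float, high: float) -> float:
    """Triangular wave: low -> high over one half-cycle, back over the next."""
    if low > high:
        raise ValueError("low must be <= high")
    if steps_per_half_cycle < 1:
        raise ValueError("steps_per_half_cycle must be >= 1")
    pos = step % (2 * steps_per_half_cycle)
    frac = pos / steps_per_half_cycle
    if frac > 1.0:
        frac = 2.0 - frac
    return low + frac * (high - low)


def cyclic_momentum(step: int, steps_per_half_cycle: int, m_base: float, m_max: float) -> float:
    """Momentum cycles inversely to the learning rate (falls while LR rises)."""
    lr_like = cyclic_schedule(step, steps_per_half_cycle, 0.0, 1.0)
    return m_max - lr_like * (m_max - m_base)


def _batches(n: int, batch_size: int, rng) -> list:
    idx = rng.permutation(n)
    return [idx[i : i + batch_size] for i in range(0, n, batch_size)]


def _val_metrics(model, x, y, cfg, batch_size=16):
    losses = []
    records = []
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.apply(xb, train=False)
        losses.append(float(combined_loss(logits, yb, cfg.lambda_ce, cfg.lambda_dice)) * len(xb))
        pred = np.argmax(np.asarray(logits), axis=1)
        for j in range(len(xb)):
            records.extend(evaluate_pair(yb[j], pred[j], image_id=f"val{i + j}"))
    agg = aggregate(records)
    dice_cols = {f"dice_{row['class']}": row["dice_mean"] for _, row in agg.per_class.iterrows()}
    return sum(losses) / x.shape[0], dice_cols, agg.weighted["dice"]


def train(model, train_set, val_set, config: TrainConfig, augment_fn=None,
          verbose: bool = False) -> TrainHistory:
    """SGD training loop with cyclic LR/momentum and early stopping.

    ``train_set``/``val_set`` are ``(images, targets)`` tuples with images
    (N, C, H, W) float32 and targets (N, H, W) integer labels.  The model's
    parameters are updated in place (``model.params``); the returned
    history carries a copy of the best-validation-loss parameters, which
    are also restored into the model on exit.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = max(1, -(-x_tr.shape[0] // cfg.batch_size))
    half_cycle = cfg.cycle_epochs * steps_per_epoch

    velocity = tree_map(np.zeros_like, model.params)
    history = []
    best_val = np.inf
    best_epoch = 0
    best_params = None
    bad_epochs = 0
    step = 0
    stopped_early = False

    for epoch in range(1, cfg.max_epochs + 1):
        epoch_losses = []
        for batch in _batches(x_tr.shape[0], cfg.batch_size, rng):
            xb, yb = x_tr[batch], y_tr[batch]
            if augment_fn is not None:
                xb, yb = augment_fn(xb, yb, rng)
            lr = cyclic_schedule(step, half_cycle, cfg.lr_base, cfg.lr_max)
            mom = cyclic_momentum(step, half_cycle, cfg.momentum_base, cfg.momentum_max)

            def loss_fn(params):
                return combined_loss(model.apply(xb, params=params, train=True),
                                     yb, cfg.lambda_ce, cfg.lambda_dice)

            loss, grads = value_and_grad(loss_fn)(model.params)
            epoch_losses.append(float(loss))

            velocity = tree_map(
                lambda p, v, g: (mom * v - lr * (g + cfg.weight_decay * p)).astype(np.float32),
                model.params, velocity, grads,
            )
            model.params = tree_map(lambda p, v: (p + v).astype(np.float32),
                                    model.params, velocity)
            step += 1

        val_loss, dice_cols, wdice = _val_metrics(model, x_va, y_va, cfg,
                                                  batch_size=cfg.batch_size)
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                 "val_loss": val_loss, "weighted_dice": wdice, **dice_cols}
        history.append(entry)
        if verbose:
            print(f"epoch {epoch:3d}  train {entry['train_loss']:.4f}  "
                  f"val {val_loss:.4f}  wdice {wdice if wdice == wdice else float('nan'):.3f}",
                  flush=True)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = copy.deepcopy(model.params)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                stopped_early = True
                break

    if best_params is not None:
        model.params = copy.deepcopy(best_params)
    return TrainHistory(epochs=history, best_epoch=best_epoch, best_val_loss=float(best_val),
                        best_params=best_params, stopped_early=stopped_early)


# ---------------------------------------------------------------------------
# 3-stage manual hyper-parameter search


def stage_configs(base: TrainConfig, stage: int, grids: dict | None = None) -> list:
    """Candidate configurations for one search stage (previous winners are
    already baked into ``base``)."""
    grids = grids or {}
    if stage == 1:
        out = []
        for entry in grids.get("lr", STAGE1_LR_GRID):
            if isinstance(entry, tuple):
                out.append(replace(base, lr_base=entry[0], lr_max=entry[1]))
            else:  # constant-LR control
                out.append(replace(base, lr_base=float(entry), lr_max=float(entry)))
        return out
    if stage == 2:
        return [replace(base, momentum_base=lo, momentum_max=hi)
                for lo, hi in grids.get("momentum", STAGE2_MOMENTUM_GRID)]
    if stage == 3:
        return [replace(base, weight_decay=wd) for wd in grids.get("weight_decay", STAGE3_WD_GRID)]
    raise ValueError("stage must be 1, 2 or 3")


def run_hpt(model_factory, train_set, val_set, base: TrainConfig, stage: int,
            grids: dict | None = None):
    """Evaluate one search stage; returns (table, winning TrainConfig).

    ``model_factory(seed)`` must build a freshly initialised model.  Each
    candidate reports the weighted mean validation Dice at its best-
    validation-loss epoch; the winner maximises that score.
    """
    rows = []
    candidates = []
    for i, cfg in enumerate(stage_configs(base, stage, grids)):
        model = model_factory(cfg.seed)
        hist = train(model, train_set, val_set, cfg)
        at_best = hist.epochs[hist.best_epoch - 1] if hist.epochs else {}
        score = at_best.get("weighted_dice", float("nan"))
        rows.append({
            "stage": stage, "config_index": i,
            "lr_base": cfg.lr_base, "lr_max": cfg.lr_max,
            "momentum_base": cfg.momentum_base, "momentum_max": cfg.momentum_max,
            "weight_decay": cfg.weight_decay,
            "best_epoch": hist.best_epoch, "best_val_loss": hist.best_val_loss,
            "weighted_dice": score,
        })
        candidates.append(cfg)
    table = pd.DataFrame(rows)
    # winner: highest weighted Dice; a NaN Dice (no usable prediction yet)
    # ranks below any score, ties broken by smaller validation loss
    key = [(-(s if s == s else -np.inf), v)
           for s, v in zip(table["weighted_dice"], table["best_val_loss"])]
    winner_idx = min(range(len(key)), key=lambda i: key[i])
    table["winner"] = [i == winner_idx for i in range(len(table))]
    return table, candidates[winner_idx]
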