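"""Initial supervised training: masked binary cross-entropy with
validation-perplexity checkpointing.

Entire records are teacher-forced through the encoder and head at once and
the Bernoulli cross-entropy over every code position up to and including
the sentinel row is backpropagated. Validation is used for checkpoint
selection only (no early stopping in this phase); the returned model always
carries the best-validation-perplexity parameters seen.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 48
    epochs: int = 50
    seed: int = 0
    grad_clip: float | None = None   # unstated upstream choice; off by default
    log_every: int = 0               # batches between loss prints (0 = silent)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("hyperparameters must be positive")

    @classmethod
    def profile(cls, name: str, **overrides) -> "TrainConfig":
        """``full``: lr 1e-4 / batch 48 / 50 epochs. ``desk``: the same batch
        size with a larger step (3e-4) and 30 epochs, sized for small synthetic
        cohorts on one CPU."""
        if name == "full":
            base = {}
        elif name == "desk":
            base = {"learning_rate": 3e-4, "epochs": 30}
        else:
            raise ValueError(f"unknown profile {name!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class FitHistory:
    train_loss: list = field(default_factory=list)       # per-epoch mean BCE
    val_perplexity: list = field(default_factory=list)   # per-epoch
    best_val_perplexity: float = np.inf
    best_epoch: int = -1


def masked_bce_loss(model, batch_records):
    """Mean masked BCE over a batch; padding rows contribute exactly zero."""
    logits, targets, row_mask = model.record_logits(batch_records)
    weight = row_mask[..., None] * np.ones(model.total_size)
    loss_elems = ad.bce_with_logits(logits, targets, weight=weight)
    n = float(weight.sum())
    return loss_elems.sum() * (1.0 / n)


def _batches(n: int, batch_size: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def fit(model, train_records, val_records, config: TrainConfig | None = None,
        optimizer_state: Adam | None = None):
    """Train in place; returns ``(model, FitHistory)``.

    The model is left holding the parameters of the best-validation-
    perplexity epoch (save-on-improve), so the returned model's validation
    perplexity is never worse than any intermediate checkpoint's.
    """
    from .evaluation import perplexity

    config = config or TrainConfig()
    if not train_records or not val_records:
        raise ValueError("train and validation cohorts must be non-empty")
    rng = np.random.default_rng(config.seed)
    params = model.trainable_params()
    opt = optimizer_state or Adam(params, lr=config.learning_rate)
    history = FitHistory()
    best_params = {k: p.data.copy() for k, p in params.items()}
    train_records = list(train_records)

    for epoch in range(config.epochs):
        epoch_losses = []
        for batch_idx in _batches(len(train_records), config.batch_size, rng):
            batch = [train_records[i] for i in batch_idx]
            opt.zero_grad()
            loss = masked_bce_loss(model, batch)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            loss.backward()
            if config.grad_clip is not None:
                _clip(params, config.grad_clip)
            opt.step()
            epoch_losses.append(float(loss.data))
            if config.log_every and len(epoch_losses) % config.log_every == 0:
                print(f"epoch {epoch} batch {len(epoch_losses)} "
                      f"loss {epoch_losses[-1]:.4f}")
        history.train_loss.append(float(np.mean(epoch_losses)))
        val_pp = perplexity(model, val_records)
        history.val_perplexity.append(val_pp)
        if val_pp < history.best_val_perplexity:
            history.best_val_perplexity = val_pp
            history.best_epoch = epoch
            best_params = {k: p.data.copy() for k, p in params.items()}

    for k, p in params.items():
        p.data = best_params[k]
    return model, history


def _clip(params: dict, max_norm: float):
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params.values() if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale
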