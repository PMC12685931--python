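"""Episodic training loop: AdamW, step-wise LR halving, top-K schedule,
per-step EMA teacher update, periodic validation with early stopping.

Defaults mirror the published configuration (155k steps, base LR 1e-4 halved
at 75k/100k, weight decay 1e-3, support size 16, upsampler top-K of 5 until
step 125k then 24, validation every 5k steps); desk-scale runs override the
sizes but keep the same machinery.  One episode per optimizer step.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from .augment import AugmentConfig, augment
from .losses import LossConfig, combined_loss
from .model import Episode, InContextSegmenter, model_forward

__all__ = ["TrainConfig", "TrainResult", "lr_at", "top_k_at", "train",
           "desk_train_config", "desk_episode_stream"]


@dataclass
class TrainConfig:
    steps: int = 155_000
    base_lr: float = 1e-4
    lr_halving_steps: tuple = (75_000, 100_000)
    weight_decay: float = 1e-3
    support_size: int = 16
    #: (step_boundary, K): K applies from its boundary up to the next one
    topk_schedule: tuple = ((0, 5), (125_000, 24))
    val_every: int = 5_000
    early_stop_patience: int = 5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    augment: Optional[AugmentConfig] = field(default_factory=AugmentConfig)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        bounds = [b for b, _ in self.topk_schedule]
        if bounds != sorted(bounds):
            raise ValueError("top-K schedule boundaries must be increasing")


@dataclass
class TrainResult:
    model: InContextSegmenter
    metrics: list
    best_val_loss: float
    stopped_early: bool

    def write_csv(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["step", "train_loss", "val_loss", "lr", "top_k"])
            writer.writeheader()
            for row in self.metrics:
                writer.writerow(row)


def desk_train_config(steps: int = 2000, seed: int = 0) -> TrainConfig:
    """CPU-scale training configuration (tiny preset, 64x64 geometry).

    Scaled-down analogue of the full-scale schedule: higher base LR for the
    short horizon, halvings at 75%/92.5% of the run, the top-K switch (5 ->
    24) at 80%, and no augmentation — the augmentation set pays off over
    long schedules but slows a 2k-step run.
    """
    return TrainConfig(
        steps=steps, base_lr=3e-3,
        lr_halving_steps=(int(0.75 * steps), int(0.925 * steps)),
        weight_decay=1e-4, support_size=8,
        topk_schedule=((0, 5), (int(0.8 * steps), 24)),
        val_every=10 ** 9, seed=seed, augment=None)


def desk_episode_stream(tasks, rng, size: int = 64, support_sizes=(4, 8, 16),
                        conjugate_after: int = 700):
    """Episode stream for desk-scale training.

    Support sizes vary per episode so the model behaves across S at
    evaluation.  After a warm-up on the base tasks, conjugate task pairs
    (same scenes, swapped target/decoy families, restricted to visually
    distinct family pairs) enter the mix: they are what forces the model to
    read the support masks instead of taking appearance shortcuts.  The
    warm-up matters — introducing conjugates from step 0 drives the
    optimizer to silence the support pathway entirely (with registry tokens
    present, all attention mass collapses into them).
    """
    from .synthetic import conjugate_task, generate_episode

    ambiguous = {frozenset(("disk", "blob-union"))}
    base = [t for t in tasks]
    conj = [conjugate_task(t) for t in base
            if t.n_distractors >= 1
            and frozenset((t.shape_family, t.distractor_family)) not in ambiguous]
    full = base + conj
    sizes = list(support_sizes)
    step = 0
    while True:
        pool = base if step < conjugate_after else full
        S = sizes[rng.integers(len(sizes))]
        yield generate_episode(pool[rng.integers(len(pool))], S, rng, size=size)
        step += 1


def lr_at(cfg: TrainConfig, step: int) -> float:
    halvings = sum(step >= b for b in cfg.lr_halving_steps)
    return cfg.base_lr * 0.5 ** halvings


def top_k_at(cfg: TrainConfig, step: int) -> int:
    k = cfg.topk_schedule[0][1]
    for boundary, value in cfg.topk_schedule:
        if step >= boundary:
            k = value
    return k


def _episode_loss(params, ema_shadow, episode: Episode, top_k: int,
                  loss_cfg: LossConfig):
    probs, _ = model_forward(params, ema_shadow, episode.query_image,
                             episode.support_images, episode.support_masks,
                             base_top_k=top_k)
    return combined_loss(probs, episode.query_mask, loss_cfg)


def train(model: InContextSegmenter,
          episode_stream: Iterable[Episode],
          cfg: TrainConfig,
          val_episodes: Optional[list] = None,
          log_csv=None,
          progress: Optional[Callable[[int, float], None]] = None) -> TrainResult:
    """Run episodic training; returns the best-validation model.

    ``episode_stream`` yields training episodes (already task-balanced);
    augmentation, the optimizer and the EMA teacher update run per step.
    Deterministic for a fixed seed and stream.
    """
    rng = np.random.default_rng(cfg.seed)
    flat, unflatten = flatten(model.params)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    metrics = []
    best_val = math.inf
    best_flat = flat.copy()
    best_ema = model.ema
    bad_rounds = 0
    stopped = False
    stream = iter(episode_stream)

    def val_loss(params, ema_shadow, step):
        losses = [
            float(_episode_loss(params, ema_shadow, ep, top_k_at(cfg, step), cfg.loss))
            for ep in val_episodes
        ]
        return float(np.mean(losses))

    loss_and_grad = value_and_grad(_episode_loss)
    step = 0
    for step in range(cfg.steps):
        episode = next(stream)
        if cfg.augment is not None:
            episode = augment(episode, cfg.augment, rng)
        k = top_k_at(cfg, step)
        params = unflatten(flat)
        loss, grads = loss_and_grad(params, model.ema.shadow, episode, k, cfg.loss)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss {loss!r} at step {step}; aborting")
        gflat, _ = flatten(grads)
        lr = lr_at(cfg, step)
        t = step + 1
        m = cfg.adam_beta1 * m + (1 - cfg.adam_beta1) * gflat
        v = cfg.adam_beta2 * v + (1 - cfg.adam_beta2) * gflat ** 2
        mhat = m / (1 - cfg.adam_beta1 ** t)
        vhat = v / (1 - cfg.adam_beta2 ** t)
        flat = flat - lr * (mhat / (np.sqrt(vhat) + cfg.adam_eps)
                            + cfg.weight_decay * flat)
        model.params = unflatten(flat)
        model.update_ema()
        row = {"step": step, "train_loss": float(loss), "val_loss": "",
               "lr": lr, "top_k": k}
        if val_episodes and (step + 1) % cfg.val_every == 0:
            vl = val_loss(model.params, model.ema.shadow, step)
            row["val_loss"] = vl
            if vl < best_val:
                best_val = vl
                best_flat = flat.copy()
                best_ema = model.ema
                bad_rounds = 0
            else:
                bad_rounds += 1
                if bad_rounds >= cfg.early_stop_patience:
                    metrics.append(row)
                    stopped = True
                    break
        metrics.append(row)
        if progress is not None:
            progress(step, float(loss))
    if val_episodes and best_val < math.inf:
        model.params = unflatten(best_flat)
        model.ema = best_ema
    result = TrainResult(model=model, metrics=metrics,
                         best_val_loss=best_val, stopped_early=stopped)
    if log_csv is not None:
        result.write_csv(log_csv)
    return result
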