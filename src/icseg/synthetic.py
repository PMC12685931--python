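"""Task-structured synthetic episodes for in-context segmentation.

A *task* couples a shape family (what to segment) with an appearance model
(how it looks): foreground/background intensity levels, texture noise, a
size range, a spatial offset budget between the support targets and the
query target (so that attention must act globally, not locally), and a
number of same-intensity decoy shapes from a *different* family.  Decoys are
what make the problem genuinely in-context: intensity alone cannot identify
the target — the model has to read the support masks to know which family to
segment.  Held-out tasks are partitioned disjointly from training tasks to
probe generalization to unseen shape/appearance combinations.

What this generator does *not* emulate: real anatomy, imaging physics,
inter-rater annotation noise, or 3-D structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .model import Episode

__all__ = [
    "SHAPE_FAMILIES",
    "TaskSpec",
    "generate_task",
    "conjugate_task",
    "generate_episode",
    "episode_stream",
    "dice_score",
    "evaluate",
    "EvaluationResult",
]

SHAPE_FAMILIES = ("disk", "rectangle", "ring", "blob-union", "thin-vessel")
MIN_MASK_AREA = 10  # pixels; episodes below this are resampled


@dataclass(frozen=True)
class TaskSpec:
    task_id: str
    shape_family: str
    fg_level: float
    bg_level: float
    noise_sigma: float
    offset_frac: float          # max query-vs-support target translation / size
    size_range: tuple           # relative (lo, hi) of the image size
    n_distractors: int
    distractor_family: str
    held_out: bool = False


def generate_task(rng, task_id: Optional[str] = None, held_out: bool = False) -> TaskSpec:
    """Sample one task: family, appearance, offsets, decoys."""
    family = SHAPE_FAMILIES[rng.integers(len(SHAPE_FAMILIES))]
    bg = rng.uniform(0.15, 0.45)
    delta = rng.uniform(0.2, 0.45) * (1 if rng.random() < 0.5 else -1)
    fg = float(np.clip(bg + delta, 0.05, 0.95))
    others = [f for f in SHAPE_FAMILIES if f != family]
    return TaskSpec(
        task_id=task_id or f"task-{rng.integers(1 << 30):08x}",
        shape_family=family,
        fg_level=fg,
        bg_level=float(bg),
        noise_sigma=float(rng.uniform(0.02, 0.06)),
        offset_frac=float(rng.uniform(0.05, 0.3)),
        size_range=(0.10, 0.22),
        n_distractors=int(rng.integers(0, 3)),
        distractor_family=others[rng.integers(len(others))],
        held_out=held_out,
    )


def conjugate_task(task: TaskSpec) -> TaskSpec:
    """The same scenes, the other semantic: swap target and decoy families.

    A task and its conjugate share one appearance model and scene statistics
    (both families present at the same intensity), so the query image alone
    cannot reveal which family is the target — only the support masks can.
    Including conjugate pairs in a training stream is what forces genuine
    in-context conditioning instead of appearance shortcuts.
    """
    import dataclasses

    return dataclasses.replace(
        task,
        task_id=task.task_id + "*",
        shape_family=task.distractor_family,
        distractor_family=task.shape_family,
        n_distractors=max(task.n_distractors, 1),
    )


# ---------------------------------------------------------------------------
# shape rendering


def _render_shape(family: str, center, scale: float, size: int, rng) -> np.ndarray:
    """Binary (size, size) raster of one shape instance."""
    mask = np.zeros((size, size), dtype=bool)
    r0, c0 = center
    if family == "disk":
        rr, cc = skdraw.disk((r0, c0), scale, shape=mask.shape)
        mask[rr, cc] = True
    elif family == "rectangle":
        aspect = rng.uniform(0.5, 1.5)
        hr, hc = scale, scale * aspect
        rr, cc = skdraw.rectangle(
            (max(int(r0 - hr), 0), max(int(c0 - hc), 0)),
            end=(min(int(r0 + hr), size - 1), min(int(c0 + hc), size - 1)),
            shape=mask.shape)
        mask[rr.astype(int), cc.astype(int)] = True
    elif family == "ring":
        rr, cc = skdraw.disk((r0, c0), scale, shape=mask.shape)
        mask[rr, cc] = True
        rr, cc = skdraw.disk((r0, c0), max(scale * 0.55, 1.5), shape=mask.shape)
        inner = np.zeros_like(mask)
        inner[rr, cc] = True
        mask &= ~inner
    elif family == "blob-union":
        for _ in range(3):
            jitter = rng.uniform(-0.6, 0.6, size=2) * scale
            rr, cc = skdraw.disk((r0 + jitter[0], c0 + jitter[1]),
                                 max(scale * rng.uniform(0.4, 0.7), 2.0),
                                 shape=mask.shape)
            mask[rr, cc] = True
    elif family == "thin-vessel":
        # jagged polyline through the local region, dilated to a ~2 px vessel
        npts = 5
        ang = rng.uniform(0, 2 * np.pi)
        along = np.linspace(-1.6 * scale, 1.6 * scale, npts)
        across = rng.uniform(-0.5 * scale, 0.5 * scale, npts)
        rows = r0 + along * np.sin(ang) + across * np.cos(ang)
        cols = c0 + along * np.cos(ang) - across * np.sin(ang)
        for i in range(npts - 1):
            rr, cc = skdraw.line(int(np.clip(rows[i], 0, size - 1)),
                                 int(np.clip(cols[i], 0, size - 1)),
                                 int(np.clip(rows[i + 1], 0, size - 1)),
                                 int(np.clip(cols[i + 1], 0, size - 1)))
            mask[rr, cc] = True
        mask = ndimage.binary_dilation(mask, iterations=1)
    else:  # pragma: no cover
        raise ValueError(f"unknown shape family {family!r}")
    return mask


def _render_sample(task: TaskSpec, center, size: int, rng):
    """One (image, mask) pair: target at `center`, decoys elsewhere."""
    scale = rng.uniform(*task.size_range) * size
    for _ in range(20):
        mask = _render_shape(task.shape_family, center, scale, size, rng)
        if mask.sum() >= MIN_MASK_AREA:
            break
        scale *= 1.3
    img = np.full((size, size), task.bg_level)
    img[mask] = task.fg_level
    decoys = np.zeros_like(mask)
    for _ in range(task.n_distractors):
        dc = rng.uniform(0.15, 0.85, size=2) * size
        dmask = _render_shape(task.distractor_family, dc,
                              rng.uniform(*task.size_range) * size, size, rng)
        dmask &= ~mask  # decoys never overwrite the target
        img[dmask] = task.fg_level
        decoys |= dmask
    img = ndimage.gaussian_filter(img, 0.7)
    img = img + rng.normal(0.0, task.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0), mask.astype(float), decoys.astype(float)


def generate_episode(task: TaskSpec, S: int, rng, size: int = 256) -> Episode:
    """One query + S support pairs sharing the task's appearance model.

    Support targets sit near a per-episode anchor; the query target is
    translated away from it by up to ``offset_frac * size``.
    """
    if S < 1:
        raise ValueError("support size S must be >= 1")
    anchor = rng.uniform(0.35, 0.65, size=2) * size
    margin = 0.18 * size

    def clipc(c):
        return np.clip(c, margin, size - margin)

    sup_images, sup_masks = [], []
    for _ in range(S):
        c = clipc(anchor + rng.uniform(-0.08, 0.08, size=2) * size)
        im, mk, _ = _render_sample(task, c, size, rng)
        sup_images.append(im)
        sup_masks.append(mk)
    qc = clipc(anchor + rng.uniform(-task.offset_frac, task.offset_frac, size=2) * size)
    q_img, q_mask, q_decoys = _render_sample(task, qc, size, rng)
    ep = Episode(query_image=q_img, query_mask=q_mask,
                 support_images=np.stack(sup_images),
                 support_masks=np.stack(sup_masks),
                 task_id=task.task_id)
    # the union of same-intensity decoy shapes is the ground truth of the
    # conjugate semantic ("segment the other family") on this same scene
    ep.query_decoy_mask = q_decoys
    return ep


def episode_stream(tasks: list, S: int, rng, size: int = 256):
    """Endless stream of episodes, sampled uniformly over task families
    (task resampling balances under-represented tasks by construction)."""
    tasks = list(tasks)
    if any(t.held_out for t in tasks):
        raise ValueError("held-out tasks must not appear in a training stream")
    while True:
        yield generate_episode(tasks[rng.integers(len(tasks))], S, rng, size=size)


# ---------------------------------------------------------------------------
# metric and evaluation protocol


def dice_score(pred_mask, target) -> float:
    """Overlap score 2|P.T| / (|P| + |T|) on binary rasters.

    Empty-vs-empty is defined as 1 (both agree there is nothing);
    empty-vs-nonempty is 0.
    """
    p = np.asarray(pred_mask) > 0.5
    t = np.asarray(target) > 0.5
    if p.shape != t.shape:
        raise ValueError("prediction and target must share a shape")
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


@dataclass
class EvaluationResult:
    #: (task_id, shape_family, S, dice) per evaluated query
    records: list

    def mean_per_task(self) -> dict:
        acc = {}
        for task_id, fam, S, d in self.records:
            acc.setdefault((task_id, S), []).append(d)
        return {k: float(np.mean(v)) for k, v in acc.items()}

    def mean_per_s(self) -> dict:
        """Two-level mean: first within each task, then across tasks."""
        per_task = self.mean_per_task()
        acc = {}
        for (task_id, S), m in per_task.items():
            acc.setdefault(S, []).append(m)
        return {S: float(np.mean(v)) for S, v in sorted(acc.items())}

    def mean_per_family_s(self) -> dict:
        """Second aggregate: within task, within family, then across families."""
        fam_of = {}
        for task_id, fam, S, d in self.records:
            fam_of[task_id] = fam
        per_task = self.mean_per_task()
        fam_acc = {}
        for (task_id, S), m in per_task.items():
            fam_acc.setdefault((fam_of[task_id], S), []).append(m)
        out = {}
        for (fam, S), v in fam_acc.items():
            out.setdefault(S, {})[fam] = float(np.mean(v))
        return {S: float(np.mean(list(fams.values()))) for S, fams in sorted(out.items())}


def evaluate(predictor, tasks: Iterable[TaskSpec], S_values, episodes_per_task: int,
             rng, size: int = 256, top_k: Optional[int] = None) -> EvaluationResult:
    """Evaluation protocol: a fresh support set is resampled for every query
    (no static support bias); aggregation is two-level (queries -> task ->
    global).  ``predictor`` is an :class:`InContextSegmenter` or any callable
    mapping an Episode to a probability mask."""
    records = []
    for task in tasks:
        for S in S_values:
            for _ in range(episodes_per_task):
                ep = generate_episode(task, S, rng, size=size)
                if hasattr(predictor, "predict"):
                    kwargs = {} if top_k is None else {"top_k": top_k}
                    probs = predictor.predict(ep, **kwargs).mask
                else:
                    probs = predictor(ep)
                records.append((task.task_id, task.shape_family, S,
                                dice_score(probs > 0.5, ep.query_mask)))
    return EvaluationResult(records=records)
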