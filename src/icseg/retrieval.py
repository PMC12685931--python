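"""Content-based support-set retrieval from an annotated pool.

The cross-attention mapper doubles as a retrieval system: every pool image
is embedded by the EMA attention encoder at the coarsest level under the
attention key projection, and query regions are embedded the same way.
Matching uses the normalized cross-correlation of these embeddings about
the index mean — the centered, scale-free version of the similarity the
attention softmax ranks within an episode — so nearest neighbours are pool
locations the model itself would consider similar.  Retrieval replaces a
static, generic support set with a query-personalized one, and the
Monte-Carlo experiment below measures the DICE increment of that swap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .augment import mask_edge
from .decoder import _flat_s
from .encoders import encode_support
from .model import Episode, InContextSegmenter
from .synthetic import dice_score, generate_episode

__all__ = [
    "EmbeddingIndex",
    "RetrievalExperimentConfig",
    "build_index",
    "sample_contour_locations",
    "build_custom_support",
    "delta_dice_experiment",
]


@dataclass
class EmbeddingIndex:
    """One entry per (pool image, coarse-grid cell).

    ``embeddings``: (n_images * grid * grid, d) key-projected EMA features;
    ``image_ids[j]`` is the pool index owning entry j.
    """

    embeddings: np.ndarray
    image_ids: np.ndarray
    locations: np.ndarray  # (n_entries, 2) coarse (row, col)
    grid: int
    pool_images: np.ndarray
    pool_masks: np.ndarray

    @property
    def center(self):
        """Mean embedding; matching correlates residuals about this mean."""
        return self.embeddings.mean(axis=0)


@dataclass
class RetrievalExperimentConfig:
    N: int = 150               # labeled pool size
    M: int = 100               # unlabeled query count
    S: int = 8                 # support set size
    repetitions: int = 10
    contour_samples: int = 8

    def __post_init__(self):
        if self.N < self.S:
            raise ValueError("pool must be at least as large as the support set")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def build_index(pool_images, pool_masks, model: InContextSegmenter) -> EmbeddingIndex:
    """Embed every pool image with the EMA attention encoder and store the
    W_K-projected coarsest feature vectors, one per coarse cell."""
    pool_images = np.asarray(pool_images)
    if len(pool_images) == 0:
        raise ValueError("cannot index an empty pool")
    pyr = encode_support(model.ema.shadow, pool_images)
    feats = np.asarray(_flat_s(pyr[32]))  # (N * g * g, d), image-major
    emb = feats @ model.params["mapper"]["W_K"]
    g = pyr[32].shape[2]
    n = len(pool_images)
    ids = np.repeat(np.arange(n), g * g)
    rr, cc = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    locs = np.tile(np.stack([rr.ravel(), cc.ravel()], axis=1), (n, 1))
    return EmbeddingIndex(embeddings=emb, image_ids=ids, locations=locs, grid=g,
                          pool_images=pool_images, pool_masks=np.asarray(pool_masks))


def sample_contour_locations(mask, n: int, rng) -> np.ndarray:
    """n pixel coordinates drawn uniformly from the mask boundary band.

    Falls back to the image centre (with a warning) when the mask is empty;
    points repeat when the boundary is shorter than n.
    """
    m = np.asarray(mask) > 0.5
    if not m.any():
        warnings.warn("empty mask: sampling the image centre instead of a contour")
        centre = np.array([[m.shape[0] // 2, m.shape[1] // 2]])
        return np.repeat(centre, n, axis=0)
    band = mask_edge(m.astype(float)) > 0.5
    coords = np.argwhere(band if band.any() else m)
    pick = rng.integers(0, len(coords), size=n)
    return coords[pick]


def build_custom_support(query_image, draft_mask, index: EmbeddingIndex,
                         S: int, model: InContextSegmenter,
                         contour_samples: int = 8, rng=None):
    """Retrieve a query-personalized support set of S distinct pool images.

    Contour points of the draft mask select coarse cells of the query; the
    query is embedded exactly as the pool was (EMA attention encoder +
    key projection) and matched by normalized cross-correlation: cosine of
    the embeddings after subtracting the index mean.  Centering and
    normalization matter — raw trained embeddings share a dominant common
    direction and raw dot products are won by a few large-norm entries
    regardless of the query.  Pool images are ranked by match frequency,
    then by best similarity; if fewer than S distinct images are matched,
    the ranking is padded with the next-most-similar pool images.
    Returns (support_images, support_masks, pool_indices).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    points = sample_contour_locations(draft_mask, contour_samples, rng)
    img = np.asarray(query_image)
    size = img.shape[-1]
    pyr = encode_support(model.ema.shadow, img[None])
    g = pyr[32].shape[2]
    feats = np.asarray(_flat_s(pyr[32]))  # (g*g, d) row-major
    q_emb = feats @ model.params["mapper"]["W_K"]
    cell_of = (points * g // size).clip(0, g - 1)
    cells = cell_of[:, 0] * g + cell_of[:, 1]
    mu = index.center
    q_unit = q_emb[cells] - mu
    q_unit = q_unit / np.maximum(np.linalg.norm(q_unit, axis=1, keepdims=True), 1e-12)
    e_cent = index.embeddings - mu
    e_unit = e_cent / np.maximum(
        np.linalg.norm(e_cent, axis=1, keepdims=True), 1e-12)
    sims = q_unit @ e_unit.T  # (points, entries), normalized cross-correlation
    nearest = np.argmax(sims, axis=1)
    best_sim_per_image = {}
    counts = {}
    for p, entry in enumerate(nearest):
        img_id = int(index.image_ids[entry])
        counts[img_id] = counts.get(img_id, 0) + 1
        s = sims[p, entry]
        best_sim_per_image[img_id] = max(best_sim_per_image.get(img_id, -np.inf), s)
    ranked = sorted(counts, key=lambda i: (-counts[i], -best_sim_per_image[i], i))
    if len(ranked) < S:
        # pad with the next-most-similar images overall
        img_best = np.full(len(index.pool_images), -np.inf)
        flat_best = sims.max(axis=0)
        np.maximum.at(img_best, index.image_ids, flat_best)
        for i in np.argsort(-img_best):
            if int(i) not in ranked:
                ranked.append(int(i))
            if len(ranked) >= S:
                break
    chosen = np.array(ranked[:S], dtype=int)
    return index.pool_images[chosen], index.pool_masks[chosen], chosen


def delta_dice_experiment(tasks, model: InContextSegmenter,
                          cfg: RetrievalExperimentConfig, rng,
                          size: int = 256,
                          sample_pair: Optional[Callable] = None,
                          custom_support_fn: Optional[Callable] = None):
    """Monte-Carlo estimate of the DICE increment from retrieval.

    Per repetition and task: resample a labeled pool of N (image, mask) pairs
    and M query pairs; fix one random generic support set of size S; for each
    query, predict with the generic support, sample contour locations of that
    prediction, retrieve a custom support, re-predict, and record
    Delta = DICE_custom - DICE_generic.  Averages are taken over queries,
    then tasks, then repetitions.

    ``sample_pair(task, rng) -> (image, mask)`` defaults to drawing single
    samples from the synthetic generator; ``custom_support_fn`` can replace
    the retrieval step (e.g. with the generic set itself as a degenerate
    control, which yields Delta = 0 exactly).

    Returns (mean_delta, records) with one record per
    (repetition, task_id, query_idx): dict of generic/custom DICE and delta.
    """
    if sample_pair is None:
        def sample_pair(task, rng):
            ep = generate_episode(task, 1, rng, size=size)
            return ep.query_image, ep.query_mask

    records = []
    for rep in range(cfg.repetitions):
        for task in tasks:
            pool = [sample_pair(task, rng) for _ in range(cfg.N)]
            pool_images = np.stack([p[0] for p in pool])
            pool_masks = np.stack([p[1] for p in pool])
            queries = [sample_pair(task, rng) for _ in range(cfg.M)]
            index = build_index(pool_images, pool_masks, model)
            generic = rng.choice(cfg.N, size=cfg.S, replace=False)
            for qi, (q_img, q_mask) in enumerate(queries):
                ep_gen = Episode(query_image=q_img,
                                 support_images=pool_images[generic],
                                 support_masks=pool_masks[generic])
                pred_gen = model.predict(ep_gen).mask
                d_gen = dice_score(pred_gen > 0.5, q_mask)
                if custom_support_fn is not None:
                    c_imgs, c_masks = custom_support_fn(
                        q_img, pred_gen, index, cfg, generic, rng)
                else:
                    c_imgs, c_masks, _ = build_custom_support(
                        q_img, pred_gen > 0.5, index, cfg.S, model,
                        contour_samples=cfg.contour_samples, rng=rng)
                ep_cus = Episode(query_image=q_img, support_images=c_imgs,
                                 support_masks=c_masks)
                d_cus = dice_score(model.predict(ep_cus).mask > 0.5, q_mask)
                records.append({"repetition": rep, "task_id": task.task_id,
                                "query": qi, "dice_generic": d_gen,
                                "dice_custom": d_cus, "delta": d_cus - d_gen})
    per_rep_task = {}
    for r in records:
        per_rep_task.setdefault((r["repetition"], r["task_id"]), []).append(r["delta"])
    per_rep = {}
    for (rep, _), v in per_rep_task.items():
        per_rep.setdefault(rep, []).append(float(np.mean(v)))
    mean_delta = float(np.mean([np.mean(v) for v in per_rep.values()]))
    return mean_delta, records
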