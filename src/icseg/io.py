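"""File I/O: rasters (PNG/TIFF/NIfTI), dataset manifests, checkpoints.

Images are min-max normalized to [0, 1] and bilinearly resized to the
working resolution; masks are selected by *view ID* (the integer label of
the structure of interest inside a multi-label ground truth), resized with
nearest-neighbour interpolation and binarized.  NIfTI volumes are sliced
along the last (transverse/axial) axis.  Masks whose selected label covers
fewer than 10 pixels are rejected, mirroring the slice-filtering rule used
when assembling 2-D training sets from volumes.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

MIN_MASK_PIXELS = 10

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "load_raster",
    "save_mask_png",
    "save_checkpoint",
    "load_checkpoint",
    "export_attention_maps",
]


@dataclass
class ManifestRecord:
    image: str
    mask: str
    task_id: str
    view_id: int = 1
    split: str = "train"
    slice_index: Optional[int] = None

    def __post_init__(self):
        if self.view_id < 1:
            raise ValueError("view_id must be >= 1")
        if self.split not in ("train", "val", "test"):
            raise ValueError("split must be train/val/test")


@dataclass
class DatasetManifest:
    records: list
    geometry: int = 256

    def to_json(self, path):
        payload = {"geometry": self.geometry,
                   "records": [asdict(r) for r in self.records]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        return cls(records=[ManifestRecord(**r) for r in payload["records"]],
                   geometry=payload["geometry"])

    def validate_paths(self, root="."):
        missing = [r.image for r in self.records
                   if not (Path(root) / r.image).exists()]
        missing += [r.mask for r in self.records
                    if not (Path(root) / r.mask).exists()]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing[:5]}")


def _read_2d(path, slice_index: Optional[int]):
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).dataobj)
        if vol.ndim == 2:
            return vol.astype(float)
        if slice_index is None:
            raise IOError(f"{path}: 3-D volume requires a slice index")
        if not 0 <= slice_index < vol.shape[-1]:
            raise IOError(f"{path}: slice {slice_index} outside volume "
                          f"(last axis has {vol.shape[-1]} slices)")
        return vol[..., slice_index].astype(float)
    try:
        arr = np.asarray(iio.imread(path)).astype(float)
    except Exception as exc:  # add path context
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., :3].mean(axis=-1)
    return arr


def load_raster(path, kind: str = "image", view_id: Optional[int] = None,
                slice_index: Optional[int] = None, size: int = 256) -> np.ndarray:
    """Load a 2-D raster as (size, size) float.

    kind="image": min-max normalized to [0, 1], bilinear resize.
    kind="mask": pixels equal to ``view_id`` (default: anything > 0) selected,
    nearest-neighbour resize, binarized at 0.5.  Raises ``ValueError`` if the
    selected mask covers fewer than 10 pixels.
    """
    arr = _read_2d(path, slice_index)
    if kind == "image":
        lo, hi = float(arr.min()), float(arr.max())
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        return resize(arr, (size, size), order=1, anti_aliasing=False,
                      preserve_range=True)
    if kind == "mask":
        sel = (arr == view_id) if view_id is not None else (arr > 0)
        sel = resize(sel.astype(float), (size, size), order=0,
                     anti_aliasing=False, preserve_range=True) > 0.5
        if sel.sum() < MIN_MASK_PIXELS:
            raise ValueError(
                f"{path}: mask for view_id={view_id} covers {int(sel.sum())} px "
                f"(< {MIN_MASK_PIXELS}); record should be dropped")
        return sel.astype(float)
    raise ValueError("kind must be 'image' or 'mask'")


def save_mask_png(path, mask):
    """Masks stored as 8-bit PNG with {0, 255}; lossless round-trip."""
    iio.imwrite(str(path), ((np.asarray(mask) > 0.5) * 255).astype(np.uint8))


def save_image_png(path, image):
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(str(path), np.round(arr * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# checkpoints


def _flatten_tree(tree, prefix, out):
    if isinstance(tree, dict):
        for k, v in tree.items():
            _flatten_tree(v, f"{prefix}/{k}", out)
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            _flatten_tree(v, f"{prefix}/#{i}", out)
    else:
        out[prefix] = np.asarray(tree)


def _unflatten_tree(flat):
    root = {}
    for key, arr in flat.items():
        parts = key.strip("/").split("/")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = arr

    def listify(node):
        if isinstance(node, dict):
            if node and all(k.startswith("#") for k in node):
                return [listify(node[f"#{i}"]) for i in range(len(node))]
            return {k: listify(v) for k, v in node.items()}
        return node

    return listify(root)


def save_checkpoint(path, model):
    """Checkpoint = npz of online + EMA parameters with an embedded config."""
    from dataclasses import asdict as dc_asdict

    flat = {}
    _flatten_tree(model.params, "params", flat)
    _flatten_tree(model.ema.shadow, "ema", flat)
    cfg = dc_asdict(model.config)
    cfg["ema_decay"] = model.ema.decay
    flat["__config__"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(str(path), **flat)


def load_checkpoint(path):
    from .encoders import EMAState
    from .model import InContextSegmenter, ModelConfig

    if not os.path.exists(path):
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(str(path)) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        flat = {k: data[k] for k in data.files if k != "__config__"}
    tree = _unflatten_tree(flat)
    decay = cfg.pop("ema_decay")
    for key in ("stage_widths", "stage_depths"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    config = ModelConfig(**cfg)
    return InContextSegmenter(config=config, params=tree["params"],
                              ema=EMAState(decay=decay, shadow=tree["ema"]))


def export_attention_maps(out_dir, prediction, S: int, flattening="row-major (H outer, W inner); support examples concatenated in order"):
    """Write per-stage dense attention maps (.npy) with JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not prediction.stage_attention:
        raise ValueError("prediction carries no attention maps; "
                         "predict with collect_attention=True")
    for stride, A, mass in prediction.stage_attention:
        A = np.asarray(A)
        rows = A.shape[0]
        h = int(np.sqrt(rows))
        np.save(out / f"attention_stride{stride}.npy", A)
        sidecar = {"S": S, "H": h, "W": h, "stride": stride,
                   "shape": list(A.shape), "flattening": flattening}
        (out / f"attention_stride{stride}.json").write_text(
            json.dumps(sidecar, indent=1))
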