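"""Reading and writing focal stacks, reference images and dataset manifests.

Disk conventions:

* a 7-plane stack is either one multi-page TIFF (page k holds plane
  ``F_{k-3}``) or seven single-plane PNG/TIFF files named
  ``<stem>_F-3 ... <stem>_F-1, <stem>_F0, <stem>_F+1 ... <stem>_F+3``;
* images are stored 16-bit (TIFF) or 8-bit (PNG) grayscale and
  auto-normalized to [0, 1] on read by their dtype range;
* a dataset is a JSON-lines manifest, one item per line, with stack path,
  reference path, class label, split tag and the generator seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from embryofuse.phantom import DatasetItem, FocalStack, LabeledDataset

__all__ = [
    "PLANE_SUFFIXES", "write_stack", "read_stack", "write_image", "read_image",
    "save_dataset", "load_dataset",
]

PLANE_SUFFIXES = ("F-3", "F-2", "F-1", "F0", "F+1", "F+2", "F+3")


def _to_uint16(plane: np.ndarray) -> np.ndarray:
    return np.round(np.clip(plane, 0.0, 1.0) * 65535.0).astype(np.uint16)


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Map an integer image onto [0, 1] by its dtype range."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_stack(stack: FocalStack, path, fmt: str = "tiff") -> Path:
    """Write a 7-plane stack as one multi-page TIFF or seven PNG files.

    Returns the TIFF path or the stem path of the PNG series.
    """
    path = Path(path)
    stack.validate()
    if fmt == "tiff":
        path = path.with_suffix(".tiff")
        tifffile.imwrite(
            path, np.stack([_to_uint16(p) for p in stack.planes]),
            metadata={"delta_z_um": stack.delta_z},
        )
        return path
    if fmt == "png":
        for suffix, plane in zip(PLANE_SUFFIXES, stack.planes):
            img = Image.fromarray(np.round(np.clip(plane, 0, 1) * 255).astype(np.uint8))
            img.save(path.parent / f"{path.stem}_{suffix}.png")
        return path
    raise ValueError(f"unknown stack format {fmt!r} (expected 'tiff' or 'png')")


def read_stack(path, delta_z: float = 1.0) -> FocalStack:
    """Read a stack from a multi-page TIFF or a PNG-series stem."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] != 7:
            raise ValueError(f"expected 7 pages in {path}, got shape {pages.shape}")
        planes = np.stack([_normalize(p) for p in pages])
    else:
        files = [path.parent / f"{path.stem}_{s}.png" for s in PLANE_SUFFIXES]
        missing = [str(f) for f in files if not f.exists()]
        if missing:
            raise FileNotFoundError(f"missing plane files: {missing}")
        planes = np.stack([_normalize(np.asarray(Image.open(f))) for f in files])
    stack = FocalStack(planes=planes, focal_offsets=np.arange(-3, 4) * delta_z,
                       delta_z=delta_z)
    stack.validate()
    return stack


def write_image(image: np.ndarray, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, _to_uint16(image))
    else:
        Image.fromarray(np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)).save(path)
    return path


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _normalize(tifffile.imread(path))
    return _normalize(np.asarray(Image.open(path).convert("L")))


def save_dataset(dataset: LabeledDataset, out_dir, fmt: str = "tiff") -> Path:
    """Write stacks, references and the JSON-lines manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.jsonl"
    with manifest.open("w") as fh:
        for i, (item, split) in enumerate(zip(dataset.items, dataset.split_assignment)):
            stem = f"item{i:05d}"
            stack_path = write_stack(item.stack, out_dir / stem, fmt=fmt)
            ref_path = write_image(item.reference, out_dir / f"{stem}_ref.png")
            fh.write(json.dumps({
                "stack": stack_path.name,
                "reference": ref_path.name,
                "class_label": item.class_label,
                "split": split,
                "delta_z": item.stack.delta_z,
                "seed": dataset.seed,
            }) + "\n")
    return manifest


def load_dataset(manifest_path) -> LabeledDataset:
    """Rebuild a dataset from a manifest (scenes are not stored on disk)."""
    manifest_path = Path(manifest_path)
    items, splits, seed = [], [], 0
    with manifest_path.open() as fh:
        for line in fh:
            rec = json.loads(line)
            stack = read_stack(manifest_path.parent / rec["stack"],
                               delta_z=rec.get("delta_z", 1.0))
            reference = read_image(manifest_path.parent / rec["reference"])
            items.append(DatasetItem(stack=stack, reference=reference,
                                     class_label=rec["class_label"], scene=None))
            splits.append(rec["split"])
            seed = rec.get("seed", 0)
    return LabeledDataset(items=items, split_assignment=splits, seed=seed)
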