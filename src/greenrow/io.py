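"""Reading and writing the pipeline's on-disk artifacts (PNG, CSV, npz)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .segmentation import normalize_image


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG as a normalized [0, 1] RGB array."""
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
        raw = raw[..., :3]
    if raw.dtype == np.uint8:
        return normalize_image(raw)
    return np.clip(np.asarray(raw, dtype=np.float64), 0.0, 1.0)


def write_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] RGB array as an 8-bit PNG."""
    iio.imwrite(path, np.rint(np.clip(img, 0, 1) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a binary mask."""
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return (raw > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, ((np.asarray(mask) > 0) * 255).astype(np.uint8))


def load_frame_dir(path):
    """Load all PNG/JPEG frames of a directory in sorted filename order.

    Returns ``(frames, names)``; filenames are assumed to sort by timestamp.
    """
    paths = sorted(
        p
        for p in Path(path).iterdir()
        if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/JPEG frames found in {path}")
    return [read_image(p) for p in paths], [p.name for p in paths]


def save_patch_dataset(path, dataset) -> None:
    """Persist a PatchDataset as a compressed npz + CSV manifest."""
    path = Path(path)
    np.savez_compressed(
        path,
        r=dataset.r,
        c=dataset.c,
        patches=dataset.patches,
        labels=dataset.labels,
        provenance=dataset.provenance,
    )
    manifest = pd.DataFrame(
        dataset.provenance, columns=["frame", "row", "col"]
    )
    manifest["label"] = dataset.labels
    manifest.to_csv(path.with_suffix(".csv"), index=False)


def load_patch_dataset(path):
    from .selftrain import PatchDataset

    data = np.load(path)
    return PatchDataset(
        int(data["r"]),
        int(data["c"]),
        data["patches"],
        data["labels"],
        data["provenance"],
    )
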