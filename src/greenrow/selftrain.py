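"""Automatic construction of foreground/background patch training data.

In frames taken just before the foreground and background rows start to
overlap, the two classes are separable by a horizontal cutoff line: every
plant pixel below the line (bottom-up row <= cutoff) is a foreground-plant
pixel (label 1), every plant pixel above it a background-plant pixel (label
0).  The (2r+1) x (2c+1) RGB neighborhood of each labeled pixel, cropped from
the background-removed image, is one training patch — no human annotation is
involved anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rowprofile import ChangePoint, bottomup_to_image_row


@dataclass
class PatchDataset:
    """Labeled mini-image dataset for the foreground/background classifier.

    Attributes
    ----------
    r, c : neighborhood half-height and half-width in pixels
    patches : float32 array of shape (n, 2r+1, 2c+1, 3), intensities in [0,1]
    labels : uint8 array of shape (n,), 1 = foreground plant
    provenance : int array of shape (n, 3) with (frame, image_row, col)
    """

    r: int
    c: int
    patches: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        expected = (n, 2 * self.r + 1, 2 * self.c + 1, 3)
        if self.patches.shape != expected:
            raise ValueError(
                f"patches shape {self.patches.shape} != expected {expected}"
            )
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)


def select_training_frames(cp: ChangePoint, valid, window: int = 3):
    """Frame numbers (1-based) used to build training data.

    The ``window`` frames immediately before the overlap change point that
    have a valid first peak are selected; ``valid`` is a per-frame boolean
    sequence (True where the frame produced a peak width).  If fewer than
    ``window`` such frames exist, all available ones are returned with a
    warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    valid = np.asarray(valid, dtype=bool)
    pre = np.flatnonzero(valid[: cp.frame_index - 1]) + 1  # 1-based
    if pre.size == 0:
        raise ValueError("no valid pre-overlap frames")
    if pre.size < window:
        warnings.warn(
            f"only {pre.size} valid pre-overlap frames available "
            f"(requested {window})"
        )
    return [int(f) for f in pre[-window:]]


def label_pixels(bg_removed: np.ndarray, cutoff_row: int):
    """Label every plant pixel of a background-removed image by a cutoff line.

    A pixel is a plant pixel iff any RGB channel is nonzero.  Plant pixels at
    or below the cutoff (bottom-up row <= ``cutoff_row``) are foreground (1);
    those above are background (0).

    Returns ``(rows, cols, labels)`` — image-coordinate rows, columns and
    binary labels, each of length n_plant_pixels.
    """
    bg_removed = np.asarray(bg_removed, dtype=np.float64)
    n_rows = bg_removed.shape[0]
    if not 0 <= cutoff_row < n_rows:
        raise ValueError(f"cutoff_row {cutoff_row} outside image ({n_rows} rows)")
    plant = bg_removed.sum(axis=2) > 0
    rows, cols = np.nonzero(plant)
    bottomup = n_rows - 1 - rows
    labels = (bottomup <= cutoff_row).astype(np.uint8)
    return rows, cols, labels


def extract_patch(
    img: np.ndarray, row: int, col: int, r: int, c: int
) -> np.ndarray:
    """Crop the (2r+1) x (2c+1) x 3 neighborhood centered at (row, col).

    Positions falling outside the image are zero-filled, consistent with the
    black background of background-removed images.
    """
    img = np.asarray(img)
    n_rows, n_cols = img.shape[:2]
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise ValueError("patch center outside image")
    patch = np.zeros((2 * r + 1, 2 * c + 1, 3), dtype=img.dtype)
    r0, r1 = max(0, row - r), min(n_rows, row + r + 1)
    c0, c1 = max(0, col - c), min(n_cols, col + c + 1)
    patch[r0 - (row - r) : r1 - (row - r), c0 - (col - c) : c1 - (col - c)] = (
        img[r0:r1, c0:c1]
    )
    return patch


def extract_patches(img: np.ndarray, rows, cols, r: int, c: int) -> np.ndarray:
    """Vectorised :func:`extract_patch` for many centers of one image."""
    img = np.asarray(img, dtype=np.float32)
    n_rows, n_cols = img.shape[:2]
    padded = np.zeros((n_rows + 2 * r, n_cols + 2 * c, 3), dtype=np.float32)
    padded[r : r + n_rows, c : c + n_cols] = img
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    window = np.lib.stride_tricks.sliding_window_view(
        padded, (2 * r + 1, 2 * c + 1), axis=(0, 1)
    )  # (n_rows, n_cols, 3, 2r+1, 2c+1)
    return np.ascontiguousarray(
        window[rows, cols].transpose(0, 2, 3, 1)
    )


def build_patch_dataset(
    frames,
    cutoffs,
    r: int = 16,
    c: int = 16,
    per_class_cap: int = 20000,
    seed: int = 0,
    frame_numbers=None,
) -> PatchDataset:
    """Pool cutoff-labeled pixels over frames into a balanced patch dataset.

    Parameters
    ----------
    frames : list of background-removed RGB images (pre-overlap)
    cutoffs : per-frame bottom-up cutoff rows (typically the first-peak upper
        boundary — the valley between the foreground and background rows)
    per_class_cap : maximum patches kept per class; both classes are
        subsampled (seeded) to ``min(n_fg, n_bg, per_class_cap)`` so the
        dataset is exactly balanced
    frame_numbers : optional identifiers stored in the provenance column
        (defaults to 0..len(frames)-1)
    """
    if per_class_cap < 1:
        raise ValueError("per_class_cap must be >= 1")
    frames = list(frames)
    if frame_numbers is None:
        frame_numbers = list(range(len(frames)))
    if len(cutoffs) != len(frames):
        raise ValueError("need one cutoff per frame")
    all_rows, all_cols, all_labels, all_frames = [], [], [], []
    for fnum, img, cutoff in zip(frame_numbers, frames, cutoffs):
        rows, cols, labels = label_pixels(img, cutoff)
        all_rows.append(rows)
        all_cols.append(cols)
        all_labels.append(labels)
        all_frames.append(np.full(rows.size, fnum))
    rows = np.concatenate(all_rows)
    cols = np.concatenate(all_cols)
    labels = np.concatenate(all_labels)
    fnums = np.concatenate(all_frames)

    rng = np.random.default_rng(seed)
    fg_idx = np.flatnonzero(labels == 1)
    bg_idx = np.flatnonzero(labels == 0)
    if fg_idx.size == 0 or bg_idx.size == 0:
        raise ValueError("degenerate training set: one class is empty")
    n_keep = min(fg_idx.size, bg_idx.size, per_class_cap)
    keep = np.concatenate(
        [
            rng.choice(fg_idx, n_keep, replace=False),
            rng.choice(bg_idx, n_keep, replace=False),
        ]
    )
    keep = keep[rng.permutation(keep.size)]

    patches = np.empty((keep.size, 2 * r + 1, 2 * c + 1, 3), dtype=np.float32)
    for i, (fnum, img) in enumerate(zip(frame_numbers, frames)):
        sel = np.flatnonzero(fnums[keep] == fnum)
        if sel.size:
            patches[sel] = extract_patches(
                img, rows[keep[sel]], cols[keep[sel]], r, c
            )
    provenance = np.column_stack([fnums[keep], rows[keep], cols[keep]])
    return PatchDataset(r, c, patches, labels[keep], provenance)


def default_cutoff(bounds) -> int:
    """Default cutoff line: the first peak's upper boundary (the valley
    between the foreground row and the background row)."""
    return bounds.upper_row
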