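"""Plant-vs-soil segmentation and background removal.

The first stage of the pipeline: a color model is fitted by K-means on
reference images with a clean background, each field pixel is assigned to its
nearest cluster center, and pixels belonging to "green" clusters (by excess
green index, 2G - R - B) are kept as plant pixels.  All non-plant pixels are
then painted exact black, producing the *background-removed image* that every
later stage consumes.

This is a deliberately simple, deterministic stand-in for a learned per-pixel
plant segmenter; :class:`ColorModelSegmenter` follows the scikit-learn
estimator protocol so a different classifier can be swapped in.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted
from skimage.transform import resize


class SegmentationError(ValueError):
    """Raised when an image or color model is unusable."""


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to floating point intensities in [0, 1].

    Parameters
    ----------
    raw : ndarray of shape (rows, cols, 3), integer values in 0..255

    Returns
    -------
    ndarray of float64, each intensity divided by 255.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise SegmentationError(
            f"expected a (rows, cols, 3) RGB image, got shape {raw.shape}"
        )
    if raw.min() < 0 or raw.max() > 255:
        raise SegmentationError("8-bit image values must lie in 0..255")
    return raw.astype(np.float64) / 255.0


def denormalize_image(img: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_image`: scale by 255 and round to uint8."""
    img = _check_rgb(img)
    return np.rint(img * 255.0).astype(np.uint8)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise SegmentationError(
            f"expected a (rows, cols, 3) RGB image, got shape {img.shape}"
        )
    return img


def rescale_image(
    img: np.ndarray, target_rows: int, target_cols: int
) -> np.ndarray:
    """Bilinearly resample an RGB image to ``(target_rows, target_cols)``.

    The native camera resolution is downscaled before any analysis (e.g.
    5152x3864 -> 1000x750) purely for computational efficiency.  A warning is
    emitted when the aspect ratio changes by more than 1%.
    """
    img = _check_rgb(img)
    if target_rows <= 0 or target_cols <= 0:
        raise SegmentationError("target size must be positive")
    src_aspect = img.shape[1] / img.shape[0]
    dst_aspect = target_cols / target_rows
    if abs(dst_aspect - src_aspect) / src_aspect > 0.01:
        warnings.warn(
            "aspect ratio changes by more than 1% "
            f"({src_aspect:.4f} -> {dst_aspect:.4f})",
            stacklevel=2,
        )
    if (target_rows, target_cols) == img.shape[:2]:
        return img.copy()
    out = resize(img, (target_rows, target_cols), order=1, anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def excess_green(colors: np.ndarray) -> np.ndarray:
    """Excess green vegetation index 2G - R - B for an (..., 3) color array."""
    colors = np.asarray(colors, dtype=np.float64)
    return 2.0 * colors[..., 1] - colors[..., 0] - colors[..., 2]


class ColorModelSegmenter(ClassifierMixin, BaseEstimator):
    """Nearest-center plant-pixel classifier fitted by K-means on clean images.

    Pixels of the reference images are pooled and clustered in RGB space;
    clusters whose center has excess green index above ``green_margin`` are
    flagged as plant clusters.  A field pixel is a plant pixel iff its nearest
    center belongs to a plant cluster.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of K-means color clusters (>= 2: at least plant and soil).
    green_margin : float, default 0.05
        Excess-green threshold above which a cluster center counts as plant.
    n_init : int, default 10
        K-means restarts.
    random_state : int or None
        Seed for K-means.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, 3)
    plant_clusters_ : ndarray of int, indices of plant clusters
    """

    def __init__(
        self,
        n_clusters: int = 2,
        green_margin: float = 0.05,
        n_init: int = 10,
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.green_margin = green_margin
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, refs, y=None):
        """Fit the color model on a list of clean-background RGB images."""
        if self.n_clusters < 2:
            raise SegmentationError("need at least 2 clusters (plant + soil)")
        if isinstance(refs, np.ndarray) and refs.ndim == 3:
            refs = [refs]
        if not refs:
            raise SegmentationError("need at least one reference image")
        pixels = np.concatenate([_check_rgb(r).reshape(-1, 3) for r in refs])
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(pixels)
        centers = km.cluster_centers_
        plant = np.flatnonzero(excess_green(centers) > self.green_margin)
        if plant.size == 0:
            raise SegmentationError(
                "no green cluster: no center has excess green above "
                f"{self.green_margin}"
            )
        if plant.size == self.n_clusters:
            warnings.warn("all clusters look green; soil model is degenerate")
        self.cluster_centers_ = centers
        self.plant_clusters_ = plant
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        """Label an (n, 3) array of colors: 1 = plant, 0 = other."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=np.float64)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        nearest = d.argmin(axis=1)
        return np.isin(nearest, self.plant_clusters_).astype(np.uint8)

    def segment(self, img: np.ndarray) -> np.ndarray:
        """Segment an RGB image into a binary plant mask (1 = plant)."""
        img = _check_rgb(img)
        return self.predict(img.reshape(-1, 3)).reshape(img.shape[:2])


def fit_color_model(
    refs, k: int = 2, seed: int | None = 0, green_margin: float = 0.05
) -> ColorModelSegmenter:
    """Fit a :class:`ColorModelSegmenter` on clean-background reference images."""
    return ColorModelSegmenter(
        n_clusters=k, green_margin=green_margin, random_state=seed
    ).fit(refs)


def segment_plants(img: np.ndarray, model: ColorModelSegmenter) -> np.ndarray:
    """Binary plant mask for ``img`` under a fitted color model."""
    return model.segment(img)


def remove_background(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Paint every non-plant pixel exact black, keeping plant intensities.

    The result is the *background-removed image*; because black pixels map to
    black again, the operation is idempotent for a fixed mask.
    """
    img = _check_rgb(img)
    mask = np.asarray(mask)
    if mask.shape != img.shape[:2]:
        raise SegmentationError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    return img * (mask > 0)[..., None]
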