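"""Seeded synthetic field scenes with exact ground truth.

The generator emulates the geometry of a row-camera field phenotyping system:
a foreground row of up to 6 plants near the bottom of the image, a denser
background row whose plants stand higher in the image (and therefore *appear*
taller), soil everywhere else, and logistic per-plant growth over the frame
sequence.  Background plants share the foreground color distribution by
default, so the pipeline must separate the rows geometrically; they are drawn
with thinner stems and leaves, reproducing the smaller apparent scale of a
row further from the camera.  Because every plant silhouette is drawn
explicitly, the per-frame foreground/background masks, the first overlap
frame and the per-plant heights are known exactly.

Plants are stem-and-leaf polygons: a vertical stem with alternating arched
leaves whose size scales with the plant's current height.  This captures what
the pipeline consumes — silhouette extent, row-profile peaks, patch-scale
stroke widths — and deliberately omits photometric realism (shadows, wind,
specularity, illumination drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon


@dataclass(frozen=True)
class SynthFieldConfig:
    """Stated world of the synthetic season (defaults are the desk scale:
    a quarter of the 1000x750 working resolution, 60 frames, 4 plants)."""

    rows: int = 188
    cols: int = 250
    n_plants: int = 4  # foreground plants, <= 6
    n_bg_plants: int = 6
    n_frames: int = 60
    fg_baseline: int = 10  # bottom-up row of the foreground plant bases
    bg_baseline: int = 80  # bottom-up row of the background plant bases
    fg_max_height: tuple = (100.0, 130.0)  # per-plant range, px
    bg_max_height: tuple = (80.0, 100.0)
    growth_rate: tuple = (0.12, 0.18)  # logistic rate per frame
    midpoint_frame: tuple = (26.0, 34.0)  # logistic midpoint
    stem_width_fg: int = 5
    stem_width_bg: int = 3
    leaf_width_fg: int = 3
    leaf_width_bg: int = 2
    fg_color: tuple = (0.25, 0.55, 0.20)
    soil_color: tuple = (0.45, 0.36, 0.26)
    bg_color_shift: tuple = (0.0, 0.0, 0.0)  # ablation knob; 0 = same colors
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_plants <= 6:
            raise ValueError("n_plants must be between 1 and 6")
        if self.n_bg_plants and self.bg_baseline <= self.fg_baseline:
            raise ValueError("background baseline must lie above foreground")
        if min(self.fg_max_height) <= 0 or min(self.bg_max_height) <= 0:
            raise ValueError("plant heights must be positive")


@dataclass
class GroundTruth:
    """Exact per-frame truth of a generated sequence.

    ``overlap_frame`` is the 1-based number of the first frame in which the
    foreground and background silhouettes share an image row (None if they
    never do) — the same convention as ``ChangePoint.frame_index``.
    """

    fg_masks: list
    bg_masks: list
    overlap_flags: np.ndarray
    overlap_frame: int | None
    heights_px: np.ndarray  # (n_frames, n_plants) silhouette heights
    plant_intervals: list = field(default_factory=list)  # (start, end) cols
    plant_centers: list = field(default_factory=list)  # stem base columns


def _logistic(t, hmax, rate, mid):
    return hmax / (1.0 + np.exp(-rate * (t - mid)))


@dataclass
class _PlantGeometry:
    x: int
    hmax: float
    rate: float
    mid: float
    lean: float  # stem lean, px per px of height
    leaf_fracs: np.ndarray  # node positions as fractions of current height
    leaf_dirs: np.ndarray  # +1 right / -1 left
    leaf_lens: np.ndarray  # leaf length as fraction of current height


def _make_plants(rng, xs, hmax_range, rate_range, mid_range, n_leaves=4):
    plants = []
    for x in xs:
        fracs = np.sort(rng.uniform(0.3, 0.95, n_leaves))
        dirs = np.where(np.arange(n_leaves) % 2 == 0, 1.0, -1.0)
        if rng.random() < 0.5:
            dirs = -dirs
        plants.append(
            _PlantGeometry(
                x=int(x),
                hmax=rng.uniform(*hmax_range),
                rate=rng.uniform(*rate_range),
                mid=rng.uniform(*mid_range),
                lean=rng.uniform(-0.05, 0.05),
                leaf_fracs=fracs,
                leaf_dirs=dirs,
                leaf_lens=rng.uniform(0.35, 0.5, n_leaves),
            )
        )
    return plants


def _thick_segment(mask, r0, c0, r1, c1, width):
    """Rasterise a thick line segment as a filled quadrilateral."""
    dr, dc = r1 - r0, c1 - c0
    norm = np.hypot(dr, dc)
    if norm == 0:
        return
    ur, uc = -dc / norm, dr / norm  # unit normal
    h = width / 2.0
    rr = np.array([r0 - ur * h, r0 + ur * h, r1 + ur * h, r1 - ur * h])
    cc = np.array([c0 - uc * h, c0 + uc * h, c1 + uc * h, c1 - uc * h])
    r_idx, c_idx = polygon(rr, cc, shape=mask.shape)
    mask[r_idx, c_idx] = True


def _draw_plant(shape, plant, baseline_bu, h, stem_w, leaf_w):
    """Silhouette mask of one plant of current height ``h`` px."""
    n_rows, n_cols = shape
    mask = np.zeros(shape, dtype=bool)
    if h < 1:
        return mask
    base_img = n_rows - 1 - baseline_bu
    top_img = n_rows - 1 - min(baseline_bu + int(round(h)) - 1, n_rows - 1)
    x_top = plant.x + plant.lean * h
    _thick_segment(mask, base_img, plant.x, top_img, x_top, stem_w)
    for frac, dirn, lfrac in zip(
        plant.leaf_fracs, plant.leaf_dirs, plant.leaf_lens
    ):
        node_bu = baseline_bu + frac * h
        if node_bu >= n_rows:
            continue
        llen = lfrac * h
        if llen < 2:
            continue
        node_img = n_rows - 1 - node_bu
        node_x = plant.x + plant.lean * frac * h
        tip_img = node_img - 0.35 * llen  # leaves arch upward and outward
        tip_x = node_x + dirn * 0.9 * llen
        _thick_segment(mask, node_img, node_x, tip_img, tip_x, leaf_w)
    return mask


def _mask_height(mask):
    rows = np.flatnonzero(mask.any(axis=1))
    return 0 if rows.size == 0 else int(rows.max() - rows.min() + 1)


def generate_field_sequence(
    cfg: SynthFieldConfig = SynthFieldConfig(), seed: int | None = None
):
    """Generate a time-lapse field sequence with exact ground truth.

    Returns ``(frames, truth)``: a list of (rows, cols, 3) float images in
    [0, 1] and a :class:`GroundTruth`.  Fully determined by ``cfg`` and
    ``seed`` (``seed=None`` uses ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = (cfg.rows, cfg.cols)

    spacing = cfg.cols / (cfg.n_plants + 1)
    fg_xs = [
        spacing * (i + 1) + rng.uniform(-0.1, 0.1) * spacing
        for i in range(cfg.n_plants)
    ]
    fg_plants = _make_plants(
        rng, fg_xs, cfg.fg_max_height, cfg.growth_rate, cfg.midpoint_frame
    )
    bg_spacing = cfg.cols / max(cfg.n_bg_plants, 1)
    bg_xs = [
        bg_spacing * (i + 0.5) + rng.uniform(-0.1, 0.1) * bg_spacing
        for i in range(cfg.n_bg_plants)
    ]
    bg_plants = _make_plants(
        rng, bg_xs, cfg.bg_max_height, cfg.growth_rate, cfg.midpoint_frame
    )

    fg_color = np.array(cfg.fg_color)
    bg_color = fg_color + np.array(cfg.bg_color_shift)
    soil = np.array(cfg.soil_color)

    frames, fg_masks, bg_masks = [], [], []
    heights = np.zeros((cfg.n_frames, cfg.n_plants))
    overlap_flags = np.zeros(cfg.n_frames, dtype=bool)
    noise_rngs = rng.spawn(cfg.n_frames)
    for t in range(cfg.n_frames):
        fg = np.zeros(shape, dtype=bool)
        for p, plant in enumerate(fg_plants):
            h = _logistic(t, plant.hmax, plant.rate, plant.mid)
            pm = _draw_plant(
                shape, plant, cfg.fg_baseline, h,
                cfg.stem_width_fg, cfg.leaf_width_fg,
            )
            heights[t, p] = _mask_height(pm)
            fg |= pm
        bg_full = np.zeros(shape, dtype=bool)
        for plant in bg_plants:
            h = _logistic(t, plant.hmax, plant.rate, plant.mid)
            bg_full |= _draw_plant(
                shape, plant, cfg.bg_baseline, h,
                cfg.stem_width_bg, cfg.leaf_width_bg,
            )
        bg = bg_full & ~fg  # foreground occludes the row behind it
        overlap_flags[t] = bool(
            (fg.any(axis=1) & bg_full.any(axis=1)).any()
        )

        img = np.empty((*shape, 3))
        img[:] = soil
        img[bg] = bg_color
        img[fg] = fg_color
        img += noise_rngs[t].normal(0.0, cfg.noise_sd, img.shape)
        frames.append(np.clip(img, 0.0, 1.0))
        fg_masks.append(fg)
        bg_masks.append(bg)

    hit = np.flatnonzero(overlap_flags)
    overlap_frame = int(hit[0]) + 1 if hit.size else None
    intervals = _true_intervals(fg_plants, cfg)
    return frames, GroundTruth(
        fg_masks,
        bg_masks,
        overlap_flags,
        overlap_frame,
        heights,
        intervals,
        [p.x for p in fg_plants],
    )


def _true_intervals(fg_plants, cfg):
    """Column interval owned by each foreground plant (midpoints between
    neighboring plant stems)."""
    xs = sorted(p.x for p in fg_plants)
    edges = (
        [0]
        + [int((a + b) / 2) for a, b in zip(xs, xs[1:])]
        + [cfg.cols - 1]
    )
    return [(edges[i], edges[i + 1]) for i in range(len(xs))]


def generate_greenhouse_refs(
    cfg: SynthFieldConfig = SynthFieldConfig(),
    seed: int | None = None,
    n_images: int = 2,
    n_plants: int = 3,
):
    """Clean-background reference images for fitting the color model.

    Mature plants in front of a uniform light backdrop, standing on a
    soil-colored floor strip (greenhouse pots/ground) — so the reference
    pixels cover all three color modes the field images contain: plant
    green, bright background and soil brown.  ``n_plants=0`` yields the
    bare backdrop and floor (uniform up to the configured noise).
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    shape = (cfg.rows, cfg.cols)
    backdrop = np.array([0.78, 0.78, 0.80])
    floor_rows = max(cfg.rows // 8, 1)
    images = []
    for _ in range(n_images):
        img = np.empty((*shape, 3))
        img[:] = backdrop
        img[-floor_rows:] = cfg.soil_color
        if n_plants:
            xs = np.linspace(0, cfg.cols, n_plants + 2)[1:-1]
            for plant in _make_plants(
                rng, xs, cfg.fg_max_height, cfg.growth_rate,
                (0.0, 0.0),  # midpoint 0: full height
            ):
                pm = _draw_plant(
                    shape, plant, 5, plant.hmax,
                    cfg.stem_width_fg, cfg.leaf_width_fg,
                )
                img[pm] = cfg.fg_color
        img += rng.normal(0.0, cfg.noise_sd, img.shape)
        images.append(np.clip(img, 0.0, 1.0))
    return images


def generate_growth_curves(
    n: int,
    mean: np.ndarray,
    eigenfunctions: np.ndarray,
    score_sds,
    noise_sd: float,
    grid: np.ndarray,
    seed: int = 0,
):
    """Sample curves from a Karhunen-Loeve model with planted components.

    ``Y_i = mean + sum_k xi_ik psi_k + eps`` with ``xi_ik ~ N(0, sd_k^2)``
    and iid N(0, noise_sd^2) grid noise.  ``eigenfunctions`` (K, m) must be
    orthonormal under trapezoid quadrature on ``grid``.

    Returns ``(curves, scores)`` for recovery tests.
    """
    grid = np.asarray(grid, dtype=np.float64)
    mean = np.asarray(mean, dtype=np.float64)
    psi = np.atleast_2d(np.asarray(eigenfunctions, dtype=np.float64))
    w = np.zeros_like(grid)
    w[1:] += 0.5 * np.diff(grid)
    w[:-1] += 0.5 * np.diff(grid)
    gram = (psi * w) @ psi.T
    if not np.allclose(gram, np.eye(psi.shape[0]), atol=1e-6):
        raise ValueError(
            "eigenfunctions are not orthonormal under trapezoid quadrature"
        )
    rng = np.random.default_rng(seed)
    score_sds = np.asarray(score_sds, dtype=np.float64)
    scores = rng.normal(0.0, 1.0, (n, psi.shape[0])) * score_sds
    curves = mean + scores @ psi
    if noise_sd > 0:
        curves = curves + rng.normal(0.0, noise_sd, curves.shape)
    return curves, scores


def orthonormal_polynomials(grid: np.ndarray, k: int) -> np.ndarray:
    """First ``k`` Legendre-like functions orthonormalised by Gram-Schmidt
    under trapezoid quadrature on ``grid`` (handy planted eigenfunctions)."""
    grid = np.asarray(grid, dtype=np.float64)
    w = np.zeros_like(grid)
    w[1:] += 0.5 * np.diff(grid)
    w[:-1] += 0.5 * np.diff(grid)
    x = np.linspace(-1.0, 1.0, grid.size)
    basis = np.vstack([x**j for j in range(k)])
    out = []
    for b in basis:
        for o in out:
            b = b - (w * o) @ b * o
        b = b / np.sqrt((w * b) @ b)
        out.append(b)
    return np.vstack(out)
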