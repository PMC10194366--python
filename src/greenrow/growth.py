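"""Monotone growth-curve fitting and functional PCA of growth curves.

Plant height is physically nondecreasing over the season, so each plant's
scattered height observations are fitted by a *smooth-then-project*
estimator: a local-linear kernel smoother evaluated on a regular grid,
followed by the pool-adjacent-violators (PAVA) projection onto nondecreasing
sequences — the least-squares-closest monotone curve to the smoothed values.

Across genotypes, the fitted curves Y_i(t) are decomposed by functional
principal components analysis via the Karhunen-Loeve expansion

    Y_i(t) = mu(t) + sum_k  xi_ik psi_k(t),

where mu is the mean function, psi_k the orthonormal eigenfunctions of the
sample covariance operator (quadrature-weighted on the grid) and xi_ik the
FPC scores.  The number of retained components K defaults to the smallest K
explaining at least 95% of the total variance; in practice the first
component moves the whole curve up or down (overall growth rate) and the
second tilts it (early vs late vigor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.isotonic import IsotonicRegression
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class GrowthCurve:
    """A fitted nondecreasing growth curve on a time grid."""

    times: np.ndarray
    heights: np.ndarray
    n_obs: int

    def __post_init__(self):
        if np.any(np.diff(self.heights) < -1e-9):
            raise ValueError("growth curve must be nondecreasing")

    def __call__(self, t):
        return np.interp(t, self.times, self.heights)


def _silverman_bandwidth(times: np.ndarray) -> float:
    """Rule-of-thumb kernel bandwidth on the time axis."""
    n = times.size
    sd = times.std(ddof=1) if n > 1 else 1.0
    iqr = np.subtract(*np.percentile(times, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(np.ptp(times), 1.0)
    return 0.9 * spread * n ** (-0.2)


def _local_linear(times, heights, grid, bandwidth):
    """Gaussian local-linear regression of heights on times, on a grid."""
    d = grid[:, None] - times[None, :]
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * d).sum(axis=1)
    s2 = (w * d * d).sum(axis=1)
    t0 = (w * heights).sum(axis=1)
    t1 = (w * d * heights).sum(axis=1)
    denom = s0 * s2 - s1 * s1
    # fall back to the local constant (Nadaraya-Watson) fit where the local
    # design is singular (e.g. a grid point far from all observations)
    safe = denom > 1e-12 * np.maximum(s0, 1e-300) ** 2
    out = np.empty_like(s0)
    out[safe] = (s2[safe] * t0[safe] - s1[safe] * t1[safe]) / denom[safe]
    out[~safe] = t0[~safe] / np.maximum(s0[~safe], 1e-300)
    return out


class MonotoneGrowthRegressor(RegressorMixin, BaseEstimator):
    """Nonparametric regression with a nondecreasing trend (smooth + PAVA).

    A Gaussian local-linear smoother (bandwidth by Silverman's rule on the
    observation times unless given) is evaluated on ``n_grid`` equally spaced
    points over the observed time range, then projected onto nondecreasing
    sequences by PAVA.  With ``smooth=False`` the PAVA projection is applied
    directly to the time-ordered observations — the pure isotonic fit.

    Attributes
    ----------
    grid_times_ : ndarray, the fitting grid
    fitted_heights_ : ndarray, nondecreasing fitted values on the grid
    bandwidth_ : float (nan when ``smooth=False``)
    n_obs_ : int
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        n_grid: int = 100,
        smooth: bool = True,
    ):
        self.bandwidth = bandwidth
        self.n_grid = n_grid
        self.smooth = smooth

    def fit(self, X, y):
        times = np.asarray(X, dtype=np.float64).ravel()
        heights = np.asarray(y, dtype=np.float64).ravel()
        if times.size != heights.size or times.size < 2:
            raise ValueError("need at least 2 (time, height) observations")
        if np.ptp(times) == 0:
            raise ValueError("all observation times are equal")
        order = np.argsort(times, kind="stable")
        times, heights = times[order], heights[order]
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        if self.smooth:
            grid = np.linspace(times[0], times[-1], self.n_grid)
            bw = (
                self.bandwidth
                if self.bandwidth is not None
                else _silverman_bandwidth(times)
            )
            smoothed = _local_linear(times, heights, grid, bw)
            fitted = iso.fit_transform(grid, smoothed)
            self.bandwidth_ = float(bw)
        else:
            grid = times
            fitted = iso.fit_transform(np.arange(times.size), heights)
            self.bandwidth_ = float("nan")
        self.grid_times_ = grid
        self.fitted_heights_ = fitted
        self.n_obs_ = times.size
        return self

    def predict(self, X):
        check_is_fitted(self, "fitted_heights_")
        t = np.asarray(X, dtype=np.float64).ravel()
        return np.interp(t, self.grid_times_, self.fitted_heights_)

    @property
    def curve_(self) -> GrowthCurve:
        check_is_fitted(self, "fitted_heights_")
        return GrowthCurve(self.grid_times_, self.fitted_heights_, self.n_obs_)


def fit_monotone_curve(times, heights, **kwargs) -> GrowthCurve:
    """Fit a nondecreasing growth curve to scattered height observations."""
    return MonotoneGrowthRegressor(**kwargs).fit(times, heights).curve_


def genotype_median_curves(
    observations: pd.DataFrame,
    grid: np.ndarray,
    genotype_col: str = "genotype",
    time_col: str = "timestamp",
    height_col: str = "height_px",
    **fit_kwargs,
):
    """Median-height growth curve per genotype, evaluated on a common grid.

    For each genotype the median height across its plants is taken at every
    observation time, a monotone curve is fitted to those medians, and the
    curve is evaluated on ``grid``.  Genotypes whose fit fails (e.g. a single
    observation time) are skipped with a warning.

    Returns ``(curves, genotypes)``: an (n_genotypes, len(grid)) array and
    the matching genotype labels.
    """
    grid = np.asarray(grid, dtype=np.float64)
    curves, names = [], []
    for geno, grp in observations.groupby(genotype_col, sort=True):
        med = grp.groupby(time_col)[height_col].median()
        try:
            curve = fit_monotone_curve(
                med.index.to_numpy(), med.to_numpy(), **fit_kwargs
            )
        except ValueError as exc:
            warnings.warn(f"genotype {geno!r} skipped: {exc}")
            continue
        curves.append(curve(grid))
        names.append(geno)
    if not curves:
        raise ValueError("no genotype produced a growth curve")
    return np.vstack(curves), names


class FPCA(TransformerMixin, BaseEstimator):
    """Functional PCA of curves sampled on a common grid.

    The sample covariance operator is eigen-decomposed under trapezoid
    quadrature, giving eigenfunctions orthonormal in L2 on the grid.  Scores
    are the quadrature inner products of the centered curves with the
    eigenfunctions.  Each eigenfunction's sign is fixed so its integral (or
    its value at the last grid point when the integral is numerically zero)
    is positive.

    Parameters
    ----------
    var_threshold : float, default 0.95
        Smallest K with cumulative explained-variance fraction >= threshold
        is retained (used when ``n_components`` is None).
    n_components : int or None
        Fixed number of retained components.

    Attributes
    ----------
    grid_ : ndarray of shape (m,)
    mean_ : ndarray of shape (m,), the mean function mu(t)
    eigenfunctions_ : ndarray of shape (rank, m), all computed psi_k
    eigenvalues_ : ndarray of shape (rank,), nonincreasing, >= 0
    explained_variance_ratio_ : ndarray of shape (rank,)
    scores_ : ndarray (n_curves, rank), training FPC scores xi_ik
    n_components_ : int, retained K
    degenerate_ : bool, True when the curves carry no variance
    """

    def __init__(
        self, var_threshold: float = 0.95, n_components: int | None = None
    ):
        self.var_threshold = var_threshold
        self.n_components = n_components

    def _quad_weights(self, grid):
        w = np.zeros_like(grid)
        w[1:] += 0.5 * np.diff(grid)
        w[:-1] += 0.5 * np.diff(grid)
        return w

    def fit(self, X, y=None, grid: np.ndarray | None = None):
        Y = np.asarray(X, dtype=np.float64)
        if Y.ndim != 2 or Y.shape[0] < 3:
            raise ValueError("need at least 3 curves on a common grid")
        n, m = Y.shape
        grid = (
            np.arange(m, dtype=np.float64)
            if grid is None
            else np.asarray(grid, dtype=np.float64)
        )
        if grid.shape != (m,):
            raise ValueError("grid length must match curve length")
        w = self._quad_weights(grid)
        sqw = np.sqrt(w)
        mean = Y.mean(axis=0)
        centered = Y - mean
        # quadrature-symmetrised covariance eigenproblem
        M = (sqw[:, None] * np.cov(centered, rowvar=False, ddof=1)) * sqw
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(evals)[::-1]
        rank = min(n - 1, m)
        evals = np.clip(evals[order][:rank], 0.0, None)
        psi = (evecs[:, order][:, :rank] / sqw[:, None]).T  # (rank, m)
        # sign convention
        integrals = psi @ w
        span = np.sqrt(grid[-1] - grid[0]) if grid[-1] > grid[0] else 1.0
        for k in range(rank):
            s = integrals[k] if abs(integrals[k]) > 1e-8 * span else psi[k, -1]
            if s < 0:
                psi[k] *= -1.0
        total = evals.sum()
        self.grid_ = grid
        self.mean_ = mean
        self.eigenfunctions_ = psi
        self.eigenvalues_ = evals
        self.scores_ = centered @ (w * psi).T
        if total <= max(1e-12, 1e-12 * np.abs(Y).max() ** 2):
            self.degenerate_ = True
            self.explained_variance_ratio_ = np.zeros(rank)
            self.n_components_ = 0
            return self
        self.degenerate_ = False
        frac = evals / total
        self.explained_variance_ratio_ = frac
        if self.n_components is not None:
            if self.n_components > rank:
                raise ValueError(
                    f"requested {self.n_components} components but only "
                    f"{rank} are available"
                )
            self.n_components_ = int(self.n_components)
        else:
            self.n_components_ = int(
                np.searchsorted(np.cumsum(frac), self.var_threshold) + 1
            )
        return self

    @property
    def components_(self):  # sklearn-style alias
        return self.eigenfunctions_

    def transform(self, X):
        check_is_fitted(self, "mean_")
        Y = np.asarray(X, dtype=np.float64)
        w = self._quad_weights(self.grid_)
        K = self.n_components_
        return (Y - self.mean_) @ (w * self.eigenfunctions_[:K]).T

    def inverse_transform(self, scores):
        check_is_fitted(self, "mean_")
        scores = np.asarray(scores, dtype=np.float64)
        K = scores.shape[-1]
        return self.mean_ + scores @ self.eigenfunctions_[:K]


def fpca(
    curves: np.ndarray,
    grid: np.ndarray | None = None,
    var_threshold: float = 0.95,
    n_components: int | None = None,
) -> FPCA:
    """Fit :class:`FPCA` to curves on a common grid and return the result."""
    return FPCA(var_threshold, n_components).fit(curves, grid=grid)


def reconstruct_curve(result: FPCA, i: int, K: int | None = None):
    """Karhunen-Loeve reconstruction of training curve ``i`` with K terms."""
    check_is_fitted(result, "mean_")
    if K is None:
        K = result.n_components_
    if K > result.eigenfunctions_.shape[0]:
        raise ValueError("K exceeds the number of computed components")
    if K == 0:
        return result.mean_.copy()
    return result.mean_ + result.scores_[i, :K] @ result.eigenfunctions_[:K]
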