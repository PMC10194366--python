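"""Monotone growth-curve fitting and functional PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenrow.growth import (
    FPCA,
    MonotoneGrowthRegressor,
    fit_monotone_curve,
    genotype_median_curves,
    reconstruct_curve,
)
from greenrow.synthfield import generate_growth_curves, orthonormal_polynomials


def pava_oracle(y):
    """Textbook pool-adjacent-violators: merge blocks until nondecreasing."""
    blocks = [[v, 1] for v in y]  # [mean, size]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            m = (
                blocks[i][0] * blocks[i][1]
                + blocks[i + 1][0] * blocks[i + 1][1]
            ) / (blocks[i][1] + blocks[i + 1][1])
            blocks[i] = [m, blocks[i][1] + blocks[i + 1][1]]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for m, size in blocks:
        out.extend([m] * size)
    return np.array(out)


class TestMonotone:
    def test_two_point_pooling(self):
        curve = fit_monotone_curve([1, 2], [10, 6], smooth=False)
        assert np.allclose(curve.heights, [8, 8])

    def test_monotone_input_preserved(self):
        t = np.arange(10.0)
        y = np.array([0, 1, 1, 2, 4, 4, 5, 7, 7, 9.0])
        curve = fit_monotone_curve(t, y, smooth=False)
        assert np.allclose(curve.heights, y)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8
        )
    )
    def test_matches_pava_oracle(self, values):
        t = np.arange(len(values), dtype=float)
        curve = fit_monotone_curve(t, values, smooth=False)
        assert np.allclose(curve.heights, pava_oracle(values), atol=1e-9)

    def test_exhaustive_small_integer_sequences(self):
        from itertools import product

        for seq in product(range(4), repeat=5):
            got = fit_monotone_curve(
                np.arange(5.0), np.array(seq, float), smooth=False
            ).heights
            assert np.allclose(got, pava_oracle(seq), atol=1e-12)

    def test_logistic_recovery(self, rng):
        t = np.sort(rng.uniform(0, 60, 200))
        truth = 120 / (1 + np.exp(-0.2 * (t - 30)))
        y = truth + rng.normal(0, 5, t.size)
        est = MonotoneGrowthRegressor().fit(t, y)
        rmse = np.sqrt(np.mean((est.predict(t) - truth) ** 2))
        assert rmse <= 5

    def test_always_nondecreasing(self, rng):
        t = np.sort(rng.uniform(0, 10, 50))
        y = rng.normal(0, 10, 50)
        est = MonotoneGrowthRegressor().fit(t, y)
        assert np.all(np.diff(est.fitted_heights_) >= -1e-9)

    def test_degenerate_times_error(self):
        with pytest.raises(ValueError):
            fit_monotone_curve([3, 3, 3], [1, 2, 3])


class TestGenotypeCurves:
    def test_single_plant_identity(self):
        df = pd.DataFrame(
            {
                "genotype": "g1",
                "timestamp": np.arange(10.0),
                "height_px": np.arange(10.0) * 2,
            }
        )
        grid = np.arange(10.0)
        curves, names = genotype_median_curves(df, grid, smooth=False)
        assert names == ["g1"]
        assert np.allclose(curves[0], np.arange(10.0) * 2, atol=1e-9)

    def test_median_of_three(self):
        t = np.tile(np.arange(8.0), 3)
        base = np.tile(np.arange(8.0) * 3, 3)
        offset = np.repeat([0.0, 2.0, 4.0], 8)
        df = pd.DataFrame(
            {"genotype": "g", "timestamp": t, "height_px": base + offset}
        )
        curves, _ = genotype_median_curves(
            df, np.arange(8.0), smooth=False
        )
        assert np.allclose(curves[0], np.arange(8.0) * 3 + 2, atol=1e-9)


class TestFPCA:
    @pytest.fixture(scope="class")
    def planted(self):
        grid = np.linspace(0, 1, 50)
        psi = orthonormal_polynomials(grid, 3)[1:]
        mean = 50 + 80 * grid
        curves, scores = generate_growth_curves(
            200, mean, psi, [3.0, 1.0], 0.0, grid, seed=42
        )
        return grid, psi, mean, curves, scores

    def test_component_recovery(self, planted):
        grid, psi, mean, curves, scores = planted
        fp = FPCA().fit(curves, grid=grid)
        assert fp.n_components_ == 2
        w = fp._quad_weights(grid)
        for k in range(2):
            cos = abs((w * fp.eigenfunctions_[k]) @ psi[k])
            assert cos >= 0.99
        assert fp.explained_variance_ratio_[0] == pytest.approx(0.9, abs=0.03)
        assert fp.explained_variance_ratio_[1] == pytest.approx(0.1, abs=0.03)

    def test_scores_center_and_decorrelate(self, planted):
        grid, _, _, curves, _ = planted
        fp = FPCA().fit(curves, grid=grid)
        k = fp.n_components_
        assert np.allclose(fp.scores_[:, :k].mean(axis=0), 0, atol=1e-8)
        corr = np.corrcoef(fp.scores_[:, 0], fp.scores_[:, 1])[0, 1]
        assert abs(corr) < 0.05

    def test_gram_identity(self, planted):
        grid, _, _, curves, _ = planted
        fp = FPCA().fit(curves, grid=grid)
        w = fp._quad_weights(grid)
        psi = fp.eigenfunctions_
        gram = (psi * w) @ psi.T
        assert np.abs(gram - np.eye(len(psi))).max() < 1e-8

    def test_explained_fractions_contract(self, planted):
        grid, _, _, curves, _ = planted
        fp = FPCA().fit(curves, grid=grid)
        frac = fp.explained_variance_ratio_
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-9

    def test_rank_one_selects_single_component(self):
        grid = np.linspace(0, 1, 30)
        psi = orthonormal_polynomials(grid, 2)[1:]
        curves, _ = generate_growth_curves(
            50, np.zeros(30), psi, [2.0], 0.0, grid, seed=0
        )
        fp = FPCA(var_threshold=0.95).fit(curves, grid=grid)
        assert fp.n_components_ == 1

    def test_identical_curves_degenerate(self):
        curves = np.tile(np.linspace(0, 5, 20), (5, 1))
        fp = FPCA().fit(curves)
        assert fp.degenerate_ and fp.n_components_ == 0

    def test_reconstruction(self, planted):
        grid, _, _, curves, _ = planted
        sub = curves[:10]
        fp = FPCA().fit(sub, grid=grid)
        # complete basis reproduces training curves
        full = reconstruct_curve(fp, 3, K=fp.eigenfunctions_.shape[0])
        assert np.abs(full - sub[3]).max() <= 1e-6
        assert np.allclose(reconstruct_curve(fp, 3, K=0), fp.mean_)
        # error is nonincreasing in K
        errs = [
            np.linalg.norm(reconstruct_curve(fp, 3, K=k) - sub[3])
            for k in range(fp.eigenfunctions_.shape[0] + 1)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))
        # two planted components reconstruct within 2% relative L2 error
        rel = np.linalg.norm(
            reconstruct_curve(fp, 3, K=2) - sub[3]
        ) / np.linalg.norm(sub[3])
        assert rel <= 0.02

    def test_too_many_components_requested(self, planted):
        grid, _, _, curves, _ = planted
        with pytest.raises(ValueError):
            FPCA(n_components=60).fit(curves[:10], grid=grid)

    def test_transform_matches_scores(self, planted):
        grid, _, _, curves, _ = planted
        fp = FPCA().fit(curves, grid=grid)
        got = fp.transform(curves[:5])
        assert np.allclose(got, fp.scores_[:5, : fp.n_components_], atol=1e-9)
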