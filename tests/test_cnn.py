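"""Patch CNN: architecture, training behavior, inference contracts."""

import numpy as np
import pytest

from greenrow.cnn import (
    CnnSpec,
    PatchCNNClassifier,
    build_model,
    predict_probabilities,
)


def separable_patches(n, r=4, c=4, seed=0, permute_labels=False):
    """Color-separable fixture: foreground pure green, background blue-green."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = np.zeros((n, 2 * r + 1, 2 * c + 1, 3), dtype=np.float32)
    X[y == 1] = [0.1, 0.8, 0.1]
    X[y == 0] = [0.1, 0.5, 0.5]
    X += rng.normal(0, 0.05, X.shape).astype(np.float32)
    if permute_labels:
        y = rng.permutation(y)
    return X, y


class TestSpec:
    def test_presets(self):
        paper = build_model(16, 16, "paper")
        assert (paper.epochs, paper.batch_size) == (100, 1000)
        desk = build_model(16, 16, "desk")
        assert (desk.epochs, desk.batch_size) == (10, 256)
        with pytest.raises(ValueError):
            build_model(16, 16, "gpu")

    def test_derived_shapes_other_neighborhoods(self):
        # 17x17 patch: two floor-division pools give 8 then 4
        spec = build_model(8, 8)
        assert spec.layer_shapes[4] == (4, 4, 64)
        assert spec.flatten_size == 4 * 4 * 64

    def test_too_small_for_two_pools(self):
        with pytest.raises(ValueError, match="pool"):
            CnnSpec(r=1, c=1)


class TestTraining:
    def test_separable_colors_learned(self):
        """>= 99% validation accuracy within 5 epochs on separable colors."""
        for seed in (0, 1, 2):
            X, y = separable_patches(2000, seed=seed)
            est = PatchCNNClassifier(
                r=4, c=4, epochs=5, batch_size=256, random_state=seed
            ).fit(X, y)
            assert est.history_.val_accuracy.iloc[-1] >= 0.99

    def test_permuted_labels_at_chance(self):
        # a quarter of the data held out so the +/-0.05 band is ~2 binomial
        # standard errors wide
        X, y = separable_patches(2000, seed=3, permute_labels=True)
        est = PatchCNNClassifier(
            r=4, c=4, epochs=5, batch_size=256, random_state=3,
            validation_fraction=0.25,
        ).fit(X, y)
        assert abs(est.history_.val_accuracy.iloc[-1] - 0.5) <= 0.05

    def test_seeded_determinism(self):
        X, y = separable_patches(300, r=2, c=2, seed=4)
        runs = [
            PatchCNNClassifier(
                r=2, c=2, epochs=3, batch_size=64, random_state=9
            ).fit(X, y)
            for _ in range(2)
        ]
        assert (
            runs[0].history_.loss.iloc[-1] == runs[1].history_.loss.iloc[-1]
        )
        p0, p1 = (m.predict_proba(X[:20])[:, 1] for m in runs)
        assert np.array_equal(p0, p1)

    def test_history_length_equals_epochs(self):
        X, y = separable_patches(200, r=2, c=2)
        est = PatchCNNClassifier(
            r=2, c=2, epochs=4, batch_size=64, random_state=0
        ).fit(X, y)
        assert len(est.history_) == 4


class TestGradients:
    def test_numeric_gradient_check(self):
        """Backprop agrees with central finite differences."""
        from greenrow.cnn import _bce_loss_and_grad

        rng = np.random.default_rng(0)
        X = rng.random((4, 5, 5, 3)).astype(np.float64)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        est = PatchCNNClassifier(
            r=2, c=2, epochs=1, batch_size=4, dropout_rate=0.0, random_state=1
        )
        spec = est._make_spec()
        est.layers_ = est._build_layers(spec, np.random.default_rng(1))
        params = [p for layer in est.layers_ for p in layer.params()]
        for name, obj in params:  # float64 for finite differences
            setattr(obj, name, getattr(obj, name).astype(np.float64))

        def loss_fn():
            logits = est._forward(X, train=True)
            return _bce_loss_and_grad(logits, y)[0]

        loss = loss_fn()
        logits = est._forward(X, train=True)
        _, dlogits, _ = _bce_loss_and_grad(logits, y)
        est._backward(dlogits)
        eps = 1e-6
        check_rng = np.random.default_rng(7)
        for name, obj in params:
            w = getattr(obj, name)
            g = getattr(obj, "d" + name)
            flat = w.reshape(-1)
            n_probe = min(3, flat.size)
            for idx in check_rng.choice(flat.size, n_probe, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-7
                )


class TestInference:
    @pytest.fixture(scope="class")
    def fitted(self):
        X, y = separable_patches(400, r=2, c=2, seed=5)
        return (
            PatchCNNClassifier(
                r=2, c=2, epochs=2, batch_size=128, random_state=5
            ).fit(X, y),
            X,
        )

    def test_batch_size_invariance(self, fitted):
        est, X = fitted
        a = est.predict_proba(X, batch_size=32)[:, 1]
        b = est.predict_proba(X, batch_size=400)[:, 1]
        assert np.allclose(a, b, atol=1e-6)

    def test_probability_map_coverage(self, fitted):
        est, _ = fitted
        rng = np.random.default_rng(0)
        img = rng.random((10, 12, 3))
        mask = rng.integers(0, 2, (10, 12))
        pmap = predict_probabilities(est, img, mask)
        assert len(pmap) == mask.sum()
        assert set(zip(pmap.rows, pmap.cols)) == set(
            zip(*np.nonzero(mask))
        )
        assert (pmap.values >= 0).all() and (pmap.values <= 1).all()

    def test_empty_mask(self, fitted):
        est, _ = fitted
        pmap = predict_probabilities(
            est, np.zeros((6, 6, 3)), np.zeros((6, 6))
        )
        assert len(pmap) == 0

    def test_dim_mismatch_errors(self, fitted):
        est, _ = fitted
        with pytest.raises(ValueError):
            predict_probabilities(est, np.zeros((6, 6, 3)), np.zeros((5, 6)))

    def test_save_load_roundtrip(self, fitted, tmp_path):
        est, X = fitted
        est.save(tmp_path / "model.npz")
        loaded = PatchCNNClassifier.load(tmp_path / "model.npz")
        assert np.array_equal(
            est.predict_proba(X[:30]), loaded.predict_proba(X[:30])
        )
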