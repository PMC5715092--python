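"""Estimator mechanics: batching, scheduling, determinism, sklearn surface."""

import numpy as np
import pytest
from sklearn.base import clone

from wellcount import (
    CellCountCNN,
    SubsetPartition,
    TrainingConfig,
    WellImage,
    predict,
    sample_minibatch,
    train_on_plates,
)
from wellcount.estimator import DEFAULT_COMPOSITION, compose_batch_indices

SIDE = 64  # smallest side the architecture accepts


def random_labeled_images(n_per_class, side=SIDE, seed=0):
    """Noise images with one category-dependent intensity block (learnable)."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c, n in enumerate(n_per_class):
        for _ in range(n):
            img = rng.integers(20, 120, (side, side)).astype(np.uint8)
            img[4 : 12 + 8 * c, 4:12] = 250  # block height encodes the class
            X.append(img)
            y.append(c)
    return np.stack(X), np.array(y)


@pytest.fixture(scope="module")
def pool():
    X, y = random_labeled_images((200, 60, 30, 30), seed=1)
    return [WellImage(x, well_id=f"w{i}", category=int(c)) for i, (x, c) in enumerate(zip(X, y))]


class TestMinibatch:
    def test_default_composition_is_77_21_10_11(self, pool, rng):
        batch = sample_minibatch(pool, TrainingConfig(), rng)
        assert len(batch) == 119
        counts = np.bincount([w.category for w in batch], minlength=4)
        assert counts.tolist() == [77, 21, 10, 11]

    def test_minimal_composition(self, pool, rng):
        cfg = TrainingConfig(minibatch_composition=(1, 1, 1, 1))
        batch = sample_minibatch(pool, cfg, rng)
        assert sorted(w.category for w in batch) == [0, 1, 2, 3]

    def test_absent_category_is_named(self, rng):
        small = [WellImage(np.zeros((8, 8)), category=c) for c in (0, 0, 1, 2)]
        with pytest.raises(ValueError, match="gt2"):
            sample_minibatch(small, TrainingConfig(), rng)

    def test_within_category_sampling_is_uniform(self, rng):
        """Each member of a category is drawn equally often (3-sigma band)."""
        y = np.array([0] * 50 + [1] * 8 + [2] * 8 + [3] * 8)
        pools = [np.flatnonzero(y == c) for c in range(4)]
        comp = (10, 4, 4, 4)
        hits = np.zeros(y.size)
        n_batches = 1000
        for _ in range(n_batches):
            idx = compose_batch_indices(pools, comp, rng)
            np.add.at(hits, idx, 1)
        for c in range(4):
            members = pools[c]
            expected = n_batches * comp[c] / len(members)
            se = np.sqrt(n_batches * (comp[c] / len(members)) * (1 - 1 / len(members)))
            assert np.all(np.abs(hits[members] - expected) < 4 * se)

    def test_scarce_category_sampled_with_replacement(self, rng):
        y = np.array([0] * 30 + [1] * 5 + [2] * 2 + [3] * 1)
        pools = [np.flatnonzero(y == c) for c in range(4)]
        idx = compose_batch_indices(pools, DEFAULT_COMPOSITION, rng)
        assert len(idx) == 119  # 11 draws from a 1-member gt2 pool

    def test_composition_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(minibatch_composition=(0, 1, 1, 1))


class TestFit:
    def test_zero_iterations_returns_initialization(self):
        X, y = random_labeled_images((4, 2, 2, 2), seed=2)
        a = CellCountCNN(n_iterations=0, random_state=3).fit(X, y)
        b = CellCountCNN(n_iterations=0, random_state=3).fit(X, y)
        assert all(
            np.array_equal(p, q)
            for p, q in zip(a.model_.state_dict(), b.model_.state_dict())
        )
        assert a.n_iter_ == 0

    def test_fixed_seed_reproduces_loss_trace(self):
        X, y = random_labeled_images((6, 3, 3, 3), seed=4)
        kw = dict(minibatch_composition=(2, 1, 1, 1), n_iterations=4,
                  learning_rate=0.01, random_state=7)
        a = CellCountCNN(**kw).fit(X, y)
        b = CellCountCNN(**kw).fit(X, y)
        assert a.history_.train_loss == b.history_.train_loss

    def test_training_loss_is_recorded_per_iteration(self):
        X, y = random_labeled_images((6, 3, 3, 3), seed=5)
        est = CellCountCNN(minibatch_composition=(2, 1, 1, 1), n_iterations=5,
                           random_state=0).fit(X, y)
        assert est.history_.iterations == [1, 2, 3, 4, 5]
        assert all(l >= 0 for l in est.history_.train_loss)
        assert all(0 <= a <= 1 for a in est.history_.train_accuracy)

    def test_diverging_learning_rate_raises(self):
        X, y = random_labeled_images((4, 2, 2, 2), seed=6)
        est = CellCountCNN(minibatch_composition=(2, 1, 1, 1), n_iterations=50,
                           learning_rate=1e8, random_state=0)
        with pytest.raises(RuntimeError, match="learning rate"):
            est.fit(X, y)

    def test_early_stopping_restores_best_checkpoint(self):
        X, y = random_labeled_images((8, 4, 3, 3), seed=7)
        Xv, yv = random_labeled_images((4, 2, 2, 2), seed=8)
        est = CellCountCNN(minibatch_composition=(2, 1, 1, 1), n_iterations=30,
                           eval_every=2, patience=2, learning_rate=0.5,
                           random_state=1)
        est.fit(X, y, X_val=Xv, y_val=yv)
        h = est.history_
        assert h.best_iteration in h.val_iterations
        assert h.best_val_loss == min(h.val_loss)


@pytest.fixture(scope="module")
def fitted():
    X, y = random_labeled_images((6, 3, 3, 3), seed=9)
    return CellCountCNN(minibatch_composition=(2, 1, 1, 1), n_iterations=2,
                        random_state=2).fit(X, y)


class TestPredict:

    def test_posterior_properties(self, fitted, rng):
        X = rng.integers(0, 256, (5, SIDE, SIDE)).astype(np.uint8)
        p = fitted.predict_proba(X)
        assert p.shape == (5, 4)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert (p.max(axis=1) >= 0.25 - 1e-9).all()

    def test_argmax_definition(self, fitted, rng):
        X = rng.integers(0, 256, (5, SIDE, SIDE)).astype(np.uint8)
        results = fitted.predict_result(X)
        for r, p in zip(results, fitted.predict_proba(X)):
            assert r.predicted_category == int(p.argmax())
            assert r.highest_output == pytest.approx(float(p.max()))

    def test_batch_equals_single_prediction(self, fitted, rng):
        X = rng.integers(0, 256, (4, SIDE, SIDE)).astype(np.uint8)
        batch = fitted.predict_proba(X)
        singles = np.vstack([fitted.predict_proba(X[i]) for i in range(4)])
        assert np.allclose(batch, singles, atol=1e-6)

    def test_module_level_predict_wrapper(self, fitted, rng):
        X = rng.integers(0, 256, (3, SIDE, SIDE)).astype(np.uint8)
        res = predict(fitted, X)
        assert [r.predicted_category for r in res] == fitted.predict(X).tolist()

    def test_wrong_image_side_raises(self, fitted):
        with pytest.raises(ValueError):
            fitted.predict(np.zeros((2, 32, 32)))


class TestSklearnSurface:
    def test_get_set_params_round_trip(self):
        est = CellCountCNN(learning_rate=0.002, random_state=5)
        params = est.get_params()
        assert params["learning_rate"] == 0.002
        est2 = clone(est)
        assert est2.get_params() == params

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            CellCountCNN().predict(np.zeros((1, SIDE, SIDE)))


class TestTrainOnPlates:
    def test_missing_plate_is_reported(self):
        with pytest.raises(KeyError, match="train plate 'p2'"):
            train_on_plates({"p1": []}, SubsetPartition(("p2",)))

    def test_staged_pools_follow_partition_order(self):
        """With two plates and a one-plate first stage, iteration 1 uses plate 1."""
        X, y = random_labeled_images((4, 2, 2, 2), seed=11)
        X2, y2 = random_labeled_images((4, 2, 2, 2), seed=12)
        plates = {
            "p1": [WellImage(x, plate_id="p1", category=int(c)) for x, c in zip(X, y)],
            "p2": [WellImage(x, plate_id="p2", category=int(c)) for x, c in zip(X2, y2)],
        }
        est = CellCountCNN(minibatch_composition=(2, 1, 1, 1),
                           stage_schedule=((2, 1), (2, 1)), rotation_stage=None,
                           n_iterations=4, random_state=0)
        fitted = train_on_plates(plates, SubsetPartition(("p1", "p2")), estimator=est)
        assert fitted.n_iter_ == 4
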