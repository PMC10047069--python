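"""Classifier head: forward pass, loss, schedule, optimizer, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score

from subspaceuq.datasets import SyntheticConfig, generate_embeddings
from subspaceuq.head import (
    HeadParameters,
    SoftmaxHead,
    TrainConfig,
    aupr,
    cross_entropy,
    cyclic_lr,
    evaluate,
    fit,
    forward,
    head_with_frozen_norm,
    hidden_activation,
)


class TestHeadParameters:
    def test_flatten_round_trips_exactly(self, rng):
        dim = 7
        p = HeadParameters(
            norm_scale=rng.standard_normal(dim),
            norm_shift=rng.standard_normal(dim),
            norm_mean=rng.standard_normal(dim),
            norm_var=np.abs(rng.standard_normal(dim)) + 0.1,
            dense_w=rng.standard_normal((dim, 2)),
            dense_b=rng.standard_normal(2),
        )
        vec = p.flatten()
        assert vec.shape == (6 * dim + 2,)
        q = HeadParameters.unflatten(vec, dim)
        for field in ("norm_scale", "norm_shift", "norm_mean", "norm_var", "dense_w", "dense_b"):
            assert np.array_equal(getattr(p, field), getattr(q, field))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="norm_var"):
            HeadParameters(
                norm_scale=np.ones(2), norm_shift=np.zeros(2), norm_mean=np.zeros(2),
                norm_var=np.array([1.0, 0.0]), dense_w=np.zeros((2, 2)),
                dense_b=np.zeros(2),
            )

    def test_json_round_trip(self, tmp_path, rng):
        p = HeadParameters.zeros(3)
        p.dense_w = rng.standard_normal((3, 2))
        p.to_json(tmp_path / "head.json")
        q = HeadParameters.from_json(tmp_path / "head.json")
        assert np.array_equal(p.dense_w, q.dense_w)

    def test_frozen_norm_reconstruction_swaps_only_dense(self, rng):
        dim = 4
        frozen = HeadParameters.zeros(dim).flatten()
        vec = rng.standard_normal(6 * dim + 2)
        head = head_with_frozen_norm(vec, frozen, dim)
        assert np.array_equal(head.norm_scale, np.ones(dim))
        assert np.array_equal(head.dense_w.ravel(), vec[4 * dim : 6 * dim])


class TestForward:
    def test_zero_logits_give_uniform_probabilities(self, identity_head, rng):
        probs = forward(identity_head, rng.standard_normal((5, 2)))
        assert np.allclose(probs, 0.5)

    def test_softmax_of_unit_logit_hand_value(self, identity_head):
        """Logits (1, 0) -> (0.7311, 0.2689)."""
        identity_head.dense_b = np.array([1.0, 0.0])
        probs = forward(identity_head, np.zeros((1, 2)))
        assert probs[0] == pytest.approx([0.7311, 0.2689], abs=5e-5)

    def test_rows_sum_to_one_and_lie_in_unit_interval(self, rng):
        p = HeadParameters.zeros(6)
        p.dense_w = rng.standard_normal((6, 2))
        probs = forward(p, rng.standard_normal((40, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((probs > 0) & (probs < 1))

    def test_inference_is_deterministic(self, rng):
        p = HeadParameters.zeros(4)
        p.dense_w = rng.standard_normal((4, 2))
        x = rng.standard_normal((10, 4))
        assert np.array_equal(forward(p, x), forward(p, x))

    def test_dimension_mismatch_raises(self, identity_head):
        with pytest.raises(ValueError, match="columns"):
            forward(identity_head, np.zeros((3, 5)))

    def test_dropout_masks_half_the_features(self):
        """Masked features per 2048-d row ~ Binomial(2048, 0.5)."""
        dim, n = 2048, 1000
        p = HeadParameters.zeros(dim)
        x = np.ones((n, dim)) + np.random.default_rng(0).standard_normal((n, dim))
        h = hidden_activation(p, x, training=False)  # no zeros without dropout
        hd = hidden_activation(
            p, x, training=True, dropout_rate=0.5, dropout_seed=1
        )
        masked_per_row = (hd == 0).sum(axis=1)
        # per-row count ~ Binomial(2048, 0.5): sd = sqrt(2048/4), SE of the mean /= sqrt(n)
        se = np.sqrt(dim * 0.25) / np.sqrt(n)
        assert abs(masked_per_row.mean() - 1024) < 3 * se
        assert not np.any(h == 0)

    def test_inverted_dropout_preserves_expected_activation(self, rng):
        dim = 32
        p = HeadParameters.zeros(dim)
        x = rng.standard_normal((4, dim)) + 2.0
        base = hidden_activation(p, x, training=True, dropout_rate=0.0)
        acc = np.zeros_like(base)
        n_masks = 2000
        for s in range(n_masks):
            acc += hidden_activation(p, x, training=True, dropout_rate=0.5, dropout_seed=s)
        assert np.allclose(acc / n_masks, base, atol=0.15)


class TestCrossEntropy:
    def test_perfect_prediction_has_negligible_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(probs, probs.copy()) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_costs_ln2(self):
        probs = np.full((8, 2), 0.5)
        labels = np.zeros((8, 2))
        labels[:, 0] = 1.0
        assert cross_entropy(probs, labels) == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_value_for_misassigned_mass(self):
        """(0.8, 0.2) against class 1 costs -ln 0.2 = 1.6094."""
        loss = cross_entropy(np.array([[0.8, 0.2]]), np.array([[0.0, 1.0]]))
        assert loss == pytest.approx(1.6094, abs=5e-5)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cross_entropy(np.array([[0.7, 0.2]]), np.array([[1.0, 0.0]]))


class TestCyclicLR:
    def test_cycle_start_is_base(self):
        cfg = TrainConfig(base_lr=1e-3, max_lr=5e-3, cycle_len=100)
        assert cyclic_lr(0, cfg) == pytest.approx(1e-3)

    def test_mid_cycle_is_max(self):
        cfg = TrainConfig(base_lr=1e-3, max_lr=5e-3, cycle_len=100)
        assert cyclic_lr(50, cfg) == pytest.approx(5e-3)

    def test_quarter_cycle_interpolates_linearly(self):
        cfg = TrainConfig(base_lr=1e-3, max_lr=5e-3, cycle_len=100)
        assert cyclic_lr(25, cfg) == pytest.approx(3e-3)

    def test_wave_is_periodic_and_bounded(self):
        cfg = TrainConfig(base_lr=1e-3, max_lr=5e-3, cycle_len=40)
        lrs = np.array([cyclic_lr(s, cfg) for s in range(200)])
        assert np.all((lrs >= 1e-3 - 1e-15) & (lrs <= 5e-3 + 1e-15))
        assert cyclic_lr(7, cfg) == pytest.approx(cyclic_lr(47, cfg))

    def test_degenerate_schedule_is_constant(self):
        cfg = TrainConfig(base_lr=2e-3, max_lr=2e-3, cycle_len=10)
        assert {cyclic_lr(s, cfg) for s in range(30)} == {2e-3}


class TestFit:
    def test_separable_data_reaches_high_training_accuracy(self):
        cfg = SyntheticConfig(
            dim=16, n_train_pos=8, n_train_neg=8, n_test_pos=4, n_test_neg=4,
            n_neg_subclusters=3, separation=10.0, seed=4,
        )
        ds = generate_embeddings(cfg)
        params, snaps = fit(ds, TrainConfig(epochs=30, seed=0))
        assert len(snaps) == 30
        assert evaluate(params, ds, "train")["accuracy"] > 0.95

    def test_identical_seed_reproduces_parameter_trajectory(self, small_dataset):
        cfg = TrainConfig(epochs=5, seed=42)
        _, snaps_a = fit(small_dataset, cfg)
        _, snaps_b = fit(small_dataset, cfg)
        for a, b in zip(snaps_a, snaps_b):
            assert np.array_equal(a, b)

    def test_zero_lr_step_applies_pure_decoupled_decay(self, rng):
        """With lr = 0 one step multiplies every dense weight by (1 - decay)."""
        lam = 0.1
        head = SoftmaxHead(
            epochs=1, batch_size=4, base_lr=1e-30, max_lr=1e-30,
            weight_decay=lam, dropout_rate=0.0, seed=0,
        )
        X = rng.standard_normal((4, 3))
        y = np.array([0, 1, 0, 1])
        # one batch = whole dataset = exactly one optimizer step
        head.fit(X, y)
        # reconstruct the pre-step weights from the same init stream
        rng_init = np.random.default_rng(0)
        w0 = 0.01 * rng_init.standard_normal((3, 2))
        adam_step = head.params_.dense_w - w0 * (1 - lam)
        assert np.max(np.abs(adam_step)) < 1e-25  # lr ~ 0 so only decay acted
        assert np.allclose(head.params_.dense_w, w0 * (1 - lam), atol=1e-25)

    def test_estimator_follows_sklearn_protocol(self, small_dataset, rng):
        from sklearn.base import clone

        head = SoftmaxHead(epochs=2, seed=1)
        clone(head)  # must not raise
        train = small_dataset.select("train")
        head.fit(train.features, train.y())
        probs = head.predict_proba(train.features)
        assert probs.shape == (train.n_images, 2)
        labels = head.predict(train.features)
        assert set(labels) <= {"ACP", "NOTACP"}


class TestEvaluate:
    def test_perfectly_separated_scores(self):
        cfg = SyntheticConfig(
            dim=8, n_train_pos=4, n_train_neg=4, n_test_pos=6, n_test_neg=6,
            n_neg_subclusters=2, separation=12.0, seed=9,
        )
        ds = generate_embeddings(cfg)
        params, _ = fit(ds, TrainConfig(epochs=30, seed=0))
        m = evaluate(params, ds, "test")
        assert m["accuracy"] == 1.0
        assert m["aupr"] == 1.0

    def test_constant_predictor_on_balanced_data_is_chance(self):
        p = HeadParameters.zeros(4)
        p.dense_b = np.array([-20.0, 20.0])  # always NOTACP
        from subspaceuq.datasets import EmbeddingDataset

        rng = np.random.default_rng(0)
        ds = EmbeddingDataset(
            rng.standard_normal((10, 4)),
            np.array(["ACP"] * 5 + ["NOTACP"] * 5, dtype=object),
            np.array([f"p{i}" for i in range(10)], dtype=object),
            np.full(10, "test", dtype=object),
            np.full(10, -1, dtype=np.int64),
        )
        assert evaluate(p, ds, "test")["accuracy"] == 0.5

    def test_empty_split_raises(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            evaluate(HeadParameters.zeros(16), small_dataset, "calib")


class TestAUPR:
    def test_worked_example_matches_rank_enumeration(self):
        """scores [0.9, 0.8, 0.3], labels [+,-,+] -> (1/1 + 2/3)/2 = 0.8333."""
        assert aupr([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(0.8333, abs=5e-5)

    def test_perfect_ranking_is_one(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        assert aupr([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1]) == 0.25

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            aupr([0.5, 0.4], [0, 0])

    def test_matches_sklearn_average_precision(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            scores = rng.random(n)
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            assert aupr(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    def test_random_scores_approach_prevalence(self, rng):
        """Mean AUPR of random scores converges to the positive prevalence."""
        pi = 0.3
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            labels = (r.random(10_000) < pi).astype(int)
            vals.append(aupr(r.random(10_000), labels))
        assert abs(np.mean(vals) - pi) < 0.02


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_cyclic_lr_always_within_bounds(step):
    cfg = TrainConfig(base_lr=1e-4, max_lr=7e-3, cycle_len=64)
    lr = cyclic_lr(step, cfg)
    assert 1e-4 - 1e-15 <= lr <= 7e-3 + 1e-15
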