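import numpy as np
import pytest

from miirkit.core import ChannelMontage, biosemi64_montage
from miirkit.cvtriplets import build_training_triplets, build_validation_triplets, make_nested_folds
from miirkit.sce import (
    SceHyper,
    SpatialFilter,
    _batch_grad,
    average_filters,
    encode,
    fit_forward_model,
    load_filter,
    normalize_polarity,
    pretrain_sce,
    save_filter,
    similarity,
    triplet_error,
    triplet_hinge_loss,
)


@pytest.fixture(scope="module")
def reduced_triplets(reduced_dataset):
    """Training/validation triplets of one inner fold of the reduced set."""
    ts, _, _ = reduced_dataset
    labels = ts.labels("stimulus")
    subjects = np.array([t.subject for t in ts])
    fold = make_nested_folds(ts)[0]
    train = build_training_triplets(fold.train_ids, labels, subjects)
    combined = np.concatenate([fold.train_ids, fold.validation_ids])
    val = build_validation_triplets(fold.validation_ids, combined, labels, subjects)
    return ts.data_stack(), train, val


class TestEncode:
    def test_zero_filter_gives_zero_output(self):
        x = np.random.default_rng(0).standard_normal((4, 20))
        y = encode(x, SpatialFilter(np.zeros(4)))
        assert np.allclose(y, 0.0)

    def test_unit_filter_linear_regime(self):
        x = 0.05 * np.random.default_rng(1).standard_normal((3, 50))
        w = np.array([1.0, 0.0, 0.0])
        y = encode(x, SpatialFilter(w))
        assert np.max(np.abs(y - x[0])) < 0.01 * 0.1

    def test_output_stays_inside_unit_interval(self):
        # tanh maps into (-1, 1); at extreme drive the float64 result
        # saturates to +-1.0 exactly, so the closed bound is the testable one
        x = 3.0 * np.random.default_rng(2).standard_normal((2, 30))
        y = encode(x, SpatialFilter(np.ones(2)))
        assert np.all(np.abs(y) < 1.0)
        y_extreme = encode(1e6 * x, SpatialFilter(np.ones(2)))
        assert np.all(np.abs(y_extreme) <= 1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            encode(np.zeros((3, 5)), SpatialFilter(np.zeros(4)))

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 40))
        w = rng.standard_normal(6)
        perm = rng.permutation(6)
        assert np.allclose(
            encode(x, SpatialFilter(w)), encode(x[perm], SpatialFilter(w[perm]))
        )


class TestSimilarity:
    def test_orthogonal_series(self):
        assert similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_self_similarity_nonnegative(self):
        p = np.random.default_rng(0).standard_normal(64)
        assert similarity(p, p) >= 0.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        p, q = rng.standard_normal(100), rng.standard_normal(100)
        assert abs(similarity(p, q) - sum(a * b for a, b in zip(p, q))) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            similarity(np.zeros(3), np.zeros(4))


class TestHingeLoss:
    @pytest.mark.parametrize(
        "s_ab,s_ac,margin,expected",
        [(3.0, 1.0, 1.0, 0.0), (1.0, 1.0, 1.0, 1.0), (0.0, 1.0, 1.0, 2.0)],
    )
    def test_values(self, s_ab, s_ac, margin, expected):
        assert triplet_hinge_loss(s_ab, s_ac, margin) == expected

    def test_tie_counts_incorrect(self):
        stack = np.ones((2, 1, 4))
        trips = np.array([[0, 1, 1]])
        # identical trials -> s_ab == s_ac -> counted incorrect
        assert triplet_error(np.ones(1), stack, trips) == 1.0


class TestPretrain:
    def test_zero_learning_rate_keeps_init(self, reduced_triplets):
        stack, train, val = reduced_triplets
        init = np.zeros(stack.shape[1])
        f, _ = pretrain_sce(
            train[:2000], val[:2000], stack, SceHyper(learning_rate=0.0, seed=0), init=init
        )
        assert np.array_equal(f.weights, init)

    def test_same_seed_identical_weights(self, reduced_triplets):
        stack, train, val = reduced_triplets
        hyper = SceHyper(max_epochs=2, seed=7)
        f1, _ = pretrain_sce(train[:3000], val[:2000], stack, hyper)
        f2, _ = pretrain_sce(train[:3000], val[:2000], stack, hyper)
        assert np.array_equal(f1.weights, f2.weights)

    def test_separable_data_low_validation_error(self, reduced_triplets):
        stack, train, val = reduced_triplets
        f, hist = pretrain_sce(train, val, stack, SceHyper(learning_rate=1e-3, seed=0))
        assert min(hist["val_error"]) < 0.05

    def test_loss_decreases_on_fixed_batch_with_small_steps(self, reduced_triplets):
        stack, train, _ = reduced_triplets
        batch = train[:500]
        rng = np.random.default_rng(0)
        w = rng.uniform(-0.01, 0.01, stack.shape[1])
        first, grad = _batch_grad(w, stack, batch, margin=1.0)
        losses = [first]
        for _ in range(10):
            loss, grad = _batch_grad(w, stack, batch, margin=1.0)
            w = w - 1e-4 * grad
            losses.append(loss)
        assert losses[-1] <= losses[0]

    def test_empty_triplets_rejected(self, reduced_triplets):
        stack, train, _ = reduced_triplets
        with pytest.raises(ValueError):
            pretrain_sce(np.empty((0, 3), dtype=int), train, stack)


class TestPolarity:
    def montage3(self):
        return ChannelMontage(("C3", "T7", "C4"))

    def test_negative_t7_flips_all(self):
        f = SpatialFilter(np.array([0.5, -0.3, 0.2]), self.montage3())
        out = normalize_polarity(f)
        assert np.allclose(out.weights, [-0.5, 0.3, -0.2])

    def test_positive_t7_unchanged(self):
        f = SpatialFilter(np.array([0.5, 0.3, 0.2]), self.montage3())
        assert np.allclose(normalize_polarity(f).weights, f.weights)

    def test_zero_t7_unchanged(self):
        f = SpatialFilter(np.array([0.5, 0.0, -0.2]), self.montage3())
        assert np.allclose(normalize_polarity(f).weights, f.weights)

    def test_missing_t7_raises(self):
        f = SpatialFilter(np.zeros(2), ChannelMontage(("C3", "C4")))
        with pytest.raises(KeyError):
            normalize_polarity(f)


class TestAverageFilters:
    def test_identical_filters(self):
        f = SpatialFilter(np.array([1.0, 2.0]))
        assert np.allclose(average_filters([f, f, f]).weights, f.weights)

    def test_polarity_prevents_cancellation(self):
        m = ChannelMontage(("T7", "Cz"))
        f = SpatialFilter(np.array([0.4, -0.1]), m)
        neg = SpatialFilter(-f.weights, m)
        avg = average_filters([normalize_polarity(f), normalize_polarity(neg)])
        assert np.allclose(avg.weights, f.weights)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        filters = [SpatialFilter(rng.standard_normal(8)) for _ in range(5)]
        avg = average_filters(filters)
        manual = sum(f.weights for f in filters) / 5
        assert np.allclose(avg.weights, manual)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_filters([])


class TestForwardModel:
    def test_exact_linear_relation_recovered(self):
        # channels 1.. are exact multiples of the encoder output; their
        # forward-model coefficients must equal those multiples
        rng = np.random.default_rng(0)
        a = rng.standard_normal(5)
        f = SpatialFilter(np.array([1.0, 0, 0, 0, 0]))
        trials = []
        for _ in range(3):
            y = rng.uniform(-0.5, 0.5, 80)
            x = np.outer(a, y)
            x[0] = np.arctanh(y)  # encoder input channel: tanh(x0) == y
            assert np.allclose(encode(x, f), y)
            trials.append(x)
        model = fit_forward_model(trials, f)
        assert np.allclose(model.pattern[1:], a[1:], atol=1e-6)

    def test_independent_noise_gives_null_pattern(self):
        rng = np.random.default_rng(1)
        n = 4000
        x = np.stack([rng.standard_normal((3, n))])
        f = SpatialFilter(np.zeros(3))
        # encoder output independent of x: use a filter on a 4th channel
        x4 = np.concatenate([x[0], rng.standard_normal((1, n))])
        f4 = SpatialFilter(np.array([0.0, 0.0, 0.0, 0.2]))
        model = fit_forward_model([x4], f4)
        y = encode(x4, f4)
        se = 1.0 / np.sqrt(n)  # approximate SE of a correlation-based slope
        scale = np.std(x4[:3], axis=1) / np.std(y)
        assert np.all(np.abs(model.pattern[:3]) < 3 * se * scale)

    def test_matches_cov_over_var_oracle(self):
        rng = np.random.default_rng(2)
        trials = [rng.standard_normal((4, 50)) for _ in range(3)]
        f = SpatialFilter(rng.standard_normal(4) * 0.2)
        model = fit_forward_model(trials, f)
        x = np.concatenate([t for t in trials], axis=1)
        y = np.concatenate([encode(t, f) for t in trials])
        expected = [np.cov(ch, y)[0, 1] / np.var(y, ddof=1) for ch in x]
        assert np.allclose(model.pattern, expected, atol=1e-10)

    def test_constant_output_rejected(self):
        x = np.random.default_rng(3).standard_normal((2, 30))
        with pytest.raises(ValueError):
            fit_forward_model([x], SpatialFilter(np.zeros(2)))

    def test_recovers_mixing_column_noise_free(self):
        # noise-free single-source data: the forward model of the perfect
        # unmixing filter is the generating mixing column
        rng = np.random.default_rng(4)
        m = rng.standard_normal(64)
        m /= np.linalg.norm(m)
        trials = [np.outer(m, rng.uniform(-1, 1, 100)) for _ in range(4)]
        w = 0.5 * m / (m @ m)
        model = fit_forward_model(trials, SpatialFilter(w))
        cos = abs(model.pattern @ m) / (np.linalg.norm(model.pattern) * np.linalg.norm(m))
        assert cos > 0.95


class TestFilterIO:
    def test_save_load_round_trip(self, tmp_path):
        m = biosemi64_montage()
        f = SpatialFilter(np.random.default_rng(0).standard_normal(64), m)
        save_filter(f, tmp_path / "f.tsv")
        back = load_filter(tmp_path / "f.tsv")
        assert np.array_equal(back.weights, f.weights)
        assert back.montage == m
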