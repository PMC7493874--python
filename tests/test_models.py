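import numpy as np
import pytest

from fpscreen.models import (
    CnnSpec,
    GridSpace,
    SpecError,
    build_cnn1d,
    build_cnn2d,
    grid_search,
    load_model,
    predict_scores,
    save_model,
    train,
)
from fpscreen.nn import ShapeError
from fpscreen import FingerprintType

SMALL_FILTERS = (32, 16, 8, 8)


def head_params(flat):
    return (
        flat * 1024 + 1024 + 1024 * 512 + 512 + 512 * 256 + 256 + 256 + 1
    )


class TestBuild1D:
    def test_param_count_matches_shape_arithmetic(self):
        # independent layer-by-layer arithmetic for the default spec:
        # conv k=3, filters 128/64/32/16, same padding, head 1024/512/256
        net = build_cnn1d(CnnSpec())
        conv = (
            (3 * 1 * 128 + 128)
            + (3 * 128 * 64 + 64)
            + (3 * 64 * 32 + 32)
            + (3 * 32 * 16 + 16)
        )
        flat = (1024 // 2**4) * 16  # four same-padding conv+pool blocks
        assert net.param_count() == conv + head_params(flat) == 1_738_865

    def test_output_in_unit_interval_on_all_minus_one_input(self):
        net = build_cnn1d(CnnSpec(conv_filters=SMALL_FILTERS))
        probs = net.predict_proba(-np.ones((3, 1024, 1), dtype=np.float32))
        assert ((probs > 0) & (probs < 1)).all()

    def test_same_seed_same_initial_weights(self):
        a = build_cnn1d(CnnSpec(conv_filters=SMALL_FILTERS, seed=4))
        b = build_cnn1d(CnnSpec(conv_filters=SMALL_FILTERS, seed=4))
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_valid_padding_shrinks_flat_dimension(self):
        net = build_cnn1d(CnnSpec(padding_mode="valid"))
        assert net.param_count() < build_cnn1d(CnnSpec()).param_count()


class TestBuild2D:
    def test_param_count_matches_shape_arithmetic(self):
        spec = CnnSpec(dimensionality="2D", kernel=(3, 2))
        net = build_cnn2d(spec, k_rows=3)
        # kernel (3 bits, 2 rows); rows pool 3 -> 1 after the first block
        conv = (
            (2 * 3 * 1 * 128 + 128)
            + (2 * 3 * 128 * 64 + 64)
            + (2 * 3 * 64 * 32 + 32)
            + (2 * 3 * 32 * 16 + 16)
        )
        flat = 1 * (1024 // 2**4) * 16
        assert net.param_count() == conv + head_params(flat)

    def test_builds_for_full_stack_and_emits_probability(self):
        spec = CnnSpec(dimensionality="2D", kernel=(3, 2),
                       conv_filters=SMALL_FILTERS)
        net = build_cnn2d(spec, k_rows=7)
        probs = net.predict_proba(-np.ones((2, 7, 1024, 1), dtype=np.float32))
        assert ((probs > 0) & (probs < 1)).all()

    def test_row_kernel_exceeding_rows_rejected_with_valid_padding(self):
        spec = CnnSpec(dimensionality="2D", kernel=(3, 2), padding_mode="valid")
        with pytest.raises(ShapeError):
            # rows collapse to 1 after the first pool; a 2-row valid kernel
            # cannot fit in the second block
            build_cnn2d(spec, k_rows=2)

    def test_k_rows_bounds_enforced(self):
        spec = CnnSpec(dimensionality="2D", kernel=(3, 2))
        with pytest.raises(SpecError):
            build_cnn2d(spec, k_rows=1)
        with pytest.raises(SpecError):
            build_cnn2d(spec, k_rows=8)


class TestSpecValidation:
    def test_kernel_must_come_from_allowed_sets(self):
        with pytest.raises(SpecError):
            CnnSpec(kernel=7)
        with pytest.raises(SpecError):
            CnnSpec(dimensionality="2D", kernel=(9, 9))

    def test_dropout_range_enforced(self):
        with pytest.raises(SpecError):
            CnnSpec(dropout_p=0.1)

    def test_round_trip_through_dict(self):
        spec = CnnSpec(dimensionality="2D", kernel=(15, 2), learning_rate=2e-4)
        assert CnnSpec.from_dict(spec.to_dict()) == spec


class TestTrainPredict:
    @pytest.fixture(scope="class")
    def trained(self, easy_dataset):
        ds = easy_dataset
        x = ds.signed(FingerprintType.FEATMORGAN)
        y = ds.labels
        spec = CnnSpec(conv_filters=SMALL_FILTERS, seed=0)
        return (
            train(spec, x[:400], y[:400], x[400:], y[400:],
                  max_epochs=8, patience=3),
            x, y,
        )

    def test_learns_separable_planted_signal(self, trained):
        model, x, y = trained
        assert max(model.history.val_metric) >= 0.9

    def test_best_epoch_checkpoint_is_kept(self, trained):
        model, _, _ = trained
        best = model.history.val_metric[model.best_epoch - 1]
        assert best == max(model.history.val_metric)

    def test_batch_and_single_scoring_agree(self, trained):
        model, x, _ = trained
        batch = predict_scores(model, x[:8])
        single = np.concatenate([predict_scores(model, x[i:i + 1])
                                 for i in range(8)])
        np.testing.assert_allclose(batch, single, atol=1e-6)

    def test_empty_input_gives_empty_output(self, trained):
        model, _, _ = trained
        assert predict_scores(model, np.zeros((0, 1024))).size == 0

    def test_shuffled_labels_give_chance_performance(self, easy_dataset):
        ds = easy_dataset
        x = ds.signed(FingerprintType.FEATMORGAN)
        rng = np.random.default_rng(0)
        y = rng.permutation(ds.labels)
        spec = CnnSpec(conv_filters=SMALL_FILTERS, seed=1)
        model = train(spec, x[:400], y[:400], x[400:], y[400:],
                      max_epochs=4, patience=4)
        assert abs(model.history.val_metric[-1] - 0.5) <= 0.1

    def test_save_load_round_trip(self, trained, tmp_path):
        model, x, _ = trained
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(
            predict_scores(back, x[:16]), predict_scores(model, x[:16]),
            atol=1e-7,
        )
        assert back.spec == model.spec


class TestGridSearch:
    def test_grid_space_size_is_product_of_axes(self):
        space = GridSpace()
        assert space.size("1D") == 7 * len(space.learning_rates) * 8 * 3 * 5 * 5
        assert space.size("2D") == 7 * len(space.learning_rates) * 8 * 10 * 5 * 5

    def test_learning_rate_ladders_are_decades(self):
        lrs = GridSpace().learning_rates
        assert 1e-6 in lrs and 1.0 in lrs and 2e-5 in lrs and 0.2 in lrs

    def test_single_spec_leaderboard(self, easy_dataset):
        ds = easy_dataset
        x = ds.signed(FingerprintType.FEATMORGAN)
        specs = [CnnSpec(conv_filters=SMALL_FILTERS, seed=0)]
        results = grid_search(iter(specs), x, ds.labels, cv_folds=2,
                              max_epochs=1, patience=0)
        assert len(results) == 1

    def test_learning_spec_outranks_inert_spec(self, easy_dataset):
        ds = easy_dataset
        x = ds.signed(FingerprintType.FEATMORGAN)
        specs = [
            CnnSpec(conv_filters=SMALL_FILTERS, learning_rate=1e-3, seed=0),
            # learning rate far too small to move off initialization
            CnnSpec(conv_filters=SMALL_FILTERS, learning_rate=1e-6, seed=0),
        ]
        results = grid_search(iter(specs), x, ds.labels, cv_folds=2,
                              max_epochs=3, patience=3)
        assert results[0].spec.learning_rate == 1e-3
        assert results[0].mean_objective > results[1].mean_objective

    def test_budget_limits_evaluations_in_order(self, easy_dataset):
        ds = easy_dataset
        x = ds.signed(FingerprintType.FEATMORGAN)
        space = GridSpace(filters=(16,), learning_rates=(1e-3, 1e-2),
                          dropouts=(0.2,), batch_sizes=(32,),
                          optimizers=("adam",))
        specs = list(space.enumerate("1D"))
        assert len(specs) == 2 * 3  # two lrs x three 1D kernels
        results = grid_search(iter(specs), x, ds.labels, budget=2,
                              cv_folds=2, max_epochs=1, patience=0)
        assert len(results) == 2
        assert sorted(r.order_evaluated for r in results) == [0, 1]

    def test_empty_grid_rejected(self, easy_dataset):
        ds = easy_dataset
        x = ds.signed(FingerprintType.FEATMORGAN)
        with pytest.raises(SpecError):
            grid_search(iter([]), x, ds.labels, cv_folds=2)
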