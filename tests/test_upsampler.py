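import numpy as np
import pytest

from fodfsr import mlp, patches, spline


class TestPatchGeometry:
    def test_example_count_and_row_lengths(self):
        rng = np.random.default_rng(0)
        lr = rng.normal(size=(8, 8, 8, 44))
        hr = rng.normal(size=(16, 16, 16, 44))
        ds = patches.extract_patches(lr, hr)
        assert len(ds) == 512
        assert ds.inputs.shape[1] == 1188
        assert ds.targets.shape[1] == 352

    def test_corner_voxel_zero_padding(self):
        lr = np.ones((4, 4, 4, 2))
        hr = np.ones((8, 8, 8, 2))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        ds = patches.extract_patches(lr, hr, mask)
        neigh = ds.inputs[0].reshape(3, 3, 3, 2)
        nonzero = (neigh != 0).any(-1)
        assert nonzero.sum() == 8  # the 2x2x2 in-volume corner of the 3x3x3 cube
        assert not nonzero[0].any()  # the out-of-volume faces are zero-padded

    def test_scatter_inverts_extraction(self):
        """Targets rearranged through the grid mapping reproduce the HR volume."""
        rng = np.random.default_rng(1)
        lr = rng.normal(size=(3, 4, 5, 7))
        hr = rng.normal(size=(6, 8, 10, 7))
        ds = patches.extract_patches(lr, hr)
        rebuilt = patches.blocks_to_volume(ds.targets, ds.provenance, (3, 4, 5), 7)
        assert np.array_equal(rebuilt, hr)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            patches.extract_patches(np.zeros((4, 4, 4, 2)), np.zeros((8, 8, 7, 2)))
        with pytest.raises(ValueError):
            patches.extract_patches(np.zeros((4, 4, 4, 2)), np.zeros((8, 8, 8, 3)))

    def test_split_assignment_is_leak_free(self):
        ids = np.repeat(np.arange(10), 5)
        splits = patches.assign_splits(ids, n_val=2, n_test=3, seed=4)
        allids = np.concatenate([splits["train"], splits["val"], splits["test"]])
        assert sorted(allids) == list(range(10))
        assert len(splits["train"]) == 5
        assert not set(splits["train"]) & set(splits["test"])

    def test_grid_mapping_center(self):
        gm = patches.GridMapping()
        assert np.allclose(gm.lr_center_in_hr([1, 2, 3]), [2.5, 4.5, 6.5])
        sl = gm.hr_block(1, 0, 2)
        assert (sl[0].start, sl[0].stop) == (2, 4)


class TestParameterCount:
    def test_toy_hand_count(self):
        assert mlp.count_parameters(mlp.DSRModelSpec(2, (3,), 1)) == 19

    def test_default_model_is_3_5_million(self):
        n = mlp.count_parameters(mlp.DSRModelSpec())
        assert n == 3_549_352
        assert round(n / 1e6, 1) == 3.5

    def test_larger_input_variant(self):
        # 5x5x5 x 44 = 5500 inputs; closed-form total just above 7.8 million
        n = mlp.count_parameters(mlp.DSRModelSpec(input_dim=125 * 44))
        assert n == 7_861_352

    def test_count_matches_instantiated_arrays(self):
        spec = mlp.DSRModelSpec(30, (17, 11), 6)
        model = mlp.DSRModel(spec)
        assert model.n_parameters() == mlp.count_parameters(spec)


class TestTraining:
    @pytest.fixture(scope="class")
    def linear_problem(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 8)) * 0.3
        X = rng.normal(size=(200, 10))
        Xv = rng.normal(size=(100, 10))
        return X, X @ A, Xv, Xv @ A

    def test_learns_linear_map(self, linear_problem):
        """A learnable-by-construction task is fit to <1% of target variance."""
        X, Y, Xv, Yv = linear_problem
        _, hist = mlp.train_dsr(
            X, Y, mlp.DSRModelSpec(10, (16,), 8),
            mlp.TrainConfig(batch_size=200, epochs=500, learning_rate=1e-2, seed=1),
            val=(Xv, Yv),
        )
        assert hist["val_mse"][-1] < 0.01 * Yv.var()

    def test_loss_history_decreasing_on_smoothed_averages(self, linear_problem):
        X, Y, *_ = linear_problem
        _, hist = mlp.train_dsr(
            X, Y, mlp.DSRModelSpec(10, (16,), 8),
            mlp.TrainConfig(batch_size=200, epochs=100, learning_rate=1e-2, seed=1),
        )
        loss = np.array(hist["train_mse"])
        assert len(loss) == 100
        assert loss[-1] < loss[0]
        smooth = loss.reshape(20, 5).mean(axis=1)
        assert np.all(np.diff(smooth) < 0)

    def test_same_seed_identical_runs(self, linear_problem):
        X, Y, *_ = linear_problem
        cfg = mlp.TrainConfig(batch_size=64, epochs=5, seed=3)
        _, h1 = mlp.train_dsr(X, Y, mlp.DSRModelSpec(10, (16,), 8), cfg)
        _, h2 = mlp.train_dsr(X, Y, mlp.DSRModelSpec(10, (16,), 8), cfg)
        assert h1["train_mse"] == h2["train_mse"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            mlp.train_dsr(np.zeros((0, 10)), np.zeros((0, 4)))

    def test_save_load_round_trip(self, tmp_path, linear_problem):
        X, Y, *_ = linear_problem
        model, _ = mlp.train_dsr(
            X, Y, mlp.DSRModelSpec(10, (16,), 8),
            mlp.TrainConfig(epochs=2, batch_size=64, seed=0))
        model.save(tmp_path / "model")
        clone = mlp.DSRModel.load(tmp_path / "model")
        assert np.allclose(model.forward(X[:10]), clone.forward(X[:10]))


class TestApply:
    def test_shapes_masking_and_chaining(self):
        rng = np.random.default_rng(2)
        model = mlp.DSRModel(mlp.DSRModelSpec(27 * 3, (8,), 8 * 3), seed=0)
        lr = rng.normal(size=(4, 4, 4, 3))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2] = True
        hr = mlp.apply_dsr(model, lr, mask)
        assert hr.shape == (8, 8, 8, 3)
        assert np.all(hr[4:] == 0)  # unmasked half stays zero
        assert np.any(hr[:4] != 0)
        again = mlp.apply_dsr(model, hr)  # chaining doubles again
        assert again.shape == (16, 16, 16, 3)

    def test_input_dim_mismatch_rejected(self):
        model = mlp.DSRModel(mlp.DSRModelSpec(27 * 3, (8,), 8 * 3))
        with pytest.raises(ValueError):
            mlp.apply_dsr(model, np.zeros((4, 4, 4, 5)))


class TestSpline:
    def test_constant_volume_all_orders(self):
        vol = np.full((4, 4, 4), 2.5)
        for order in (0, 1, 2):
            assert np.allclose(spline.spline_upsample(vol, order), 2.5)

    def test_order0_is_block_replication(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(3, 3, 3))
        up = spline.spline_upsample(vol, 0)
        expected = np.repeat(np.repeat(np.repeat(vol, 2, 0), 2, 1), 2, 2)
        assert np.array_equal(up, expected)

    def test_linear_worked_example(self):
        """1D pair (a, b): the inner HR sample sits a quarter of the way over."""
        a, b = 2.0, 6.0
        lr = np.array([a, b]).reshape(2, 1, 1)
        up = spline.spline_upsample(lr, 1)
        assert up[1, 0, 0] == pytest.approx(a + 0.25 * (b - a))
        assert up[2, 0, 0] == pytest.approx(a + 0.75 * (b - a))
        # boundary samples extend by mirror symmetry
        assert up[0, 0, 0] == pytest.approx(a)
        assert up[3, 0, 0] == pytest.approx(b)

    def test_linearity_superposition(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 4, 4, 4))
        for order in (0, 1, 2):
            lhs = spline.spline_upsample(x + 2 * y, order)
            rhs = spline.spline_upsample(x, order) + 2 * spline.spline_upsample(y, order)
            assert np.allclose(lhs, rhs, atol=1e-10)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError):
            spline.spline_upsample(np.zeros((2, 2, 2)), 3)

    def test_sh_volume_channelwise(self):
        rng = np.random.default_rng(5)
        lr = rng.normal(size=(2, 2, 2, 3))
        up = spline.spline_upsample_sh(lr, 1)
        assert up.shape == (4, 4, 4, 3)
        for c in range(3):
            assert np.allclose(up[..., c], spline.spline_upsample(lr[..., c], 1))
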