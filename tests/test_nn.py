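import numpy as np
import pytest

from padpulse import nn


def waveform_like_data(n, rng, informative=True):
    """Smooth pulse-like inputs whose amplitude encodes the label."""
    t = np.arange(256) / 256
    X = np.zeros((n, 2, 256))
    y = rng.uniform(0, 0.8, n)
    for i in range(n):
        base = np.sin(np.pi * np.clip(t / 0.3, 0, 1)) ** 2
        amp = (1.0 - 0.6 * y[i]) if informative else 1.0
        X[i, 0] = 100 + 30 * base + rng.normal(0, 0.5, 256)
        X[i, 1] = 90 + 40 * amp * base + rng.normal(0, 0.5, 256)
    return X, y


class TestBuildModel:
    def test_default_structure_is_5_conv_3_fc(self):
        d = nn.build_model().describe()
        assert d["n_conv_layers"] == 5
        assert d["n_fc_layers"] == 3
        assert d["latent_dim"] == 64

    def test_zero_input_gives_finite_output(self):
        model = nn.build_model(seed=0)
        out = model.predict(np.zeros((3, 2, 256)))
        assert np.all(np.isfinite(out))

    def test_invalid_layer_counts_rejected(self):
        with pytest.raises(ValueError):
            nn.NetworkConfig(kernel_counts=(16, 32, 32), kernel_sizes=(11, 7, 5)).validate()

    def test_latent_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nn.NetworkConfig(kernel_counts=(16, 32, 32, 64, 64)).validate()

    def test_row_swap_symmetry_of_shared_kernels(self):
        # with untrained (random) weights, swapping the two input rows must
        # swap the per-row conv features exactly (kernels are shared)
        model = nn.build_model(seed=3)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 2, 256))
        model._forward(model.standardize(x), train=False)
        maps_a = model._conv_maps.copy()  # (2, C, L')
        xs = x[:, ::-1, :].copy()
        model._forward(model.standardize(xs), train=False)
        maps_b = model._conv_maps.copy()
        np.testing.assert_allclose(maps_a, maps_b[::-1], atol=1e-10)


class TestTraining:
    def test_overfits_small_sample(self):
        rng = np.random.default_rng(5)
        X, y = waveform_like_data(50, rng)
        model = nn.build_model(seed=0)
        for _ in range(10):  # up to 500 epochs, stop when memorised
            nn.train(
                model, (X, y), None,
                nn.TrainingConfig(epochs=50, learning_rate=1e-3, batch_size=16, seed=0),
            )
            if model.history["train_loss"][-1] < 1e-3:
                break
        assert len(model.history["train_loss"]) <= 500
        assert model.history["train_loss"][-1] < 1e-3

    def test_constant_labels_learned(self):
        rng = np.random.default_rng(6)
        X, _ = waveform_like_data(40, rng, informative=False)
        y = np.full(40, 0.35)
        model = nn.build_model(seed=0)
        nn.train(
            model, (X, y), (X, y),
            nn.TrainingConfig(epochs=120, learning_rate=1e-3, batch_size=16, seed=0),
        )
        assert min(model.history["val_loss"]) < 1e-4

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        X, y = waveform_like_data(30, rng)
        losses = []
        for _ in range(2):
            model = nn.build_model(seed=2)
            nn.train(model, (X, y), None, nn.TrainingConfig(epochs=3, seed=2))
            losses.append(model.history["train_loss"])
        assert losses[0] == losses[1]  # bit-identical

    def test_labels_out_of_range_rejected(self):
        rng = np.random.default_rng(8)
        X, y = waveform_like_data(10, rng)
        with pytest.raises(ValueError):
            nn.train(nn.build_model(), (X, y + 1.0), None, nn.TrainingConfig(epochs=1))


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(9)
    X, y = waveform_like_data(60, rng)
    model = nn.build_model(seed=1)
    nn.train(model, (X, y), None, nn.TrainingConfig(epochs=5, seed=1))
    return model


class TestPrediction:
    def test_batch_equals_per_sample(self, trained):
        rng = np.random.default_rng(10)
        X, _ = waveform_like_data(8, rng)
        batch = trained.predict(X)
        singles = np.array([trained.predict(X[i : i + 1])[0] for i in range(8)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_duplicated_rows_give_duplicated_outputs(self, trained):
        rng = np.random.default_rng(11)
        X, _ = waveform_like_data(3, rng)
        doubled = np.concatenate([X, X])
        out = trained.predict(doubled)
        np.testing.assert_allclose(out[:3], out[3:], atol=1e-12)

    def test_output_clipped_to_severity_range(self, trained):
        rng = np.random.default_rng(12)
        X, _ = waveform_like_data(16, rng)
        out = trained.predict(1000.0 * X)
        assert np.all((out >= 0.0) & (out <= 0.8))

    def test_wrong_length_rejected(self, trained):
        with pytest.raises(ValueError):
            trained.predict(np.zeros((2, 2, 100)))

    def test_predict_severity_resamples(self, trained):
        rng = np.random.default_rng(13)
        b = 100 + rng.normal(0, 1, 300)
        a = 90 + rng.normal(0, 1, 300)
        assert 0.0 <= nn.predict_severity(trained, b, a) <= 0.8


class TestClassify:
    def test_threshold_is_inclusive(self):
        assert nn.classify([0.4], 0.4)[0]

    def test_zero_prediction_is_healthy(self):
        assert not nn.classify([0.0], 0.1)[0]

    def test_elementwise_rule(self):
        out = nn.classify([0.05, 0.39, 0.40, 0.80], 0.40)
        np.testing.assert_array_equal(out, [False, False, True, True])

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            nn.classify([0.5], 0.9)


class TestHyperparameterSensitivity:
    def test_perturbation_table(self, tmp_path):
        rng = np.random.default_rng(14)
        X, y = waveform_like_data(24, rng)
        df = nn.hyperparameter_sensitivity(
            nn.NetworkConfig(),
            (X, y),
            (X, y),
            nn.TrainingConfig(epochs=2, seed=0),
        )
        # the four perturbed cases plus the reference row
        assert list(df.perturbation) == [
            "none", "kernel_count_x", "kernel_count_x", "kernel_size_+", "kernel_size_+",
        ]
        assert list(df.amount[1:]) == [1.5, 2.0, 1, 2]
        assert df.relative_change.iloc[0] == 0.0
        # CSV round trip
        path = tmp_path / "sens.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        np.testing.assert_allclose(back.final_val_loss, df.final_val_loss)
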