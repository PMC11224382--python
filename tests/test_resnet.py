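"""Residual classifier: architecture contracts, residual algebra, training."""

import numpy as np
import pytest

from podfusion.errors import DegenerateInputError, ShapeError
from podfusion.nnet import BatchNorm2d, Conv2d, ReLU
from podfusion.resnet_rh import (
    ArchitectureSpec,
    ResidualModule,
    TrainConfig,
    audit,
    build_model,
    fit,
    predict,
    residual_forward,
    stratified_split,
    train,
)
from podfusion.synthetic import GeneratorConfig, generate_dataset
from podfusion.experiment import _representations


def small_model(in_channels=4, seed=0):
    return build_model(ArchitectureSpec(in_channels=in_channels, base_channels=4), seed=seed)


@pytest.fixture(scope="module")
def easy_data():
    """Small, well-separated fused dataset (identity class maps)."""
    config = GeneratorConfig(n_per_class=10, rgb_size=(44, 42), seed=21)
    dataset = generate_dataset(config)
    rep = _representations(dataset)
    return rep["fused"], dataset.labels


class TestResidualForward:
    def test_zero_branch_identity_on_nonnegative_input(self, rng):
        x = np.abs(rng.normal(size=(2, 3, 4, 4)))
        out = residual_forward(x, branch=lambda t: np.zeros_like(t))
        assert np.array_equal(out, x)

    def test_activation_applied_after_sum(self, rng):
        x = rng.normal(size=(1, 2, 3, 3))
        out = residual_forward(x, branch=lambda t: -2 * t)
        assert np.array_equal(out, np.maximum(-x, 0.0))

    def test_telescoped_sum_without_activation(self, rng):
        # composing modules with activation disabled satisfies
        # x_L = x_l + sum_i F(x_i)
        branches = [lambda t, k=k: 0.1 * k * np.tanh(t) for k in range(1, 4)]
        x = rng.normal(size=(2, 2, 3, 3))
        recorded = []
        h = x
        for br in branches:
            recorded.append(br(h))
            h = residual_forward(h, br, activation=None)
        assert np.allclose(h, x + sum(recorded))

    def test_shape_mismatch_between_paths_raises(self, rng):
        x = rng.normal(size=(1, 2, 4, 4))
        with pytest.raises(ShapeError):
            residual_forward(x, branch=lambda t: t[:, :, ::2, ::2])

    def test_module_matches_hand_assembled_layers(self, rng):
        module = ResidualModule(3, rng=np.random.default_rng(5))
        x = rng.normal(size=(2, 3, 5, 5))
        got = module.forward(x, train=True)
        conv1, bn1, relu, conv2, bn2 = module.branch.layers
        h = conv1.forward(x.copy(), True)
        h = bn1.forward(h, True)
        h = relu.forward(h, True)
        h = conv2.forward(h, True)
        h = bn2.forward(h, True)
        assert np.allclose(got, np.maximum(x + h, 0.0))


class TestBuildModel:
    def test_forward_shape_contract(self, rng):
        model = small_model()
        scores = model.forward(rng.uniform(size=(5, 22, 21, 4)))
        assert scores.shape == (5, 4)

    def test_audit_reports_eight_modules(self):
        report = audit(small_model())
        assert report["n_modules"] == 8
        assert report["in_channels"] == 4 and report["n_classes"] == 4
        assert report["module_kinds"].count("downsample") == 3

    def test_single_source_ablation_channel_counts(self, rng):
        for channels in (1, 3):
            model = small_model(in_channels=channels)
            out = model.forward(rng.uniform(size=(2, 22, 21, channels)))
            assert out.shape == (2, 4)

    def test_wrong_channel_count_at_forward_raises(self, rng):
        with pytest.raises(ShapeError):
            small_model(in_channels=4).forward(rng.uniform(size=(2, 22, 21, 3)))

    def test_zeroed_branches_make_trunk_residual_free(self, rng):
        # with every branch and shortcut zeroed, plain residual modules pass
        # features through unchanged (ReLU after conv1 makes them nonnegative)
        model = small_model()
        for module in model.modules:
            for layer in module.branch.layers:
                if isinstance(layer, (Conv2d,)):
                    layer.weight[...] = 0.0
        x = rng.uniform(size=(2, 22, 21, 4))
        h = model.relu1.forward(
            model.bn1.forward(model.conv1.forward(x.transpose(0, 3, 1, 2), True), True), True
        )
        for module in model.modules:
            if isinstance(module, ResidualModule):
                assert np.allclose(module.forward(h, train=True), h)
                break


class TestTraining:
    def test_easy_dataset_reaches_high_training_accuracy(self, easy_data):
        x, y = easy_data
        model = small_model(seed=3)
        history = fit(model, x, y, TrainConfig(epochs=12, batch_size=8, seed=3))
        assert history["accuracy"].iloc[-1] > 0.95

    def test_zero_learning_rate_freezes_loss(self, easy_data):
        x, y = easy_data
        # full-batch so batch-norm sees the same statistics every epoch: with
        # no updates the loss must be bit-stable across epochs
        model = small_model(seed=1)
        h = fit(model, x, y, TrainConfig(epochs=3, batch_size=64, learning_rate=0.0, seed=1))
        losses = h["loss"].to_numpy()
        assert np.ptp(losses) < 1e-12

    def test_fixed_seed_reproduces_history(self, easy_data):
        x, y = easy_data
        runs = []
        for _ in range(2):
            model = small_model(seed=2)
            runs.append(fit(model, x, y, TrainConfig(epochs=3, batch_size=8, seed=2)))
        assert np.array_equal(runs[0]["loss"], runs[1]["loss"])

    def test_train_splits_70_30_stratified(self, easy_data):
        x, y = easy_data
        model = small_model(seed=0)
        result = train(model, (x, y), TrainConfig(epochs=1, batch_size=8, seed=0))
        assert result.test_idx.size == 12  # ceil(0.3 * 40)
        assert np.array_equal(np.bincount(y[result.test_idx]), [3, 3, 3, 3])

    def test_single_class_split_raises(self):
        with pytest.raises(DegenerateInputError):
            stratified_split(np.zeros(10), 0.7, 0)

    def test_split_at_paper_scale_gives_125_test(self):
        labels = np.repeat([0, 1, 2, 3], 104)
        train_idx, test_idx = stratified_split(labels, 0.70, 0)
        assert test_idx.size == 125 and train_idx.size == 291


class TestPredict:
    def test_single_sample_and_argmax_semantics(self, rng):
        model = small_model(seed=4)
        labels, scores = predict(model, rng.uniform(size=(22, 21, 4)))
        assert labels.shape == (1,) and scores.shape == (1, 4)
        assert labels[0] == scores[0].argmax()
        assert labels[0] in range(4)

    def test_tie_breaks_to_lowest_index(self):
        scores = np.array([[0.5, 0.5, 0.1, 0.5]])
        assert scores.argmax(axis=1)[0] == 0  # documented tie rule

    def test_dim_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            predict(small_model(), rng.uniform(size=(2, 22, 21, 2)))
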