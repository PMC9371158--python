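"""Architectures, training protocol, prediction, and gradient access."""

import numpy as np
import pytest

import wearcam as w
from wearcam.convnet import (
    ConvBlock,
    ModelSpec,
    TrainedModel,
    _init_params,
    build_architecture,
    build_small_architecture,
    last_conv_length,
)
from wearcam.signal_data import Dataset, SignalWindow
from wearcam.splitting import split_subject_dependent


class TestArchitectures:
    def test_cnn1_structure(self):
        spec = build_architecture("CNN1", 17)
        assert spec.n_conv_layers == 8
        assert all(b.kernel_size == 8 and b.n_filters == 100 for b in spec.blocks)
        assert [b.followed_by_pool for b in spec.blocks] == [True, True, True, False]
        assert spec.dropout_rate == 0.5

    def test_cnn2_structure(self):
        spec = build_architecture("CNN2", 17)
        assert spec.n_conv_layers == 6
        assert all(b.kernel_size == 4 for b in spec.blocks)
        assert [b.followed_by_pool for b in spec.blocks] == [True, True, False]

    def test_bui_walking_head_width(self):
        # identification net for an activity performed by 29 subjects
        spec = build_architecture("CNN1", 29)
        assert spec.n_classes == 29
        params = _init_params(spec, np.random.default_rng(0))
        assert params["fc_w"].shape[1] == 29

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            build_architecture("CNN1", 1)


class TestLastConvLength:
    @pytest.mark.parametrize(
        "name,input_length,expected",
        [("CNN1", 151, 19), ("CNN2", 151, 38), ("CNN1", 160, 20)],
    )
    def test_printed_resolutions(self, name, input_length, expected):
        spec = build_architecture(name, 17)
        assert last_conv_length(spec, input_length) == expected

    def test_no_pooling_is_identity(self):
        spec = ModelSpec(
            name="custom",
            blocks=[ConvBlock(2, 10, 3, followed_by_pool=False)],
            n_classes=2,
        )
        assert last_conv_length(spec, 151) == 151

    def test_monotone_in_input_length(self):
        spec = build_architecture("CNN1", 17)
        lengths = [last_conv_length(spec, n) for n in range(1, 400)]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))


def _toy_two_class_dataset(n_per_class=30, seed=0):
    """Linearly separable toy: two sinusoid classes with distinct amplitude."""
    rng = np.random.default_rng(seed)
    t = np.arange(64) / 50.0
    windows = []
    for cls, amp, offset in [("low", 1.0, 0.0), ("high", 4.0, 2.0)]:
        for i in range(n_per_class):
            base = offset + amp * np.sin(2 * np.pi * 2.0 * t)
            vals = np.stack([base, base * 0.5, base * 0.2], axis=1)
            vals = vals + 0.05 * rng.standard_normal(vals.shape)
            windows.append(SignalWindow(values=vals, activity=cls, subject=1 + i % 3, trial=i))
    return Dataset(windows=windows, activity_vocabulary=["low", "high"], subject_roster=[1, 2, 3])


@pytest.fixture(scope="module")
def toy_model():
    ds = _toy_two_class_dataset()
    plan = split_subject_dependent(ds, 0.3, seed=42)
    spec = ModelSpec(
        name="custom",
        blocks=[ConvBlock(1, 6, 5, followed_by_pool=True)],
        n_classes=2,
        input_length=64,
        dropout_rate=0.1,
    )
    config = w.TrainConfig(epochs=15, batch_size=16, seed=0)
    return w.train_model(spec, ds, plan, config), ds, plan, spec, config


class TestTraining:
    def test_separable_toy_reaches_high_f1(self, toy_model):
        model, *_ = toy_model
        best = max(h["val_macro_f1"] for h in model.training_history)
        assert best >= 0.95

    def test_checkpoint_is_earliest_argmax(self, toy_model):
        model, *_ = toy_model
        f1s = [h["val_macro_f1"] for h in model.training_history]
        assert model.checkpoint_epoch == int(np.argmax(f1s))

    def test_history_length_equals_epochs(self, toy_model):
        model, _, _, _, config = toy_model
        assert len(model.training_history) == config.epochs

    def test_same_seed_reproduces_history(self):
        ds = _toy_two_class_dataset(n_per_class=10)
        plan = split_subject_dependent(ds, 0.3, seed=42)
        spec = ModelSpec(
            name="custom",
            blocks=[ConvBlock(1, 4, 3, followed_by_pool=True)],
            n_classes=2,
            input_length=64,
        )
        config = w.TrainConfig(epochs=3, batch_size=8, seed=5)
        h1 = w.train_model(spec, ds, plan, config).training_history
        h2 = w.train_model(spec, ds, plan, config).training_history
        assert h1 == h2

    def test_val_only_class_recorded_as_warning(self):
        ds = _toy_two_class_dataset(n_per_class=6)
        # route every "high" window to validation
        acts = ds.activities()
        hi = np.flatnonzero(acts == "high")
        lo = np.flatnonzero(acts == "low")
        plan = w.SplitPlan(strategy="SD", train_indices=lo, val_indices=hi, seed=None)
        spec = ModelSpec(
            name="custom",
            blocks=[ConvBlock(1, 4, 3, followed_by_pool=True)],
            n_classes=2,
            input_length=64,
        )
        model = w.train_model(spec, ds, plan, w.TrainConfig(epochs=1, batch_size=8, seed=0))
        assert any("absent from training" in msg for msg in model.warnings)

    def test_model_save_load_round_trip(self, toy_model, tmp_path):
        model, ds, *_ = toy_model
        model.save(tmp_path / "m")
        back = TrainedModel.load(tmp_path / "m")
        x = ds.values()[:5]
        np.testing.assert_allclose(back.scores(x), model.scores(x), atol=1e-12)
        assert back.classes == model.classes


class TestPrediction:
    def test_scores_are_probabilities(self, toy_model):
        model, ds, *_ = toy_model
        preds = w.predict(model, ds.windows[:8])
        for p in preds:
            assert p.class_scores.shape == (2,)
            assert p.class_scores.sum() == pytest.approx(1.0, abs=1e-6)
            assert (p.class_scores >= 0).all()

    def test_tie_breaks_to_lowest_index(self):
        spec = ModelSpec(
            name="custom",
            blocks=[ConvBlock(1, 4, 3, followed_by_pool=False)],
            n_classes=3,
            input_length=8,
        )
        params = _init_params(spec, np.random.default_rng(0))
        params["fc_w"][:] = 0.0  # uniform scores: exact three-way tie
        params["fc_b"][:] = 0.0
        model = TrainedModel(spec=spec, params=params, classes=[0, 1, 2])
        win = SignalWindow(values=np.ones((8, 3)), activity="x", subject=1)
        assert w.predict(model, [win])[0].predicted_class == 0

    def test_shape_mismatch_names_expected(self, toy_model):
        model, *_ = toy_model
        bad = SignalWindow(values=np.zeros((10, 3)), activity="low", subject=1)
        with pytest.raises(ValueError, match=r"\(64, 3\)"):
            w.predict(model, [bad])


class TestActivationsAndGradient:
    def _random_model(self, score_mode="logit", pool_last=True, seed=0):
        spec = ModelSpec(
            name="custom",
            blocks=[
                ConvBlock(1, 5, 3, followed_by_pool=True),
                ConvBlock(1, 4, 3, followed_by_pool=pool_last),
            ],
            n_classes=3,
            input_length=20,
        )
        params = _init_params(spec, np.random.default_rng(seed))
        return TrainedModel(spec=spec, params=params, classes=[0, 1, 2], score_mode=score_mode)

    def test_zero_class_head_gives_zero_gradient(self):
        model = self._random_model()
        model.params["fc_w"][:, 1] = 0.0
        win = SignalWindow(values=np.random.default_rng(0).normal(size=(20, 3)), activity="x", subject=1)
        _, grad = w.activations_and_gradient(model, win, class_index=1)
        np.testing.assert_array_equal(grad, 0.0)

    @pytest.mark.parametrize("score_mode", ["logit", "prob"])
    def test_gradient_matches_central_finite_differences(self, score_mode):
        model = self._random_model(score_mode=score_mode)
        win = SignalWindow(values=np.random.default_rng(1).normal(size=(20, 3)), activity="x", subject=1)
        maps, grad = w.activations_and_gradient(model, win, class_index=2)
        h = 1e-3
        for pos, k in [(0, 0), (2, 1), (4, 3)]:
            up, down = maps.copy(), maps.copy()
            up[pos, k] += h
            down[pos, k] -= h
            fd = (
                model.class_score_from_maps(up, 2) - model.class_score_from_maps(down, 2)
            ) / (2 * h)
            assert grad[pos, k] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_cnn1_shapes_on_standard_window(self):
        spec = build_architecture("CNN1", 4)
        params = _init_params(spec, np.random.default_rng(0))
        model = TrainedModel(spec=spec, params=params, classes=list(range(4)))
        win = SignalWindow(values=np.random.default_rng(2).normal(size=(151, 3)), activity="x", subject=1)
        maps, grad = w.activations_and_gradient(model, win, class_index=0)
        assert maps.shape == (19, 100)
        assert grad.shape == (19, 100)

    def test_invalid_class_index_rejected(self):
        model = self._random_model()
        win = SignalWindow(values=np.zeros((20, 3)), activity="x", subject=1)
        with pytest.raises(ValueError, match="class_index"):
            w.activations_and_gradient(model, win, class_index=7)


class TestSmallArchitecture:
    def test_desk_scale_spec_resolution(self):
        spec = build_small_architecture(17)
        assert last_conv_length(spec, 151) == 38
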