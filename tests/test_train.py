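"""Training recipe: step-decay schedule against its closed form,
optimizer single-step arithmetic, smoke training, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricedom import arch, nn, synth
from ricedom.train import (DivergenceError, HyperParams, evaluate,
                           make_optimizer, scheduled_lr, train_model)


class TestScheduledLr:
    @pytest.mark.parametrize("lr,gamma,step,epoch,expected", [
        (0.1, 0.1, 10, 10, 0.01),
        (0.1, 0.1, 10, 9, 0.1),
        (0.1, 0.1, 10, 0, 0.1),
        # tuned recipe for this architecture: lr 1.9e-4, gamma 0.085, step 15
        (0.00019, 0.085, 15, 30, 0.00019 * 0.085**2),
    ])
    def test_worked_examples(self, lr, gamma, step, epoch, expected):
        assert scheduled_lr(lr, gamma, step, epoch) == pytest.approx(expected, rel=1e-12)

    def test_matches_closed_form_on_random_draws(self):
        """Oracle: direct evaluation of initial_lr * gamma^floor(e/s) over
        10^4 random parameter draws."""
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            lr = 10 ** rng.uniform(-5, -1)
            gamma = 10 ** rng.uniform(-5, -1)
            step = int(rng.integers(1, 40))
            epoch = int(rng.integers(0, 200))
            assert scheduled_lr(lr, gamma, step, epoch) == lr * gamma ** (epoch // step)

    def test_seven_distinct_values_for_tuned_recipe_over_100_epochs(self):
        lrs = {scheduled_lr(0.00019, 0.085, 15, e) for e in range(100)}
        assert len(lrs) == 7

    @settings(derandomize=True, max_examples=200)
    @given(lr=st.floats(1e-6, 1.0), gamma=st.floats(1e-6, 0.999),
           step=st.integers(1, 100), epoch=st.integers(0, 1000))
    def test_piecewise_constant_within_intervals(self, lr, gamma, step, epoch):
        """The rate is constant inside each step_size interval and
        non-increasing across epochs."""
        base = scheduled_lr(lr, gamma, step, epoch)
        assert scheduled_lr(lr, gamma, step, (epoch // step) * step) == base
        assert scheduled_lr(lr, gamma, step, epoch + step) <= base

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            scheduled_lr(0.1, 0.1, 0, 1)
        with pytest.raises(ValueError):
            scheduled_lr(0.1, 0.1, 10, -1)


class _OneWeight(nn.Layer):
    """Scalar model f(w) = w*x for optimizer arithmetic tests."""

    def __init__(self, w0):
        self.w = nn.Param("w", np.array([w0], dtype=np.float64))

    def params(self):
        return [self.w]


class TestMakeOptimizer:
    def test_sgd_single_step_on_quadratic(self):
        layer = _OneWeight(1.0)
        opt = nn.SGD(layer.params(), lr=0.1, weight_decay=0.0)
        layer.w.grad[:] = layer.w.data  # grad of 0.5 w^2
        opt.step()
        assert layer.w.data[0] == pytest.approx(0.9)

    def test_sgd_weight_decay_on_zero_gradient(self):
        layer = _OneWeight(1.0)
        opt = nn.SGD(layer.params(), lr=0.1, weight_decay=0.1)
        layer.w.grad[:] = 0.0
        opt.step()
        assert layer.w.data[0] == pytest.approx(0.99)

    def test_adam_first_step_magnitude_is_lr(self):
        """Adam's bias-corrected first step is ~lr regardless of gradient
        scale."""
        for gscale in (1e-4, 1.0, 1e4):
            layer = _OneWeight(0.0)
            opt = nn.Adam(layer.params(), lr=0.01)
            layer.w.grad[:] = gscale
            opt.step()
            assert abs(layer.w.data[0]) == pytest.approx(0.01, rel=1e-3)

    def test_unknown_optimizer_listed_in_error(self):
        with pytest.raises(ValueError, match="SGD"):
            HyperParams(optimizer="RMSProp")

    def test_bn_parameters_excluded_from_decay(self):
        plan = arch.default_plan(width_mult=0.1, input_size=16)
        model = arch.build_model(plan, rng=np.random.default_rng(0))
        opt = make_optimizer(model, HyperParams(weight_decay=0.1))
        decayed = {p.name for p in opt.params if p.decay}
        assert not any(".bn." in n or n == "fc.bias" for n in decayed)
        assert any(n.endswith(".weight") for n in decayed)


@pytest.fixture(scope="module")
def tiny_binary_data():
    """64 well-milled vs substandard crops at 32 px: a separable 2-class
    smoke set."""
    rng = np.random.default_rng(12)
    X, y = synth.render_crop_dataset(32, rng, crop_size=32,
                                     retention_levels={0: 0.5, 1: 4.5, 2: 12.0})
    keep = y != 1
    X, y = X[keep], (y[keep] // 2)
    Xp = X.astype(np.float32) / 255.0
    Xp = (Xp - Xp.mean(axis=(0, 1, 2))) / Xp.std(axis=(0, 1, 2))
    return Xp.transpose(0, 3, 1, 2).copy(), y


class TestTrainModel:
    def _model(self, classes=2):
        plan = arch.default_plan(classes, width_mult=0.2, input_size=32)
        return arch.build_model(plan, rng=np.random.default_rng(0))

    def test_history_lr_sequence_follows_schedule(self, tiny_binary_data):
        X, y = tiny_binary_data
        hp = HyperParams(optimizer="Adam", learning_rate=1e-3, step_size=1,
                         gamma=0.5, weight_decay=0.0, batch_size=32, epochs=3)
        hist, _ = train_model(self._model(), X, y, hp, rng=np.random.default_rng(1))
        assert hist.lrs == [1e-3, 5e-4, 2.5e-4]

    def test_smoke_training_loss_decreases(self, tiny_binary_data):
        """Three epochs on 64 separable images strictly decrease the mean
        training loss."""
        X, y = tiny_binary_data
        hp = HyperParams(optimizer="Adam", learning_rate=1e-3, step_size=15,
                         gamma=0.085, weight_decay=1e-4, batch_size=16, epochs=3)
        hist, _ = train_model(self._model(), X, y, hp, rng=np.random.default_rng(2))
        losses = hist.train_losses
        assert losses[0] > losses[1] > losses[2]

    def test_zero_epochs_returns_empty_history_and_initial_state(self, tiny_binary_data):
        X, y = tiny_binary_data
        model = self._model()
        before = model.state_dict()
        hp = HyperParams(epochs=0)
        hist, best = train_model(model, X, y, hp, rng=np.random.default_rng(3))
        assert len(hist) == 0
        assert all(np.array_equal(before[k], best["state"][k]) for k in before)

    def test_seed_determinism(self, tiny_binary_data):
        X, y = tiny_binary_data
        hp = HyperParams(optimizer="SGD", learning_rate=1e-2, step_size=15,
                         gamma=0.5, weight_decay=0.0, batch_size=16, epochs=2)
        runs = []
        for _ in range(2):
            hist, _ = train_model(self._model(), X, y, hp,
                                  rng=np.random.default_rng(5))
            runs.append((hist.train_losses, hist.lrs))
        assert runs[0] == runs[1]

    def test_divergence_aborts_with_epoch_index(self, tiny_binary_data):
        X, y = tiny_binary_data
        hp = HyperParams(optimizer="SGD", learning_rate=1e6, step_size=15,
                         gamma=0.5, weight_decay=0.0, batch_size=16, epochs=3)
        with pytest.raises(DivergenceError, match="epoch"), \
                np.errstate(over="ignore", invalid="ignore"):
            train_model(self._model(), X, y, hp, rng=np.random.default_rng(6))


class TestEvaluate:
    def test_confusion_total_equals_subset_size(self, tiny_binary_data):
        X, y = tiny_binary_data
        model = arch.build_model(
            arch.default_plan(2, width_mult=0.2, input_size=32),
            rng=np.random.default_rng(0))
        cm = evaluate(model, X, y, n_classes=2)
        assert cm.total == len(y)

    def test_empty_subset_rejected(self):
        model = arch.build_model(
            arch.default_plan(2, width_mult=0.1, input_size=16),
            rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((0, 3, 16, 16), np.float32), np.zeros(0, int), 2)

    def test_constant_classifier_fills_one_column(self):
        """A model that always predicts class 0 on a balanced 3-class set
        puts 10/10/10 in column 0."""
        class Constant(nn.Network):
            def __init__(self):
                super().__init__([])

            def forward(self, x, train=False):
                out = np.zeros((len(x), 3), np.float32)
                out[:, 0] = 1.0
                return out

        y = np.repeat([0, 1, 2], 10)
        cm = evaluate(Constant(), np.zeros((30, 3, 4, 4), np.float32), y, 3)
        assert cm.counts[:, 0].tolist() == [10, 10, 10]
        assert cm.counts.sum() == 30
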