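import numpy as np
import pytest

from posekit.models import ModelConfig, build_model
from posekit.skeleton import split_train_val
from posekit.synthetic import make_dataset, toy_creature
from posekit.training import (
    ScheduleState,
    TrainSchedule,
    fit,
    map_loss,
    replay_schedule,
    schedule_step,
)


class TestMapLoss:
    def test_zero_when_predictions_match(self, rng):
        t = rng.normal(0, 1, (2, 4, 4, 3))
        assert float(map_loss([t, t], t).data) == 0.0

    def test_mean_over_outputs(self):
        target = np.zeros((1, 2, 2, 1))
        a = np.full((1, 2, 2, 1), np.sqrt(0.1))  # per-output MSE 0.1
        b = np.full((1, 2, 2, 1), np.sqrt(0.3))  # per-output MSE 0.3
        assert float(map_loss([a, b], target).data) == pytest.approx(0.2)

    def test_zero_prediction_gives_target_mean_square(self, rng):
        target = rng.normal(0, 1, (2, 8, 8, 4))
        m = float((target**2).mean())
        assert float(map_loss([np.zeros_like(target)], target).data) == pytest.approx(m)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            map_loss([np.zeros((1, 2, 2, 1))], np.zeros((1, 4, 4, 1)))


class TestScheduleStep:
    def test_plateau_reduces_rate_after_patience(self):
        sched = TrainSchedule()
        state = ScheduleState(lr=1e-3)
        for epoch in range(1, 12):
            state, stop, best = schedule_step(1.0, state, sched)
            if epoch == 1:
                assert best  # first loss is always an improvement over inf
        assert state.lr == pytest.approx(2e-4)
        assert not stop

    def test_improvement_resets_counters(self):
        sched = TrainSchedule()
        history = [1.0] * 5 + [0.99] + [0.99] * 9  # improvement of 0.01 at epoch 6
        lrs, stop_at = replay_schedule(history, sched)
        assert all(lr == pytest.approx(1e-3) for lr in lrs)
        assert stop_at is None

    def test_sub_threshold_improvement_ignored(self):
        sched = TrainSchedule()
        # a small early gain that never exceeds the 1e-3 min delta relative
        # to the best epoch does not reset the patience counter
        history = [1.0, 0.9996, 0.9992] + [0.9992] * 9
        lrs, _ = replay_schedule(history, sched)
        assert lrs[-1] == pytest.approx(1e-3 / 5)
        # but a cumulative drift past the threshold counts as improvement
        lrs2, _ = replay_schedule([1.0 - 5e-4 * i for i in range(12)], sched)
        assert lrs2[-1] == pytest.approx(1e-3)

    def test_stop_after_fifty_stagnant_epochs(self):
        sched = TrainSchedule()
        lrs, stop_at = replay_schedule([1.0] * 60, sched)
        assert stop_at == 50
        # rate was cut at epochs 11, 21, 31, 41, 51 (1-based)
        assert lrs[-1] == pytest.approx(1e-3 / 5**5)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainSchedule(lr_factor=1.0)
        with pytest.raises(ValueError):
            TrainSchedule(learning_rate=0)


@pytest.fixture(scope="module")
def tiny_fit():
    spec = toy_creature(32, jitter=4.0, noise_level=0.0)
    ds = make_dataset(spec, 8, seed=2)
    train, val = split_train_val(ds, 0.25, seed=0)
    cfg = ModelConfig(
        arch="stacked_densenet", n_stacks=1, output_stride=4,
        n_keypoints=5, n_graph_maps=0, input_shape=(32, 32, 1),
        growth_rate=4, n_layers_per_block=1, n_down=1, front_filters=4,
        seed=0,
    )
    model = build_model(cfg)
    sched = TrainSchedule(max_epochs=5, seed=0)
    result = fit(model, train, val, augment_config=None, schedule=sched)
    return model, result, sched


class TestFit:
    def test_history_is_complete_and_finite(self, tiny_fit):
        _, result, _ = tiny_fit
        h = result.history
        assert list(h.columns) == ["epoch", "loss", "val_loss", "lr"]
        assert len(h) == 5
        assert np.isfinite(h[["loss", "val_loss", "lr"]].to_numpy()).all()

    def test_best_val_is_running_minimum(self, tiny_fit):
        _, result, _ = tiny_fit
        assert result.best_val_loss == result.history.val_loss.min()
        assert result.best_epoch == int(result.history.val_loss.idxmin())

    def test_lr_history_replays_from_val_losses(self, tiny_fit):
        _, result, sched = tiny_fit
        lrs, _ = replay_schedule(result.history.val_loss.tolist(), sched)
        assert np.allclose(lrs, result.history.lr.tolist())

    def test_fit_is_repeatable_with_fixed_seed(self):
        spec = toy_creature(32, jitter=4.0, noise_level=0.0)
        ds = make_dataset(spec, 6, seed=5)
        train, val = split_train_val(ds, 0.34, seed=1)

        def run():
            cfg = ModelConfig(
                arch="stacked_densenet", n_stacks=1, output_stride=8,
                n_keypoints=5, n_graph_maps=0, input_shape=(32, 32, 1),
                growth_rate=4, n_layers_per_block=1, n_down=1,
                front_filters=4, seed=3,
            )
            model = build_model(cfg)
            sched = TrainSchedule(max_epochs=3, seed=7)
            return fit(model, train, val, None, sched).history

        h1, h2 = run(), run()
        assert np.allclose(h1.val_loss, h2.val_loss, rtol=1e-5)

    def test_empty_split_rejected(self, tiny_fit, toy_dataset):
        model, _, _ = tiny_fit
        with pytest.raises(ValueError):
            fit(model, toy_dataset.subset([]), toy_dataset, None, TrainSchedule())
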