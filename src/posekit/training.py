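"""Training: mean-squared-error map loss, plateau schedule, and the fit loop.

The loss is the mean over the model's supervised outputs of the per-output
mean squared error against one shared target stack (intermediate
supervision).  Optimisation uses Adam at an initial learning rate of 1e-3
with batches of 16.  The learning rate is divided by 5 whenever the
validation loss fails to improve by more than 1e-3 for 10 consecutive
epochs, and training stops once it fails to improve for 50 consecutive
epochs; the weights from the best validation epoch are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_example
from .confmaps import render_targets
from .models import PoseModel
from .nn import Adam, core
from .skeleton import AnnotationSet

__all__ = [
    "TrainSchedule",
    "ScheduleState",
    "TrainingDivergence",
    "map_loss",
    "schedule_step",
    "replay_schedule",
    "fit",
    "FitResult",
]


@dataclass(frozen=True)
class TrainSchedule:
    """Optimisation schedule: step size, batching, plateau rules."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    lr_factor: float = 5.0
    lr_min_delta: float = 1e-3
    lr_patience: int = 10
    stop_patience: int = 50
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.lr_min_delta,
               self.lr_patience, self.stop_patience, self.max_epochs) <= 0:
            raise ValueError("schedule values must be positive")
        if self.lr_factor <= 1:
            raise ValueError("lr_factor must exceed 1")


@dataclass
class ScheduleState:
    """Mutable plateau-tracking state carried across epochs."""

    lr: float
    best: float = np.inf
    wait_lr: int = 0
    wait_stop: int = 0


class TrainingDivergence(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


def map_loss(outputs, target: np.ndarray):
    """Mean over supervised outputs of per-output MSE against ``target``.

    ``outputs`` is the list of stack outputs (autodiff tensors or arrays),
    all compared to the same ground-truth stack.
    """
    if not isinstance(outputs, (list, tuple)):
        outputs = [outputs]
    target = np.asarray(target)
    tensors = [
        o if isinstance(o, core.Tensor) else core.Tensor(np.asarray(o))
        for o in outputs
    ]
    for t in tensors:
        if t.shape != target.shape:
            raise ValueError(
                f"output shape {t.shape} does not match target {target.shape}"
            )
    total = core.mse(tensors[0], target)
    for t in tensors[1:]:
        total = core.add(total, core.mse(t, target))
    return core.scale(total, 1.0 / len(tensors))


def schedule_step(
    val_loss: float, state: ScheduleState, schedule: TrainSchedule
) -> tuple[ScheduleState, bool, bool]:
    """Advance the plateau schedule by one epoch.

    Improvement means ``val_loss < best - lr_min_delta``.  After
    ``lr_patience`` consecutive non-improving epochs the learning rate is
    divided by ``lr_factor`` (and the patience counter resets); after
    ``stop_patience`` consecutive non-improving epochs the stop flag is
    raised.  The best flag marks epochs that set a new best.
    """
    improved = val_loss < state.best - schedule.lr_min_delta
    if improved:
        state.best = val_loss
        state.wait_lr = 0
        state.wait_stop = 0
    else:
        state.wait_lr += 1
        state.wait_stop += 1
        if state.wait_lr >= schedule.lr_patience:
            state.lr /= schedule.lr_factor
            state.wait_lr = 0
    return state, state.wait_stop >= schedule.stop_patience, improved


def replay_schedule(
    history: list[float], schedule: TrainSchedule
) -> tuple[list[float], int | None]:
    """Replay the rule over a validation-loss history.

    Returns the learning rate in force *after* each epoch and the epoch
    index (0-based) at which training would stop, or None.
    """
    state = ScheduleState(lr=schedule.learning_rate)
    lrs: list[float] = []
    stop_at = None
    for i, loss in enumerate(history):
        state, stop, _ = schedule_step(loss, state, schedule)
        lrs.append(state.lr)
        if stop and stop_at is None:
            stop_at = i
    return lrs, stop_at


@dataclass
class FitResult:
    """Outcome of :func:`fit`: per-epoch log and the best epoch."""

    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _targets_for(
    aset: AnnotationSet, model: PoseModel, indices
) -> np.ndarray:
    cfg = model.config
    h, w, _ = cfg.input_shape
    include_graph = cfg.n_graph_maps > 0
    stacks = []
    for i in indices:
        stack = render_targets(
            aset.keypoint_set(i), aset.skeleton, (h, w),
            cfg.output_stride, cfg.sigma, include_graph,
        )
        stacks.append(stack.maps.transpose(1, 2, 0))
    return np.stack(stacks).astype(np.float32)


def fit(
    model: PoseModel,
    train_set: AnnotationSet,
    val_set: AnnotationSet,
    augment_config: AugmentConfig | None = None,
    schedule: TrainSchedule | None = None,
    log_path=None,
) -> FitResult:
    """Train a pose model and keep the best-validation-epoch weights.

    Each epoch every training example is augmented with freshly sampled
    parameters (spatial transforms move the drawn targets with the image;
    noise transforms touch only the image), targets are rendered at the
    model's output stride, and the map loss is optimised with Adam at the
    scheduled learning rate.  Validation loss is computed on unaugmented
    data.  The model is left holding the best epoch's weights.
    """
    schedule = schedule or TrainSchedule()
    cfg = model.config
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(schedule.seed)
    optimizer = Adam(model.parameters(), lr=schedule.learning_rate)
    state = ScheduleState(lr=schedule.learning_rate)
    include_graph = cfg.n_graph_maps > 0
    h, w, _ = cfg.input_shape

    val_images = val_set.images
    val_targets = _targets_for(val_set, model, range(len(val_set)))

    rows = []
    best_epoch, best_val = -1, np.inf
    best_state = None
    n_train = len(train_set)
    for epoch in range(schedule.max_epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for lo in range(0, n_train, schedule.batch_size):
            batch = order[lo : lo + schedule.batch_size]
            images, targets = [], []
            for i in batch:
                img, kp = train_set.images[i], train_set.keypoint_set(i)
                if augment_config is not None:
                    img, kp = augment_example(
                        img, kp, train_set.skeleton, augment_config, rng
                    )
                stack = render_targets(
                    kp, train_set.skeleton, (h, w),
                    cfg.output_stride, cfg.sigma, include_graph,
                )
                images.append(img)
                targets.append(stack.maps.transpose(1, 2, 0))
            x = np.stack(images)
            y = np.stack(targets).astype(np.float32)

            outputs = model(x, train=True)
            loss = map_loss(outputs, y)
            if not np.isfinite(loss.data):
                raise TrainingDivergence(epoch)
            optimizer.zero_grad()
            loss.backward()
            optimizer.lr = state.lr
            optimizer.step()
            epoch_losses.append(float(loss.data))

        val_losses = []
        for lo in range(0, len(val_set), schedule.batch_size):
            sl = slice(lo, lo + schedule.batch_size)
            outputs = model(val_images[sl], train=False)
            val_losses.append(
                float(map_loss(outputs, val_targets[sl]).data)
                * (min(sl.stop or len(val_set), len(val_set)) - sl.start)
            )
        val_loss = sum(val_losses) / len(val_set)
        if not np.isfinite(val_loss):
            raise TrainingDivergence(epoch)

        state, stop, improved = schedule_step(val_loss, state, schedule)
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = {
                k: v.copy() for k, v in model.state_arrays().items()
            }
        rows.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "lr": state.lr,
            }
        )
        if stop:
            break

    if best_state is not None:
        model.load_state_arrays(best_state)
    history = pd.DataFrame(rows)
    if log_path is not None:
        history.to_csv(log_path, index=False)
    return FitResult(history=history, best_epoch=best_epoch,
                     best_val_loss=best_val)
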