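"""Training protocol: LR schedule with patience, freeze -> unfreeze of the
PWM kernels, and rotating k-fold cross-validation.

The schedule starts at lr 0.01 and multiplies it by 0.1 whenever the
validation loss has not improved for ``patience`` epochs; training stops
once the learning rate drops below 5e-7. The model is first trained with
the convolution kernels frozen to the database PWMs; optionally the kernels
are then unfrozen and fine-tuned for a few more epochs with the same
validation monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ActivityMatrix, EncodedBatch
from .model import SequenceModel, mse_loss
from .optim import ProxAdam

__all__ = [
    "TrainSchedule",
    "PathSchedule",
    "FitResult",
    "ScheduleDriver",
    "fit",
    "crossvalidate",
    "r_squared",
]


@dataclass
class TrainSchedule:
    initial_lr: float = 0.01
    decay_factor: float = 0.1
    patience: int = 10
    stop_lr: float = 5e-7
    finetune_epochs: int = 10
    batch_size: int = 128
    min_rel_improvement: float = 1e-6
    warmup_epochs: int = 0  # epochs before patience counting starts
    max_epochs: int = 10_000  # safety net; the LR floor is the real stop

    def __post_init__(self):
        if not 0 < self.decay_factor < 1:
            raise ValueError("decay factor must lie in (0, 1)")
        if self.stop_lr >= self.initial_lr:
            raise ValueError("stop_lr must be below the initial learning rate")


@dataclass
class PathSchedule(TrainSchedule):
    """Shorter schedule for warm-started penalty-path steps: each step
    resumes from an already converged model, so a low starting rate and
    tight patience reach the stopping criterion quickly."""

    initial_lr: float = 1e-3
    patience: int = 3
    stop_lr: float = 5e-6
    finetune_epochs: int = 0
    max_epochs: int = 60


@dataclass
class FitResult:
    history: list[dict]  # per epoch: epoch, lr, train_loss, val_loss, phase
    best_val_loss: float
    best_state: dict[str, np.ndarray]
    n_decays: int
    n_epochs: int


class ScheduleDriver:
    """Patience/decay bookkeeping decoupled from the actual training step.

    ``update`` is called once per epoch with the validation loss; it returns
    False when the learning-rate floor has been crossed and training should
    stop. Improvement means a relative decrease of at least
    ``min_rel_improvement`` over the best loss seen so far.
    """

    def __init__(self, schedule: TrainSchedule):
        self.schedule = schedule
        self.lr = schedule.initial_lr
        self.best = np.inf
        self.stale = 0
        self.n_decays = 0
        self.epoch = 0
        self.improved = False

    def update(self, val_loss: float) -> bool:
        s = self.schedule
        self.epoch += 1
        self.improved = val_loss < self.best * (1.0 - s.min_rel_improvement)
        if self.improved or not np.isfinite(self.best):
            self.best = val_loss
            self.stale = 0
            return True
        if self.epoch <= s.warmup_epochs:
            return True  # escape phase: no patience counting yet
        self.stale += 1
        if self.stale >= s.patience:
            self.lr *= s.decay_factor
            self.n_decays += 1
            self.stale = 0
            if self.lr < s.stop_lr:
                return False
        return True


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    X, Y = data
    if isinstance(X, EncodedBatch):
        X = X.onehot
    if isinstance(Y, ActivityMatrix):
        Y = Y.values
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("sequence and activity region counts differ")
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    return X, Y


def _epoch(model, X, Y, opt, batch_size, rng) -> float:
    order = rng.permutation(X.shape[0])
    total, count = 0.0, 0
    for lo in range(0, len(order), batch_size):
        idx = order[lo : lo + batch_size]
        pred = model.forward(X[idx])
        loss = mse_loss(pred, Y[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        total += float(loss.data) * len(idx)
        count += len(idx)
    return total / count


def _val_loss(model, X, Y) -> float:
    pred = model.predict(X)
    return float(np.mean((pred - Y) ** 2))


def fit(
    model: SequenceModel,
    train_data,
    val_data,
    schedule: TrainSchedule | None = None,
    optimizer: ProxAdam | None = None,
    seed: int = 0,
    finetune: bool = False,
    restore_best: bool = True,
) -> FitResult:
    """Train to the learning-rate floor; optionally fine-tune kernels after.

    Phase 1 trains with the kernels frozen. If ``finetune`` is set, the
    kernels are then unfrozen and trained for ``schedule.finetune_epochs``
    more epochs while validation is still monitored. The best-validation
    parameter state is returned (and restored onto the model by default).
    """
    schedule = schedule or TrainSchedule()
    Xtr, Ytr = _as_arrays(train_data)
    Xva, Yva = _as_arrays(val_data)
    rng = np.random.default_rng(seed)
    intercept = model.params["intercept"]
    if intercept.requires_grad and not np.any(intercept.data):
        # start a fresh intercept at the target mean so the coefficient
        # matrix does not have to absorb a common offset through the
        # (all-positive) pooled features
        intercept.data[...] = Ytr.mean(axis=0)
    opt = optimizer or ProxAdam(model.params.trainable(), lr=schedule.initial_lr)

    driver = ScheduleDriver(schedule)
    history: list[dict] = []
    # the incoming state is the incumbent: warm starts must never lose to it
    best_state = model.params.copy_arrays()
    best_val = _val_loss(model, Xva, Yva)

    epoch = 0
    while epoch < schedule.max_epochs:
        epoch += 1
        opt.lr = driver.lr
        train_loss = _epoch(model, Xtr, Ytr, opt, schedule.batch_size, rng)
        val = _val_loss(model, Xva, Yva)
        history.append(
            {"epoch": epoch, "lr": driver.lr, "train_loss": train_loss,
             "val_loss": val, "phase": "frozen"}
        )
        if val < best_val:
            best_val = val
            best_state = model.params.copy_arrays()
        if not driver.update(val):
            break

    if finetune and schedule.finetune_epochs > 0:
        model.params.load_arrays(best_state)
        model.set_kernels_frozen(False)
        opt.add_param("kernels", model.params["kernels"])
        opt.lr = schedule.initial_lr * schedule.decay_factor  # gentle restart
        for fe in range(schedule.finetune_epochs):
            epoch += 1
            train_loss = _epoch(model, Xtr, Ytr, opt, schedule.batch_size, rng)
            val = _val_loss(model, Xva, Yva)
            history.append(
                {"epoch": epoch, "lr": opt.lr, "train_loss": train_loss,
                 "val_loss": val, "phase": "finetune"}
            )
            if val < best_val:
                best_val = val
                best_state = model.params.copy_arrays()

    if restore_best:
        model.params.load_arrays(best_state)
    return FitResult(
        history=history,
        best_val_loss=float(best_val),
        best_state=best_state,
        n_decays=driver.n_decays,
        n_epochs=epoch,
    )


# -------------------------------------------------------------------- CV
def r_squared(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-output R^2 = 1 - SS_res / SS_tot, SS_tot around the target mean."""
    ss_res = ((target - pred) ** 2).sum(axis=0)
    ss_tot = ((target - target.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)


@dataclass
class CVResult:
    per_fold_r2: np.ndarray  # (k, c)
    mean_r2: np.ndarray  # (c,)
    stderr_r2: np.ndarray  # (c,)
    per_fold_coefs: list[np.ndarray]
    per_fold_history: list[FitResult]


def crossvalidate(
    batch: EncodedBatch,
    activity: ActivityMatrix,
    folds,
    model_factory,
    schedule: TrainSchedule | None = None,
    seed: int = 0,
    finetune: bool = False,
) -> CVResult:
    """Rotate the test fold over all k folds; validation is the cyclically
    next fold, the remaining k-2 folds train. Reports per-output R^2 per
    fold and its mean and standard error across folds."""
    k = folds.k
    if k < 3:
        raise ValueError("rotating train/val/test needs at least 3 folds")
    ids = batch.region_ids
    if ids != activity.region_ids:
        raise ValueError("sequence and activity region ids are not aligned")
    r2s, coefs, fits = [], [], []
    for test_fold in range(k):
        val_fold = (test_fold + 1) % k
        te = folds.indices(ids, test_fold)
        va = folds.indices(ids, val_fold)
        if len(te) == 0 or len(va) == 0:
            raise ValueError(f"fold {test_fold} or {val_fold} has no regions")
        tr = np.array(
            [i for i, r in enumerate(ids)
             if folds.fold_of[r] not in (test_fold, val_fold)],
            dtype=int,
        )
        model = model_factory(seed=seed + test_fold)
        res = fit(
            model,
            (batch.onehot[tr], activity.values[tr]),
            (batch.onehot[va], activity.values[va]),
            schedule=schedule,
            seed=seed + test_fold,
            finetune=finetune,
        )
        pred = model.predict(batch.onehot[te])
        r2s.append(r_squared(pred, activity.values[te]))
        coefs.append(model.params["coef"].data.copy())
        fits.append(res)
    per_fold = np.stack(r2s)
    return CVResult(
        per_fold_r2=per_fold,
        mean_r2=per_fold.mean(axis=0),
        stderr_r2=per_fold.std(axis=0, ddof=1) / np.sqrt(k),
        per_fold_coefs=coefs,
        per_fold_history=fits,
    )
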