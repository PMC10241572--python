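"""Training schedule, early stopping, the epoch loop, and Grad-CAM.

The schedule mirrors the transfer-learning protocol of the motivating
study: Adam at a base learning rate of 1e-4, dropped to 1e-5 once the epoch
count exceeds 30, for at most 200 epochs with batch size 64, stopping when
the validation loss has not improved for 10 consecutive epochs. The weights
snapshot with the best validation loss is restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .nnet import TrainableClassifier
from .superpose import SuperpositionImage
from .io import POSITIVE_LABEL

__all__ = ["TrainConfig", "learning_rate_at", "early_stop_check", "train_classifier", "grad_cam"]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 64
    base_lr: float = 1e-4
    reduced_lr: float = 1e-5
    lr_switch_epoch: int = 30
    early_stop_patience: int = 10
    seed: int = 0
    resolution: int = 224

    def __post_init__(self) -> None:
        if self.reduced_lr >= self.base_lr:
            raise ValueError("reduced_lr must be < base_lr")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Base rate through the switch epoch (inclusive), reduced rate after."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return config.base_lr if epoch <= config.lr_switch_epoch else config.reduced_lr


def early_stop_check(val_loss_history: list[float], patience: int) -> bool:
    """True iff no strict improvement occurred in the last ``patience`` epochs.

    Equivalently: the minimum of the last ``patience`` entries is >= the
    minimum of all earlier entries (a strict improvement resets the counter).
    Histories no longer than ``patience`` never trigger.
    """
    if not val_loss_history:
        raise ValueError("history must be non-empty")
    if len(val_loss_history) <= patience:
        return False
    return min(val_loss_history[-patience:]) >= min(val_loss_history[:-patience])


def _stack(records: list[SuperpositionImage]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([r.pixels for r in records])
    labels = np.array([1 if r.label == POSITIVE_LABEL else 0 for r in records])
    return images, labels


def train_classifier(
    classifier: TrainableClassifier,
    train_records: list[SuperpositionImage],
    val_records: list[SuperpositionImage],
    config: TrainConfig,
) -> tuple[TrainableClassifier, pd.DataFrame]:
    """Run the epoch loop; return the best-validation-loss classifier and history.

    Each epoch shuffles the training records with a seed derived from
    ``config.seed`` and the epoch number, steps through mini-batches at the
    scheduled learning rate, then scores the validation loss. Training stops
    at ``max_epochs`` or when the patience rule fires, whichever is first;
    the weights from the best validation epoch are restored.
    """
    if not train_records:
        raise ValueError("empty training set")
    if not val_records:
        raise ValueError("empty validation set")
    x_train, y_train = _stack(train_records)
    x_val, y_val = _stack(val_records)

    history: list[dict] = []
    val_losses: list[float] = []
    best = {"loss": np.inf, "weights": classifier.get_weights()}
    for epoch in range(1, config.max_epochs + 1):
        lr = learning_rate_at(epoch, config)
        order = np.random.default_rng((config.seed, epoch)).permutation(len(x_train))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            batch_losses.append(classifier.fit_step(x_train[sel], y_train[sel], lr))
        val_loss = classifier.loss_on(x_val, y_val)
        val_losses.append(val_loss)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best["loss"]:
            best = {"loss": val_loss, "weights": classifier.get_weights()}
        if early_stop_check(val_losses, config.early_stop_patience):
            break
    classifier.set_weights(best["weights"])
    return classifier, pd.DataFrame(history)


def grad_cam(
    activations: np.ndarray, gradients: np.ndarray, target_size: tuple[int, int]
) -> np.ndarray:
    """Gradient-weighted class activation map.

    Channel weights are the global-average-pooled gradients,
    ``alpha_k = mean(dscore/dA^k)``; the map is
    ``ReLU(sum_k alpha_k A^k)``, bilinearly upsampled to ``target_size`` and
    normalized so its maximum is 1 (all-zero maps stay all-zero). Invariant
    to positive rescaling of the gradients.
    """
    activations = np.asarray(activations, dtype=np.float64)
    gradients = np.asarray(gradients, dtype=np.float64)
    if activations.shape != gradients.shape or activations.ndim != 3:
        raise ValueError("activations and gradients must both be (K, h, w)")
    alpha = gradients.mean(axis=(1, 2))
    cam = np.maximum(np.tensordot(alpha, activations, axes=1), 0.0)
    if cam.shape != tuple(target_size):
        cam = _sk_resize(
            cam, target_size, order=1, mode="edge", anti_aliasing=False, preserve_range=True
        )
        cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam
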