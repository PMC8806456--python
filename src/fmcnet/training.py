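"""Loss, momentum-SGD update rule, layer freezing and the training loop.

The update rule is implemented explicitly (not through a framework
optimizer) so it can be tested against a hand-unrolled recurrence:

    v_{i+1} = mu * v_i - lambda * eps * w_i - eps * <dL/dw>_{D_i}
    w_{i+1} = w_i + v_{i+1}

with momentum mu = 0.95, weight decay lambda = 1e-6 and learning rate
eps = 1e-4 as defaults (the transfer-learning settings); all three are
configurable.  The loss is mean binary cross-entropy over the batch.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .fmc_core import ArchitectureSpec, ModelGraph, build_architecture

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    pass


def logistic_loss(predictions: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; predictions clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(predictions, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"predictions and labels differ in shape: {p.shape} vs {y.shape}")
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean())


@dataclass
class OptimizerState:
    """Per-parameter velocities plus the momentum-SGD hyperparameters."""

    learning_rate: float = 1e-4
    momentum: float = 0.95
    weight_decay: float = 1e-6
    iteration: int = 0
    velocities: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


def momentum_step(state: OptimizerState, name: str, w: np.ndarray,
                  grad: np.ndarray) -> np.ndarray:
    """One momentum-SGD update of parameter ``name``; returns the new weights."""
    if w.shape != grad.shape:
        raise ValueError(f"weight/gradient shape mismatch for {name}: {w.shape} vs {grad.shape}")
    v = state.velocities.get(name)
    if v is None:
        v = np.zeros_like(w)
    elif v.shape != w.shape:
        raise ValueError(f"velocity shape mismatch for {name}")
    eps, mu, lam = state.learning_rate, state.momentum, state.weight_decay
    v_new = mu * v - lam * eps * w - eps * grad
    state.velocities[name] = v_new
    return w + v_new


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-4
    momentum: float = 0.95
    weight_decay: float = 1e-6
    freeze_first_n_conv: int = 3
    loss_eps: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.freeze_first_n_conv <= 5:
            raise ValueError("freeze_first_n_conv must lie in [0, 5]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "loss": self.train_loss,
            "train_acc": self.train_acc,
            "val_acc": self.val_acc,
        })

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def from_scratch_config(seed: int = 0, epochs: int = 30, **overrides) -> TrainConfig:
    """Training settings for models initialized randomly (no transfer).

    Freezing general early layers only makes sense when they carry
    transferred weights, so nothing is frozen here; the learning rate is
    higher than the transfer recipe's 1e-4 because optimization starts far
    from any optimum.
    """
    defaults = dict(epochs=epochs, batch_size=32, learning_rate=1e-3,
                    momentum=0.9, weight_decay=1e-6, freeze_first_n_conv=0,
                    seed=seed)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def apply_freeze(model: ModelGraph, n: int) -> dict[str, bool]:
    """Mark conv1..convN parameters non-trainable; return the mask."""
    if not 0 <= n <= 5:
        raise ValueError(f"freeze count must lie in [0, 5], got {n}")
    frozen_prefixes = tuple(f"conv{i}." for i in range(1, n + 1))
    mask = {}
    for name, p in model.params.items():
        trainable = not name.startswith(frozen_prefixes)
        p.requires_grad = trainable
        mask[name] = trainable
    return mask


def load_initial_weights(model: ModelGraph, weights_file=None,
                         rng: np.random.Generator | None = None) -> dict:
    """Initialize from a checkpoint where names/shapes match; report the rest.

    When a stored kernel is narrower than the model's along input channels
    (a skip connection widened the layer's input), the stored slice is
    copied and only the extra input-channel block keeps its scaled-Gaussian
    scheme initialization — transferred knowledge is preserved.
    """
    report = {"matched": [], "sliced": [], "unmatched": []}
    if weights_file is None:
        report["unmatched"] = sorted(model.params)
        return report
    try:
        with np.load(weights_file) as npz:
            state = {k: npz[k] for k in npz.files if k != "__spec__"}
    except (OSError, ValueError) as e:
        raise OSError(f"cannot read weights file {weights_file}: {e}") from e

    for name, p in model.params.items():
        if name not in state:
            report["unmatched"].append(name)
            continue
        src = state[name]
        if src.shape == p.data.shape:
            p.data = src.astype(model.dtype).copy()
            report["matched"].append(name)
        elif (src.ndim == 4 and p.data.ndim == 4 and src.shape[:2] == p.data.shape[:2]
              and src.shape[3] == p.data.shape[3] and src.shape[2] < p.data.shape[2]):
            p.data[:, :, : src.shape[2], :] = src.astype(model.dtype)
            report["sliced"].append(name)
        else:
            report["unmatched"].append(name)
    if not report["matched"] and not report["sliced"]:
        logger.warning("no checkpoint keys matched %s; keeping scheme initialization",
                       weights_file)
    return report


def _accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    if len(labels) == 0:
        return float("nan")
    return float(((probs >= 0.5).astype(int) == labels).mean())


def _predict_in_batches(model: ModelGraph, x: np.ndarray, batch_size: int) -> np.ndarray:
    out = [model.predict_proba(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out) if out else np.empty(0)


def train(model: ModelGraph, splits: dict[str, tuple[np.ndarray, np.ndarray]],
          config: TrainConfig, verbose: bool = False
          ) -> tuple[ModelGraph, TrainHistory]:
    """Train ``model`` on ``splits['train']``, tracking validation accuracy.

    The checkpoint with the best validation accuracy is restored into the
    model before returning (ties resolved toward the earliest epoch).
    """
    x_train, y_train = splits["train"]
    x_val, y_val = splits.get("val", (np.empty((0,) + x_train.shape[1:]), np.empty(0, dtype=int)))
    if len(x_train) == 0:
        raise ValueError("training split is empty")

    apply_freeze(model, config.freeze_first_n_conv)
    trainable = [(name, p) for name, p in model.params.items() if p.requires_grad]
    state = OptimizerState(learning_rate=config.learning_rate,
                           momentum=config.momentum,
                           weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best = (-np.inf, None)

    n = len(x_train)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            for _, p in trainable:
                p.zero_grad()
            logits, _ = model.forward(xb)
            loss = nn.pair_logit_bce(logits, yb, eps=config.loss_eps)
            probs = nn.pair_sigmoid(nn.Tensor(logits.data))
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingDivergedError(
                    f"non-finite loss {lval} at epoch {epoch + 1}")
            loss.backward()
            for name, p in trainable:
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                p.data = momentum_step(state, name, p.data, g)
            state.iteration += 1
            losses.append(lval * len(idx))
            correct += int(((probs.data >= 0.5).astype(int) == yb).sum())
        train_loss = float(np.sum(losses) / n)
        train_acc = correct / n
        val_probs = _predict_in_batches(model, x_val, config.batch_size)
        val_acc = _accuracy(val_probs, y_val)
        history.train_loss.append(train_loss)
        history.train_acc.append(train_acc)
        history.val_acc.append(val_acc)
        score = val_acc if np.isfinite(val_acc) else train_acc
        if score > best[0]:
            best = (score, model.state_dict())
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs} loss={train_loss:.4f} "
                  f"train_acc={train_acc:.3f} val_acc={val_acc:.3f}", file=sys.stderr)

    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: ModelGraph, path, config: TrainConfig | None = None):
    """Write named parameters plus the architecture spec to an .npz container."""
    payload = {k: v for k, v in model.state_dict().items()}
    meta = {"spec": model.spec.to_dict()}
    if config is not None:
        meta["train_config"] = config.to_dict()
    payload["__spec__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> ModelGraph:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    try:
        with np.load(path) as npz:
            if "__spec__" not in npz.files:
                raise ValueError("missing architecture metadata")
            meta = json.loads(bytes(npz["__spec__"]).decode())
            state = {k: npz[k] for k in npz.files if k != "__spec__"}
    except (OSError, ValueError, json.JSONDecodeError) as e:
        raise OSError(f"cannot load checkpoint {path}: {e}") from e
    spec = ArchitectureSpec.from_dict(meta["spec"])
    model = build_architecture(spec)
    model.load_state_dict(state)
    return model


def parameter_checksums(model: ModelGraph) -> dict[str, float]:
    """Cheap content fingerprints used to verify frozen-layer conservation."""
    return {k: float(np.sum(v.astype(np.float64) * np.arange(1, v.size + 1).reshape(v.shape)))
            for k, v in ((k, v) for k, v in model.state_dict().items())}


def clone_model(model: ModelGraph) -> ModelGraph:
    clone = build_architecture(model.spec, rng=np.random.default_rng(0), dtype=model.dtype)
    clone.load_state_dict(copy.deepcopy(model.state_dict()))
    return clone
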