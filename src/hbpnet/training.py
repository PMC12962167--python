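"""Training: the clipped cross-entropy objective and the optimization loop.

The supervision target is a per-frame heartbeat probability in [0, 1], so the
natural objective is binary cross-entropy between the label curve ``y`` and
the prediction ``y_hat``.  Two refinements matter in practice:

* the per-sample loss is *bounded*: log arguments are floored at
  ``exp(-clip)`` so a single maximally wrong frame contributes exactly
  ``clip`` (default 10) instead of diverging, while gradients elsewhere in
  the batch are untouched;
* the constant self-entropy of the label is subtracted, so the reported loss
  is zero exactly when ``y == y_hat``.  The subtracted term does not depend
  on the prediction and therefore does not affect gradients — the optimizer
  sees plain clipped BCE.

Alternative objectives used in ablations (MSE, negative Pearson, a 50/50
hybrid) are provided under the same interface.  Optimization follows AdamW
with a 5-epoch linear warm-up into a cosine-annealed learning rate.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.model import HbpNet

__all__ = ["TrainConfig", "TrainLog", "bce_loss", "bce_loss_grad", "alt_loss",
           "learning_rate", "AdamW", "train"]


@dataclass
class TrainConfig:
    """Optimization protocol (defaults follow the full-scale recipe)."""

    optimizer: str = "adamw"
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    warmup_epochs: int = 5
    epochs: int = 30
    batch_size: int = 8
    loss: str = "bce"            # bce | mse | neg_pearson | hybrid
    loss_clip: float = 10.0
    hybrid_weight: float = 0.5   # weight of BCE in the hybrid loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.loss_clip <= 0:
            raise ValueError("learning rate and loss clip must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")
        if self.loss not in ("bce", "mse", "neg_pearson", "hybrid"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainLog:
    """Per-epoch record of the run, serializable as CSV."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    seconds: list[float] = field(default_factory=list)

    def append(self, epoch, train_loss, val_loss, lr, seconds) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(float(train_loss))
        self.val_loss.append(float(val_loss))
        self.lr.append(float(lr))
        self.seconds.append(float(seconds))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(epoch=self.epochs, train_loss=self.train_loss,
                                 val_loss=self.val_loss, lr=self.lr,
                                 seconds=self.seconds))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def _check_pair(y: np.ndarray, y_hat: np.ndarray, probabilities: bool = True):
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty inputs")
    if probabilities:
        for name, v in (("y", y), ("y_hat", y_hat)):
            if v.min() < 0 or v.max() > 1:
                raise ValueError(f"{name} values must lie in [0, 1]")
    return y, y_hat


def bce_loss(y, y_hat, clip: float = 10.0) -> float:
    """Clipped binary cross-entropy, zero iff ``y == y_hat``.

    Per element: ``-[y log y_hat + (1-y) log(1-y_hat)]`` minus the label's
    own entropy, with every log argument floored at ``exp(-clip)``.  The
    result is the mean over elements; it is 0 exactly at ``y == y_hat``,
    bounded above by ``clip``, and equals ``clip`` for a single maximally
    wrong sample (y=1, y_hat=0 or vice versa).
    """
    y, y_hat = _check_pair(y, y_hat)
    floor = np.exp(-clip)
    cross = -(y * np.log(np.maximum(y_hat, floor))
              + (1 - y) * np.log(np.maximum(1 - y_hat, floor)))
    self_ent = -(y * np.log(np.maximum(y, floor))
                 + (1 - y) * np.log(np.maximum(1 - y, floor)))
    return float(np.mean(np.minimum(cross - self_ent, clip)))


def bce_loss_grad(y: np.ndarray, y_hat: np.ndarray,
                  clip: float = 10.0) -> np.ndarray:
    """d(bce_loss)/d(y_hat), elementwise over arrays of matching shape.

    The label-entropy term is constant and contributes nothing; flooring
    makes the gradient vanish where a log argument is saturated.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    floor = np.exp(-clip)
    g = np.zeros_like(y_hat)
    live1 = y_hat > floor
    g[live1] -= (y[live1] / np.maximum(y_hat[live1], floor))
    live0 = (1 - y_hat) > floor
    g[live0] += ((1 - y[live0]) / np.maximum(1 - y_hat[live0], floor))
    return g / y.size


def alt_loss(name: str, y, y_hat, clip: float = 10.0,
             hybrid_weight: float = 0.5) -> float:
    """Ablation objectives: ``mse``, ``neg_pearson``, or ``hybrid``."""
    if name == "mse":
        y, y_hat = _check_pair(y, y_hat, probabilities=False)
        return float(np.mean((y - y_hat) ** 2))
    if name == "neg_pearson":
        y, y_hat = _check_pair(y, y_hat, probabilities=False)
        if np.std(y) == 0 or np.std(y_hat) == 0:
            raise ValueError("Pearson correlation undefined for constant input")
        r = np.corrcoef(y, y_hat)[0, 1]
        return float(1.0 - r)
    if name == "hybrid":
        return hybrid_weight * bce_loss(y, y_hat, clip) \
            + (1 - hybrid_weight) * alt_loss("neg_pearson", y, y_hat)
    if name == "bce":
        return bce_loss(y, y_hat, clip)
    raise ValueError(f"unknown loss {name!r}")


def _loss_and_grad(name: str, y: np.ndarray, y_hat: np.ndarray,
                   clip: float, hybrid_weight: float):
    """Batched loss value and gradient for the training loop."""
    if name == "bce":
        return (bce_loss(y, y_hat, clip),
                bce_loss_grad(y, y_hat, clip))
    if name == "mse":
        return (float(np.mean((y - y_hat) ** 2)),
                2.0 * (y_hat - y) / y.size)
    if name == "neg_pearson":
        yc = y - y.mean()
        pc = y_hat - y_hat.mean()
        sy, sp = np.sqrt((yc ** 2).sum()), np.sqrt((pc ** 2).sum())
        if sy == 0 or sp == 0:
            raise ValueError("Pearson correlation undefined for constant input")
        r = float((yc * pc).sum() / (sy * sp))
        grad = -(yc / (sy * sp) - r * pc / (sp ** 2))
        return 1.0 - r, grad
    if name == "hybrid":
        l1, g1 = _loss_and_grad("bce", y, y_hat, clip, hybrid_weight)
        l2, g2 = _loss_and_grad("neg_pearson", y, y_hat, clip, hybrid_weight)
        w = hybrid_weight
        return w * l1 + (1 - w) * l2, w * g1 + (1 - w) * g2
    raise ValueError(f"unknown loss {name!r}")


# --------------------------------------------------------------------------
# optimizer and schedule
# --------------------------------------------------------------------------

def learning_rate(config: TrainConfig, epoch: float) -> float:
    """LR at (fractional) epoch: linear warm-up, then cosine decay to ~0.

    ``learning_rate(cfg, 0) == 0`` and ``learning_rate(cfg, warmup) == base``;
    from there the rate follows half a cosine, reaching 0 at ``epochs``.
    """
    base, wu, E = config.learning_rate, config.warmup_epochs, config.epochs
    if epoch < wu:
        return base * epoch / wu
    span = max(E - wu, 1)
    return 0.5 * base * (1.0 + np.cos(np.pi * (epoch - wu) / span))


class AdamW:
    """AdamW with decoupled weight decay over a model's parameter list."""

    def __init__(self, params, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value -= lr * (update + self.weight_decay * p.value)


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _stack(clips) -> np.ndarray:
    return np.stack([np.asarray(c.data if hasattr(c, "data") else c,
                                dtype=np.float32) for c in clips])


def _labels_array(labels) -> np.ndarray:
    return np.stack([np.asarray(l.values if hasattr(l, "values") else l,
                                dtype=np.float64) for l in labels])


def evaluate_loss(model: HbpNet, clips, labels, config: TrainConfig) -> float:
    """Mean loss over a clip set in evaluation mode."""
    x = _stack(clips)
    y = _labels_array(labels)
    total = 0.0
    for i in range(0, len(x), config.batch_size):
        xb, yb = x[i:i + config.batch_size], y[i:i + config.batch_size]
        pred, _ = model.forward(xb, training=False)
        loss, _ = _loss_and_grad(config.loss, yb, pred.astype(np.float64),
                                 config.loss_clip, config.hybrid_weight)
        total += loss * len(xb)
    return total / len(x)


def recalibrate_bn(model: HbpNet, clips, batch_size: int = 8) -> None:
    """Refresh batch-norm running statistics over a clip set.

    Momentum-averaged running statistics lag the final weights after a short
    training run; this pass recomputes each layer's running mean/variance as
    the exact average of its batch statistics over the given clips (forward
    passes run in training mode, so deeper layers see the same normalization
    behavior they saw during optimization).
    """
    bns = model.enc_bns + model.dec_bns + model.head_bns
    for b in bns:
        b._collect = [np.zeros_like(b.running_mean),
                      np.zeros_like(b.running_var), 0]
    x = _stack(clips)
    for i in range(0, len(x), batch_size):
        model.forward(x[i:i + batch_size], training=True)
    for b in bns:
        s_mean, s_var, count = b._collect
        if count:
            b.running_mean[...] = s_mean / count
            b.running_var[...] = s_var / count
        b._collect = None
    model._relu_cache = {}


def train(model: HbpNet, train_clips, train_labels, val_clips, val_labels,
          config: TrainConfig):
    """Optimize the model; returns ``(best_state, final_state, log)``.

    The best state is the parameter snapshot with the lowest validation
    loss.  All stochastic elements (shuffling) draw from ``config.seed``;
    runs are reproducible given identical thread settings.
    """
    if len(train_clips) == 0:
        raise ValueError("empty training set")
    for c, l in zip(list(train_clips) + list(val_clips),
                    list(train_labels) + list(val_labels)):
        n_frames = (c.data.shape[1] if hasattr(c, "data")
                    else np.asarray(c).shape[1])
        n_lab = len(l.values) if hasattr(l, "values") else len(l)
        if n_frames != n_lab:
            raise ValueError(
                f"label length {n_lab} does not match clip length {n_frames}")

    x = _stack(train_clips)
    y = _labels_array(train_labels)
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.params(), config.betas, weight_decay=config.weight_decay)
    log = TrainLog()
    best_val = np.inf
    best_state = model.state_dict()
    n = len(x)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))

    for epoch in range(config.epochs):
        t_start = time.perf_counter()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(steps_per_epoch):
            sel = order[s * config.batch_size:(s + 1) * config.batch_size]
            if sel.size == 0:
                continue
            xb, yb = x[sel], y[sel]
            lr = learning_rate(config, epoch + s / steps_per_epoch)
            model.zero_grad()
            pred, _ = model.forward(xb, training=True)
            loss, grad = _loss_and_grad(config.loss, yb,
                                        pred.astype(np.float64),
                                        config.loss_clip, config.hybrid_weight)
            model.backward(grad.astype(np.float32))
            opt.step(lr)
            epoch_loss += loss * len(sel)
        epoch_loss /= n
        # precise-BN refresh so evaluation-mode behavior tracks the weights
        recalibrate_bn(model, train_clips, config.batch_size)
        val_loss = (evaluate_loss(model, val_clips, val_labels, config)
                    if len(val_clips) else epoch_loss)
        log.append(epoch, epoch_loss, val_loss,
                   learning_rate(config, epoch), time.perf_counter() - t_start)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
    final_state = model.state_dict()
    model.load_state_dict(best_state)
    return best_state, final_state, log
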