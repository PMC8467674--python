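"""Training loop: pixel-sum cross-entropy, Adam, he_normal initialization.

Defaults follow the published protocol: Adam with learning rate 1e-4,
beta1 = 0.9, beta2 = 0.999, batch size 4, 120 epochs, he_normal weight
initialization. The per-image loss is the SUM of per-pixel binary
cross-entropy terms averaged over the batch; a ``loss_reduction="mean"``
switch divides by the pixel count instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architectures import UNetModel
from .nn import Adam, batch_loss, batch_loss_grad, init_weights
from .nn.losses import CLAMP_EPS, cross_entropy  # re-exported  # noqa: F401


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 4
    epochs: int = 120
    init_scheme: str = "he_normal"
    loss_reduction: str = "sum"
    clamp_eps: float = CLAMP_EPS
    shuffle: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("decay rates must lie in [0, 1)")


@dataclass
class TrainResult:
    history: list[float] = field(default_factory=list)  # one loss per epoch
    steps: int = 0


def _stack(data):
    """list of (image, mask) -> (N,1,H,W) inputs and (N,1,H,W) labels."""
    xs = np.stack([np.asarray(img, dtype=np.float64) for img, _ in data])
    ys = np.stack([np.asarray(mask, dtype=np.float64) for _, mask in data])
    return xs[:, None], ys[:, None]


def train(model: UNetModel, data, cfg: TrainConfig | None = None,
          initialize: bool = True) -> TrainResult:
    """Train ``model`` on (image, mask) pairs; returns per-epoch loss history.

    Fully deterministic under ``cfg.seed`` (initialization and shuffling
    both derive from it).
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    if not data:
        raise ValueError("training data must be non-empty")
    if initialize:
        init_weights(model, cfg.init_scheme, cfg.seed)
    xs, ys = _stack(data)
    n = xs.shape[0]
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1,
               beta2=cfg.beta2, eps=cfg.adam_eps)
    model.train()
    result = TrainResult()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = xs[idx], ys[idx]
            pred = model(xb)
            loss = batch_loss(yb, pred, cfg.clamp_eps, cfg.loss_reduction)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {result.steps}")
            opt.zero_grad()
            model.backward(batch_loss_grad(yb, pred, cfg.clamp_eps,
                                           cfg.loss_reduction))
            opt.step()
            epoch_losses.append(loss)
            result.steps += 1
        result.history.append(float(np.mean(epoch_losses)))
    model.eval()
    return result
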