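"""Mask-respecting mini-batch training: cross-entropy, Adam, noise schedules.

Training never changes the sparsity structure: gradients at masked positions
are zeroed before every optimizer step, so masked weights stay exactly 0 and
``sparsity(state)`` is invariant through any ``train`` call.  Internal
activation noise during training follows a schedule — either constant or a
linear taper that reaches ``sigma_end`` exactly at the final epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ModulationConfig, NetworkState, backward, forward

_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class NoiseSchedule:
    kind: str = "constant"  # "constant" | "linear_taper"
    sigma_start: float = 0.0
    sigma_end: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_taper"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.sigma_start < 0 or self.sigma_end < 0:
            raise ValueError("schedule sigmas must be >= 0")
        if self.kind == "constant" and self.sigma_start != self.sigma_end:
            raise ValueError("constant schedule requires sigma_start == sigma_end")

    def sigma_at(self, epoch: int, n_epochs: int) -> float:
        """Noise level for ``epoch`` in [0, n_epochs)."""
        if self.kind == "constant" or n_epochs == 1:
            return self.sigma_start
        frac = epoch / (n_epochs - 1)  # hits sigma_end exactly at the last epoch
        return self.sigma_start + (self.sigma_end - self.sigma_start) * frac


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 128
    noise_schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, -log p(true class), floored before log."""
    p = probabilities[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(p, _LOG_FLOOR)).mean())


class _Adam:
    """Adam with the conventional defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.v = [np.zeros(s, dtype=np.float32) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train(
    state: NetworkState,
    data,
    config: TrainConfig,
    rng: np.random.Generator,
    train_modulation: ModulationConfig | None = None,
) -> tuple[NetworkState, list[dict]]:
    """Train in place on the bundle's train split; return (state, loss history).

    ``train_modulation`` lets a treatment impose damping / a bounded
    activation during its tuning epochs (the schedule still controls the
    noise sigma).  History rows carry epoch, mean loss, and the sigma used.
    """
    X, y = data.split("train")
    if len(X) == 0:
        raise ValueError("training split is empty")

    opt = _Adam([w.shape for w in state.weights] + [b.shape for b in state.biases],
                config.learning_rate)
    n = len(X)
    history = []
    for epoch in range(config.epochs):
        sigma = config.noise_schedule.sigma_at(epoch, config.epochs)
        base = train_modulation or state.modulation
        if base is not None:
            mod = ModulationConfig(
                internal_noise_sigma=sigma,
                damping_factor=base.damping_factor,
                activation_override=base.activation_override,
                enabled=base.enabled,
            )
        else:
            mod = ModulationConfig(internal_noise_sigma=sigma)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs, cache = forward(state, X[idx], mod=mod,
                                   rng=rng if sigma > 0 else None,
                                   return_cache=True)
            losses.append(cross_entropy(probs, y[idx]) * len(idx))
            gw, gb = backward(state, cache, probs, y[idx])
            for g, m in zip(gw, state.masks):
                g *= m  # masked weights never move
            opt.step(state.weights + state.biases, gw + gb)
            for w, m in zip(state.weights, state.masks):
                w *= m  # guard against numerical drift off exact zero
        history.append({"epoch": epoch, "mean_loss": sum(losses) / n, "sigma": sigma})
    return state, history


def history_to_csv(history: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)
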