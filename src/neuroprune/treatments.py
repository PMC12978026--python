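"""The three antidepressant-analogue protocols.

All three start from byte-identical copies of the same pruned checkpoint:

* **Ketamine-like synaptogenesis** — score every pruned ("ghost") connection
  by its accumulated gradient magnitude over noise-free mini-batches, regrow
  the top half per layer with small random weights, then consolidate briefly
  with the new mask locked.  The only protocol that changes the structure.
* **SSRI-like refinement** — structure untouched; long, slow training while
  internal activation noise tapers linearly from 0.5 to 0.
* **Neurosteroid-like tonic inhibition** — structure untouched; a 0.7
  post-activation gain and bounded (tanh) activations are imposed, with a
  few tuning epochs so the circuit settles under the drug.  The modulation
  is state-dependent: evaluation may switch it off ("drug withdrawn"),
  which restores both the unit gain and the rectifier activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ModulationConfig, NetworkState, backward, forward, sparsity
from .training import NoiseSchedule, TrainConfig, train


@dataclass(frozen=True)
class KetamineConfig:
    regrow_fraction_of_pruned: float = 0.5
    grad_batches: int = 30
    batch_size: int = 128
    init_sigma: float = 0.03
    consolidation_epochs: int = 15
    consolidation_lr: float = 5e-4

    def __post_init__(self) -> None:
        if not (0.0 <= self.regrow_fraction_of_pruned <= 1.0):
            raise ValueError("regrow_fraction_of_pruned must be in [0, 1]")
        if self.grad_batches < 1:
            raise ValueError("grad_batches must be >= 1")


@dataclass(frozen=True)
class SsriConfig:
    epochs: int = 100
    learning_rate: float = 1e-5
    noise_schedule: NoiseSchedule = field(
        default_factory=lambda: NoiseSchedule("linear_taper", 0.5, 0.0))

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass(frozen=True)
class NeurosteroidConfig:
    damping_factor: float = 0.7
    activation_override: str = "bounded"
    tuning_epochs: int = 10
    tuning_lr: float = 5e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.damping_factor <= 1.0):
            raise ValueError("damping_factor must be in (0, 1]")


def accumulate_ghost_gradients(
    state: NetworkState,
    data,
    n_batches: int = 30,
    rng: np.random.Generator | None = None,
    batch_size: int = 128,
) -> list[np.ndarray]:
    """Accumulated |gradient| per masked weight entry over noise-free batches.

    The forward pass uses the masked weights as-is; the backward pass
    produces gradients for every entry, including those masked to zero.
    Per layer, returns sum_b |dL/dw| at masked positions and 0 at unmasked
    ones (live entries are not regrowth candidates).
    """
    if all((m == 1).all() for m in state.masks):
        raise ValueError("ghost gradients need a sparse state; network is dense")
    if rng is None:
        rng = np.random.default_rng(0)
    X, y = data.split("train")
    order = rng.permutation(len(X))
    scores = [np.zeros_like(w) for w in state.weights]
    for b in range(n_batches):
        lo = (b * batch_size) % len(X)
        idx = order[lo:lo + batch_size]
        if len(idx) == 0:
            idx = order[:batch_size]
        probs, cache = forward(state, X[idx], mod=None, return_cache=True)
        gw, _ = backward(state, cache, probs, y[idx])
        for s, g in zip(scores, gw):
            s += np.abs(g)
    for s, m in zip(scores, state.masks):
        s *= (1.0 - m)  # only ghosts are candidates
    return scores


def ketamine_protocol(
    state: NetworkState,
    data,
    config: KetamineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Gradient-guided regrowth of half the pruned connections + consolidation."""
    config = config or KetamineConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    out = state.copy()
    if config.regrow_fraction_of_pruned > 0:
        scores = accumulate_ghost_gradients(
            out, data, n_batches=config.grad_batches, rng=rng,
            batch_size=config.batch_size)
        for w, m, s in zip(out.weights, out.masks, scores):
            ghosts = np.flatnonzero(m.ravel() == 0)
            k = int(np.floor(config.regrow_fraction_of_pruned * len(ghosts)))
            if k == 0:
                continue
            ghost_scores = s.ravel()[ghosts]
            # top-k by score, ties resolved in row-major order
            top = ghosts[np.argsort(-ghost_scores, kind="stable")[:k]]
            m.ravel()[top] = 1.0
            w.ravel()[top] = rng.normal(0.0, config.init_sigma, size=k).astype(np.float32)
    if config.consolidation_epochs > 0:
        tc = TrainConfig(epochs=config.consolidation_epochs,
                         learning_rate=config.consolidation_lr)
        train(out, data, tc, rng)
    return out


def ssri_protocol(
    state: NetworkState,
    data,
    config: SsriConfig | None = None,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Slow drift of the surviving weights under a tapering noise schedule."""
    config = config or SsriConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    out = state.copy()
    tc = TrainConfig(epochs=config.epochs, learning_rate=config.learning_rate,
                     noise_schedule=config.noise_schedule)
    train(out, data, tc, rng)
    assert sparsity(out) == sparsity(state)
    return out


def neurosteroid_protocol(
    state: NetworkState,
    data,
    config: NeurosteroidConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[NetworkState, ModulationConfig]:
    """Impose tonic inhibition (gain 0.7, bounded activation), tune, return both.

    The returned state carries the modulation so later forward passes apply
    it by default; evaluation can toggle ``enabled`` to model withdrawal.
    """
    config = config or NeurosteroidConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    out = state.copy()
    mod = ModulationConfig(damping_factor=config.damping_factor,
                           activation_override=config.activation_override,
                           enabled=True)
    if config.tuning_epochs > 0:
        tc = TrainConfig(epochs=config.tuning_epochs, learning_rate=config.tuning_lr)
        train(out, data, tc, rng, train_modulation=mod)
    out.modulation = mod
    assert sparsity(out) == sparsity(state)
    return out, mod
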