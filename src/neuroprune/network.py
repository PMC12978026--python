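"""The sparse feed-forward circuit with noise injection and gain modulation.

A NetworkState holds four weight matrices (2->512->512->256->4), their
biases, and congruent binary masks.  Everywhere the network is used the
effective weight is ``weights * masks``; biases are never masked.  Two
neuromodulatory hooks act on every hidden layer, after its nonlinearity and
in this order: additive Gaussian "internal activation" noise (stress
analogue), then a multiplicative damping factor (tonic-inhibition analogue).
The damping scales the whole post-synaptic signal, noise included — tonic
inhibition damps overall firing, which is exactly how it buffers stress.
The output layer is plain linear + softmax and receives neither.

The hidden nonlinearity is either the rectifier (ReLU) or a bounded
saturating unit (tanh); a ModulationConfig may override it while the drug
analogue is "present".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._streams import substream

CANONICAL_LAYER_SIZES = (2, 512, 512, 256, 4)

_ACTIVATIONS = ("rectifier", "bounded")


@dataclass
class ModulationConfig:
    """Evaluation/treatment-time modulation: the "drug present/absent" switch.

    ``enabled`` toggles the drug analogue (damping and activation override);
    internal activation noise is a stressor, not a drug, and applies whenever
    ``internal_noise_sigma > 0`` regardless of ``enabled``.
    """

    internal_noise_sigma: float = 0.0
    damping_factor: float = 1.0
    activation_override: str | None = None
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.internal_noise_sigma < 0:
            raise ValueError("internal_noise_sigma must be >= 0")
        if not (0.0 < self.damping_factor <= 1.0):
            raise ValueError("damping_factor must be in (0, 1]")
        if self.activation_override is not None and self.activation_override not in _ACTIVATIONS:
            raise ValueError(f"activation_override must be one of {_ACTIVATIONS}")


@dataclass
class NetworkState:
    """Weights, biases, binary masks, and the resting activation kind."""

    weights: list[np.ndarray]  # each (n_out, n_in), float32
    biases: list[np.ndarray]   # each (n_out,), float32
    masks: list[np.ndarray]    # 0/1 float32, congruent with weights
    activation: str = "rectifier"
    # Persistent drug modulation attached by a treatment (neurosteroid).
    modulation: ModulationConfig | None = None

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.biases) == len(self.masks)):
            raise ValueError("weights, biases, masks must have equal layer counts")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        for w, b, m in zip(self.weights, self.biases, self.masks):
            if w.shape != m.shape:
                raise ValueError("mask shape must match weight shape")
            if b.shape != (w.shape[0],):
                raise ValueError("bias shape must match weight rows")
            vals = np.unique(m)
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("masks must contain only 0/1 entries")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(w.shape[0] for w in self.weights)

    def copy(self) -> "NetworkState":
        return NetworkState(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            masks=[m.copy() for m in self.masks],
            activation=self.activation,
            modulation=replace(self.modulation) if self.modulation else None,
        )

    def effective_weights(self) -> list[np.ndarray]:
        return [w * m for w, m in zip(self.weights, self.masks)]

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for w, b, m in zip(self.weights, self.biases, self.masks):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
            h.update(np.ascontiguousarray(m).tobytes())
        h.update(self.activation.encode())
        return h.hexdigest()


def init_network(
    layer_sizes: tuple[int, ...] = CANONICAL_LAYER_SIZES,
    seed: int = 42,
    activation: str = "rectifier",
) -> NetworkState:
    """Random dense network, Kaiming-uniform init: W, b ~ U(+-1/sqrt(fan_in))."""
    rng = substream(seed, "init")
    weights, biases, masks = [], [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-bound, bound, size=(n_out, n_in)).astype(np.float32))
        biases.append(rng.uniform(-bound, bound, size=n_out).astype(np.float32))
        masks.append(np.ones((n_out, n_in), dtype=np.float32))
    return NetworkState(weights, biases, masks, activation=activation)


def param_count(state: NetworkState) -> int:
    """Total trainable parameters (weights + biases), mask-independent."""
    return int(sum(w.size for w in state.weights) + sum(b.size for b in state.biases))


def sparsity(state: NetworkState) -> float:
    """Overall fraction of weight entries masked to zero (biases excluded)."""
    masked = sum(int((m == 0).sum()) for m in state.masks)
    total = sum(m.size for m in state.masks)
    return masked / total


def _apply_activation(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "rectifier":
        return np.maximum(z, 0.0)
    return np.tanh(z)


def _activation_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "rectifier":
        return (z > 0).astype(z.dtype)
    t = np.tanh(z)
    return 1.0 - t * t


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _resolve_modulation(
    state: NetworkState, mod: ModulationConfig | None
) -> tuple[float, float, str]:
    """Effective (sigma, gamma, activation) for a forward pass."""
    if mod is None:
        mod = state.modulation
    if mod is None:
        return 0.0, 1.0, state.activation
    sigma = mod.internal_noise_sigma
    if not mod.enabled:
        return sigma, 1.0, state.activation
    act = mod.activation_override or state.activation
    return sigma, mod.damping_factor, act


def forward(
    state: NetworkState,
    inputs: np.ndarray,
    mod: ModulationConfig | None = None,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Run the circuit, returning class-probability rows (and a backprop cache).

    Per hidden layer: masked linear map -> nonlinearity -> noise -> damping.
    Output layer: masked linear map -> softmax.
    """
    dtype = state.weights[0].dtype  # float32 in production; oracles may use float64
    X = np.asarray(inputs, dtype=dtype)
    if X.ndim != 2 or X.shape[1] != state.weights[0].shape[1]:
        raise ValueError(
            f"inputs must be (n, {state.weights[0].shape[1]}), got {X.shape}")
    sigma, gamma, act = _resolve_modulation(state, mod)
    if sigma > 0 and rng is None:
        raise ValueError("an rng is required when internal_noise_sigma > 0")

    eff = state.effective_weights()
    a = X
    pre, post = [], [X]
    for layer in range(state.n_layers - 1):
        z = a @ eff[layer].T + state.biases[layer]
        h = _apply_activation(z, act)
        if sigma > 0:
            h = h + rng.normal(0.0, sigma, size=h.shape).astype(dtype)
        if gamma != 1.0:
            h = h * gamma
        pre.append(z)
        post.append(h)
        a = h
    logits = a @ eff[-1].T + state.biases[-1]
    probs = softmax(logits.astype(np.float64)).astype(dtype)
    if return_cache:
        return probs, {"pre": pre, "post": post, "gamma": gamma, "act": act, "eff": eff}
    return probs


def backward(
    state: NetworkState, cache: dict, probs: np.ndarray, labels: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Dense gradients of mean cross-entropy w.r.t. every weight/bias entry.

    Gradients are computed for ALL entries, masked or not — masked entries
    simply sit at value zero.  Callers that train must zero masked gradients
    themselves; the ghost-gradient scorer wants the full field.
    """
    n = probs.shape[0]
    eff, gamma, act = cache["eff"], cache["gamma"], cache["act"]
    pre, post = cache["pre"], cache["post"]

    delta = probs.astype(post[-1].dtype).copy()
    delta[np.arange(n), labels] -= 1.0
    delta /= n

    grads_w = [None] * state.n_layers
    grads_b = [None] * state.n_layers
    grads_w[-1] = delta.T @ post[-1]
    grads_b[-1] = delta.sum(axis=0)
    upstream = delta @ eff[-1]
    for layer in range(state.n_layers - 2, -1, -1):
        # post-activation hooks: noise adds, damping scales
        if gamma != 1.0:
            upstream = upstream * gamma
        dz = upstream * _activation_grad(pre[layer], act)
        grads_w[layer] = dz.T @ post[layer]
        grads_b[layer] = dz.sum(axis=0)
        if layer > 0:
            upstream = dz @ eff[layer]
    return grads_w, grads_b


def save_checkpoint(state: NetworkState, path) -> None:
    """Serialize a NetworkState to a single .npz checkpoint."""
    payload = {"format_version": np.array(1), "activation": np.array(state.activation)}
    for i, (w, b, m) in enumerate(zip(state.weights, state.biases, state.masks)):
        payload[f"w{i}"] = w
        payload[f"b{i}"] = b
        payload[f"m{i}"] = m.astype(np.uint8)
    mod = state.modulation
    if mod is not None:
        payload["mod"] = np.array([mod.internal_noise_sigma, mod.damping_factor,
                                   float(mod.enabled)])
        payload["mod_act"] = np.array(mod.activation_override or "")
    np.savez(path, **payload)


def load_checkpoint(path) -> NetworkState:
    with np.load(path, allow_pickle=False) as data:
        n = sum(1 for k in data.files if k.startswith("w"))
        weights = [data[f"w{i}"].astype(np.float32) for i in range(n)]
        biases = [data[f"b{i}"].astype(np.float32) for i in range(n)]
        masks = [data[f"m{i}"].astype(np.float32) for i in range(n)]
        activation = str(data["activation"])
        modulation = None
        if "mod" in data.files:
            sig, gam, en = data["mod"]
            override = str(data["mod_act"]) or None
            modulation = ModulationConfig(
                internal_noise_sigma=float(sig), damping_factor=float(gam),
                activation_override=override, enabled=bool(en))
    return NetworkState(weights, biases, masks, activation=activation,
                        modulation=modulation)
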