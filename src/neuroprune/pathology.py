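"""Magnitude-based synaptic elimination: the depressive insult and relapse.

The "depressed" circuit is produced by removing the smallest 95% of weights
(by absolute value) within each layer.  The relapse challenge repeats the
same operation on 40% of whatever survived treatment.  Masked weights are
set to exactly zero and never resurrected by further pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkState, sparsity


@dataclass(frozen=True)
class PruneEvent:
    """Record of one pruning wave (for run reports)."""

    fraction: float
    scope: str  # "of_all_weights" | "of_remaining_weights"
    per_layer: bool
    removed_counts: tuple[int, ...]
    resulting_sparsity: float

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "scope": self.scope,
            "per_layer": self.per_layer,
            "removed_counts": list(self.removed_counts),
            "resulting_sparsity": self.resulting_sparsity,
        }


def prune_magnitude(
    state: NetworkState, fraction: float, per_layer: bool = True
) -> tuple[NetworkState, PruneEvent]:
    """Mask the smallest ``fraction`` of currently unmasked weights per layer.

    Removal count per layer is floor(fraction * n_unmasked).  Ties in |w|
    break by row-major index order (deterministic; measure-zero for
    continuous weights).  Returns a modified copy; the input is untouched.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if not per_layer:
        raise NotImplementedError("only per-layer pruning is defined")

    out = state.copy()
    removed = []
    for w, m in zip(out.weights, out.masks):
        flat_m = m.ravel()
        alive = np.flatnonzero(flat_m)
        k = int(np.floor(fraction * len(alive)))
        removed.append(k)
        if k == 0:
            continue
        mags = np.abs(w.ravel()[alive])
        # stable sort: equal magnitudes drop in row-major order
        drop = alive[np.argsort(mags, kind="stable")[:k]]
        flat_m[drop] = 0.0
        w.ravel()[drop] = 0.0
    event = PruneEvent(
        fraction=fraction,
        scope="of_all_weights" if sparsity(state) == 0 else "of_remaining_weights",
        per_layer=True,
        removed_counts=tuple(removed),
        resulting_sparsity=sparsity(out),
    )
    return out, event


def relapse_prune(
    state: NetworkState, fraction: float = 0.40
) -> tuple[NetworkState, PruneEvent]:
    """The relapse challenge: prune ``fraction`` of the surviving weights.

    Identical rule to the initial insult, applied to whatever is unmasked
    now — including any connections a treatment regrew.
    """
    return prune_magnitude(state, fraction, per_layer=True)
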