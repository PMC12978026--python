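"""Hierarchical, named random streams derived from one master seed.

Every source of randomness in a run (data sampling, weight init, training
shuffles and noise, ghost-gradient batches, regrowth init, evaluation noise)
draws from its own child stream of the master seed, so that e.g. adding an
extra evaluation never perturbs training reproducibility.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: stream name -> spawn key. Append-only; never renumber.
_STREAMS = {
    "data": 0,
    "init": 1,
    "train": 2,
    "ghost": 3,
    "regrow": 4,
    "noise-eval": 5,
    "treat-ketamine": 6,
    "treat-ssri": 7,
    "treat-neurosteroid": 8,
    "sweep": 9,
}


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return the named child generator of ``master_seed``.

    ``index`` selects independent replicates within one named stream
    (e.g. repeat evaluations, grid points of a sweep).
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown stream name: {name!r} (known: {sorted(_STREAMS)})")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[name], index))
    return np.random.default_rng(ss)
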