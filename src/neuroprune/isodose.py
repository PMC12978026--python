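"""Iso-dose matching: compare protocols at equal network alteration.

The protocols differ not only in mechanism but in how much they change the
network.  The per-parameter-normalised L1 norm of effective-weight
differences serves as a cross-mechanism "dose" proxy: regrowth, pruning and
drift all register through the masked weights.  Parameter sweeps produce
dose-outcome records per protocol; records with overlapping doses are then
tabulated side by side, so outcome differences reflect mechanism rather
than magnitude of alteration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._streams import substream
from .evaluation import COMBINED_STRESS, EvalCondition, accuracy, relapse_challenge
from .network import NetworkState
from .treatments import (KetamineConfig, NeurosteroidConfig, SsriConfig,
                         ketamine_protocol, neurosteroid_protocol, ssri_protocol)
from .training import NoiseSchedule

logger = logging.getLogger(__name__)

PROTOCOLS = ("ketamine", "ssri", "neurosteroid")


@dataclass(frozen=True)
class DoseRecord:
    protocol: str
    config_summary: dict
    l1_dose: float
    combined_pct: float
    extreme_pct: float
    relapse_drop_pct: float
    baseline_checksum: str = ""


def l1_dose(before: NetworkState, after: NetworkState) -> float:
    """Mean |effective-weight change| per weight entry (biases excluded)."""
    if [w.shape for w in before.weights] != [w.shape for w in after.weights]:
        raise ValueError("architectures are not congruent")
    total = sum(w.size for w in before.weights)
    change = 0.0
    for wb, mb, wa, ma in zip(before.weights, before.masks,
                              after.weights, after.masks):
        change += float(np.abs(wa.astype(np.float64) * ma - wb.astype(np.float64) * mb).sum())
    return change / total


def default_grids() -> dict[str, list[dict]]:
    """The default hyperparameter grids swept per protocol."""
    grids = {
        "ketamine": [{"regrow_fraction_of_pruned": f} for f in (0.1, 0.2, 0.3, 0.5)],
        "ssri": [{"learning_rate": lr, "epochs": e}
                 for lr, e in itertools.product((1e-6, 5e-6, 1e-5, 5e-5), (25, 100))],
        "neurosteroid": [{"damping_factor": g, "tuning_epochs": t}
                         for g, t in itertools.product((0.5, 0.7, 0.9), (0, 5, 10))],
    }
    return grids


def _run_protocol(protocol: str, overrides: dict, pruned: NetworkState, data, rng):
    if protocol == "ketamine":
        cfg = KetamineConfig(**overrides)
        return ketamine_protocol(pruned.copy(), data, cfg, rng), cfg
    if protocol == "ssri":
        cfg = SsriConfig(**overrides)
        return ssri_protocol(pruned.copy(), data, cfg, rng), cfg
    if protocol == "neurosteroid":
        cfg = NeurosteroidConfig(**overrides)
        state, _ = neurosteroid_protocol(pruned.copy(), data, cfg, rng)
        return state, cfg
    raise ValueError(f"unknown protocol {protocol!r}")


def sweep_protocol(
    protocol: str,
    grid: list[dict],
    pruned_state: NetworkState,
    data,
    seed: int = 42,
    n_repeats: int = 8,
) -> list[DoseRecord]:
    """Run every grid point from a fresh copy of the pruned baseline.

    Each record carries the L1 dose against the baseline plus the outcome
    triple (combined stress, extreme noise, relapse drop), sorted by dose.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    baseline_sum = pruned_state.checksum()
    records = []
    for i, overrides in enumerate(grid):
        rng = substream(seed, "sweep", index=i)
        treated, cfg = _run_protocol(protocol, overrides, pruned_state, data, rng)
        combined = EvalCondition(extra_input_sigma=1.0, internal_sigma=0.5,
                                 n_repeats=n_repeats, seed=seed)
        extreme = EvalCondition(internal_sigma=2.5, n_repeats=n_repeats, seed=seed)
        drop, _ = relapse_challenge(treated, data, combined)
        records.append(DoseRecord(
            protocol=protocol,
            config_summary=dict(overrides),
            l1_dose=l1_dose(pruned_state, treated),
            combined_pct=accuracy(treated, combined, data),
            extreme_pct=accuracy(treated, extreme, data),
            relapse_drop_pct=drop,
            baseline_checksum=baseline_sum,
        ))
    return sorted(records, key=lambda r: r.l1_dose)


def match_doses(
    records_by_protocol: dict[str, list[DoseRecord]],
    rel_tolerance: float = 0.25,
) -> pd.DataFrame:
    """Group records from different protocols with overlapping doses.

    Two records match when their doses differ by at most ``rel_tolerance``
    relative to the larger.  Greedy grouping walks the dose axis; each group
    holds at most one record per protocol.  Returns a long-format table
    (group, protocol, dose, outcomes); empty with a warning when the dose
    ranges are disjoint.
    """
    if len([p for p, r in records_by_protocol.items() if r]) < 2:
        raise ValueError("need records from at least two protocols")
    pool = sorted(
        (r for recs in records_by_protocol.values() for r in recs),
        key=lambda r: r.l1_dose)
    used = set()
    rows = []
    group = 0
    for i, anchor in enumerate(pool):
        if id(anchor) in used:
            continue
        members = {anchor.protocol: anchor}
        for other in pool[i + 1:]:
            if id(other) in used or other.protocol in members:
                continue
            hi = max(anchor.l1_dose, other.l1_dose)
            if hi > 0 and (hi - anchor.l1_dose if other.l1_dose >= anchor.l1_dose
                           else hi - other.l1_dose) / hi > rel_tolerance:
                continue
            if hi == 0 or abs(other.l1_dose - anchor.l1_dose) / hi <= rel_tolerance:
                members[other.protocol] = other
        if len(members) >= 2:
            for rec in members.values():
                used.add(id(rec))
                rows.append({
                    "group": group, "protocol": rec.protocol,
                    "l1_dose": rec.l1_dose, "combined_pct": rec.combined_pct,
                    "extreme_pct": rec.extreme_pct,
                    "relapse_drop_pct": rec.relapse_drop_pct,
                    **{f"cfg_{k}": v for k, v in rec.config_summary.items()},
                })
            group += 1
    if not rows:
        logger.warning("no overlapping doses found across protocols; empty match table")
        return pd.DataFrame(columns=["group", "protocol", "l1_dose", "combined_pct",
                                     "extreme_pct", "relapse_drop_pct"])
    return pd.DataFrame(rows).sort_values(["group", "protocol"]).reset_index(drop=True)


def records_to_frame(records: list[DoseRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protocol": r.protocol, "l1_dose": r.l1_dose,
        "combined_pct": r.combined_pct, "extreme_pct": r.extreme_pct,
        "relapse_drop_pct": r.relapse_drop_pct,
        **{f"cfg_{k}": v for k, v in r.config_summary.items()},
    } for r in records])
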