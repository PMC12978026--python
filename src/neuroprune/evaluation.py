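"""The stress-testing battery: accuracy tables, noise sweeps, relapse drops.

Conditions mirror the clinical read-outs:

* **clean** — held-out intrinsic draws, no perturbation, no internal noise;
* **standard** — the everyday noisy test set (input jitter sigma=0.8);
* **combined stress** — standard inputs + extra input noise (sigma=1.0) +
  internal activation noise (sigma=0.5);
* **noise sweep** — standard inputs, graded internal noise only;
* **relapse challenge** — prune 40% of surviving weights on a copy and
  re-measure combined stress; the drop (percentage points) is the relapse
  vulnerability.

Noisy conditions are averaged over ``n_repeats`` independent noise draws
from a fixed evaluation stream, which tightens the stochastic read-outs
without changing their expectation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import ModulationConfig, NetworkState, forward, sparsity
from .pathology import relapse_prune
from .task import add_input_noise

logger = logging.getLogger(__name__)

DEFAULT_SWEEP_SIGMAS = (0.0, 0.3, 0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class EvalCondition:
    base_split: str = "standard"  # "clean" | "standard"
    extra_input_sigma: float = 0.0
    internal_sigma: float = 0.0
    modulation_enabled: bool = True
    n_repeats: int = 8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.extra_input_sigma < 0 or self.internal_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


COMBINED_STRESS = EvalCondition(base_split="standard", extra_input_sigma=1.0,
                                internal_sigma=0.5)


@dataclass
class EvalReport:
    """One condition-row of the performance table, plus its sweep curve."""

    label: str
    sparsity_pct: float
    clean_pct: float | None = None
    standard_pct: float | None = None
    combined_pct: float | None = None
    sweep: dict[float, float] = field(default_factory=dict)
    relapse_drop_pct: float | None = None


def _effective_mod(state: NetworkState, condition: EvalCondition) -> ModulationConfig:
    base = state.modulation
    if base is not None and condition.modulation_enabled:
        return ModulationConfig(
            internal_noise_sigma=condition.internal_sigma,
            damping_factor=base.damping_factor,
            activation_override=base.activation_override,
            enabled=True,
        )
    # drug absent/withdrawn: unit gain, resting activation; stress noise stays
    return ModulationConfig(internal_noise_sigma=condition.internal_sigma,
                            enabled=False)


def accuracy(
    state: NetworkState,
    condition: EvalCondition,
    data,
    rng: np.random.Generator | None = None,
) -> float:
    """Top-1 accuracy (%) under a condition, repeat-averaged over noise draws.

    When ``rng`` is omitted the condition's own seed drives the noise, so a
    given (state, condition, data) triple always reproduces the same number.
    """
    X, y = data.split(condition.base_split)
    if len(X) == 0:
        raise ValueError(f"split {condition.base_split!r} is empty")
    mod = _effective_mod(state, condition)
    deterministic = condition.extra_input_sigma == 0 and condition.internal_sigma == 0
    repeats = 1 if deterministic else condition.n_repeats
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(condition.seed))
    accs = []
    for _ in range(repeats):
        Xp = add_input_noise(X, condition.extra_input_sigma, rng) \
            if condition.extra_input_sigma > 0 else X
        probs = forward(state, Xp, mod=mod,
                        rng=rng if condition.internal_sigma > 0 else None)
        accs.append((probs.argmax(axis=1) == y).mean() * 100.0)
    return float(np.mean(accs))


def noise_sweep(
    state: NetworkState,
    sigmas=DEFAULT_SWEEP_SIGMAS,
    data=None,
    base: EvalCondition | None = None,
) -> dict[float, float]:
    """Accuracy on the standard split at graded internal noise, no extra input noise."""
    sigmas = tuple(sigmas)
    if len(sigmas) == 0:
        raise ValueError("sigmas must be non-empty")
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be >= 0")
    base = base or EvalCondition()
    out = {}
    for s in sigmas:
        cond = replace(base, base_split="standard", extra_input_sigma=0.0,
                       internal_sigma=float(s))
        out[float(s)] = accuracy(state, cond, data)
    return out


def relapse_challenge(
    state: NetworkState,
    data,
    condition: EvalCondition = COMBINED_STRESS,
    fraction: float = 0.40,
) -> tuple[float, dict]:
    """Combined-stress drop (percentage points) after 40% relapse pruning of a copy."""
    before = accuracy(state, condition, data)
    pruned, event = relapse_prune(state.copy(), fraction)
    after = accuracy(pruned, condition, data)
    return before - after, {
        "combined_before_pct": before,
        "combined_after_pct": after,
        "post_relapse_sparsity": event.resulting_sparsity,
        "prune_event": event.to_dict(),
    }


def evaluate_battery(
    state: NetworkState,
    data,
    label: str,
    n_repeats: int = 8,
    seed: int = 42,
    sweep_sigmas=DEFAULT_SWEEP_SIGMAS,
    modulation_enabled: bool = True,
    with_relapse: bool = True,
    with_clean_standard: bool = True,
) -> EvalReport:
    """Run the full battery for one condition-row of the performance table."""
    base = EvalCondition(n_repeats=n_repeats, seed=seed,
                         modulation_enabled=modulation_enabled)
    report = EvalReport(label=label, sparsity_pct=sparsity(state) * 100.0)
    if with_clean_standard:
        report.clean_pct = accuracy(state, replace(base, base_split="clean"), data)
        report.standard_pct = accuracy(state, base, data)
    combined = replace(base, extra_input_sigma=1.0, internal_sigma=0.5)
    report.combined_pct = accuracy(state, combined, data)
    report.sweep = noise_sweep(state, sweep_sigmas, data, base=base)
    if with_relapse:
        drop, _ = relapse_challenge(state, data, combined)
        report.relapse_drop_pct = drop
    return report


_SWEEP_LABELS = {0.0: "No noise", 0.5: "Moderate (sigma=0.5)", 1.0: "High (sigma=1.0)",
                 1.5: "Severe (sigma=1.5)", 2.5: "Extreme (sigma=2.5)"}


def compile_report(reports: list[EvalReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the two summary tables from per-condition reports.

    Table 1: sparsity / clean / standard / combined stress / extreme stress /
    relapse drop per condition.  Table 2: the internal-noise sweep at the
    canonical columns.  Missing metrics (e.g. withdrawn-state clean accuracy)
    stay as NaN and render as dashes.
    """
    rows1, rows2 = [], []
    for r in reports:
        rows1.append({
            "condition": r.label,
            "sparsity_pct": r.sparsity_pct,
            "clean_pct": r.clean_pct,
            "standard_pct": r.standard_pct,
            "combined_pct": r.combined_pct,
            "extreme_pct": r.sweep.get(2.5),
            "relapse_drop_pct": r.relapse_drop_pct,
        })
        row2 = {"condition": r.label}
        for sig, lab in _SWEEP_LABELS.items():
            row2[lab] = r.sweep.get(sig)
        rows2.append(row2)
    return pd.DataFrame(rows1), pd.DataFrame(rows2)


def write_report_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_report_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def report_to_text(table1: pd.DataFrame, table2: pd.DataFrame) -> str:
    buf = io.StringIO()
    with pd.option_context("display.width", 120, "display.float_format",
                           lambda v: f"{v:.1f}"):
        buf.write("Post-treatment performance and relapse vulnerability\n")
        buf.write(table1.to_string(index=False, na_rep="-"))
        buf.write("\n\nAccuracy (%) under increasing internal activation noise\n")
        buf.write(table2.to_string(index=False, na_rep="-"))
    return buf.getvalue()
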