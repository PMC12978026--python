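"""End-to-end experiment object: the model/results surface of the package.

``PruningTreatmentExperiment`` is built from a :class:`~neuroprune.config.RunConfig`
(or a dataset) and its :meth:`fit` runs the whole protocol — generate the
task, train the dense circuit, apply the 95% pruning insult, treat three
identical copies, and run the evaluation battery.  It returns an
:class:`ExperimentResults` carrying the trained states, the two summary
tables, per-protocol L1 doses, training histories and prune events, with a
``summary()`` text rendering and a ``save()`` that writes checkpoints,
CSV tables and a JSON bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._streams import substream
from .config import RunConfig
from .evaluation import compile_report, evaluate_battery, report_to_text
from .isodose import l1_dose
from .network import NetworkState, init_network, param_count, save_checkpoint, sparsity
from .pathology import prune_magnitude
from .task import ClusterSpec, DatasetBundle, generate_dataset
from .training import TrainConfig, train
from .treatments import ketamine_protocol, neurosteroid_protocol, ssri_protocol

logger = logging.getLogger(__name__)

CONDITION_LABELS = ("Untreated (pruned)", "Ketamine-like", "SSRI-like",
                    "Neurosteroid-like (on)", "Neurosteroid-like (off)")


@dataclass
class ExperimentResults:
    """Fitted states, evaluation tables and provenance of one full run."""

    config: RunConfig
    data: DatasetBundle
    states: dict[str, NetworkState]
    table1: pd.DataFrame
    table2: pd.DataFrame
    doses: dict[str, float]
    histories: dict[str, list[dict]] = field(default_factory=dict)
    prune_event: dict | None = None
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        head = (
            f"Pruning-plasticity experiment (seed {self.config.master_seed})\n"
            f"Network {self.config.layer_sizes}, "
            f"{param_count(self.states['dense'])} trainable parameters; "
            f"pruned sparsity {sparsity(self.states['pruned']) * 100:.1f}%\n\n"
        )
        doses = "\n".join(f"  {k}: L1 dose {v:.6f}" for k, v in self.doses.items())
        return head + report_to_text(self.table1, self.table2) + \
            "\n\nPer-parameter L1 weight change vs pruned baseline:\n" + doses

    def metrics_dict(self) -> dict:
        return {
            "seed": self.config.master_seed,
            "config_checksum": self.config.checksum(),
            "param_count": param_count(self.states["dense"]),
            "sparsity": {k: sparsity(s) for k, s in self.states.items()},
            "table1": self.table1.to_dict(orient="records"),
            "table2": self.table2.to_dict(orient="records"),
            "l1_doses": self.doses,
            "prune_event": self.prune_event,
        }

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, state in self.states.items():
            save_checkpoint(state, outdir / f"{name}.npz")
        self.table1.to_csv(outdir / "table1_performance.csv", index=False)
        self.table2.to_csv(outdir / "table2_noise_sweep.csv", index=False)
        bundle = self.metrics_dict()
        bundle["histories"] = self.histories
        with open(outdir / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        return outdir


class PruningTreatmentExperiment:
    """The full simulation protocol as a fit-once model object.

    Parameters
    ----------
    config : RunConfig, optional
        Every knob of the run; defaults reproduce the canonical protocol.
    data : DatasetBundle, optional
        Pre-generated task data; generated from the config when omitted.
    """

    def __init__(self, config: RunConfig | None = None,
                 data: DatasetBundle | None = None):
        self.config = config or RunConfig()
        self._data = data

    @classmethod
    def from_config_file(cls, path) -> "PruningTreatmentExperiment":
        return cls(RunConfig.from_file(path))

    def _generate_data(self) -> DatasetBundle:
        d = self.config.data
        return generate_dataset(
            ClusterSpec(centers=tuple(tuple(c) for c in d.centers),
                        cluster_sigma=d.cluster_sigma),
            n_train=d.n_train, n_test_standard=d.n_test_standard,
            n_test_clean=d.n_test_clean,
            input_noise_sigma_standard=d.input_noise_sigma_standard,
            seed=self.config.master_seed)

    def fit(self) -> ExperimentResults:
        cfg = self.config
        seed = cfg.master_seed
        stage_seconds: dict[str, float] = {}

        def _stage(name):
            t0 = time.perf_counter()

            def done():
                stage_seconds[name] = time.perf_counter() - t0
                logger.info("stage %-12s %6.1fs", name, stage_seconds[name])
            return done

        done = _stage("data")
        data = self._data if self._data is not None else self._generate_data()
        done()

        done = _stage("train-dense")
        dense = init_network(cfg.layer_sizes, seed=seed)
        bl = cfg.baseline
        dense, hist_dense = train(
            dense, data,
            TrainConfig(epochs=bl.epochs, learning_rate=bl.learning_rate,
                        batch_size=bl.batch_size),
            substream(seed, "train"))
        done()

        done = _stage("prune")
        pruned, prune_event = prune_magnitude(dense, cfg.prune_fraction)
        logger.info("sparsity after insult: %.2f%%", sparsity(pruned) * 100)
        done()

        baseline_sum = pruned.checksum()
        done = _stage("treat")
        ket = ketamine_protocol(pruned.copy(), data, cfg.ketamine,
                                substream(seed, "treat-ketamine"))
        ssri = ssri_protocol(pruned.copy(), data, cfg.ssri,
                             substream(seed, "treat-ssri"))
        neuro, _ = neurosteroid_protocol(pruned.copy(), data, cfg.neurosteroid,
                                         substream(seed, "treat-neurosteroid"))
        assert pruned.checksum() == baseline_sum  # treatments worked on copies
        done()

        done = _stage("evaluate")
        ev = cfg.evaluation
        kw = dict(n_repeats=ev.n_repeats, seed=seed, sweep_sigmas=ev.sweep_sigmas)
        reports = [
            evaluate_battery(pruned, data, CONDITION_LABELS[0],
                             with_relapse=False, **kw),
            evaluate_battery(ket, data, CONDITION_LABELS[1], **kw),
            evaluate_battery(ssri, data, CONDITION_LABELS[2], **kw),
            evaluate_battery(neuro, data, CONDITION_LABELS[3], **kw),
            evaluate_battery(neuro, data, CONDITION_LABELS[4],
                             modulation_enabled=False, with_relapse=False,
                             with_clean_standard=False, **kw),
        ]
        table1, table2 = compile_report(reports)
        done()

        doses = {"ketamine": l1_dose(pruned, ket), "ssri": l1_dose(pruned, ssri),
                 "neurosteroid": l1_dose(pruned, neuro)}
        return ExperimentResults(
            config=cfg, data=data,
            states={"dense": dense, "pruned": pruned, "ketamine": ket,
                    "ssri": ssri, "neurosteroid": neuro},
            table1=table1, table2=table2, doses=doses,
            histories={"dense": hist_dense},
            prune_event=prune_event.to_dict(),
            stage_seconds=stage_seconds,
        )


def run_full_experiment(config: RunConfig | None = None,
                        outdir=None) -> ExperimentResults:
    """Convenience wrapper: fit the experiment and optionally save artifacts."""
    results = PruningTreatmentExperiment(config).fit()
    if outdir is not None:
        results.save(outdir)
    return results
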