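"""Tests for the evaluation battery: accuracy, sweeps, relapse, report plumbing."""

import numpy as np
import pandas as pd
import pytest

from neuroprune import (EvalCondition, accuracy, compile_report, evaluate_battery,
                        init_network, noise_sweep, relapse_challenge)
from neuroprune.evaluation import (COMBINED_STRESS, EvalReport, read_report_csv,
                                   write_report_csv)

from conftest import TOY_LAYERS, make_state


class TestAccuracy:
    def test_deterministic_path_repeats_identically(self, toy_data, toy_trained):
        cond = EvalCondition(base_split="clean")
        assert accuracy(toy_trained, cond, toy_data) == \
            accuracy(toy_trained, cond, toy_data)

    def test_noisy_condition_reproducible_via_condition_seed(self, toy_data,
                                                             toy_trained):
        cond = EvalCondition(extra_input_sigma=1.0, internal_sigma=0.5,
                             n_repeats=2, seed=5)
        assert accuracy(toy_trained, cond, toy_data) == \
            accuracy(toy_trained, cond, toy_data)

    def test_chance_level_for_random_networks(self):
        """Untrained noisy nets on balanced 4-class data sit at the 25% chance level.

        Internal noise decorrelates predictions from the input; any such
        predictor scores ~25% on balanced labels.  (A noise-free random net
        can map whole clusters to a wrong class and land far from chance in
        either direction, so the floor is asserted under noise.)
        """
        from neuroprune import generate_dataset
        data = generate_dataset(n_train=4, n_test_standard=4_000,
                                n_test_clean=4, seed=13)
        cond = EvalCondition(internal_sigma=2.5, n_repeats=4)
        accs = [accuracy(init_network(TOY_LAYERS, seed=s), cond, data)
                for s in range(30)]
        assert min(accs) >= 20.0  # chance floor on 4,000 balanced points
        assert np.mean(accs) == pytest.approx(25.0, abs=3.0)

    def test_trained_dense_clean_accuracy(self, toy_data, toy_trained):
        assert accuracy(toy_trained, EvalCondition(base_split="clean"),
                        toy_data) >= 99.0

    def test_empty_split_rejected(self, toy_data, toy_trained):
        import dataclasses
        empty = dataclasses.replace(
            toy_data, test_clean=(np.zeros((0, 2), dtype=np.float32),
                                  np.zeros(0, dtype=np.int64)))
        with pytest.raises(ValueError, match="empty"):
            accuracy(toy_trained, EvalCondition(base_split="clean"), empty)

    def test_repeat_averaging_shrinks_variance(self, toy_data, toy_trained):
        def spread(n_repeats):
            vals = [accuracy(toy_trained,
                             EvalCondition(internal_sigma=1.5,
                                           n_repeats=n_repeats, seed=s),
                             toy_data) for s in range(12)]
            return np.var(vals)

        v1, v16 = spread(1), spread(16)
        assert v16 < v1


class TestNoiseSweep:
    def test_zero_sigma_equals_standard_accuracy(self, toy_data, toy_pruned):
        sweep = noise_sweep(toy_pruned, (0.0,), toy_data)
        std = accuracy(toy_pruned, EvalCondition(), toy_data)
        assert sweep[0.0] == std

    def test_extreme_noise_degrades(self, toy_data, toy_trained):
        sweep = noise_sweep(toy_trained, (0.0, 2.5), toy_data)
        assert sweep[2.5] <= sweep[0.0] + 3.0

    def test_single_sigma_gives_single_entry(self, toy_data, toy_trained):
        assert len(noise_sweep(toy_trained, (0.5,), toy_data)) == 1

    def test_empty_or_negative_sigmas_rejected(self, toy_data, toy_trained):
        with pytest.raises(ValueError):
            noise_sweep(toy_trained, (), toy_data)
        with pytest.raises(ValueError):
            noise_sweep(toy_trained, (-0.5,), toy_data)


class TestRelapseChallenge:
    def test_zero_weight_state_has_zero_drop(self, toy_data):
        sizes = TOY_LAYERS
        zero = make_state(
            [np.zeros((o, i)) for i, o in zip(sizes[:-1], sizes[1:])],
            dtype=np.float32)
        drop, detail = relapse_challenge(zero, toy_data)
        assert drop == 0.0
        assert detail["combined_before_pct"] == detail["combined_after_pct"]

    def test_original_state_unmodified(self, toy_data, toy_pruned):
        checksum = toy_pruned.checksum()
        relapse_challenge(toy_pruned, toy_data)
        assert toy_pruned.checksum() == checksum

    def test_post_relapse_sparsity_recorded(self, toy_data, toy_pruned):
        _, detail = relapse_challenge(toy_pruned, toy_data)
        assert detail["post_relapse_sparsity"] == pytest.approx(0.97, abs=0.01)


class TestCompileReport:
    def _reports(self):
        full = EvalReport(label="treated", sparsity_pct=95.0, clean_pct=99.0,
                          standard_pct=98.0, combined_pct=90.0,
                          sweep={0.0: 98.0, 2.5: 40.0}, relapse_drop_pct=5.0)
        partial = EvalReport(label="withdrawn", sparsity_pct=95.0,
                             combined_pct=80.0, sweep={0.0: 95.0, 2.5: 50.0})
        return [full, partial]

    def test_shape_and_missing_cells(self):
        t1, t2 = compile_report(self._reports())
        assert list(t1["condition"]) == ["treated", "withdrawn"]
        assert t1.shape == (2, 7)
        row = t1[t1["condition"] == "withdrawn"].iloc[0]
        assert pd.isna(row["clean_pct"]) and pd.isna(row["relapse_drop_pct"])
        assert row["combined_pct"] == 80.0
        assert t2[t2["condition"] == "treated"]["Extreme (sigma=2.5)"].iloc[0] == 40.0

    def test_csv_round_trip(self, tmp_path):
        t1, _ = compile_report(self._reports())
        path = tmp_path / "table1.csv"
        write_report_csv(t1, path)
        back = read_report_csv(path)
        pd.testing.assert_frame_equal(back, t1)


def test_combined_stress_condition_matches_battery(toy_data, toy_pruned):
    report = evaluate_battery(toy_pruned, toy_data, "untreated", n_repeats=2,
                              sweep_sigmas=(0.0, 2.5))
    assert report.combined_pct == accuracy(
        toy_pruned,
        EvalCondition(extra_input_sigma=1.0, internal_sigma=0.5, n_repeats=2),
        toy_data)
    assert COMBINED_STRESS.extra_input_sigma == 1.0
    assert COMBINED_STRESS.internal_sigma == 0.5
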