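"""Tests for ghost gradients and the three treatment protocols."""

import dataclasses

import numpy as np
import pytest

from neuroprune import (KetamineConfig, NeurosteroidConfig, SsriConfig,
                        accumulate_ghost_gradients, cross_entropy, forward,
                        ketamine_protocol, neurosteroid_protocol, sparsity,
                        ssri_protocol)
from neuroprune import DatasetBundle, ClusterSpec

from conftest import make_state


def tiny_bundle(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    return DatasetBundle(train=(X, y), test_standard=(X, y), test_clean=(X, y),
                         spec=ClusterSpec(centers=((0, 0), (1, 1))), seed=0)


def masked_toy_net(seed=0, n_hidden=4, mask_out=((0, 0),)):
    """Dense random 2->h->2 net with selected layer-0 entries masked to zero."""
    rng = np.random.default_rng(seed)
    w0 = rng.normal(0, 0.5, size=(n_hidden, 2))
    w1 = rng.normal(0, 0.5, size=(2, n_hidden))
    m0 = np.ones_like(w0)
    for r, c in mask_out:
        m0[r, c] = 0.0
        w0[r, c] = 0.0
    return make_state([w0, w1], biases=[rng.normal(size=n_hidden),
                                        rng.normal(size=2)], masks=[m0, np.ones_like(w1)])


class TestGhostGradients:
    def test_dense_state_rejected(self, toy_data, toy_trained):
        with pytest.raises(ValueError, match="dense"):
            accumulate_ghost_gradients(toy_trained, toy_data)

    def test_scores_nonnegative_and_zero_at_unmasked(self, toy_data, toy_pruned):
        scores = accumulate_ghost_gradients(toy_pruned, toy_data, n_batches=2,
                                            rng=np.random.default_rng(0))
        for s, m in zip(scores, toy_pruned.masks):
            assert np.all(s >= 0)
            assert np.all(s[m == 1] == 0)

    def test_dead_input_gives_zero_score(self):
        # second input coordinate is always zero -> no gradient can reach
        # layer-0 weights wired to it
        net = masked_toy_net(mask_out=((0, 1), (1, 1)))
        data = tiny_bundle([[1.0, 0.0], [2.0, 0.0], [-1.0, 0.0]], [0, 1, 0])
        scores = accumulate_ghost_gradients(net, data, n_batches=1,
                                            rng=np.random.default_rng(1),
                                            batch_size=3)
        assert scores[0][0, 1] == 0.0 and scores[0][1, 1] == 0.0

    def test_matches_central_finite_difference(self):
        net = masked_toy_net(seed=3, mask_out=((2, 0),))
        data = tiny_bundle([[0.7, -1.2], [1.5, 0.4], [-0.3, 0.9], [0.2, -0.8]],
                           [0, 1, 1, 0])
        scores = accumulate_ghost_gradients(net, data, n_batches=1,
                                            rng=np.random.default_rng(2),
                                            batch_size=4)

        def loss_at(v):
            probe = net.copy()
            probe.masks[0][2, 0] = 1.0
            probe.weights[0][2, 0] = v
            X, y = data.train
            return cross_entropy(forward(probe, X), y)

        h = 1e-4
        fd = abs(loss_at(h) - loss_at(-h)) / (2 * h)
        assert scores[0][2, 0] == pytest.approx(fd, abs=1e-4)


class TestKetamineProtocol:
    def test_regrowth_counts_and_sparsity(self, toy_data, toy_pruned):
        cfg = KetamineConfig(consolidation_epochs=1)
        before_masks = [m.copy() for m in toy_pruned.masks]
        out = ketamine_protocol(toy_pruned.copy(), toy_data, cfg,
                                np.random.default_rng(5))
        for m_before, m_after in zip(before_masks, out.masks):
            ghosts = int((m_before == 0).sum())
            regrown = int(((m_after == 1) & (m_before == 0)).sum())
            assert regrown == int(np.floor(0.5 * ghosts))
            # no live entry was switched off
            assert np.all(m_after[m_before == 1] == 1)
        assert sparsity(out) == pytest.approx(0.475, abs=0.03)

    def test_zero_regrowth_leaves_mask(self, toy_data, toy_pruned):
        cfg = KetamineConfig(regrow_fraction_of_pruned=0.0, consolidation_epochs=1)
        out = ketamine_protocol(toy_pruned.copy(), toy_data, cfg,
                                np.random.default_rng(5))
        for ma, mb in zip(out.masks, toy_pruned.masks):
            assert np.array_equal(ma, mb)

    def test_full_regrowth_is_dense(self, toy_data, toy_pruned):
        cfg = KetamineConfig(regrow_fraction_of_pruned=1.0, consolidation_epochs=0)
        out = ketamine_protocol(toy_pruned.copy(), toy_data, cfg,
                                np.random.default_rng(5))
        assert sparsity(out) == 0.0

    def test_ranking_agrees_with_sort_oracle(self, toy_data, toy_pruned):
        rng = np.random.default_rng(6)
        scores = accumulate_ghost_gradients(toy_pruned, toy_data, n_batches=30,
                                            rng=rng, batch_size=128)
        out = ketamine_protocol(toy_pruned.copy(), toy_data,
                                KetamineConfig(consolidation_epochs=0),
                                np.random.default_rng(6))
        for s, m_before, m_after in zip(scores, toy_pruned.masks, out.masks):
            ghosts = np.flatnonzero(m_before.ravel() == 0)
            k = int(np.floor(0.5 * len(ghosts)))
            expected = set(
                ghosts[np.argsort(-s.ravel()[ghosts], kind="stable")[:k]])
            regrown = set(np.flatnonzero((m_after.ravel() == 1)
                                         & (m_before.ravel() == 0)))
            assert regrown == expected


class TestStructurePreservingProtocols:
    def test_ssri_keeps_masks(self, toy_data, toy_pruned):
        out = ssri_protocol(toy_pruned.copy(), toy_data,
                            SsriConfig(epochs=3), np.random.default_rng(7))
        for ma, mb in zip(out.masks, toy_pruned.masks):
            assert np.array_equal(ma, mb)

    def test_ssri_final_epoch_noise_is_zero(self):
        cfg = SsriConfig(epochs=5)
        assert cfg.noise_schedule.sigma_at(4, 5) == 0.0
        assert cfg.noise_schedule.sigma_at(0, 5) == 0.5

    def test_ssri_epoch_floor(self):
        with pytest.raises(ValueError):
            SsriConfig(epochs=0)

    def test_neurosteroid_keeps_masks_and_returns_modulation(self, toy_data,
                                                             toy_pruned):
        out, mod = neurosteroid_protocol(toy_pruned.copy(), toy_data,
                                         NeurosteroidConfig(tuning_epochs=2),
                                         np.random.default_rng(8))
        assert mod.damping_factor == 0.7
        assert mod.activation_override == "bounded"
        assert mod.enabled
        assert out.modulation == mod
        for ma, mb in zip(out.masks, toy_pruned.masks):
            assert np.array_equal(ma, mb)

    def test_protocols_start_from_identical_copies(self, toy_data, toy_pruned):
        checksum = toy_pruned.checksum()
        ssri_protocol(toy_pruned.copy(), toy_data, SsriConfig(epochs=1),
                      np.random.default_rng(1))
        ketamine_protocol(toy_pruned.copy(), toy_data,
                          KetamineConfig(consolidation_epochs=1),
                          np.random.default_rng(1))
        neurosteroid_protocol(toy_pruned.copy(), toy_data,
                              NeurosteroidConfig(tuning_epochs=1),
                              np.random.default_rng(1))
        assert toy_pruned.checksum() == checksum
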