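"""Network: conv scanning, pooling, positional encoding, attention, training."""

import numpy as np
import pytest

import motifcoop as mc
from motifcoop import data as md
from motifcoop.network import (AttentionClassifier, ModelConfig,
                               compute_feature_maps, conv_scan,
                               horizontal_pool, positional_encoding,
                               vertical_pool)


def plant(motif, end_bp, length=200, seed=0):
    """Background sequence with the motif's consensus ending at ``end_bp``."""
    rng = np.random.default_rng(seed)
    chars = list("".join(rng.choice(list("ACGT"), size=length)))
    cons = motif.consensus
    start = end_bp - motif.length + 1
    chars[start:start + motif.length] = list(cons)
    return "".join(chars)


class TestConvScan:
    def test_consensus_word_scores_column_max_sum_at_end(self, tiny_library):
        motif = tiny_library[0]
        seq = plant(motif, end_bp=120)
        scores = conv_scan(md.one_hot(seq).astype(float),
                           tiny_library.filter_tensor(),
                           motif_lengths=tiny_library.motif_lengths)
        expected = motif.pssm.max(axis=0).sum()
        assert scores[120, 0] == pytest.approx(expected)
        assert scores[:, 0].max() == pytest.approx(expected)
        assert int(scores[:, 0].argmax()) == 120

    def test_all_n_sequence_scores_zero(self, tiny_library):
        scores = conv_scan(md.one_hot("N" * 100).astype(float),
                           tiny_library.filter_tensor())
        np.testing.assert_allclose(scores, 0.0)

    def test_incomplete_windows_masked(self, tiny_library):
        scores = conv_scan(md.one_hot("ACGT" * 25).astype(float),
                           tiny_library.filter_tensor(),
                           motif_lengths=tiny_library.motif_lengths,
                           mask_incomplete=True)
        for k, m in enumerate(tiny_library):
            assert np.all(np.isneginf(scores[: m.length - 1, k]))
            assert np.all(np.isfinite(scores[m.length - 1:, k]))

    def test_strand_mirror_symmetry(self, tiny_library):
        motif = tiny_library[1]
        seq = plant(motif, end_bp=77, seed=4)
        rc_seq = md.revcomp(seq)
        filters = tiny_library.filter_tensor()
        k = len(tiny_library)
        fwd = conv_scan(md.one_hot(seq).astype(float), filters)
        rc = conv_scan(md.one_hot(rc_seq).astype(float), filters)
        # the motif window [i-l+1, i] on the forward strand is the window
        # ending at L+l-2-i of the reverse strand, scored by the rc filter
        length, ell = len(seq), motif.length
        for i in range(ell - 1, length):
            j = length + ell - 2 - i
            if j > length - 1:
                continue
            assert fwd[i, 1] == pytest.approx(rc[j, k + 1], abs=1e-9)

    def test_sequence_shorter_than_motif_rejected(self, tiny_library):
        with pytest.raises(ValueError, match="shorter"):
            conv_scan(md.one_hot("ACG").astype(float),
                      tiny_library.filter_tensor(),
                      motif_lengths=tiny_library.motif_lengths)


class TestVerticalPool:
    def test_elementwise_max_of_strand_pair(self):
        fwd = np.array([[[3.0, 1.0]]])
        rc = np.array([[[1.5, 2.0]]])
        merged = vertical_pool(np.concatenate([fwd, rc], axis=-1))
        np.testing.assert_allclose(merged, [[[3.0, 2.0]]])

    def test_identical_strands_unchanged(self):
        half = np.random.default_rng(0).normal(size=(2, 5, 3))
        both = np.concatenate([half, half], axis=-1)
        np.testing.assert_allclose(vertical_pool(both), half)

    def test_compute_rc_mode_is_identity(self):
        x = np.random.default_rng(1).normal(size=(2, 5, 6))
        assert vertical_pool(x, compute_rc=True) is x

    def test_odd_filter_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            vertical_pool(np.zeros((1, 4, 3)))


class TestHorizontalPool:
    def test_shape_200_to_50(self):
        x = np.random.default_rng(0).normal(size=(3, 200, 7))
        pooled, arg = horizontal_pool(x, 4)
        assert pooled.shape == (3, 50, 7)
        assert arg.shape == (3, 50, 7)

    def test_constant_map_unchanged(self):
        x = np.full((1, 8, 2), 1.5)
        pooled, _ = horizontal_pool(x, 4)
        np.testing.assert_allclose(pooled, 1.5)

    def test_spike_survives_with_recorded_position(self):
        x = np.zeros((1, 200, 1))
        x[0, 81, 0] = 9.0
        pooled, arg = horizontal_pool(x, 4)
        assert pooled[0, 20, 0] == 9.0
        assert arg[0, 20, 0] == 81

    def test_tie_breaks_to_lowest_coordinate(self):
        x = np.ones((1, 4, 1))
        _, arg = horizontal_pool(x, 4)
        assert arg[0, 0, 0] == 0


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        p = positional_encoding(6, 8)
        np.testing.assert_allclose(p[0, 0::2], 0.0, atol=1e-12)
        np.testing.assert_allclose(p[0, 1::2], 1.0)

    def test_bounded_by_unit_interval(self):
        p = positional_encoding(50, 20)
        assert np.all(np.abs(p) <= 1.0)

    def test_first_column_is_sine_of_position(self):
        p = positional_encoding(5, 8)
        assert p[1, 0] == pytest.approx(np.sin(1.0))
        assert p[3, 0] == pytest.approx(np.sin(3.0))

    def test_frequency_formula(self):
        m, f, n = 10, 6, 10000.0
        p = positional_encoding(m, f, n)
        for i in range(m):
            for j in range(f // 2):
                div = n ** (2 * j / f)
                assert p[i, 2 * j] == pytest.approx(np.sin(i / div))
                assert p[i, 2 * j + 1] == pytest.approx(np.cos(i / div))


class TestAttention:
    def _model(self, library, **kw):
        cfg = ModelConfig(n_motifs=len(library), input_len=40, **kw)
        return AttentionClassifier(library, cfg)

    def test_softmax_rows_sum_to_one(self, tiny_library):
        model = self._model(tiny_library, seed=0)
        maps = np.random.default_rng(0).normal(size=(3, 40, 4))
        _, s, _ = model.attention_state(maps)
        np.testing.assert_allclose(s.sum(axis=-1), 1.0, atol=1e-12)

    def test_zero_projections_give_uniform_attention(self, tiny_library):
        model = self._model(tiny_library, seed=0)
        model.params["Wq"][:] = 0.0
        model.params["Wk"][:] = 0.0
        maps = np.random.default_rng(1).normal(size=(2, 40, 4))
        _, s, _ = model.attention_state(maps)
        m = model.config.m_positions
        np.testing.assert_allclose(s, 1.0 / m)

    def test_single_position_attention_is_one(self, tiny_library):
        cfg = ModelConfig(n_motifs=4, input_len=4, seed=0)
        model = AttentionClassifier(tiny_library, cfg)
        maps = np.random.default_rng(2).normal(size=(1, 4, 4))
        _, s, _ = model.attention_state(maps)
        np.testing.assert_allclose(s, 1.0)


class TestTraining:
    def test_same_seed_same_first_epoch_loss(self, small_library,
                                             small_simulation):
        _, dataset, _ = small_simulation
        cfg = ModelConfig(n_motifs=len(small_library), epochs=1, seed=5)
        maps = compute_feature_maps(dataset.onehot_array()[:200],
                                    small_library, cfg)
        labels = dataset.labels()[:200]
        tr, te = np.arange(0, 160), np.arange(160, 200)
        losses = []
        for _ in range(2):
            model = AttentionClassifier(small_library, cfg)
            hist = model.fit(maps, labels, tr, te, epochs=1)
            losses.append(hist[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_label_shuffle_gives_chance_auc(self, small_library,
                                            small_simulation):
        _, dataset, _ = small_simulation
        cfg = ModelConfig(n_motifs=len(small_library), epochs=5, seed=5,
                          restore_best=False)
        maps = compute_feature_maps(dataset.onehot_array(), small_library, cfg)
        rng = np.random.default_rng(0)
        labels = rng.permutation(dataset.labels())
        model = AttentionClassifier(small_library, cfg)
        hist = model.fit(maps, labels, dataset.train_idx, dataset.test_idx)
        assert abs(hist[-1]["test_auc"] - 0.5) < 0.1

    def test_trained_model_separates_classes(self, trained_small):
        model, maps, _, dataset = trained_small
        assert model.test_auc > 0.8
        probs = model.predict(maps)
        labels = dataset.labels()
        assert probs[labels == 1].mean() > probs[labels == 0].mean()

    def test_conv_filters_frozen_by_construction(self, trained_small,
                                                 small_library):
        # the conv stage is precomputed from the library and owns no
        # trainable parameters; the filters equal the library PSSMs exactly
        model, _, _, _ = trained_small
        filt = model.library.filter_tensor()
        w = small_library.max_length
        for i, m in enumerate(small_library):
            np.testing.assert_array_equal(filt[i, :, w - m.length:], m.pssm)


class TestPredict:
    def test_scores_in_unit_interval(self, trained_small):
        model, maps, _, _ = trained_small
        probs = model.predict(maps[:50])
        assert np.all((probs > 0) & (probs < 1))

    def test_duplicate_inputs_identical_scores(self, trained_small):
        model, maps, _, _ = trained_small
        doubled = np.concatenate([maps[:5], maps[:5]])
        probs = model.predict(doubled)
        np.testing.assert_allclose(probs[:5], probs[5:], rtol=1e-12)

    def test_wrong_length_rejected(self, trained_small):
        model, maps, _, _ = trained_small
        with pytest.raises(ValueError, match="length"):
            model.predict(maps[:2, :100, :])


class TestPersistence:
    def test_save_load_round_trip(self, trained_small, small_library, tmp_path):
        model, maps, _, _ = trained_small
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = AttentionClassifier.load(path, small_library)
        np.testing.assert_array_equal(loaded.predict(maps[:20]),
                                      model.predict(maps[:20]))

    def test_wrong_library_rejected(self, trained_small, tmp_path):
        model, _, _, _ = trained_small
        path = tmp_path / "ckpt.npz"
        model.save(path)
        other = mc.synthetic_library(n_motifs=12, seed=99)
        with pytest.raises(ValueError, match="library"):
            AttentionClassifier.load(path, other)


class TestConfigValidation:
    def test_input_length_cap(self, tiny_library):
        cfg = ModelConfig(n_motifs=4, input_len=1004)
        with pytest.raises(ValueError, match="1000"):
            cfg.validate()

    def test_feature_head_divisibility(self):
        cfg = ModelConfig(n_motifs=6, n_heads=4)
        with pytest.raises(ValueError, match="divisible"):
            cfg.validate()

    def test_default_attended_dimensions(self):
        cfg = ModelConfig(n_motifs=224)
        assert cfg.m_positions == 50
        assert cfg.n_features == 224
        assert cfg.n_filters == 448
        cfg_rc = ModelConfig(n_motifs=224, compute_rc=True)
        assert cfg_rc.n_features == 448
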