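"""Dual-pass pretraining: corruption, heads, combined loss, training loop."""

import numpy as np
import pytest

from toxembed import chem, pretrain, synthetic
from toxembed.losses import LossConfig, weighted_focal_loss
from toxembed.pretrain import (
    EncoderConfig,
    HeadConfig,
    PretrainConfig,
    PretrainData,
    PretrainModel,
    collate,
    combined_loss,
    corrupt,
    corrupt_batch,
    fit_pretrain,
    load_checkpoint,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def tiny_setup(small_corpus):
    mols = small_corpus.molecules[:60]
    vocab = chem.Vocab.from_corpus(mols)
    config = EncoderConfig.tiny(len(vocab), max_length=48, dropout=0.0, seed=0)
    seqs = [chem.tokenize(m, vocab, 48) for m in mols]
    ids, pad = collate(seqs, vocab, 48)
    return mols, vocab, config, ids, pad


class TestCorrupt:
    def test_masked_fraction_near_rate(self, tiny_setup):
        _, vocab, _, ids, _ = tiny_setup
        rng = np.random.default_rng(0)
        big = np.tile(ids, (120, 1))  # ~1e5 non-special positions
        result = corrupt_batch(big, vocab, 0.15, rng)
        non_special = ~np.isin(big, list(vocab.special_ids))
        frac = result.mask.sum() / non_special.sum()
        assert frac == pytest.approx(0.15, abs=0.005)

    def test_specials_never_masked(self, tiny_setup):
        _, vocab, _, ids, _ = tiny_setup
        result = corrupt_batch(ids, vocab, 0.9, np.random.default_rng(1))
        special = np.isin(ids, list(vocab.special_ids))
        assert not np.any(result.mask & special)
        assert np.all(result.corrupted[result.mask] == vocab.mask_id)

    def test_same_seed_same_pattern(self, tiny_setup):
        _, vocab, _, ids, _ = tiny_setup
        a = corrupt_batch(ids, vocab, 0.15, np.random.default_rng(42))
        b = corrupt_batch(ids, vocab, 0.15, np.random.default_rng(42))
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.corrupted, b.corrupted)

    def test_degenerate_all_special_sequence(self, tiny_setup):
        _, vocab, *_ = tiny_setup
        ids = np.array([[vocab.begin_id, vocab.end_id, vocab.pad_id]])
        result = corrupt_batch(ids, vocab, 0.5, np.random.default_rng(0))
        assert result.n_masked == 0
        np.testing.assert_array_equal(result.corrupted, ids)

    def test_single_sequence_wrapper(self, tiny_setup):
        mols, vocab, *_ = tiny_setup
        seq = chem.tokenize(mols[0], vocab)
        result = corrupt(seq, vocab, 0.3, np.random.default_rng(0))
        assert result.corrupted.shape == (1, seq.length)

    def test_bert_policy_keeps_some_tokens(self, tiny_setup):
        _, vocab, _, ids, _ = tiny_setup
        rng = np.random.default_rng(3)
        big = np.tile(ids, (30, 1))
        result = corrupt_batch(big, vocab, 0.5, rng, policy="bert")
        masked_tokens = result.corrupted[result.mask]
        # 80/10/10: not every selected token becomes the mask token
        assert (masked_tokens == vocab.mask_id).mean() < 0.95

    def test_invalid_rate(self, tiny_setup):
        _, vocab, _, ids, _ = tiny_setup
        with pytest.raises(ValueError):
            corrupt_batch(ids, vocab, 1.0, np.random.default_rng(0))


class TestCollate:
    def test_pads_to_batch_longest(self, tiny_setup):
        mols, vocab, *_ = tiny_setup
        seqs = [chem.tokenize(m, vocab) for m in mols[:5]]
        ids, pad = collate(seqs, vocab, 48)
        assert ids.shape == pad.shape
        assert ids.shape[1] == max(s.length for s in seqs)
        for i, s in enumerate(seqs):
            assert pad[i].sum() == s.length

    def test_rejects_overlong(self, tiny_setup):
        mols, vocab, *_ = tiny_setup
        seqs = [chem.tokenize(mols[0], vocab)]
        with pytest.raises(ValueError):
            collate(seqs, vocab, max_length=3)


class TestDualPass:
    def test_output_shapes(self, tiny_setup):
        _, vocab, config, ids, pad = tiny_setup
        model = PretrainModel(config, n_physchem=7, n_invitro=4)
        outs = model.dual_pass(ids, pad, vocab, 0.15, np.random.default_rng(0))
        assert outs.masking_logits.shape == (*ids.shape, len(vocab))
        assert outs.physchem.shape == (ids.shape[0], 7)
        assert outs.invitro.shape == (ids.shape[0], 4)

    def test_clean_pass_independent_of_mask_pattern(self, tiny_setup):
        _, vocab, config, ids, pad = tiny_setup
        model = PretrainModel(config, 3, 3).eval()
        out1 = model.dual_pass(ids, pad, vocab, 0.15, np.random.default_rng(1))
        out2 = model.dual_pass(ids, pad, vocab, 0.15, np.random.default_rng(2))
        assert not np.array_equal(out1.corruption.mask, out2.corruption.mask)
        np.testing.assert_array_equal(out1.physchem.data, out2.physchem.data)
        np.testing.assert_array_equal(out1.invitro.data, out2.invitro.data)

    def test_zero_mask_rate_equals_clean_input(self, tiny_setup):
        _, vocab, config, ids, pad = tiny_setup
        model = PretrainModel(config, 2, 2).eval()
        outs = model.dual_pass(ids, pad, vocab, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(outs.corruption.corrupted, ids)
        assert outs.corruption.n_masked == 0


class TestCombinedLoss:
    def test_arithmetic_mean_of_components(self, tiny_setup, rng):
        _, vocab, config, ids, pad = tiny_setup
        model = PretrainModel(config, 4, 3).eval()
        outs = model.dual_pass(ids, pad, vocab, 0.15, np.random.default_rng(0))
        pc = rng.normal(size=(ids.shape[0], 4))
        labels = rng.integers(0, 2, size=(ids.shape[0], 3)).astype(float)
        total, comps = combined_loss(outs, pc, labels, np.ones(3))
        parts = [comps["masking"], comps["physchem"], comps["invitro"]]
        assert comps["total"] == pytest.approx(np.mean(parts), rel=1e-6)

    def test_invitro_component_is_weighted_focal_alpha1_gamma2(self, tiny_setup, rng):
        """The differentiable in vitro term equals the analytic weighted
        focal loss evaluated at the fixed pretraining setting."""
        _, vocab, config, ids, pad = tiny_setup
        model = PretrainModel(
            config, 0, 3, HeadConfig(mask=False, physchem=False, invitro=True)
        ).eval()
        outs = model.dual_pass(ids, pad, vocab, 0.15, np.random.default_rng(0))
        labels = rng.integers(0, 2, size=(ids.shape[0], 3)).astype(float)
        labels[rng.random(labels.shape) < 0.2] = np.nan
        obs = ~np.isnan(labels)
        n_pos = np.nansum(labels, axis=0)
        n_neg = obs.sum(axis=0) - n_pos
        w = pretrain.INVITRO_ALPHA * n_neg / n_pos + (1 - pretrain.INVITRO_ALPHA)
        _, comps = combined_loss(outs, None, labels, w)
        want = weighted_focal_loss(
            labels, outs.invitro.data.astype(float), LossConfig(gamma=2.0, weights=w)
        )
        assert comps["invitro"] == pytest.approx(want, rel=1e-5)

    def test_disabled_head_mode(self, tiny_setup, rng):
        _, vocab, config, ids, pad = tiny_setup
        model = PretrainModel(
            config, 4, 0, HeadConfig(mask=True, physchem=True, invitro=False)
        ).eval()
        outs = model.dual_pass(ids, pad, vocab, 0.15, np.random.default_rng(0))
        total, comps = combined_loss(outs, rng.normal(size=(ids.shape[0], 4)), None, None)
        assert "invitro" not in comps
        assert comps["total"] == pytest.approx(
            np.mean([comps["masking"], comps["physchem"]]), rel=1e-6
        )

    def test_all_heads_disabled_rejected(self):
        with pytest.raises(ValueError):
            HeadConfig(mask=False, physchem=False, invitro=False)


class TestFitPretrain:
    def test_history_one_record_per_epoch_and_determinism(self, small_corpus):
        mols = small_corpus.molecules[:80]
        vocab = chem.Vocab.from_corpus(mols)
        config = EncoderConfig.tiny(len(vocab), max_length=48, seed=1)
        data = PretrainData(
            mols,
            small_corpus.descriptors.values[:80],
            small_corpus.invitro.select_molecules(range(80)),
        )
        cfg = PretrainConfig(epochs=2, batch_size=32, lr=1e-3, seed=5)
        first = fit_pretrain(data, config, cfg)
        second = fit_pretrain(data, config, cfg)
        assert len(first.history) == 2
        assert first.history[0]["train_total"] == second.history[0]["train_total"]
        for key in ("val_mask_accuracy", "val_physchem_loss", "val_invitro_aupr"):
            assert key in first.history[0]

    def test_masking_memorization_on_training_corpus(self, small_corpus):
        """Overfit sanity check: with a fixed mask pattern, the tiny
        encoder memorizes the masked tokens of a 50-molecule corpus."""
        mols = small_corpus.molecules[:50]
        vocab = chem.Vocab.from_corpus(mols)
        config = EncoderConfig.tiny(len(vocab), max_length=48, dropout=0.0, seed=0)
        model = PretrainModel(
            config, 0, 0, HeadConfig(mask=True, physchem=False, invitro=False)
        )
        seqs = [chem.tokenize(m, vocab, 48) for m in mols]
        ids, pad = collate(seqs, vocab, 48)
        rng = np.random.default_rng(0)
        corr = corrupt_batch(ids, vocab, 0.15, rng)
        from toxembed.nn import Adam
        from toxembed.nn import autograd as ag

        opt = Adam(model.parameters(), lr=1e-3)
        for _ in range(150):
            h = model.encoder(corr.corrupted, pad, rng)
            logits = model.masking_head(h, pad, 0.0, rng)
            loss = ag.masked_cross_entropy(logits, corr.originals, corr.mask)
            opt.zero_grad()
            loss.backward()
            opt.step()
        pred = logits.data.argmax(-1)
        acc = (pred[corr.mask] == corr.originals[corr.mask]).mean()
        assert acc >= 0.95

    def test_divergence_aborts(self, small_corpus):
        """A non-finite loss aborts immediately with a diagnostic instead
        of silently training on garbage."""
        mols = small_corpus.molecules[:40]
        vocab = chem.Vocab.from_corpus(mols)
        config = EncoderConfig.tiny(len(vocab), max_length=48, seed=0)
        targets = small_corpus.descriptors.values[:40].copy()
        targets[0, 0] = np.inf  # poisons the regression loss
        data = PretrainData(mols, targets, None)
        cfg = PretrainConfig(epochs=1, batch_size=16, seed=0)
        heads = HeadConfig(mask=False, physchem=True, invitro=False)
        with pytest.raises(RuntimeError, match="diverged"):
            fit_pretrain(data, config, cfg, heads)

    def test_checkpoint_round_trip(self, tmp_path, small_corpus):
        mols = small_corpus.molecules[:60]
        vocab = chem.Vocab.from_corpus(mols)
        config = EncoderConfig.tiny(len(vocab), max_length=48, seed=2)
        data = PretrainData(
            mols,
            small_corpus.descriptors.values[:60],
            small_corpus.invitro.select_molecules(range(60)),
        )
        cfg = PretrainConfig(epochs=1, batch_size=32, seed=0)
        result = fit_pretrain(data, config, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(result, path)
        model, vocab_back = load_checkpoint(path)
        assert vocab_back.tokens == result.vocab.tokens
        from toxembed.downstream import extract_embeddings

        emb1 = extract_embeddings(mols[:5], result.model, result.vocab)
        emb2 = extract_embeddings(mols[:5], model, vocab_back)
        np.testing.assert_allclose(emb1, emb2, atol=1e-6)
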