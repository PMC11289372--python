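import numpy as np
import pytest

from massnovo.model import (
    ModelConfig,
    SpectrumTransformer,
    collate,
    internal_order_ids,
    load_checkpoint,
    save_checkpoint,
)
from massnovo.spectra_io import Peak, PrecursorInfo, Spectrum, preprocess_spectrum
from massnovo.synthetic import SimulationConfig, generate_corpus, noiseless
from massnovo.training import learning_rate, train
from massnovo.vocabulary import STOP_INDEX, tokenize


def _permute_peaks(s: Spectrum, rng) -> tuple[Spectrum, np.ndarray]:
    perm = rng.permutation(len(s.peaks))
    return (
        Spectrum(
            peaks=[s.peaks[i] for i in perm],
            precursor=s.precursor,
            identifier=s.identifier,
            annotation=s.annotation,
            preprocessed=True,
        ),
        perm,
    )


class TestEncoder:
    def test_peak_permutation_equivariance(self, tiny_model, noiseless_corpus):
        """A spectrum is a bag of peaks: permuting them permutes the
        contextualized encoding rows identically."""
        rng = np.random.default_rng(0)
        s = noiseless_corpus[0]
        enc = tiny_model.encode_spectrum(s)
        permuted, perm = _permute_peaks(s, rng)
        enc_perm = tiny_model.encode_spectrum(permuted)
        assert np.abs(enc_perm - enc[perm]).max() < 1e-5

    def test_encoding_shape(self, tiny_model, tiny_cfg):
        rng = np.random.default_rng(1)
        s = Spectrum(
            peaks=[Peak(float(m), 1.0) for m in rng.uniform(100, 1500, 150)],
            precursor=PrecursorInfo(800.0, 2),
            preprocessed=True,
        )
        enc = tiny_model.encode_spectrum(s)
        assert enc.shape == (150, tiny_cfg.d)

    def test_deterministic_under_fixed_weights(self, tiny_model, noiseless_corpus):
        a = tiny_model.encode_spectrum(noiseless_corpus[1])
        b = tiny_model.encode_spectrum(noiseless_corpus[1])
        assert np.abs(a - b).max() <= 1e-7

    def test_zero_peaks_rejected(self, tiny_model):
        s = Spectrum(peaks=[], precursor=PrecursorInfo(500.0, 2))
        with pytest.raises(ValueError):
            tiny_model.encode_spectrum(s)


class TestDecodeStep:
    def _memory(self, model, s):
        batch = collate([s], with_targets=False)
        return model.encode(batch)

    def test_empty_prefix_scores(self, tiny_model, tiny_cfg, noiseless_corpus):
        s = noiseless_corpus[0]
        memory, mask = self._memory(tiny_model, s)
        scores = tiny_model.decode_step(
            [], memory, mask, s.precursor.mass, s.precursor.charge
        )
        assert scores.shape == (tiny_cfg.vocab_size,)
        probs = np.exp(scores - scores.max())
        probs /= probs.sum()
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_prefix_at_max_length_rejected(self, tiny_model, noiseless_corpus):
        s = noiseless_corpus[0]
        memory, mask = self._memory(tiny_model, s)
        prefix = [0] * (tiny_model.config.max_length + 1)
        with pytest.raises(ValueError):
            tiny_model.decode_step(
                prefix, memory, mask, s.precursor.mass, s.precursor.charge
            )

    def test_scores_depend_on_spectrum(self, tiny_model, noiseless_corpus):
        """Conditioning is non-degenerate: changing a peak intensity changes
        the next-token scores."""
        s = noiseless_corpus[2]
        memory, mask = self._memory(tiny_model, s)
        base = tiny_model.decode_step([], memory, mask, s.precursor.mass, 2)
        bumped_peaks = [Peak(p.mz, p.intensity) for p in s.peaks]
        bumped_peaks[0] = Peak(bumped_peaks[0].mz, bumped_peaks[0].intensity * 5 + 0.5)
        bumped = Spectrum(
            peaks=bumped_peaks, precursor=s.precursor, preprocessed=True
        )
        memory2, mask2 = self._memory(tiny_model, bumped)
        other = tiny_model.decode_step([], memory2, mask2, s.precursor.mass, 2)
        assert np.abs(base - other).max() > 1e-6


class TestPrecursorEmbedding:
    def test_charge_vector_additivity(self, tiny_model):
        """Same mass, different charge: embeddings differ exactly by the
        difference of the learned charge vectors."""
        mass = np.array([1234.5])
        e2 = tiny_model.embed_precursor(mass, np.array([2])).data
        e3 = tiny_model.embed_precursor(mass, np.array([3])).data
        table = tiny_model.charge_embedding.weight.data
        np.testing.assert_allclose(e2 - e3, (table[1] - table[2])[None], atol=1e-7)

    def test_charge_clamped_above_ten(self, tiny_model):
        mass = np.array([1000.0])
        high = tiny_model.embed_precursor(mass, np.array([15])).data
        ten = tiny_model.embed_precursor(mass, np.array([10])).data
        np.testing.assert_allclose(high, ten)


class TestParameterCount:
    def test_count_independent_of_data(self, tiny_model, noiseless_corpus):
        before = tiny_model.count_parameters()
        tiny_model.forward_loss(collate(noiseless_corpus[:4]))
        assert tiny_model.count_parameters() == before

    def test_halving_d_shrinks_blocks_about_4x(self):
        big = SpectrumTransformer(ModelConfig(n_layers=2, d=128, n_heads=4))
        small = SpectrumTransformer(ModelConfig(n_layers=2, d=64, n_heads=4))
        # attention/FFN blocks scale ~d^2; embeddings/output scale ~d
        ratio = big.count_parameters() / small.count_parameters()
        assert 3.0 < ratio < 4.5


class TestTraining:
    def test_first_batch_loss_near_uniform(self, noiseless_corpus):
        model = SpectrumTransformer(ModelConfig(n_layers=2, d=64, n_heads=4, seed=3))
        loss, _ = model.forward_loss(collate(noiseless_corpus[:32]))
        assert float(loss.data) == pytest.approx(np.log(28), abs=0.3)

    def test_learning_rate_schedule(self):
        # halfway through a 100k-step linear warmup
        assert learning_rate(50_000, 5e-4, 100_000, 1_000_000) == pytest.approx(2.5e-4)
        assert learning_rate(0, 5e-4, 100_000, 1_000_000) == 0.0
        peak = learning_rate(100_000, 5e-4, 100_000, 1_000_000)
        assert peak == pytest.approx(5e-4)
        # cosine decay reaches ~0 at the end
        assert learning_rate(999_999, 5e-4, 100_000, 1_000_000) < 1e-8

    def test_memorizes_single_pair(self, noiseless_corpus):
        """Teacher-forced loss on a memorized training pair approaches 0."""
        cfg = ModelConfig(
            n_layers=1, d=32, n_heads=2, seed=0, batch_size=1, weight_decay=0.0
        )
        pair = noiseless_corpus[:1]
        result = train(
            pair,
            cfg,
            n_epochs=300,
            validation=pair,
            learning_rate_peak=2e-3,
            warmup_steps=30,
        )
        loss, acc = result.model.forward_loss(collate(pair))
        assert float(loss.data) < 0.05
        assert acc == 1.0

    def test_masters_reduced_alphabet_world(self):
        """End-to-end learnability probe: on spectra of peptides drawn from
        a five-residue alphabet the desk-scale model reads the b/y mass
        ladders almost perfectly within a few epochs — evidence that the
        architecture, encodings, and training loop are wired correctly and
        that remaining error on the full vocabulary is a matter of
        optimization budget, not correctness."""
        from massnovo.synthetic import theoretical_spectrum
        from massnovo.training import peptide_disjoint_split

        sim = noiseless(SimulationConfig(seed=3))
        rng = np.random.default_rng(3)
        alphabet = list("GASPV")
        peptides = set()
        while len(peptides) < 5000:
            n = rng.integers(6, 9)
            peptides.add("".join(rng.choice(alphabet, n)))
        corpus = [
            preprocess_spectrum(
                theoretical_spectrum(tokenize(p), 2, sim, rng, identifier=f"s{i}")
            )
            for i, p in enumerate(sorted(peptides))
        ]
        train_set, val_set = peptide_disjoint_split(corpus, (0.94, 0.06), seed=3)
        cfg = ModelConfig(
            n_layers=2, d=64, n_heads=4, seed=0, peak_lr=3e-3, batch_size=32,
            norm_first=True,
        )
        result = train(train_set, cfg, n_epochs=8, validation=val_set)
        assert result.history["val_acc"].iloc[-1] >= 0.90

    def test_gradient_reaches_all_parameters(self, noiseless_corpus):
        model = SpectrumTransformer(ModelConfig(n_layers=1, d=32, n_heads=2, seed=1))
        loss, _ = model.forward_loss(collate(noiseless_corpus[:8]))
        loss.backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert missing == []

    def test_unannotated_spectrum_rejected(self, noiseless_corpus):
        from dataclasses import replace

        bad = [replace(noiseless_corpus[0], annotation=None)]
        with pytest.raises(ValueError):
            train(bad + noiseless_corpus[1:8], ModelConfig(n_layers=1, d=32, n_heads=2))

    def test_fixed_seed_reproducible_losses(self, noiseless_corpus):
        cfg = ModelConfig(n_layers=1, d=32, n_heads=2, seed=9)
        histories = []
        for _ in range(2):
            res = train(
                noiseless_corpus, cfg, n_epochs=2, val_fraction=0.25, val_every=5
            )
            histories.append(res.history["train_loss"].to_numpy())
        np.testing.assert_array_equal(histories[0], histories[1])


class TestCheckpoint:
    def test_round_trip(self, tiny_model, tmp_path, noiseless_corpus):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        loaded = load_checkpoint(path)
        a = tiny_model.encode_spectrum(noiseless_corpus[0])
        b = loaded.encode_spectrum(noiseless_corpus[0])
        np.testing.assert_array_equal(a, b)

    def test_config_mismatch_detected(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        with pytest.raises(ValueError, match="config mismatch"):
            load_checkpoint(path, expect_config=ModelConfig(n_layers=2, d=128, n_heads=4))


def test_internal_order_reverses_and_places_nterm_mod_last():
    p = tokenize("+42.010565AGK")
    ids = internal_order_ids(p)
    from massnovo.vocabulary import TOKEN_INDEX

    assert ids == [TOKEN_INDEX["K"], TOKEN_INDEX["G"], TOKEN_INDEX["A"], TOKEN_INDEX["+42.010565"]]


def test_collate_labels_end_with_stop(noiseless_corpus):
    batch = collate(noiseless_corpus[:4])
    for i, s in enumerate(noiseless_corpus[:4]):
        n = len(s.annotation.tokens)
        assert batch.labels[i, n] == STOP_INDEX
        assert (batch.labels[i, n + 1 :] == -1).all()
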