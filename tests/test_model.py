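import numpy as np
import pytest

import specembed as se
from specembed.model import _split_replicates
from specembed.spectra_io import Spectrum


def _spec(peptide, title, charge=2, seed=0):
    base = se.predict_spectrum(peptide, charge)
    return base.copy_with(title=title)


class TestArchitecture:
    def test_default_config_has_six_blocks_and_256_latent(self, tiny_model):
        cfg = se.EncoderConfig()
        assert cfg.n_tcn_blocks == 6
        assert len(cfg.dilation_schedule) == 6
        assert cfg.latent_dim == 256
        assert len(tiny_model.encoder.blocks) == 6

    def test_channels_grow_by_factor(self):
        assert se.EncoderConfig().block_channels == (16, 24, 36, 54, 81, 122)

    def test_full_size_parameter_count_in_stated_band(self):
        model = se.SpecEmbedModel(se.EncoderConfig(), se.VectorizationConfig(), seed=0)
        n = model.encoder.n_parameters()
        assert 3.0e6 <= n <= 4.5e6

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            se.EncoderConfig(dilation_schedule=(1, 2, 4, 8, 16, 32))  # increasing
        with pytest.raises(ValueError):
            se.EncoderConfig(n_tcn_blocks=5)  # schedule length mismatch
        with pytest.raises(ValueError):
            se.LossConfig(am_margin=1.0)

    def test_embeddings_unit_norm_any_weights(self, tiny_model, rng):
        spectra = [_spec(p, f"s{i}") for i, p in enumerate(se.sample_peptides(8, (6, 12), rng))]
        vecs = tiny_model.embed_spectra(spectra)
        np.testing.assert_allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-5)
        pep_vec = tiny_model.embed_peptide("ACDEFGHK")
        assert pep_vec.shape == (256,)
        assert np.linalg.norm(pep_vec) == pytest.approx(1.0, abs=1e-5)


class TestEmbedding:
    def test_inference_is_deterministic(self, tiny_model):
        s = _spec("ACDEFGHK", "a")
        v1 = tiny_model.embed_spectra([s])
        v2 = tiny_model.embed_spectra([s])
        np.testing.assert_array_equal(v1, v2)

    def test_batch_size_invariance(self, tiny_model):
        spectra = [_spec(p, f"s{i}") for i, p in enumerate(se.sample_peptides(10, (6, 12), 3))]
        single = tiny_model.embed_spectra(spectra[:1])
        batched = tiny_model.embed_spectra(spectra, batch_size=10)
        np.testing.assert_allclose(single[0], batched[0], atol=1e-5)

    def test_charge_mismatch_reported_with_offenders(self, tiny_model):
        s3 = _spec("ACDEFGHK", "bad_title", charge=3)
        with pytest.raises(ValueError, match="bad_title"):
            tiny_model.embed_spectra([s3])

    def test_embedding_smoke_large_batch(self, tiny_model):
        spectra = [_spec("ACDEFGHK", f"s{i}") for i in range(300)]
        vecs = tiny_model.embed_spectra(spectra)
        assert vecs.shape == (300, 256)


class TestLossFunctions:
    def test_am_softmax_two_class_closed_form(self):
        """cos_y=0.9, cos_other=0.1, s=30, m=0.35:
        loss = -log(e^{30*0.55} / (e^{30*0.55} + e^{3}))."""
        spec = np.array([[0.9, 0.1]], dtype=np.float32)  # cos with the 2 anchors
        anchors = np.eye(2, dtype=np.float32)
        loss = se.am_softmax_loss(spec, anchors, np.array([0]), se.LossConfig())
        expect = -np.log(np.exp(30 * 0.55) / (np.exp(30 * 0.55) + np.exp(3.0)))
        assert loss == pytest.approx(float(expect), rel=1e-5)

    def test_reconstruction_loss_closed_forms(self, rng):
        target = rng.random((4, 32)).astype(np.float32)
        assert se.reconstruction_loss(target, target) == 0.0
        zero = np.zeros_like(target)
        assert se.reconstruction_loss(zero, target) == pytest.approx(
            float((target**2).mean()), rel=1e-6
        )
        with pytest.raises(ValueError):
            se.reconstruction_loss(zero[:, :8], target)


class TestReplicateHandling:
    def test_cap_limits_replicates_to_ten(self):
        spectra = [_spec("ACDEFGHK", f"a{i}") for i in range(15)]
        spectra += [_spec("LMNPQSTR", f"b{i}") for i in range(3)]
        rng = np.random.default_rng(0)
        classes, train_idx, val_idx, labels = _split_replicates(spectra, 10, rng)
        counts = {c: 0 for c in range(len(classes))}
        for lab in labels:
            counts[lab] += 1
        # capped at 10 minus the one held-out validation replicate
        assert max(counts.values()) == 9

    def test_singleton_peptides_dropped_entirely(self):
        spectra = [_spec("ACDEFGHK", "a0")]
        spectra += [_spec("LMNPQSTR", f"b{i}") for i in range(3)]
        spectra += [_spec("GGHHKKLR", f"c{i}") for i in range(2)]
        rng = np.random.default_rng(0)
        classes, train_idx, val_idx, _ = _split_replicates(spectra, 10, rng)
        assert "ACDEFGHK" not in classes
        assert len(classes) == 2
        assert len(val_idx) == 2  # one held out per multi-replicate peptide

    def test_mixed_charges_rejected(self):
        spectra = [_spec("ACDEFGHK", "a", 2), _spec("ACDEFGHK", "b", 3)]
        with pytest.raises(ValueError, match="mixed"):
            se.train(
                spectra,
                se.EncoderConfig.reduced(),
                se.VectorizationConfig.reduced(),
                training_config=se.TrainingConfig(charge=2, epochs=1),
            )

    def test_too_few_classes_rejected(self):
        spectra = [_spec("ACDEFGHK", f"a{i}") for i in range(4)]
        with pytest.raises(ValueError, match="classes"):
            se.train(
                spectra,
                se.EncoderConfig.reduced(),
                se.VectorizationConfig.reduced(),
                training_config=se.TrainingConfig(charge=2, epochs=1),
            )


class TestPersistence:
    def test_roundtrip_embeddings_bit_identical(self, tiny_model, tmp_path):
        probe = [_spec("ACDEFGHK", "p")]
        before = tiny_model.embed_spectra(probe)
        path = tmp_path / "w.npz"
        tiny_model.save(path)
        loaded = se.SpecEmbedModel.load(path)
        np.testing.assert_array_equal(before, loaded.embed_spectra(probe))

    def test_truncated_file_rejected(self, tiny_model, tmp_path):
        path = tmp_path / "w.npz"
        tiny_model.save(path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError):
            se.SpecEmbedModel.load(path)

    def test_config_mismatch_rejected(self, tiny_model, tmp_path):
        path = tmp_path / "w.npz"
        tiny_model.save(path)
        with pytest.raises(ValueError, match="match"):
            se.SpecEmbedModel.load(path, expect_config=se.EncoderConfig())


class TestTraining:
    def test_short_training_separates_a_few_classes(self):
        """A 10-peptide, 8-epoch run already pulls same-peptide embeddings
        together relative to different-peptide ones."""
        peptides, spectra = se.make_training_set(10, 4, 2, seed=7)
        result = se.train(
            spectra,
            se.EncoderConfig.reduced(),
            se.VectorizationConfig.reduced(),
            se.LossConfig(),
            se.TrainingConfig(charge=2, epochs=8, seed=7, batch_size=16),
        )
        assert len(result.history) == 8
        assert result.n_classes == 10
        model = result.model
        by_pep: dict[str, list] = {}
        for s in spectra:
            by_pep.setdefault(s.peptide, []).append(s)
        same, diff = [], []
        vecs = {p: model.embed_spectra(reps) for p, reps in by_pep.items()}
        keys = list(vecs)
        for i, p in enumerate(keys):
            V = vecs[p]
            same.extend((V @ V.T)[np.triu_indices(len(V), 1)].tolist())
            for q in keys[i + 1 :]:
                diff.extend((vecs[p] @ vecs[q].T).ravel().tolist())
        assert np.mean(same) > np.mean(diff)

    def test_plain_adam_fallback_runs(self):
        peptides, spectra = se.make_training_set(5, 3, 2, seed=3)
        result = se.train(
            spectra,
            se.EncoderConfig.reduced(),
            se.VectorizationConfig.reduced(),
            se.LossConfig(),
            se.TrainingConfig(charge=2, epochs=2, seed=3, batch_size=8, use_radam=False),
        )
        assert np.isfinite(result.history["train_loss"]).all()
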