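import numpy as np
import pytest
from pyteomics import mass as pt_mass

import specembed as se
from specembed.synthetic import fragment_mz
from specembed.vectorize import bin_spectrum


class TestSamplePeptides:
    def test_distinct_tryptic_like(self):
        peps = se.sample_peptides(100, (8, 20), rng_seed=1)
        assert len(set(peps)) == 100
        assert all(p[-1] in "KR" for p in peps)
        assert all(8 <= len(p) <= 20 for p in peps)

    def test_deterministic(self):
        assert se.sample_peptides(20, (6, 10), 5) == se.sample_peptides(20, (6, 10), 5)

    def test_exact_length(self):
        assert all(len(p) == 6 for p in se.sample_peptides(3, (6, 6), 2))

    def test_infeasible_request_rejected(self):
        with pytest.raises(ValueError):
            se.sample_peptides(10**12, (6, 6), 0)


class TestPredictSpectrum:
    def test_dipeptide_fragment_mzs(self):
        """b1/y1 of 'AG': hand-computed from residue monoisotopic masses."""
        assert fragment_mz("AG", "b", 1) == pytest.approx(72.0444, abs=1e-4)
        assert fragment_mz("AG", "y", 1) == pytest.approx(76.0393, abs=1e-4)

    def test_peak_count_is_2_l_minus_1(self):
        for pep in ("ACDEFGHK", "LMNPQSTVWYR"):
            spec = se.predict_spectrum(pep, 2)
            assert len(spec.peaks) == 2 * (len(pep) - 1)

    def test_deterministic(self):
        a = se.predict_spectrum("ACDEFGHK", 2)
        b = se.predict_spectrum("ACDEFGHK", 2)
        assert a.peaks == b.peaks
        assert a.precursor_mz == b.precursor_mz

    def test_fragments_match_independent_mass_oracle(self):
        """b/y m/z vs pyteomics' fragment calculator on 50 random peptides
        (carbamidomethyl handled via a fixed composition shift)."""
        cam = 57.021464
        for pep in se.sample_peptides(50, (6, 25), rng_seed=9):
            L = len(pep)
            for k in range(1, L):
                b_ref = pt_mass.fast_mass(pep[:k], ion_type="b", charge=1)
                b_ref += cam * pep[:k].count("C")
                y_ref = pt_mass.fast_mass(pep[-k:], ion_type="y", charge=1)
                y_ref += cam * pep[-k:].count("C")
                assert fragment_mz(pep, "b", k) == pytest.approx(b_ref, abs=1e-4)
                assert fragment_mz(pep, "y", k) == pytest.approx(y_ref, abs=1e-4)

    def test_doubly_charged_fragments(self):
        params = se.FragmentationParams(fragment_charges=(1, 2))
        spec = se.predict_spectrum("ACDEFGHK", 2, params)
        assert len(spec.peaks) == 4 * 7
        singly = fragment_mz("ACDEFGHK", "y", 4, 1)
        doubly = fragment_mz("ACDEFGHK", "y", 4, 2)
        assert doubly == pytest.approx((singly + 1.007276) / 2, abs=1e-6)


class TestMakeReplicates:
    def test_zero_noise_is_identity(self):
        spec = se.predict_spectrum("ACDEFGHK", 2)
        reps = se.make_replicates(spec, 3, se.ReplicateNoiseParams.quiet(), 0)
        for r in reps:
            assert r.peaks == spec.peaks
            assert r.peptide == spec.peptide

    def test_dropout_matches_binomial_expectation(self):
        spec = se.predict_spectrum("ACDEFGHLMNPQSTVWYDEFR", 2)  # 40 peaks
        n_peaks = len(spec.peaks)
        p_drop = 0.5
        params = se.ReplicateNoiseParams(
            intensity_cv=0, dropout_p=p_drop, n_noise_peaks=0, mz_jitter_sd=0
        )
        reps = se.make_replicates(spec, 1000, params, rng_seed=4)
        counts = np.array([len(r.peaks) for r in reps])
        expect = n_peaks * (1 - p_drop)
        sd = np.sqrt(n_peaks * p_drop * (1 - p_drop))
        assert abs(counts.mean() - expect) < 3 * sd / np.sqrt(1000)

    def test_zero_mz_jitter_keeps_mz_exact(self):
        spec = se.predict_spectrum("ACDEFGHK", 2)
        params = se.ReplicateNoiseParams(mz_jitter_sd=0, dropout_p=0, n_noise_peaks=0)
        (rep,) = se.make_replicates(spec, 1, params, 0)
        assert rep.mz == spec.mz

    def test_deterministic_given_seed(self):
        spec = se.predict_spectrum("ACDEFGHK", 2)
        a = se.make_replicates(spec, 5, rng_seed=3)
        b = se.make_replicates(spec, 5, rng_seed=3)
        assert all(x.peaks == y.peaks for x, y in zip(a, b))


class TestMakeBenchmark:
    def test_no_foreign_means_all_truth_in_library(self):
        bench = se.make_benchmark(20, 40, 0.0, seed=2)
        lib = set(bench.library_peptides)
        assert all(p in lib for p in bench.truth.values())

    def test_foreign_count_floor_rule(self):
        bench = se.make_benchmark(20, 201, 0.5, seed=2)
        n_foreign = sum(1 for v in bench.truth.values() if v == "foreign")
        assert n_foreign == 100

    def test_foreign_peptides_disjoint_from_library(self):
        bench = se.make_benchmark(20, 40, 0.5, seed=2)
        lib = set(bench.library_peptides)
        foreign_titles = [t for t, v in bench.truth.items() if v == "foreign"]
        assert len(foreign_titles) == 20
        for spec in bench.query_spectra:
            assert spec.peptide is None  # queries are unannotated

    def test_different_seeds_give_different_queries(self):
        a = se.make_benchmark(10, 20, 0.0, seed=1)
        b = se.make_benchmark(10, 20, 0.0, seed=2)
        assert any(
            x.peaks != y.peaks for x, y in zip(a.query_spectra, b.query_spectra)
        )


def test_same_peptide_replicates_more_similar_than_different(reduced_training_data):
    """Raw binned-cosine of same-peptide replicate pairs exceeds that of
    different-peptide pairs on average — the premise that a latent space can
    amplify."""
    _, spectra = reduced_training_data
    vc = se.VectorizationConfig.reduced()
    by_pep: dict[str, list] = {}
    for s in spectra:
        by_pep.setdefault(s.peptide, []).append(s)
    peps = list(by_pep)[:50]
    vecs = {}
    for p in peps:
        vs = np.stack([bin_spectrum(r, vc) for r in by_pep[p]])
        vecs[p] = vs / np.linalg.norm(vs, axis=1, keepdims=True)
    same, diff = [], []
    for i, p in enumerate(peps):
        V = vecs[p]
        same.extend((V @ V.T)[np.triu_indices(len(V), 1)].tolist())
        for q in peps[i + 1 : i + 4]:
            diff.extend((vecs[p] @ vecs[q].T).ravel().tolist())
    assert np.mean(same) > np.mean(diff)
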