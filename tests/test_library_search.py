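from collections import Counter

import numpy as np
import pandas as pd
import pytest

import specembed as se
from specembed import library_search as ls
from oracles import linear_scan_search


def _unit_rows(rng, n, d=8):
    v = rng.normal(size=(n, d)).astype(np.float32)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_library(rng, n=1000, d=8):
    peptides = se.sample_peptides(n, (6, 20), rng)
    charges = rng.choice([2, 3], size=n)
    masses = np.array([se.peptide_mass(p) for p in peptides])
    return ls.VectorLibrary(
        peptides=peptides,
        charges=charges,
        masses=masses,
        vectors=_unit_rows(rng, n, d),
        sources=["experimental"] * n,
        is_decoy=rng.random(n) < 0.5,
    )


class TestLibraryBuild:
    def test_annotated_spectra_become_entries_with_sequence_mass(self, tiny_model):
        peps = se.sample_peptides(10, (6, 12), 1)
        spectra = [se.predict_spectrum(p, 2) for p in peps]
        lib = ls.build_library_from_spectra(spectra, tiny_model)
        assert len(lib) == 10
        assert lib.sources == ["experimental"] * 10
        for i, p in enumerate(lib.peptides):
            assert lib.masses[i] == pytest.approx(se.peptide_mass(p), abs=1e-9)

    def test_unannotated_or_wrong_charge_skipped(self, tiny_model):
        peps = se.sample_peptides(3, (6, 12), 2)
        spectra = [se.predict_spectrum(p, 2) for p in peps]
        spectra[0] = spectra[0].copy_with(peptide=None)
        spectra[1] = se.predict_spectrum(peps[1], 3)
        lib = ls.build_library_from_spectra(spectra, tiny_model)
        assert len(lib) == 1

    def test_predicted_library_deterministic(self, tiny_model):
        peps = se.sample_peptides(4, (6, 12), 3)
        a = ls.build_library_from_peptides(peps, 2, tiny_model)
        b = ls.build_library_from_peptides(peps, 2, tiny_model)
        assert a.sources == ["predicted"] * 4
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_empty_peptide_list_gives_empty_library(self, tiny_model):
        lib = ls.build_library_from_peptides([], 2, tiny_model)
        assert len(lib) == 0


class TestDecoys:
    def test_decoys_preserve_length_composition_terminals(self, tiny_model):
        peps = se.sample_peptides(20, (8, 16), 4)
        target = ls.build_library_from_peptides(peps, 2, tiny_model)
        decoys = ls.make_decoys(target, tiny_model, rng_seed=0)
        assert len(decoys) == len(target)
        assert decoys.is_decoy.all()
        for t, d in zip(target.peptides, decoys.peptides):
            assert len(d) == len(t)
            assert Counter(d) == Counter(t)
            assert d[0] == t[0] and d[-1] == t[-1]

    def test_decoy_sequences_disjoint_from_targets(self, tiny_model):
        peps = se.sample_peptides(30, (8, 16), 5)
        target = ls.build_library_from_peptides(peps, 2, tiny_model)
        decoys = ls.make_decoys(target, tiny_model, rng_seed=1)
        assert not set(decoys.peptides) & set(target.peptides)

    def test_decoys_deterministic_given_seed(self, tiny_model):
        peps = se.sample_peptides(10, (8, 16), 6)
        target = ls.build_library_from_peptides(peps, 2, tiny_model)
        a = ls.make_decoys(target, tiny_model, rng_seed=9)
        b = ls.make_decoys(target, tiny_model, rng_seed=9)
        assert a.peptides == b.peptides


class TestHybridMerge:
    def test_experimental_wins_on_shared_peptides(self, tiny_model):
        p1, p2, p3 = se.sample_peptides(3, (8, 12), 7)
        exp = ls.build_library_from_spectra(
            [se.predict_spectrum(p, 2) for p in (p1, p2)], tiny_model
        )
        pred = ls.build_library_from_peptides([p2, p3], 2, tiny_model)
        merged = ls.merge_hybrid(exp, pred)
        assert set(merged.peptides) == {p1, p2, p3}
        src = dict(zip(merged.peptides, merged.sources))
        assert src[p2] == "experimental"
        assert src[p3] == "predicted"

    def test_disjoint_sets_union(self, tiny_model):
        a, b = se.sample_peptides(2, (8, 12), 8)
        exp = ls.build_library_from_spectra([se.predict_spectrum(a, 2)], tiny_model)
        pred = ls.build_library_from_peptides([b], 2, tiny_model)
        assert len(ls.merge_hybrid(exp, pred)) == 2

    def test_identical_sets_equal_experimental(self, tiny_model):
        peps = se.sample_peptides(3, (8, 12), 9)
        exp = ls.build_library_from_spectra(
            [se.predict_spectrum(p, 2) for p in peps], tiny_model
        )
        pred = ls.build_library_from_peptides(peps, 2, tiny_model)
        merged = ls.merge_hybrid(exp, pred)
        assert merged.peptides == exp.peptides
        np.testing.assert_array_equal(merged.vectors, exp.vectors)


class TestSearch:
    def test_identical_vector_scores_one(self, rng):
        lib = _random_library(rng, n=50)
        i = 7
        query = se.predict_spectrum(lib.peptides[i], int(lib.charges[i]))
        results = ls.search([query], lib.vectors[i][None, :], lib, ppm_tol=10)
        assert results[0].peptide == lib.peptides[i]
        assert results[0].score == pytest.approx(1.0, abs=1e-6)

    def test_ppm_window_half_width(self, rng):
        lib = _random_library(rng, n=200)
        mz = 400.68726
        half = 10 * 1e-6 * mz
        assert half == pytest.approx(0.0040069, abs=1e-6)
        cand = lib.candidates(2, mz, 10)
        pm = lib.precursor_mz
        manual = [
            i
            for i in range(len(lib))
            if lib.charges[i] == 2 and abs(pm[i] - mz) <= half
        ]
        assert sorted(cand.tolist()) == manual

    def test_indexed_search_equals_linear_scan_oracle(self, rng):
        """Top hit and score identical to a dense linear scan on a
        1000-entry random library."""
        lib = _random_library(rng, n=1000)
        pm = lib.precursor_mz
        queries, qvecs = [], []
        for k in range(200):
            i = int(rng.integers(len(lib)))
            jitter = pm[i] * rng.uniform(-8e-6, 8e-6)
            queries.append(
                se.predict_spectrum(lib.peptides[i], int(lib.charges[i])).copy_with(
                    precursor_mz=float(pm[i] + jitter), title=f"q{k}"
                )
            )
            qvecs.append(_unit_rows(rng, 1, 8)[0])
        qvecs = np.stack(qvecs)
        results = {r.query_id: r for r in ls.search(queries, qvecs, lib, ppm_tol=10)}
        for q, v in zip(queries, qvecs):
            expect = linear_scan_search(
                q.precursor_mz, q.charge, v, lib.peptides, lib.charges,
                pm, lib.vectors, lib.is_decoy, 10.0,
            )
            if expect is None:
                assert q.title not in results
            else:
                r = results[q.title]
                assert (r.peptide, r.is_decoy, r.n_candidates) == (
                    expect[0], expect[2], expect[3],
                )
                assert r.score == pytest.approx(expect[1], abs=1e-7)

    def test_empty_library_rejected(self, rng, tiny_model):
        empty = ls.build_library_from_peptides([], 2, tiny_model)
        q = se.predict_spectrum("ACDEFGHK", 2)
        with pytest.raises(ValueError):
            ls.search([q], np.zeros((1, 256)), empty)

    def test_library_save_load_roundtrip(self, rng, tmp_path):
        lib = _random_library(rng, n=20)
        path = tmp_path / "lib.npz"
        lib.save(path)
        back = ls.VectorLibrary.load(path)
        assert back.peptides == lib.peptides
        np.testing.assert_array_equal(back.vectors, lib.vectors)
        np.testing.assert_array_equal(back.is_decoy, lib.is_decoy)


def _results(scores_t, scores_d):
    out = []
    for i, s in enumerate(scores_t):
        out.append(ls.VVMResult(f"t{i}", f"PEPT{i}K", s, False, 1, 2))
    for i, s in enumerate(scores_d):
        out.append(ls.VVMResult(f"d{i}", f"DECY{i}K", s, True, 1, 2))
    return out


class TestFdr:
    def test_hand_swept_example(self):
        """T:{0.9,0.8,0.7}, D:{0.75} -> q(0.9)=q(0.8)=0, q(0.7)=1/3."""
        table = ls.estimate_fdr(_results([0.9, 0.8, 0.7], [0.75]), level="psm").table
        q = dict(zip(table["score_threshold"], table["q_value"]))
        assert q[0.9] == 0.0
        assert q[0.8] == 0.0
        assert q[0.7] == pytest.approx(1 / 3)
        assert q[0.75] == pytest.approx(1 / 3)  # running-min of 0.5 and 1/3

    def test_all_targets_fdr_zero(self):
        table = ls.estimate_fdr(_results([0.9, 0.5, 0.1], []), level="psm").table
        assert (table["fdr"] == 0).all()

    def test_simple_ratio(self):
        scores_t = list(np.linspace(0.9, 0.5, 99))
        table = ls.estimate_fdr(_results(scores_t, [0.49]), level="psm").table
        row = table.iloc[-1]
        assert row["fdr"] == pytest.approx(1 / 99, abs=1e-9)

    def test_q_values_non_increasing_with_score(self, rng):
        res = _results(rng.random(50).tolist(), rng.random(50).tolist())
        table = ls.estimate_fdr(res, level="psm").table
        ordered = table.sort_values("score_threshold")
        assert (np.diff(ordered["q_value"].to_numpy()) <= 1e-12).all()

    def test_peptide_level_collapses_to_best_psm(self):
        res = [
            ls.VVMResult("q1", "AAAAAAK", 0.9, False, 1, 2),
            ls.VVMResult("q2", "AAAAAAK", 0.6, False, 1, 2),
            ls.VVMResult("q3", "CCCCCCK", 0.7, True, 1, 2),
        ]
        table = ls.estimate_fdr(res, level="peptide").table
        assert len(table) == 2  # one row per unique peptide
        assert set(table["score_threshold"]) == {0.9, 0.7}

    def test_plus_one_variant(self):
        table = ls.estimate_fdr(_results([0.9], []), level="psm", plus_one=True).table
        assert table["fdr"].iloc[0] == 1.0


class TestApplyCutoff:
    def test_alpha_one_accepts_all_targets(self):
        res = _results([0.9, 0.5], [0.7])
        fdr = ls.estimate_fdr(res, level="psm")
        acc = ls.apply_cutoff(res, fdr, alpha=1.0)
        assert acc.n_psm == 2
        assert all(not r.is_decoy for r in acc.results)

    def test_unreachable_alpha_accepts_nothing(self):
        """When only a decoy outscores every target, no target survives the
        cutoff (the q<=alpha threshold sits above all target scores)."""
        res = _results([0.5], [0.9])
        fdr = ls.estimate_fdr(res, level="psm")
        acc = ls.apply_cutoff(res, fdr, alpha=0.01)
        assert acc.n_psm == 0 and acc.n_unique_peptides == 0

    def test_shrinking_alpha_is_monotone(self, rng):
        res = _results(rng.uniform(0.5, 1, 80).tolist(), rng.uniform(0, 0.8, 40).tolist())
        fdr = ls.estimate_fdr(res, level="psm")
        prev = None
        for alpha in (0.5, 0.2, 0.1, 0.05, 0.01):
            acc = ls.apply_cutoff(res, fdr, alpha=alpha)
            ids = {r.query_id for r in acc.results}
            if prev is not None:
                assert ids <= prev
            prev = ids
            assert acc.n_unique_peptides <= acc.n_psm
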