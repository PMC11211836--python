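"""Hybrid search: merge an (incomplete) experimental spectral library with
predicted spectra of database peptides and search both in one latent space.

The experimental library covers only half the peptides the queries come
from; the predicted-spectrum library fills the gap.  Where both cover a
peptide, the experimental vector wins.
"""

import specembed as se
from specembed import library_search as ls
from specembed.evaluate import score_against_truth

peptides, spectra = se.make_training_set(n_peptides=40, n_replicates=5, charge=2, seed=4)
model = se.train(
    spectra,
    se.EncoderConfig.reduced(),
    se.VectorizationConfig.reduced(),
    se.LossConfig(),
    se.TrainingConfig(charge=2, epochs=12, seed=4),
).model

bench = se.make_benchmark(
    n_queries=120, foreign_fraction=0.0, charge=2, seed=4, library_peptides=peptides
)
covered = set(peptides[:20])  # experimental spectra exist for half the peptides
exp_lib = ls.build_library_from_spectra(
    [s for s in bench.library_spectra if s.peptide in covered], model
)
pred_lib = ls.build_library_from_peptides(peptides, charge=2, model=model)
qvecs = model.embed_spectra(bench.query_spectra)


def accepted_correct(lib: ls.VectorLibrary) -> int:
    comb = ls.combine(lib, ls.make_decoys(lib, model, rng_seed=4))
    res = ls.search(bench.query_spectra, qvecs, comb, ppm_tol=10.0)
    acc = ls.apply_cutoff(res, ls.estimate_fdr(res, level="peptide"), alpha=0.05)
    return score_against_truth(acc.results, bench.truth).n_correct_unique_peptides


print(f"library-only (20 peptides covered): "
      f"{accepted_correct(exp_lib)} correct unique peptides")
print(f"hybrid (experimental + predicted) : "
      f"{accepted_correct(ls.merge_hybrid(exp_lib, pred_lib))} correct unique peptides")
# hybrid recovers peptides the experimental library never saw, at the same
# peptide-level FDR control
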