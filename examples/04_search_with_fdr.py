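"""The full search workflow: train, build target+decoy vector libraries,
search queries, and control the peptide-level FDR by target-decoy
competition.

Half the queries here are "foreign" — spectra of peptides absent from the
library — so the run also shows how the precursor-mass window and decoy
competition keep false discoveries in check.
"""

import specembed as se
from specembed import library_search as ls
from specembed.evaluate import score_against_truth

# train a small model
peptides, spectra = se.make_training_set(n_peptides=40, n_replicates=5, charge=2, seed=3)
model = se.train(
    spectra,
    se.EncoderConfig.reduced(),
    se.VectorizationConfig.reduced(),
    se.LossConfig(),
    se.TrainingConfig(charge=2, epochs=12, seed=3),
).model

# labelled benchmark: 40-peptide library, 100 queries, 50% foreign
bench = se.make_benchmark(
    n_queries=100, foreign_fraction=0.5, charge=2, seed=3, library_peptides=peptides
)
target = ls.build_library_from_spectra(bench.library_spectra, model)
decoys = ls.make_decoys(target, model, rng_seed=3)
combined = ls.combine(target, decoys)

queries = bench.query_spectra
results = ls.search(queries, model.embed_spectra(queries), combined, ppm_tol=10.0)
print(f"{len(results)} of {len(queries)} queries had a candidate within 10 ppm")
# foreign queries rarely match any library precursor mass, so most drop here

fdr = ls.estimate_fdr(results, level="peptide")
accepted = ls.apply_cutoff(results, fdr, alpha=0.01)
print(f"score threshold at peptide q<=0.01: {accepted.threshold:.4f}")
print(f"accepted: {accepted.n_psm} PSMs, {accepted.n_unique_peptides} unique peptides")

score = score_against_truth(accepted.results, bench.truth)
print(f"of which correct: {score.n_correct} "
      f"(true false-discovery proportion {score.false_discovery_proportion:.3f})")
# the true FDP should sit at or below the 1% target, up to binomial noise
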