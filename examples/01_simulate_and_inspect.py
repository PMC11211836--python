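"""Generate synthetic HCD-like replicate spectra and look at one.

The simulator predicts b/y fragment spectra for tryptic-like peptides and
then perturbs them with intensity jitter, peak dropout, m/z jitter and
noise peaks — the replicate-to-replicate variation real libraries show.
"""

import specembed as se

peptides, spectra = se.make_training_set(
    n_peptides=5, n_replicates=3, charge=2, seed=1
)
print(f"{len(peptides)} peptides, {len(spectra)} replicate spectra\n")

spec = spectra[0]
print(f"peptide   : {spec.peptide}")
print(f"precursor : m/z {spec.precursor_mz:.4f}, charge {spec.charge}+")
print(f"peaks     : {len(spec.peaks)} (theoretical b/y ions + noise)")
for mz, inten in spec.peaks[:5]:
    print(f"   {mz:9.4f}  {inten:.3f}")
print("...")
# The m/z values are fragment masses of the annotated peptide; intensities
# are relative to the strongest peak of the clean prediction.
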