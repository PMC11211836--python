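"""In-silico tryptic digestion of a small FASTA database.

Cleaves after K/R (not before P), up to two missed cleavages, keeps
peptides of 6-30 residues, and reports monoisotopic masses with fixed
carbamidomethyl on cysteine.
"""

from pathlib import Path

import specembed as se
from specembed.digest import il_ambiguous_groups

fasta = Path("example_proteins.fasta")
fasta.write_text(
    ">sp|DEMO1|ALBU Synthetic demo protein\n"
    "MKWVTFISLLLLFSSAYSRGVFRRDTHKSEIAHRFKDLGEEHFK\n"
    ">sp|DEMO2|KRAS Synthetic demo protein\n"
    "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAGQEEYSAMRDQYMRTGEGFLCVFAINNTKSFEDIHHYREQIKR\n"
)

peptides = se.digest_proteins(se.read_fasta(fasta))
print(f"{len(peptides)} peptides (6-30 aa, <=2 missed cleavages)\n")
print("sequence                        mass (Da)  missed  proteins")
for p in peptides[:10]:
    accs = ";".join(sorted(p.protein_accessions))
    print(f"{p.sequence:<30}  {p.neutral_mass:9.4f}  {p.n_missed:>6}  {accs}")

groups = il_ambiguous_groups(peptides)
print(f"\nI/L-ambiguous sequence groups: {len(groups)}")
# Peptides sharing an I->L collapsed form cannot be told apart by mass or
# (usually) fragmentation; the report flags them for downstream care.

fasta.unlink()
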