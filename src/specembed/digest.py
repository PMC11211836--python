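"""In-silico tryptic digestion of proteins into candidate peptides.

Cleavage after K/R (suppressed before proline by default), up to two missed
cleavages, peptide length 6-30, fixed carbamidomethyl on C.  Peptides are
deduplicated by sequence across proteins, merging protein accessions and
keeping the minimum missed-cleavage count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .masses import mz_from_mass, peptide_neutral_mass
from .spectra_io import ProteinRecord


@dataclass(frozen=True)
class DigestConfig:
    missed_cleavages_max: int = 2
    len_min: int = 6
    len_max: int = 30
    charges: tuple[int, ...] = (2, 3)
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if self.missed_cleavages_max < 0:
            raise ValueError("missed_cleavages_max must be >= 0")


@dataclass
class Peptide:
    sequence: str
    n_missed: int
    neutral_mass: float
    protein_accessions: set[str] = field(default_factory=set)


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Indices i such that trypsin cuts between sequence[i-1] and sequence[i]."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P"):
            sites.append(i)
    return sites


def digest_protein(protein: ProteinRecord, config: DigestConfig = DigestConfig()) -> list[Peptide]:
    """Tryptic peptides of one protein with up to the configured missed
    cleavages, filtered by length and deduplicated by sequence."""
    seq = protein.sequence
    bounds = [0] + cleavage_sites(seq, config.proline_rule) + [len(seq)]
    by_seq: dict[str, Peptide] = {}
    n_frag = len(bounds) - 1
    for start_i in range(n_frag):
        for n_missed in range(config.missed_cleavages_max + 1):
            end_i = start_i + n_missed + 1
            if end_i > n_frag:
                break
            pep = seq[bounds[start_i]:bounds[end_i]]
            if not config.len_min <= len(pep) <= config.len_max:
                continue
            hit = by_seq.get(pep)
            if hit is None:
                try:
                    mass = peptide_neutral_mass(pep)
                except ValueError:
                    continue  # non-standard residue slipped through (lenient FASTA mode)
                by_seq[pep] = Peptide(
                    sequence=pep,
                    n_missed=n_missed,
                    neutral_mass=mass,
                    protein_accessions={protein.accession},
                )
            else:
                hit.n_missed = min(hit.n_missed, n_missed)
                hit.protein_accessions.add(protein.accession)
    return sorted(by_seq.values(), key=lambda p: p.sequence)


def digest_proteins(
    proteins: Iterable[ProteinRecord], config: DigestConfig = DigestConfig()
) -> list[Peptide]:
    """Digest many proteins, merging duplicate sequences across proteins."""
    by_seq: dict[str, Peptide] = {}
    for protein in proteins:
        for pep in digest_protein(protein, config):
            hit = by_seq.get(pep.sequence)
            if hit is None:
                by_seq[pep.sequence] = pep
            else:
                hit.n_missed = min(hit.n_missed, pep.n_missed)
                hit.protein_accessions |= pep.protein_accessions
    return sorted(by_seq.values(), key=lambda p: p.sequence)


def il_ambiguous_groups(peptides: Iterable[Peptide]) -> dict[str, list[str]]:
    """Group peptide sequences that collapse under I=L; groups with more
    than one member are reported so users know which identifications are
    isobarically ambiguous.  I and L stay distinct everywhere else."""
    groups: dict[str, list[str]] = {}
    for pep in peptides:
        groups.setdefault(pep.sequence.replace("I", "L"), []).append(pep.sequence)
    return {k: sorted(v) for k, v in groups.items() if len(v) > 1}


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass, fixed carbamidomethyl-C included."""
    return peptide_neutral_mass(sequence)


def precursor_mz(neutral_mass: float, charge: int) -> float:
    return mz_from_mass(neutral_mass, charge)
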