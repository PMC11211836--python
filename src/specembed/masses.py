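"""Monoisotopic mass constants for peptide/fragment arithmetic.

Cysteine carries the fixed carbamidomethyl modification (+57.021464 Da)
throughout the package: ``C`` always denotes carbamidomethyl-cysteine.
"""

from __future__ import annotations

PROTON = 1.007276
WATER = 18.010565
CARBAMIDOMETHYL = 57.021464

# Standard residue monoisotopic masses (Da); C includes the fixed mod.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919 + CARBAMIDOMETHYL,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}


def peptide_neutral_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide (Da), fixed mods included."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    try:
        return sum(RESIDUE_MASS[a] for a in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge
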