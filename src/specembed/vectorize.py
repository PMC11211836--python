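"""Deterministic transforms from spectra and peptides into model inputs.

A spectrum becomes a 20 000-dimensional binned intensity vector (0.1-Da
bins over [0, 2000) Da), zero-padded to 20 480; the padded vector and its
element-wise reversal form the two input channels of the encoder.  Meta
information (charge one-hot, scaled precursor mass, scaled NCE) rides in a
small side vector.  Peptides become 30x20 one-hot matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masses import AA_INDEX, AMINO_ACIDS, PROTON
from .spectra_io import Spectrum

MAX_PEPTIDE_LEN = 30
N_AMINO_ACIDS = len(AMINO_ACIDS)
META_DIM = 7  # 4 charge bits + precursor + nce + nce-present flag
PRECURSOR_MASS_SCALE = 5000.0  # Da; keeps tryptic neutral masses in [0, 1]
NCE_SCALE = 100.0


@dataclass(frozen=True)
class VectorizationConfig:
    bin_width: float = 0.1
    mz_min: float = 0.0
    mz_max: float = 2000.0
    padded_len: int = 20480
    aggregate: str = "sum"  # or "max"
    normalize: str = "basepeak"  # or "l2"

    @property
    def n_bins(self) -> int:
        return int(round((self.mz_max - self.mz_min) / self.bin_width))

    def __post_init__(self) -> None:
        if self.padded_len < self.n_bins:
            raise ValueError("padded_len must be >= n_bins")
        if self.aggregate not in ("sum", "max"):
            raise ValueError("aggregate must be 'sum' or 'max'")
        if self.normalize not in ("basepeak", "l2"):
            raise ValueError("normalize must be 'basepeak' or 'l2'")

    @classmethod
    def reduced(cls) -> "VectorizationConfig":
        """Desk-scale config: 0.5-Da bins over [0, 1000) padded to 2048."""
        return cls(bin_width=0.5, mz_max=1000.0, padded_len=2048)


@dataclass
class InputMatrix:
    binned: np.ndarray  # (padded_len,)
    reversed: np.ndarray  # element-wise reversal of `binned`
    meta: np.ndarray  # (META_DIM,)
    empty: bool = False


@dataclass
class PeptideOneHot:
    matrix: np.ndarray  # (30, 20) binary
    length: int


def bin_spectrum(spectrum: Spectrum, config: VectorizationConfig) -> np.ndarray:
    """Bin a peak list into the padded intensity vector.

    Peak at m/z x lands in bin floor((x - mz_min)/bin_width); peaks outside
    [mz_min, mz_max) are dropped; same-bin intensities combine by the
    configured aggregate; the result is normalized (base peak -> 1 by
    default).  An empty spectrum yields the all-zero vector.
    """
    out = np.zeros(config.padded_len, dtype=np.float32)
    if not spectrum.peaks:
        return out
    mz = np.asarray(spectrum.mz)
    inten = np.asarray(spectrum.intensity)
    keep = (mz >= config.mz_min) & (mz < config.mz_max)
    if not keep.any():
        return out
    idx = np.floor((mz[keep] - config.mz_min) / config.bin_width).astype(np.int64)
    if config.aggregate == "sum":
        np.add.at(out, idx, inten[keep].astype(np.float32))
    else:
        np.maximum.at(out, idx, inten[keep].astype(np.float32))
    if config.normalize == "basepeak":
        peak = out.max()
        if peak > 0:
            out /= peak
    else:
        norm = np.linalg.norm(out)
        if norm > 0:
            out /= norm
    return out


def make_meta_vector(spectrum: Spectrum) -> np.ndarray:
    meta = np.zeros(META_DIM, dtype=np.float32)
    meta[spectrum.charge - 1] = 1.0
    neutral = spectrum.precursor_mz * spectrum.charge - spectrum.charge * PROTON
    meta[4] = min(neutral / PRECURSOR_MASS_SCALE, 1.0)
    if spectrum.nce is not None:
        meta[5] = min(spectrum.nce / NCE_SCALE, 1.0)
        meta[6] = 1.0
    return meta


def make_input_matrix(spectrum: Spectrum, config: VectorizationConfig) -> InputMatrix:
    binned = bin_spectrum(spectrum, config)
    return InputMatrix(
        binned=binned,
        reversed=binned[::-1].copy(),
        meta=make_meta_vector(spectrum),
        empty=not binned.any(),
    )


def encode_peptide(peptide: str) -> PeptideOneHot:
    """One-hot encode a peptide, zero-padded to 30 rows.

    Residues beyond position 30 or outside the 20-letter alphabet are hard
    errors (C always denotes carbamidomethyl-cysteine).
    """
    if not 1 <= len(peptide) <= MAX_PEPTIDE_LEN:
        raise ValueError(f"peptide length {len(peptide)} outside 1..{MAX_PEPTIDE_LEN}")
    mat = np.zeros((MAX_PEPTIDE_LEN, N_AMINO_ACIDS), dtype=np.float32)
    for row, residue in enumerate(peptide):
        try:
            mat[row, AA_INDEX[residue]] = 1.0
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} in {peptide!r}") from None
    return PeptideOneHot(matrix=mat, length=len(peptide))


def add_gaussian_noise(
    binned: np.ndarray, sigma: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Training-time augmentation: add N(0, sigma * basepeak) per element and
    clip at zero.  Never applied at inference.  Deterministic given a seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if sigma == 0:
        return binned.copy()
    scale = sigma * float(binned.max()) if binned.any() else sigma
    noisy = binned + rng.normal(0.0, scale, size=binned.shape).astype(binned.dtype)
    return np.clip(noisy, 0.0, None)
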