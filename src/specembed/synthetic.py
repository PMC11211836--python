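"""Synthetic tryptic peptides and HCD-like spectra.

This simulator makes every downstream stage (training, library/database/
hybrid search, FDR control) runnable with no external data.  It generates
tryptic-like peptides, theoretical b/y fragment spectra with a bell-shaped
positional intensity profile (a deliberately crude HCD caricature standing
in for a learned intensity predictor), and noisy "experimental" replicates
with multiplicative intensity jitter, peak dropout, m/z jitter and random
noise peaks — the kinds of variation that make replicate spectra of one
peptide disagree.

It emulates: b/y dominance of HCD, mid-sequence fragments being strongest,
y-series exceeding b-series, replicate-to-replicate intensity variation.
It does NOT emulate: learned sequence-specific intensities, neutral losses,
isotope envelopes, a/c/x/z ions, co-isolation — so results on this data
bound what the method can do on real spectra only qualitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .masses import PROTON, RESIDUE_MASS, WATER, mz_from_mass, peptide_neutral_mass
from .spectra_io import Spectrum

_RESIDUES = "ACDEFGHILMNPQSTVWY"  # interior draw; K/R reserved for the C-terminus


@dataclass(frozen=True)
class FragmentationParams:
    """Theoretical-spectrum generator settings (the predicted-spectrum
    stand-in used for database-mode and decoy libraries)."""

    ion_series: tuple[str, ...] = ("b", "y")
    series_weights: tuple[float, ...] = (1.0, 1.5)  # y stronger than b in HCD
    fragment_charges: tuple[int, ...] = (1,)
    profile_width: float = 0.25  # Gaussian width of the positional bell, x sequence length
    basepeak_scale: float = 1.0
    nce: float | None = 27.0

    def __post_init__(self) -> None:
        if not self.ion_series:
            raise ValueError("at least one ion series required")
        if len(self.series_weights) != len(self.ion_series):
            raise ValueError("one weight per ion series")
        if any(w <= 0 for w in self.series_weights):
            raise ValueError("series weights must be > 0")


@dataclass(frozen=True)
class ReplicateNoiseParams:
    """Experimental-variation model for replicate spectra.

    Defaults are set so replicate pairs of one peptide span a broad range of
    raw binned-vector cosine similarities (most above 0.5, a tail below),
    mimicking the replicate disagreement real libraries show.
    """

    intensity_cv: float = 0.8  # sigma of log-normal multiplicative jitter
    dropout_p: float = 0.2  # per-peak loss probability
    n_noise_peaks: int = 15  # uniform-m/z low-intensity contaminants
    noise_intensity_max: float = 0.15  # x base peak
    mz_jitter_sd: float = 0.005  # Da
    noise_mz_range: tuple[float, float] = (100.0, 980.0)

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.mz_jitter_sd < 0 or self.n_noise_peaks < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @classmethod
    def quiet(cls) -> "ReplicateNoiseParams":
        return cls(intensity_cv=0.0, dropout_p=0.0, n_noise_peaks=0, mz_jitter_sd=0.0)


@dataclass
class BenchmarkSet:
    """A labelled library + query set; every non-foreign query's peptide is
    in the library, foreign queries have no correct answer."""

    library_spectra: list[Spectrum]
    query_spectra: list[Spectrum]
    truth: dict[str, str]  # query title -> peptide sequence or "foreign"
    seed: int
    library_peptides: list[str] = field(default_factory=list)


def sample_peptides(
    n: int,
    length_range: tuple[int, int] = (8, 20),
    rng_seed: int | np.random.Generator = 0,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> list[str]:
    """Draw n distinct tryptic-like peptides (uniform residues, K/R ending)."""
    lo, hi = length_range
    if lo < 6 or hi > 30 or lo > hi:
        raise ValueError("length_range must satisfy 6 <= lo <= hi <= 30")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    feasible = sum(len(_RESIDUES) ** (L - 1) * 2 for L in range(lo, hi + 1))
    if n > feasible:
        raise ValueError(f"cannot draw {n} distinct peptides from {feasible} possible")
    out: list[str] = []
    seen: set[str] = set(exclude)
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise ValueError("failed to draw enough distinct peptides")
        L = int(rng.integers(lo, hi + 1))
        body = "".join(_RESIDUES[i] for i in rng.integers(0, len(_RESIDUES), size=L - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out


def fragment_mz(peptide: str, kind: str, k: int, z: int = 1) -> float:
    """Monoisotopic m/z of the b_k or y_k fragment at charge z."""
    if kind == "b":
        mass = sum(RESIDUE_MASS[a] for a in peptide[:k]) + PROTON
    elif kind == "y":
        mass = sum(RESIDUE_MASS[a] for a in peptide[-k:]) + WATER + PROTON
    else:
        raise ValueError(f"unknown ion series {kind!r}")
    return (mass + (z - 1) * PROTON) / z


def predict_spectrum(
    peptide: str,
    charge: int,
    params: FragmentationParams | None = None,
) -> Spectrum:
    """Deterministic theoretical HCD spectrum: all b/y cleavage fragments at
    the enabled fragment charges, intensities from a Gaussian bell over the
    cleavage position (mid-sequence strongest)."""
    params = params or FragmentationParams()
    if charge not in (2, 3):
        raise ValueError("predicted spectra support precursor charge 2 or 3")
    L = len(peptide)
    if L < 2:
        raise ValueError("peptide too short to fragment")
    mid = (L - 1) / 2.0
    width = max(params.profile_width * L, 1.0)
    peaks: list[tuple[float, float]] = []
    for series, weight in zip(params.ion_series, params.series_weights):
        for k in range(1, L):
            pos = math.exp(-0.5 * ((k - mid) / width) ** 2)
            for z in params.fragment_charges:
                peaks.append((fragment_mz(peptide, series, k, z), weight * pos / z))
    top = max(i for _, i in peaks)
    peaks = [(m, params.basepeak_scale * i / top) for m, i in peaks]
    return Spectrum(
        peaks=peaks,
        precursor_mz=mz_from_mass(peptide_neutral_mass(peptide), charge),
        charge=charge,
        nce=params.nce,
        peptide=peptide,
        title=f"pred|{peptide}/{charge}",
    )


def make_replicates(
    spectrum: Spectrum,
    k: int,
    noise_params: ReplicateNoiseParams | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> list[Spectrum]:
    """k independently jittered replicates of a spectrum (annotation kept)."""
    np_ = noise_params or ReplicateNoiseParams()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    mz = np.asarray(spectrum.mz)
    inten = np.asarray(spectrum.intensity)
    base = inten.max() if inten.size else 1.0
    out: list[Spectrum] = []
    for r in range(k):
        if np_.intensity_cv > 0:
            jit = inten * np.exp(rng.normal(0.0, np_.intensity_cv, size=inten.shape))
        else:
            jit = inten.copy()
        if np_.mz_jitter_sd > 0:
            jmz = mz + rng.normal(0.0, np_.mz_jitter_sd, size=mz.shape)
        else:
            jmz = mz.copy()
        if np_.dropout_p > 0:
            keep = rng.random(size=mz.shape) >= np_.dropout_p
            if not keep.any():
                keep[int(np.argmax(jit))] = True  # never drop every peak
        else:
            keep = np.ones(mz.shape, dtype=bool)
        peaks = list(zip(jmz[keep].tolist(), jit[keep].tolist()))
        if np_.n_noise_peaks > 0:
            lo, hi = np_.noise_mz_range
            nmz = rng.uniform(lo, hi, size=np_.n_noise_peaks)
            nint = rng.uniform(0.0, np_.noise_intensity_max * base, size=np_.n_noise_peaks)
            peaks.extend(zip(nmz.tolist(), nint.tolist()))
        out.append(
            spectrum.copy_with(
                peaks=peaks,
                title=f"{spectrum.title}|rep{r}" if spectrum.title else f"rep{r}",
            )
        )
    return out


def make_benchmark(
    n_lib_peptides: int = 100,
    n_queries: int = 500,
    foreign_fraction: float = 0.5,
    charge: int = 2,
    frag_params: FragmentationParams | None = None,
    noise_params: ReplicateNoiseParams | None = None,
    seed: int = 0,
    library_peptides: list[str] | None = None,
    length_range: tuple[int, int] = (8, 20),
) -> BenchmarkSet:
    """Build a labelled search benchmark.

    Library = one noisy replicate per library peptide (annotated).  Queries
    = fresh replicates of randomly chosen library peptides plus replicates
    of foreign peptides (disjoint from the library) in the stated fraction;
    foreign query count = floor(foreign_fraction * n_queries).  Query
    spectra carry no annotation; ground truth lives in the ``truth`` map.
    """
    if not 0 <= foreign_fraction < 1:
        raise ValueError("foreign_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frag = frag_params or FragmentationParams()
    noise = noise_params or ReplicateNoiseParams()
    if library_peptides is None:
        library_peptides = sample_peptides(n_lib_peptides, length_range, rng)
    else:
        library_peptides = list(library_peptides)
    n_foreign = int(math.floor(foreign_fraction * n_queries))
    n_true = n_queries - n_foreign
    foreign_peptides = sample_peptides(
        n_foreign, length_range, rng, exclude=frozenset(library_peptides)
    ) if n_foreign else []

    library_spectra = []
    for pep in library_peptides:
        ideal = predict_spectrum(pep, charge, frag)
        rep = make_replicates(ideal, 1, noise, rng)[0]
        library_spectra.append(rep.copy_with(title=f"lib|{pep}/{charge}"))

    query_spectra: list[Spectrum] = []
    truth: dict[str, str] = {}
    picks = rng.integers(0, len(library_peptides), size=n_true)
    for qi, pick in enumerate(picks):
        pep = library_peptides[int(pick)]
        rep = make_replicates(predict_spectrum(pep, charge, frag), 1, noise, rng)[0]
        title = f"query_{qi:05d}"
        query_spectra.append(rep.copy_with(title=title, peptide=None))
        truth[title] = pep
    for fi, pep in enumerate(foreign_peptides):
        rep = make_replicates(predict_spectrum(pep, charge, frag), 1, noise, rng)[0]
        title = f"query_{n_true + fi:05d}"
        query_spectra.append(rep.copy_with(title=title, peptide=None))
        truth[title] = "foreign"

    return BenchmarkSet(
        library_spectra=library_spectra,
        query_spectra=query_spectra,
        truth=truth,
        seed=seed,
        library_peptides=library_peptides,
    )


def make_training_set(
    n_peptides: int = 100,
    n_replicates: int = 6,
    charge: int = 2,
    frag_params: FragmentationParams | None = None,
    noise_params: ReplicateNoiseParams | None = None,
    seed: int = 1,
    length_range: tuple[int, int] = (8, 20),
) -> tuple[list[str], list[Spectrum]]:
    """Annotated replicate spectra for metric-learning training."""
    rng = np.random.default_rng(seed)
    frag = frag_params or FragmentationParams()
    noise = noise_params or ReplicateNoiseParams()
    peptides = sample_peptides(n_peptides, length_range, rng)
    spectra: list[Spectrum] = []
    for pep in peptides:
        ideal = predict_spectrum(pep, charge, frag)
        spectra.extend(make_replicates(ideal, n_replicates, noise, rng))
    return peptides, spectra
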