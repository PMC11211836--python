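"""Vector libraries, unified latent-space search, and target-decoy FDR.

A vector library holds one unit-norm latent vector per (peptide, charge)
entry, whether the vector came from an embedded experimental spectrum, an
embedded predicted spectrum (database mode), or a merged hybrid of the two.
Searching compares a query embedding against all library entries with
matching charge and precursor m/z within a ppm tolerance and reports the
top cosine hit, target or decoy alike; decoy hit rates then estimate the
false discovery rate by target-decoy competition at the peptide level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .masses import mz_from_mass, peptide_neutral_mass
from .spectra_io import Spectrum
from .synthetic import FragmentationParams, predict_spectrum

log = logging.getLogger(__name__)

Predictor = Callable[[str, int], Spectrum]


def default_predictor(peptide: str, charge: int) -> Spectrum:
    return predict_spectrum(peptide, charge, FragmentationParams())


@dataclass
class VectorLibrary:
    """Columnar store of library entries with a per-charge sorted m/z index."""

    peptides: list[str]
    charges: np.ndarray  # int
    masses: np.ndarray  # neutral monoisotopic, Da
    vectors: np.ndarray  # (N, latent_dim) unit-norm rows
    sources: list[str]  # "experimental" | "predicted"
    is_decoy: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=np.int64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.is_decoy = np.asarray(self.is_decoy, dtype=bool)
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        self._index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for z in np.unique(self.charges):
            rows = np.where(self.charges == z)[0]
            mz = (self.masses[rows] + z * 1.007276) / z
            order = np.argsort(mz)
            self._index[int(z)] = (rows[order], mz[order])

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def precursor_mz(self) -> np.ndarray:
        return (self.masses + self.charges * 1.007276) / self.charges

    def candidates(self, charge: int, query_mz: float, ppm_tol: float) -> np.ndarray:
        """Row indices with matching charge and precursor m/z within tolerance."""
        if charge not in self._index:
            return np.empty(0, dtype=np.int64)
        rows, mz = self._index[charge]
        half = ppm_tol * 1e-6 * query_mz
        lo = np.searchsorted(mz, query_mz - half, side="left")
        hi = np.searchsorted(mz, query_mz + half, side="right")
        return rows[lo:hi]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            peptides=np.asarray(self.peptides),
            charges=self.charges,
            masses=self.masses,
            vectors=self.vectors,
            sources=np.asarray(self.sources),
            is_decoy=self.is_decoy,
        )

    @classmethod
    def load(cls, path: str | Path) -> "VectorLibrary":
        with np.load(path, allow_pickle=False) as d:
            return cls(
                peptides=[str(p) for p in d["peptides"]],
                charges=d["charges"],
                masses=d["masses"],
                vectors=d["vectors"],
                sources=[str(s) for s in d["sources"]],
                is_decoy=d["is_decoy"],
            )


def _concat_libraries(libs: Sequence[VectorLibrary]) -> VectorLibrary:
    libs = [l for l in libs if len(l)]
    if not libs:
        raise ValueError("no non-empty libraries to combine")
    dims = {l.vectors.shape[1] for l in libs}
    if len(dims) > 1:
        raise ValueError(f"latent dimension mismatch across libraries: {dims}")
    return VectorLibrary(
        peptides=sum((l.peptides for l in libs), []),
        charges=np.concatenate([l.charges for l in libs]),
        masses=np.concatenate([l.masses for l in libs]),
        vectors=np.concatenate([l.vectors for l in libs]),
        sources=sum((l.sources for l in libs), []),
        is_decoy=np.concatenate([l.is_decoy for l in libs]),
    )


def build_library_from_spectra(spectra: list[Spectrum], model) -> VectorLibrary:
    """Embed annotated experimental spectra into a target vector library.

    Unannotated spectra and spectra whose charge does not match the model
    are skipped with a warning.
    """
    kept = []
    n_skipped = 0
    for s in spectra:
        if not s.peptide or s.charge != model.charge:
            n_skipped += 1
            continue
        kept.append(s)
    if n_skipped:
        log.warning("build_library_from_spectra: skipped %d spectra", n_skipped)
    if not kept:
        return VectorLibrary([], np.empty(0, int), np.empty(0),
                             np.zeros((0, model.encoder_config.latent_dim)), [], np.empty(0, bool))
    vectors = model.embed_spectra(kept)
    return VectorLibrary(
        peptides=[s.peptide for s in kept],
        charges=np.asarray([s.charge for s in kept]),
        masses=np.asarray([peptide_neutral_mass(s.peptide) for s in kept]),
        vectors=vectors,
        sources=["experimental"] * len(kept),
        is_decoy=np.zeros(len(kept), dtype=bool),
    )


def build_library_from_peptides(
    peptides: Sequence[str],
    charge: int,
    model,
    predictor: Predictor = default_predictor,
) -> VectorLibrary:
    """Predict a spectrum per peptide and embed it (database mode)."""
    peptides = list(peptides)
    if not peptides:
        log.warning("build_library_from_peptides: empty peptide list")
        return VectorLibrary([], np.empty(0, int), np.empty(0),
                             np.zeros((0, model.encoder_config.latent_dim)), [], np.empty(0, bool))
    spectra = [predictor(p, charge) for p in peptides]
    vectors = model.embed_spectra(spectra)
    return VectorLibrary(
        peptides=peptides,
        charges=np.full(len(peptides), charge),
        masses=np.asarray([peptide_neutral_mass(p) for p in peptides]),
        vectors=vectors,
        sources=["predicted"] * len(peptides),
        is_decoy=np.zeros(len(peptides), dtype=bool),
    )


def shuffle_decoy(peptide: str, rng: np.random.Generator) -> str:
    """Shuffle interior residues, keeping the first and last fixed."""
    if len(peptide) <= 3:
        return peptide
    interior = list(peptide[1:-1])
    rng.shuffle(interior)
    return peptide[0] + "".join(interior) + peptide[-1]


def make_decoys(
    library: VectorLibrary,
    model,
    rng_seed: int = 0,
    predictor: Predictor = default_predictor,
    max_tries: int = 20,
) -> VectorLibrary:
    """One decoy per target: interior-shuffled sequence (same length,
    composition, terminal residues, hence same mass), re-predicted and
    re-embedded.  Decoys colliding with any target sequence are re-shuffled
    up to ``max_tries`` times, then dropped with a warning."""
    rng = np.random.default_rng(rng_seed)
    target_set = set(library.peptides)
    decoy_peps: list[str] = []
    decoy_charges: list[int] = []
    for pep, z, dec in zip(library.peptides, library.charges, library.is_decoy):
        if dec:
            continue
        for _ in range(max_tries):
            cand = shuffle_decoy(pep, rng)
            if cand != pep and cand not in target_set:
                decoy_peps.append(cand)
                decoy_charges.append(int(z))
                break
        else:
            log.warning("make_decoys: no valid decoy for %s after %d tries", pep, max_tries)
    if not decoy_peps:
        raise ValueError("no decoys could be generated")
    spectra = [predictor(p, z) for p, z in zip(decoy_peps, decoy_charges)]
    vectors = model.embed_spectra(spectra, check_charge=False)
    return VectorLibrary(
        peptides=decoy_peps,
        charges=np.asarray(decoy_charges),
        masses=np.asarray([peptide_neutral_mass(p) for p in decoy_peps]),
        vectors=vectors,
        sources=["predicted"] * len(decoy_peps),
        is_decoy=np.ones(len(decoy_peps), dtype=bool),
    )


def merge_hybrid(experimental: VectorLibrary, predicted: VectorLibrary) -> VectorLibrary:
    """Union keyed by (peptide, charge); where both sources cover a key, the
    experimental entries win and the predicted one is dropped."""
    if len(experimental) and len(predicted):
        de = experimental.vectors.shape[1]
        dp = predicted.vectors.shape[1]
        if de != dp:
            raise ValueError(f"latent dimension mismatch: {de} vs {dp}")
    exp_keys = set(zip(experimental.peptides, experimental.charges.tolist()))
    keep = [
        i
        for i in range(len(predicted))
        if (predicted.peptides[i], int(predicted.charges[i])) not in exp_keys
    ]
    if not len(experimental):
        return predicted
    if not keep:
        return experimental
    pred_subset = VectorLibrary(
        peptides=[predicted.peptides[i] for i in keep],
        charges=predicted.charges[keep],
        masses=predicted.masses[keep],
        vectors=predicted.vectors[keep],
        sources=[predicted.sources[i] for i in keep],
        is_decoy=predicted.is_decoy[keep],
    )
    return _concat_libraries([experimental, pred_subset])


def combine(target: VectorLibrary, decoy: VectorLibrary) -> VectorLibrary:
    return _concat_libraries([target, decoy])


@dataclass
class VVMResult:
    query_id: str
    peptide: str
    score: float
    is_decoy: bool
    n_candidates: int
    charge: int


def search(
    query_spectra: list[Spectrum],
    query_vectors: np.ndarray,
    library: VectorLibrary,
    ppm_tol: float = 10.0,
) -> list[VVMResult]:
    """Best vector-vector match per query among charge- and mass-matched
    candidates (targets and decoys compete in one pool).

    Queries with no candidate in the tolerance window are omitted (and
    hence excluded from the FDR denominator).  Cosine ties are broken in
    favor of the decoy, then lexicographically by peptide.
    """
    if not len(library):
        raise ValueError("empty library")
    results: list[VVMResult] = []
    for spec, vec in zip(query_spectra, query_vectors):
        cand = library.candidates(spec.charge, spec.precursor_mz, ppm_tol)
        if cand.size == 0:
            continue
        scores = library.vectors[cand] @ vec
        best_score = scores.max()
        tied = cand[np.isclose(scores, best_score, rtol=0, atol=0)]
        # conservative tie-break: decoy first, then lexicographic peptide
        best = min(
            tied.tolist(),
            key=lambda i: (not library.is_decoy[i], library.peptides[i]),
        )
        results.append(
            VVMResult(
                query_id=spec.title,
                peptide=library.peptides[best],
                score=float(best_score),
                is_decoy=bool(library.is_decoy[best]),
                n_candidates=int(cand.size),
                charge=spec.charge,
            )
        )
    return results


def results_frame(results: list[VVMResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "peptide": r.peptide,
                "charge": r.charge,
                "score": r.score,
                "is_decoy": r.is_decoy,
                "n_candidates": r.n_candidates,
            }
            for r in results
        ]
    )


@dataclass
class FdrTable:
    table: pd.DataFrame  # score_threshold, n_target, n_decoy, fdr, q_value
    level: str  # "psm" | "peptide"
    plus_one: bool = False

    def threshold_at(self, alpha: float) -> float | None:
        """Lowest score threshold with q <= alpha, or None if unreachable."""
        ok = self.table[self.table["q_value"] <= alpha]
        if ok.empty:
            return None
        return float(ok["score_threshold"].min())


def estimate_fdr(
    results: list[VVMResult] | pd.DataFrame,
    level: str = "peptide",
    plus_one: bool = False,
    collapse_charge: bool = False,
) -> FdrTable:
    """Target-decoy FDR estimate swept over all observed scores.

    At peptide level, results collapse to the best score per peptide
    sequence first (charges pooled unless ``collapse_charge``).  FDR above
    a threshold = n_decoy / n_target (0 when no targets; the +1 variant is
    available via ``plus_one``); q-values are the running minimum of FDR
    from high scores downward.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if df.empty:
        raise ValueError("no search results to estimate FDR from")
    if level == "peptide":
        key = ["peptide", "charge"] if collapse_charge else ["peptide"]
        df = df.sort_values("score", ascending=False).drop_duplicates(subset=key, keep="first")
    elif level != "psm":
        raise ValueError("level must be 'psm' or 'peptide'")
    df = df.sort_values("score", ascending=False).reset_index(drop=True)
    n_decoy = df["is_decoy"].cumsum().to_numpy(dtype=float)
    n_target = (~df["is_decoy"]).cumsum().to_numpy(dtype=float)
    numer = n_decoy + 1.0 if plus_one else n_decoy
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_target > 0, numer / np.maximum(n_target, 1), 0.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    table = pd.DataFrame(
        {
            "score_threshold": df["score"].to_numpy(),
            "n_target": n_target.astype(int),
            "n_decoy": n_decoy.astype(int),
            "fdr": fdr,
            "q_value": q,
        }
    )
    return FdrTable(table=table, level=level, plus_one=plus_one)


@dataclass
class AcceptedSet:
    results: list[VVMResult]
    threshold: float | None
    n_psm: int
    n_unique_peptides: int


def apply_cutoff(
    results: list[VVMResult], fdr_table: FdrTable, alpha: float = 0.01
) -> AcceptedSet:
    """Target results scoring at or above the q <= alpha threshold."""
    threshold = fdr_table.threshold_at(alpha)
    if threshold is None:
        log.warning("apply_cutoff: no threshold achieves q <= %g; empty result", alpha)
        return AcceptedSet(results=[], threshold=None, n_psm=0, n_unique_peptides=0)
    accepted = [r for r in results if not r.is_decoy and r.score >= threshold]
    return AcceptedSet(
        results=accepted,
        threshold=threshold,
        n_psm=len(accepted),
        n_unique_peptides=len({r.peptide for r in accepted}),
    )
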