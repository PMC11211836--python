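"""Evaluation analyses: similarity amplification and benchmark scoring.

The similarity-amplification analysis contrasts the cosine similarity of
two spectra in raw binned-vector space with the cosine of their latent
embeddings: a well-trained encoder pushes same-peptide pairs toward latent
cosine 1 even when their raw similarity is mediocre, while keeping
different-peptide pairs apart."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import Spectrum
from .vectorize import VectorizationConfig, bin_spectrum


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def similarity_amplification(
    pairs: list[tuple[Spectrum, Spectrum, bool]],
    model,
    vec_config: VectorizationConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Raw vs latent cosine for labelled spectrum pairs.

    ``pairs`` holds (spectrum_a, spectrum_b, same_peptide).  Returns the
    per-pair table and a summary with mean/median per pair type and per
    raw-similarity stratum (raw < 0.5 vs >= 0.5).
    """
    if not pairs:
        raise ValueError("empty pair set")
    vc = vec_config or model.vec_config
    spectra_a = [a for a, _, _ in pairs]
    spectra_b = [b for _, b, _ in pairs]
    vecs_a = model.embed_spectra(spectra_a, check_charge=False)
    vecs_b = model.embed_spectra(spectra_b, check_charge=False)
    rows = []
    for i, (a, b, same) in enumerate(pairs):
        raw = _cosine(bin_spectrum(a, vc), bin_spectrum(b, vc))
        latent = float(np.dot(vecs_a[i], vecs_b[i]))
        rows.append(
            {
                "pair_type": "same_peptide" if same else "different_peptide",
                "raw_cosine": raw,
                "latent_cosine": latent,
            }
        )
    table = pd.DataFrame(rows)
    summary: dict = {}
    for ptype, sub in table.groupby("pair_type"):
        entry = {
            "n": int(len(sub)),
            "raw_mean": float(sub["raw_cosine"].mean()),
            "raw_median": float(sub["raw_cosine"].median()),
            "latent_mean": float(sub["latent_cosine"].mean()),
            "latent_median": float(sub["latent_cosine"].median()),
        }
        low = sub[sub["raw_cosine"] < 0.5]
        high = sub[sub["raw_cosine"] >= 0.5]
        entry["low_raw"] = {
            "n": int(len(low)),
            "raw_mean": float(low["raw_cosine"].mean()) if len(low) else float("nan"),
            "latent_mean": float(low["latent_cosine"].mean()) if len(low) else float("nan"),
        }
        entry["high_raw"] = {
            "n": int(len(high)),
            "raw_mean": float(high["raw_cosine"].mean()) if len(high) else float("nan"),
            "latent_mean": float(high["latent_cosine"].mean()) if len(high) else float("nan"),
        }
        summary[ptype] = entry
    return table, summary


def make_replicate_pairs(
    spectra_by_peptide: dict[str, list[Spectrum]],
    n_same: int,
    n_diff: int,
    rng_seed: int = 0,
) -> list[tuple[Spectrum, Spectrum, bool]]:
    """Sample same-peptide and different-peptide spectrum pairs."""
    rng = np.random.default_rng(rng_seed)
    peptides = [p for p, reps in spectra_by_peptide.items() if len(reps) >= 2]
    multi = sorted(spectra_by_peptide)
    pairs: list[tuple[Spectrum, Spectrum, bool]] = []
    for _ in range(n_same):
        pep = peptides[int(rng.integers(len(peptides)))]
        reps = spectra_by_peptide[pep]
        i, j = rng.choice(len(reps), size=2, replace=False)
        pairs.append((reps[int(i)], reps[int(j)], True))
    for _ in range(n_diff):
        p1, p2 = rng.choice(len(multi), size=2, replace=False)
        r1 = spectra_by_peptide[multi[int(p1)]]
        r2 = spectra_by_peptide[multi[int(p2)]]
        pairs.append(
            (r1[int(rng.integers(len(r1)))], r2[int(rng.integers(len(r2)))], False)
        )
    return pairs


@dataclass
class BenchmarkScore:
    """Truth-based scoring of an accepted identification set."""

    n_accepted: int
    n_correct: int
    n_wrong: int
    false_discovery_proportion: float
    n_correct_unique_peptides: int


def score_against_truth(accepted_results, truth: dict[str, str]) -> BenchmarkScore:
    """Compare accepted identifications with the simulator's ground truth.

    A hit is correct when the query's true peptide equals the reported one;
    foreign queries have no correct answer, so any accepted foreign hit is
    a false discovery.
    """
    n_correct = n_wrong = 0
    correct_peps = set()
    for r in accepted_results:
        true_pep = truth.get(r.query_id, "foreign")
        if true_pep == r.peptide:
            n_correct += 1
            correct_peps.add(r.peptide)
        else:
            n_wrong += 1
    n = n_correct + n_wrong
    return BenchmarkScore(
        n_accepted=n,
        n_correct=n_correct,
        n_wrong=n_wrong,
        false_discovery_proportion=(n_wrong / n) if n else 0.0,
        n_correct_unique_peptides=len(correct_peps),
    )
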