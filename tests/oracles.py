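"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: the digestion oracle
enumerates all substrings and tests cleavage-boundary conditions directly,
and the search oracle is a dense linear scan with no index.
"""

from __future__ import annotations

import re

import numpy as np


def brute_force_digest(
    sequence: str,
    missed_max: int = 2,
    len_min: int = 6,
    len_max: int = 30,
    proline_rule: bool = True,
) -> dict[str, int]:
    """All tryptic peptides of a protein by substring enumeration.

    Returns {peptide: minimum missed-cleavage count}.  A substring is a
    valid peptide iff its start is the protein N-terminus or a cleavage
    site, its end is the C-terminus or a cleavage site, and the cleavage
    sites strictly inside it number at most ``missed_max``.
    """
    pattern = r"[KR](?!P)" if proline_rule else r"[KR]"
    sites = {m.end() for m in re.finditer(pattern, sequence)}
    n = len(sequence)
    out: dict[str, int] = {}
    for start in range(n):
        if start != 0 and start not in sites:
            continue
        for end in range(start + 1, n + 1):
            if end != n and end not in sites:
                continue
            if not len_min <= end - start <= len_max:
                continue
            inside = sum(1 for s in sites if start < s < end)
            pep = sequence[start:end]
            if pep not in out or inside < out[pep]:
                out[pep] = inside
    return {p: m for p, m in out.items() if m <= missed_max}


def linear_scan_search(
    query_mz: float,
    query_charge: int,
    query_vec: np.ndarray,
    peptides: list[str],
    charges: np.ndarray,
    mzs: np.ndarray,
    vectors: np.ndarray,
    is_decoy: np.ndarray,
    ppm_tol: float,
) -> tuple[str, float, bool, int] | None:
    """Dense scan over every entry: charge equality, ppm window on m/z,
    max cosine with decoy-first then lexicographic tie-break."""
    half = ppm_tol * 1e-6 * query_mz
    best = None
    n_cand = 0
    for i in range(len(peptides)):
        if charges[i] != query_charge or abs(mzs[i] - query_mz) > half:
            continue
        n_cand += 1
        score = float(np.dot(vectors[i], query_vec))
        key = (-score, not is_decoy[i], peptides[i])
        if best is None or key < best[0]:
            best = (key, peptides[i], score, bool(is_decoy[i]))
    if best is None:
        return None
    return best[1], best[2], best[3], n_cand
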