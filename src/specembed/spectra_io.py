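"""Readers/writers for the text formats the pipeline touches.

MGF (query spectra) and FASTA (protein databases) are parsed through
pyteomics; the NIST-style MSP spectral-library format is parsed by a small
block reader here.  All parsers emit the package's domain types and never
emit a :class:`Spectrum` that violates its invariants (peaks sorted by m/z,
non-negative intensities, charge in 1..4).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from pyteomics import fasta as _pt_fasta
from pyteomics import mgf as _pt_mgf

log = logging.getLogger(__name__)

VALID_CHARGES = (1, 2, 3, 4)
SEARCH_CHARGES = (2, 3)  # charges with trained models; others parsed but routed out
_AMBIGUOUS_RESIDUES = set("BJOUXZ")


@dataclass
class Spectrum:
    """A single MS/MS spectrum: peak list plus precursor meta-information."""

    peaks: list[tuple[float, float]]
    precursor_mz: float
    charge: int
    nce: float | None = None
    peptide: str | None = None
    title: str = ""
    is_decoy: bool = False
    charge_known: bool = True

    def __post_init__(self) -> None:
        self.peaks = sorted(((float(m), float(i)) for m, i in self.peaks), key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")
        if any(m <= 0 for m, _ in self.peaks):
            raise ValueError("non-positive peak m/z")
        if self.charge not in VALID_CHARGES:
            raise ValueError(f"charge {self.charge} outside {VALID_CHARGES}")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")

    @property
    def mz(self) -> list[float]:
        return [m for m, _ in self.peaks]

    @property
    def intensity(self) -> list[float]:
        return [i for _, i in self.peaks]

    def copy_with(self, **kw) -> "Spectrum":
        return replace(self, **kw)


@dataclass
class ProteinRecord:
    accession: str
    sequence: str


@dataclass
class ParseReport:
    """Counts of what a parser kept and what it skipped."""

    n_parsed: int = 0
    n_skipped: int = 0
    messages: list[str] = field(default_factory=list)

    def skip(self, msg: str) -> None:
        self.n_skipped += 1
        self.messages.append(msg)
        log.warning("%s", msg)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(
    path: str | Path,
    nce_key: str = "nce",
    report: ParseReport | None = None,
) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Blocks missing a CHARGE line are emitted with ``charge_known=False``
    (and a placeholder charge of 2) so callers can route them out of search;
    malformed blocks are skipped and counted in the parse report.  A file
    from which nothing parses is a hard error.
    """
    report = report if report is not None else ParseReport()
    spectra: list[Spectrum] = []
    with _pt_mgf.MGF(str(path), convert_arrays=1, read_charges=False) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"index={i}"))
            try:
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise ValueError("missing PEPMASS")
                precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                charge_raw = params.get("charge")
                if charge_raw:
                    charge = abs(int(charge_raw[0]))
                    charge_known = True
                else:
                    charge, charge_known = 2, False
                nce = params.get(nce_key)
                peaks = list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
                spectra.append(
                    Spectrum(
                        peaks=peaks,
                        precursor_mz=precursor_mz,
                        charge=charge,
                        nce=float(nce) if nce is not None else None,
                        peptide=params.get("seq") or None,
                        title=title,
                        charge_known=charge_known,
                    )
                )
                report.n_parsed += 1
            except (ValueError, KeyError, TypeError) as exc:
                report.skip(f"MGF block {title!r} skipped: {exc}")
    if not spectra:
        raise ValueError(f"no spectra parsed from {path}")
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path, nce_key: str = "nce") -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.title}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            if s.nce is not None:
                fh.write(f"{nce_key.upper()}={s.nce:g}\n")
            if s.peptide:
                fh.write(f"SEQ={s.peptide}\n")
            for m, i in s.peaks:
                fh.write(f"{m:.5f} {i:.6g}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

_MSP_NAME = re.compile(r"^Name:\s*(?P<pep>[A-Za-z]+)(?:\((?P<mods>[^)]*)\))?/(?P<z>\d+)")
_ALLOWED_MOD_TOKENS = {"", "cam", "carbamidomethyl"}


def read_msp(path: str | Path, report: ParseReport | None = None) -> list[Spectrum]:
    """Read a NIST-style MSP spectral library.

    Each block: ``Name: PEPTIDE/2``, optional header lines (MW, Comment,
    NCE), ``Num peaks: N`` and N peak lines.  Blocks whose declared peak
    count disagrees with the actual one, or that carry modification tokens
    other than fixed carbamidomethyl-C, are skipped with a warning.
    """
    report = report if report is not None else ParseReport()
    spectra: list[Spectrum] = []
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.strip().startswith("Name:") and current:
            blocks.append(current)
            current = []
        if line.strip():
            current.append(line.rstrip("\n"))
    if current:
        blocks.append(current)

    for block in blocks:
        name_line = block[0]
        m = _MSP_NAME.match(name_line)
        if not m:
            report.skip(f"MSP block with unparsable Name line skipped: {name_line!r}")
            continue
        peptide, charge = m.group("pep").upper(), int(m.group("z"))
        mods = (m.group("mods") or "").lower()
        if any(tok.strip() not in _ALLOWED_MOD_TOKENS for tok in mods.split(",")):
            report.skip(f"MSP block {peptide!r} skipped: unsupported modifications {mods!r}")
            continue
        num_peaks = None
        nce = None
        precursor_mz = None
        peak_lines: list[str] = []
        in_peaks = False
        for line in block[1:]:
            low = line.lower()
            if low.startswith("num peaks:"):
                num_peaks = int(line.split(":", 1)[1])
                in_peaks = True
            elif in_peaks:
                peak_lines.append(line)
            elif low.startswith("precursormz:") or low.startswith("precursor_mz:"):
                precursor_mz = float(line.split(":", 1)[1])
            elif low.startswith("comment:"):
                nce_m = re.search(r"nce[=:]\s*([0-9.]+)", low)
                if nce_m:
                    nce = float(nce_m.group(1))
        try:
            peaks = [
                (float(parts[0]), float(parts[1]))
                for parts in (pl.replace("\t", " ").split() for pl in peak_lines)
            ]
        except (ValueError, IndexError):
            report.skip(f"MSP block {peptide!r} skipped: unparsable peak line")
            continue
        if num_peaks is None or len(peaks) != num_peaks:
            report.skip(
                f"MSP block {peptide!r} skipped: Num peaks {num_peaks} != {len(peaks)} lines"
            )
            continue
        if charge not in VALID_CHARGES:
            report.skip(f"MSP block {peptide!r} skipped: charge {charge}")
            continue
        if precursor_mz is None:
            from .masses import mz_from_mass, peptide_neutral_mass

            try:
                precursor_mz = mz_from_mass(peptide_neutral_mass(peptide), charge)
            except ValueError as exc:
                report.skip(f"MSP block {peptide!r} skipped: {exc}")
                continue
        spectra.append(
            Spectrum(
                peaks=peaks,
                precursor_mz=precursor_mz,
                charge=charge,
                nce=nce,
                peptide=peptide,
                title=f"{peptide}/{charge}",
            )
        )
        report.n_parsed += 1
    return spectra


def write_msp(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            if not s.peptide:
                raise ValueError("MSP blocks require a peptide annotation")
            fh.write(f"Name: {s.peptide}/{s.charge}\n")
            fh.write(f"PrecursorMz: {s.precursor_mz:.6f}\n")
            if s.nce is not None:
                fh.write(f"Comment: NCE={s.nce:g}\n")
            fh.write(f"Num peaks: {len(s.peaks)}\n")
            for m, i in s.peaks:
                fh.write(f"{m:.5f}\t{i:.6g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    strict: bool = True,
    report: ParseReport | None = None,
) -> Iterator[ProteinRecord]:
    """Read protein records; ambiguous residues (B/J/O/U/X/Z) reject the
    record in strict mode, otherwise the offending residues are dropped."""
    report = report if report is not None else ParseReport()
    with _pt_fasta.FASTA(str(path)) as reader:
        for header, sequence in reader:
            accession = header.split()[0] if header.split() else ""
            seq = sequence.strip().upper()
            if not seq:
                report.skip(f"FASTA record {accession!r} skipped: empty sequence")
                continue
            bad = _AMBIGUOUS_RESIDUES.intersection(seq)
            if bad:
                if strict:
                    report.skip(
                        f"FASTA record {accession!r} rejected: ambiguous residues {sorted(bad)}"
                    )
                    continue
                seq = "".join(a for a in seq if a not in _AMBIGUOUS_RESIDUES)
                if not seq:
                    report.skip(f"FASTA record {accession!r} skipped: nothing left")
                    continue
            report.n_parsed += 1
            yield ProteinRecord(accession=accession, sequence=seq)
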