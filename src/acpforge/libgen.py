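"""Exhaustive sliding-window peptide library generation.

A protein sequence is decomposed into every contiguous subsequence
(window) within a configurable length range, stepping one residue at a
time from the N- to the C-terminus.  For a protein of N residues and
step 1 the number of windows is the closed form

    sum_{L=Lmin}^{min(Lmax, N)} (N - L + 1)

e.g. a 142-residue protein yields 2688 windows for lengths 5-25.
Duplicate sequences arising from internal repeats are kept as separate
windows; :func:`distinct_sequences` exposes any collapse explicitly.

Coordinates are 1-based and inclusive at both ends throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _validate_sequence(seq: str, context: str = "sequence") -> None:
    for pos, letter in enumerate(seq, start=1):
        if letter not in STANDARD_AA:
            raise ValueError(
                f"non-standard residue {letter!r} at position {pos} in {context}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A source protein: id, free-text description and validated sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        _validate_sequence(self.sequence, context=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """One contiguous subsequence of a source protein (1-based, inclusive)."""

    source_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid window coordinates {self.start}..{self.end}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"window {self.start}..{self.end} does not match sequence "
                f"length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def peptide_id(self) -> str:
        return f"{self.source_id}|{self.start}-{self.end}"


@dataclass
class PeptideLibrary:
    """Ordered collection of windows plus the enumeration parameters."""

    windows: list[PeptideWindow]
    lmin: int
    lmax: int
    step: int
    source: ProteinRecord | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": [w.peptide_id for w in self.windows],
                "source_id": [w.source_id for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "length": [w.length for w in self.windows],
                "sequence": [w.sequence for w in self.windows],
            }
        )


def expected_window_count(n: int, lmin: int, lmax: int) -> int:
    """Closed-form window count for step 1: sum over L of (n - L + 1)."""
    return sum(n - L + 1 for L in range(lmin, min(lmax, n) + 1))


def read_fasta(path: str | Path, skip_invalid: bool = False) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are uppercased.  A record containing a letter outside the 20
    standard amino acids raises ``ValueError`` naming the offending
    character and position; with ``skip_invalid=True`` such records are
    dropped with a logged warning instead.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            records.append(
                ProteinRecord(id=rec.id, description=rec.description, sequence=seq)
            )
        except ValueError as exc:
            if skip_invalid:
                logger.warning("dropping record %s: %s", rec.id, exc)
            else:
                raise
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def bundled_alpha_lactalbumin() -> ProteinRecord:
    """The human alpha-lactalbumin precursor (UniProt P00709, 142 aa).

    Shipped as reference data so library-wide computations run offline.
    """
    ref = resources.files("acpforge.data") / "P00709.fasta"
    with resources.as_file(ref) as path:
        return read_fasta(path)[0]


def enumerate_windows(
    protein: ProteinRecord,
    lmin: int = 5,
    lmax: int = 25,
    step: int = 1,
) -> PeptideLibrary:
    """Enumerate every window of each length in [lmin, min(lmax, N)].

    Windows are ordered by (start, length).  ``lmin > N`` yields an empty
    library with a logged warning rather than an error.
    """
    if lmin < 1 or lmax < lmin:
        raise ValueError(f"require 1 <= lmin <= lmax, got {lmin}..{lmax}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    n = len(protein)
    if lmin > n:
        logger.warning(
            "lmin=%d exceeds protein length %d; empty library", lmin, n
        )
        return PeptideLibrary([], lmin, lmax, step, protein)
    windows = [
        PeptideWindow(
            source_id=protein.id,
            start=start,
            end=start + L - 1,
            sequence=protein.sequence[start - 1 : start + L - 1],
        )
        for start in range(1, n + 1, step)
        for L in range(lmin, min(lmax, n) + 1)
        if start + L - 1 <= n
    ]
    return PeptideLibrary(windows, lmin, lmax, step, protein)


def distinct_sequences(
    library: PeptideLibrary,
) -> tuple[int, dict[str, list[PeptideWindow]]]:
    """Number of unique sequence strings and their source windows."""
    mapping: dict[str, list[PeptideWindow]] = {}
    for w in library:
        mapping.setdefault(w.sequence, []).append(w)
    return len(mapping), mapping


def length_distribution(library: PeptideLibrary) -> pd.DataFrame:
    """Table of (length, count), sorted by length ascending."""
    if not library.windows:
        return pd.DataFrame(columns=["length", "count"]).astype(int)
    counts = pd.Series([w.length for w in library]).value_counts().sort_index()
    return counts.rename_axis("length").reset_index(name="count")


def write_library_tsv(library: PeptideLibrary, path: str | Path) -> None:
    """Write the library as TSV (1-based inclusive start/end coordinates)."""
    library.to_frame().to_csv(path, sep="\t", index=False)


def write_library_fasta(library: PeptideLibrary, path: str | Path) -> None:
    """Write the library as FASTA with ids ``source|start-end``."""
    recs = [
        SeqRecord(Seq(w.sequence), id=w.peptide_id, description="")
        for w in library
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_library_tsv(path: str | Path) -> PeptideLibrary:
    """Re-read a library TSV written by :func:`write_library_tsv`."""
    df = pd.read_csv(path, sep="\t")
    windows = [
        PeptideWindow(
            source_id=str(r.source_id),
            start=int(r.start),
            end=int(r.end),
            sequence=str(r.sequence),
        )
        for r in df.itertuples()
    ]
    lengths = [w.length for w in windows] or [0]
    return PeptideLibrary(windows, min(lengths), max(lengths), 1)


def windows_from_sequences(sequences: Iterable[str], source_id: str = "adhoc") -> PeptideLibrary:
    """Wrap bare peptide strings as a library (coordinates are synthetic).

    Convenience for screening externally supplied peptides that do not
    carry source coordinates; windows are laid out end to end so ids stay
    unique.
    """
    windows = []
    offset = 1
    for seq in sequences:
        windows.append(
            PeptideWindow(source_id=source_id, start=offset, end=offset + len(seq) - 1, sequence=seq)
        )
        offset += len(seq)
    lengths = [w.length for w in windows] or [0]
    return PeptideLibrary(windows, min(lengths), max(lengths), 1)
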