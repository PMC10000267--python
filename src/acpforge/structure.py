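"""Secondary-structure annotations and the helix-containing filter.

Annotations normally come from an external de-novo structure predictor
and enter as a TSV of dash-joined segment labels such as
``coil-helix-coil-helix``.  The screening criterion is *contains at
least one helix segment*, not *fully helical*: experimentally validated
candidates carry mixed labels.

For synthetic end-to-end runs a deterministic propensity-based surrogate
annotator is provided.  It slides a 4-residue window over the peptide,
marks windows whose mean helix propensity (Chou-Fasman-style table
shipped as data) exceeds a cutoff as helix, and merges adjacent labels.
It makes no claim to structural accuracy; it exists so pipelines run
without a structure server.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

from .libgen import _validate_sequence

VALID_TOKENS = ("helix", "coil", "sheet")

# Labels may be joined by hyphen, en dash, or em dash.
_SPLIT_RE = re.compile(r"[-‐–—]+")
_JOIN = "–"  # en dash, matching the conventional display form


@dataclass(frozen=True)
class StructureAnnotation:
    peptide_id: str
    segments: tuple[str, ...]
    raw_label: str

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"no segments for {self.peptide_id!r}")
        for seg in self.segments:
            if seg not in VALID_TOKENS:
                raise ValueError(f"unknown structure token {seg!r}")


def parse_label(peptide_id: str, label: str) -> StructureAnnotation:
    """Parse a dash-joined label into normalized segments."""
    tokens = [t.strip().lower() for t in _SPLIT_RE.split(str(label)) if t.strip()]
    if not tokens:
        raise ValueError(f"empty structure label for {peptide_id!r}")
    for tok in tokens:
        if tok not in VALID_TOKENS:
            raise ValueError(
                f"unknown structure token {tok!r} for peptide {peptide_id!r}"
            )
    return StructureAnnotation(peptide_id, tuple(tokens), _JOIN.join(tokens))


def format_label(annotation: StructureAnnotation) -> str:
    """Dash-joined display form; inverse of :func:`parse_label`."""
    return _JOIN.join(annotation.segments)


def parse_structure_table(path: str | Path) -> list[StructureAnnotation]:
    """Read a TSV with columns (peptide_id, structure_label)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "structure_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"structure table must have columns {sorted(required)}")
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            out.append(parse_label(str(row.peptide_id), row.structure_label))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return out


def write_structure_table(annotations: list[StructureAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "peptide_id": [a.peptide_id for a in annotations],
            "structure_label": [format_label(a) for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def has_helix(annotation: StructureAnnotation) -> bool:
    """True iff any segment is helix (the screening filter)."""
    return "helix" in annotation.segments


@lru_cache(maxsize=1)
def helix_propensities() -> dict[str, float]:
    """Per-residue helix propensity table (shipped CSV)."""
    ref = resources.files("acpforge.data") / "helix_propensity.csv"
    with ref.open() as fh:
        return {row["residue"]: float(row["propensity"]) for row in csv.DictReader(fh)}


def surrogate_helix_annotator(
    sequence: str,
    peptide_id: str = "",
    cutoff: float = 1.0,
    window: int = 4,
) -> StructureAnnotation:
    """Deterministic propensity-based helix/coil annotation.

    Every window of ``window`` consecutive residues whose mean propensity
    exceeds ``cutoff`` marks its residues as helix; the remainder is
    coil.  Runs of identical labels collapse into segments.  Peptides
    shorter than ``window`` are labelled by their overall mean.
    """
    _validate_sequence(sequence)
    table = helix_propensities()
    values = [table[r] for r in sequence]
    n = len(values)
    if n < window:
        label = "helix" if sum(values) / n > cutoff else "coil"
        return StructureAnnotation(peptide_id, (label,), label)
    is_helix = [False] * n
    for i in range(n - window + 1):
        if sum(values[i : i + window]) / window > cutoff:
            for j in range(i, i + window):
                is_helix[j] = True
    segments: list[str] = []
    for flag in is_helix:
        label = "helix" if flag else "coil"
        if not segments or segments[-1] != label:
            segments.append(label)
    return StructureAnnotation(peptide_id, tuple(segments), _JOIN.join(segments))
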