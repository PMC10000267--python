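"""Per-peptide physicochemical descriptors, principally integer net charge.

The default charge model is the simple residue-count convention used
throughout antimicrobial/anticancer peptide screening: lysine and
arginine contribute +1, aspartate and glutamate -1, histidine 0, and the
termini are ignored, so

    net_charge = (#K + #R) - (#D + #E).

The model is configurable (per-residue contributions, terminal charges,
and an optional Henderson-Hasselbalch mode at a given pH) because
different prediction servers use different conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .libgen import STANDARD_AA, PeptideLibrary, _validate_sequence

#: Default per-residue contributions; all unlisted standard residues are 0.
DEFAULT_CONTRIBUTIONS: Mapping[str, float] = {
    "K": 1.0,
    "R": 1.0,
    "H": 0.0,
    "D": -1.0,
    "E": -1.0,
}

# Side-chain / terminal pKa values for the optional pH-dependent mode.
_PKA_SIDECHAIN = {"K": 10.5, "R": 12.5, "H": 6.0, "D": 3.9, "E": 4.1, "C": 8.3, "Y": 10.1}
_PKA_NTERM = 9.0
_PKA_CTERM = 2.0


@dataclass(frozen=True)
class ChargeModel:
    """Residue-additive charge model.

    Parameters
    ----------
    contributions
        Map residue letter -> charge contribution.  Unlisted standard
        residues contribute 0.
    include_termini
        Add +1 for the free N-terminal amine and -1 for the C-terminal
        carboxylate (integer convention) or their Henderson-Hasselbalch
        fractional charges in pH mode.
    ph
        If set, ignore ``contributions`` and compute the fractional net
        charge from side-chain pKa values at this pH.
    """

    contributions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRIBUTIONS)
    )
    include_termini: bool = False
    ph: float | None = None

    def __post_init__(self) -> None:
        for letter, value in self.contributions.items():
            if letter not in STANDARD_AA:
                raise ValueError(f"charge model key {letter!r} is not a standard residue")
            if not pd.notna(value) or value in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite contribution for {letter!r}")

    @classmethod
    def from_yaml(cls, path_or_text: str) -> "ChargeModel":
        """Build a model from a YAML mapping, e.g. ``{H: 0.5, termini: true}``.

        Keys that are single residue letters override contributions;
        ``termini`` and ``ph`` map to the corresponding fields.
        """
        try:
            raw = yaml.safe_load(open(path_or_text).read())
        except OSError:
            raw = yaml.safe_load(path_or_text)
        raw = raw or {}
        contributions = dict(DEFAULT_CONTRIBUTIONS)
        termini = bool(raw.pop("termini", False))
        ph = raw.pop("ph", None)
        for key, value in raw.items():
            contributions[str(key).upper()] = float(value)
        return cls(contributions=contributions, include_termini=termini, ph=ph)


DEFAULT_CHARGE_MODEL = ChargeModel()


@dataclass(frozen=True)
class ChargeAnnotation:
    peptide_id: str
    sequence: str
    net_charge: float


def _hh_charge(sequence: str, ph: float, include_termini: bool) -> float:
    pos = sum(
        1.0 / (1.0 + 10 ** (ph - _PKA_SIDECHAIN[r]))
        for r in sequence
        if r in "KRH"
    )
    neg = sum(
        1.0 / (1.0 + 10 ** (_PKA_SIDECHAIN[r] - ph))
        for r in sequence
        if r in "DECY"
    )
    if include_termini:
        pos += 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
        neg += 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    return pos - neg


def net_charge(sequence: str, model: ChargeModel = DEFAULT_CHARGE_MODEL) -> float:
    """Net charge of a peptide under ``model``.

    With the default model the result is the integer
    ``(#K + #R) - (#D + #E)`` (returned as ``int``).
    """
    if not sequence:
        raise ValueError("empty sequence")
    _validate_sequence(sequence)
    if model.ph is not None:
        return _hh_charge(sequence, model.ph, model.include_termini)
    total = sum(model.contributions.get(r, 0.0) for r in sequence)
    if model.include_termini:
        total += 1.0 - 1.0  # +1 N-terminal amine, -1 C-terminal carboxylate
    return int(total) if float(total).is_integer() else total


def annotate_charges(
    library: PeptideLibrary, model: ChargeModel = DEFAULT_CHARGE_MODEL
) -> list[ChargeAnnotation]:
    """One :class:`ChargeAnnotation` per window, input order preserved."""
    out = []
    for w in library:
        try:
            out.append(ChargeAnnotation(w.peptide_id, w.sequence, net_charge(w.sequence, model)))
        except ValueError as exc:
            raise ValueError(f"peptide {w.peptide_id}: {exc}") from exc
    return out


def charge_distribution(annotations: Iterable[ChargeAnnotation]) -> pd.DataFrame:
    """Table of (charge, count) sorted by charge ascending."""
    charges = [a.net_charge for a in annotations]
    if not charges:
        return pd.DataFrame(columns=["charge", "count"])
    counts = pd.Series(charges).value_counts().sort_index()
    return counts.rename_axis("charge").reset_index(name="count")


def charges_table(annotations: Iterable[ChargeAnnotation]) -> pd.DataFrame:
    """Tidy export: (peptide_id, sequence, length, net_charge)."""
    anns = list(annotations)
    return pd.DataFrame(
        {
            "peptide_id": [a.peptide_id for a in anns],
            "sequence": [a.sequence for a in anns],
            "length": [len(a.sequence) for a in anns],
            "net_charge": [a.net_charge for a in anns],
        }
    )
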