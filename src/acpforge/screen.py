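"""Candidate screening: filter, rank, collapse redundancy, shortlist.

The screening rule mirrors the discovery workflow: keep peptides with
net charge >= +3 that contain at least one helix segment and are called
ACP by the consensus score; rank survivors by consensus descending; then
greedily drop candidates whose sequence is redundant with an
already-kept, higher-ranked candidate; finally take the top k.

Filters are evaluated charge -> structure -> consensus, so structure
annotations need only be supplied for charge-passing peptides (structure
prediction is the expensive external step).

Known positive-control peptides can be carried through the report
without being filtered or competing for the shortlist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .libgen import PeptideLibrary, PeptideWindow
from .scores import ACP, round3

logger = logging.getLogger(__name__)

SELECTED = "selected"


@dataclass(frozen=True)
class ScreenConfig:
    min_charge: float = 3
    require_helix: bool = True
    consensus_threshold: float = 0.5
    redundancy_mode: str = "substring"  # or "overlap_fraction"
    overlap_fraction_cutoff: float = 0.8
    top_k: int = 2

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.overlap_fraction_cutoff <= 1:
            raise ValueError("overlap_fraction_cutoff must lie in (0, 1]")
        if self.redundancy_mode not in ("substring", "overlap_fraction"):
            raise ValueError(f"unknown redundancy mode {self.redundancy_mode!r}")


@dataclass(frozen=True)
class RankedCandidate:
    rank: int | None
    peptide: PeptideWindow
    net_charge: float
    has_helix: bool | None
    consensus: float | None
    call: str | None
    status: str

    @property
    def peptide_id(self) -> str:
        return self.peptide.peptide_id


def _lookup(mapping: Mapping[str, object], pid: str, what: str, strict: bool):
    if pid in mapping:
        return mapping[pid]
    if strict:
        raise ValueError(f"missing {what} annotation for peptide {pid!r}")
    return None


def apply_filters(
    library: PeptideLibrary,
    charges: Mapping[str, float],
    structures: Mapping[str, bool],
    consensus: Mapping[str, float],
    config: ScreenConfig = ScreenConfig(),
    control_ids: Iterable[str] = (),
    strict: bool = True,
) -> list[RankedCandidate]:
    """Filter and rank the library.

    ``charges`` maps peptide_id -> net charge, ``structures`` maps
    peptide_id -> helix-containing flag (needed only for charge-passing
    peptides), ``consensus`` maps peptide_id -> consensus score.
    Survivors come first, ranked 1..n by consensus descending (ties:
    higher charge, then shorter length, then lexicographic sequence);
    control peptides and filtered-out peptides follow unranked with an
    explanatory status.
    """
    controls = set(control_ids)
    survivors: list[RankedCandidate] = []
    others: list[RankedCandidate] = []
    for w in library:
        pid = w.peptide_id
        charge = _lookup(charges, pid, "charge", strict)
        if charge is None:
            others.append(RankedCandidate(None, w, float("nan"), None, None, None,
                                          "filtered_out:missing_charge"))
            continue
        if pid in controls:
            helix = structures.get(pid)
            cons = consensus.get(pid)
            call = None if cons is None else (ACP if cons >= config.consensus_threshold else "non-ACP")
            others.append(RankedCandidate(None, w, charge, helix, cons, call, "control"))
            continue
        if charge < config.min_charge:
            others.append(RankedCandidate(None, w, charge, None, None, None,
                                          f"filtered_out:min_charge<{config.min_charge}"))
            continue
        helix = _lookup(structures, pid, "structure", strict)
        if helix is None:
            others.append(RankedCandidate(None, w, charge, None, None, None,
                                          "filtered_out:missing_structure"))
            continue
        if config.require_helix and not helix:
            others.append(RankedCandidate(None, w, charge, helix, consensus.get(pid),
                                          None, "filtered_out:require_helix"))
            continue
        cons = _lookup(consensus, pid, "consensus", strict)
        if cons is None:
            others.append(RankedCandidate(None, w, charge, helix, None, None,
                                          "filtered_out:missing_consensus"))
            continue
        call = ACP if cons >= config.consensus_threshold else "non-ACP"
        if call != ACP:
            others.append(RankedCandidate(None, w, charge, helix, cons, call,
                                          f"filtered_out:consensus<{config.consensus_threshold}"))
            continue
        survivors.append(RankedCandidate(None, w, charge, helix, cons, call, SELECTED))
    survivors.sort(
        key=lambda c: (-c.consensus, -c.net_charge, c.peptide.length, c.peptide.sequence)
    )
    ranked = [replace(c, rank=i) for i, c in enumerate(survivors, start=1)]
    return ranked + others


def _redundant(a: PeptideWindow, b: PeptideWindow, config: ScreenConfig) -> bool:
    if config.redundancy_mode == "substring":
        return a.sequence in b.sequence or b.sequence in a.sequence
    if a.source_id != b.source_id:
        return False
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    shorter = min(a.length, b.length)
    return overlap >= config.overlap_fraction_cutoff * shorter


def collapse_redundant(
    ranked: list[RankedCandidate], config: ScreenConfig = ScreenConfig()
) -> list[RankedCandidate]:
    """Greedy scan from best rank; later redundant candidates are marked.

    The kept set is pairwise non-redundant; kept candidates are re-ranked
    1..m without gaps.  Unranked entries (controls, filtered-out) pass
    through unchanged.
    """
    kept: list[RankedCandidate] = []
    out: list[RankedCandidate] = []
    for cand in ranked:
        if cand.rank is None:
            out.append(cand)
            continue
        hit = next((k for k in kept if _redundant(cand.peptide, k.peptide, config)), None)
        if hit is None:
            kept.append(cand)
            out.append(replace(cand, rank=len(kept)))
        else:
            out.append(replace(cand, rank=None, status=f"redundant_of:{hit.peptide_id}"))
    return out


def select_top(
    ranked: list[RankedCandidate], top_k: int = 2
) -> list[RankedCandidate]:
    """First ``top_k`` kept candidates in rank order."""
    kept = sorted((c for c in ranked if c.status == SELECTED and c.rank is not None),
                  key=lambda c: c.rank)
    if len(kept) < top_k:
        logger.warning("only %d candidates survive screening (top_k=%d)", len(kept), top_k)
    return kept[:top_k]


def run_screen(
    library: PeptideLibrary,
    charges: Mapping[str, float],
    structures: Mapping[str, bool],
    consensus: Mapping[str, float],
    config: ScreenConfig = ScreenConfig(),
    control_ids: Iterable[str] = (),
    strict: bool = True,
) -> tuple[list[RankedCandidate], list[RankedCandidate]]:
    """Full screen: filter -> rank -> collapse -> shortlist.

    Returns (all candidates with status, shortlist).
    """
    ranked = apply_filters(library, charges, structures, consensus, config,
                           control_ids=control_ids, strict=strict)
    collapsed = collapse_redundant(ranked, config)
    return collapsed, select_top(collapsed, config.top_k)


def candidates_frame(candidates: list[RankedCandidate]) -> pd.DataFrame:
    """Tidy report of the screen, one row per candidate."""
    return pd.DataFrame(
        {
            "rank": [c.rank for c in candidates],
            "peptide_id": [c.peptide_id for c in candidates],
            "sequence": [c.peptide.sequence for c in candidates],
            "length": [c.peptide.length for c in candidates],
            "net_charge": [c.net_charge for c in candidates],
            "has_helix": [c.has_helix for c in candidates],
            "consensus": [None if c.consensus is None else round3(c.consensus)
                          for c in candidates],
            "call": [c.call for c in candidates],
            "status": [c.status for c in candidates],
        }
    )
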