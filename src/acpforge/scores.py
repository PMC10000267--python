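"""Consensus scoring of external ACP-probability predictors.

Each peptide carries one probability in [0, 1] per predictor.  The
ranking statistic is the geometric mean of the k probabilities,

    consensus = (p_1 * p_2 * ... * p_k) ** (1/k),

which penalizes disagreement: a single near-zero predictor annihilates
the consensus regardless of the others.  A peptide is called ACP when
its consensus reaches a threshold (default 0.5, inclusive).

Probabilities of exactly 0 are legal and yield consensus 0; no epsilon
flooring is applied.  Peptides missing from any predictor are excluded
(a geometric mean over fewer predictors is not comparable), unless
strict mode turns that into an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACP = "ACP"
NON_ACP = "non-ACP"


@dataclass
class ScoreTable:
    """Peptide x predictor probability matrix (NaN marks missing)."""

    probabilities: pd.DataFrame  # index peptide_id, columns predictor names

    def __post_init__(self) -> None:
        values = self.probabilities.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if np.any(bad & ~np.isnan(values)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.probabilities.shape[1] < 1:
            raise ValueError("need at least one predictor")

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.probabilities.index)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.probabilities.columns)

    def complete_cases(self) -> "ScoreTable":
        """Drop peptides missing from any predictor (logged)."""
        complete = self.probabilities.dropna()
        dropped = len(self.probabilities) - len(complete)
        if dropped:
            logger.warning("excluding %d peptides with missing predictor values", dropped)
        return ScoreTable(complete)


@dataclass(frozen=True)
class ConsensusResult:
    peptide_id: str
    consensus: float
    call: str
    n_predictors: int


def read_score_tables(
    paths: Sequence[str | Path],
    predictor_names: Sequence[str] | None = None,
    strict: bool = False,
) -> ScoreTable:
    """Join one (peptide_id, probability) TSV per predictor.

    Default policy inner-joins on peptide_id and logs exclusions;
    ``strict=True`` errors if any peptide is missing from any file.
    Duplicate peptide ids within one file, or probabilities outside
    [0, 1], are always errors.
    """
    if predictor_names is None:
        predictor_names = [Path(p).stem for p in paths]
    columns = {}
    for path, name in zip(paths, predictor_names):
        df = pd.read_csv(path, sep="\t")
        if not {"peptide_id", "probability"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns (peptide_id, probability)")
        if df["peptide_id"].duplicated().any():
            dup = df.loc[df["peptide_id"].duplicated(), "peptide_id"].iloc[0]
            raise ValueError(f"{path}: duplicate peptide_id {dup!r}")
        out_of_range = df[(df["probability"] < 0) | (df["probability"] > 1)]
        if len(out_of_range):
            row = out_of_range.iloc[0]
            raise ValueError(
                f"{path}: probability {row['probability']} outside [0, 1] "
                f"for peptide {row['peptide_id']!r}"
            )
        columns[name] = df.set_index("peptide_id")["probability"]
    wide = pd.DataFrame(columns)
    if strict and wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index[0]
        raise ValueError(f"peptide {missing!r} missing from at least one predictor file")
    return ScoreTable(wide).complete_cases()


def read_wide_scores(path: str | Path) -> ScoreTable:
    """Read a single wide TSV: peptide_id column plus one column per predictor."""
    df = pd.read_csv(path, sep="\t")
    if "peptide_id" not in df.columns:
        raise ValueError(f"{path}: missing peptide_id column")
    return ScoreTable(df.set_index("peptide_id").astype(float))


def consensus_score(probabilities: Sequence[float]) -> float:
    """Geometric mean of k probabilities in [0, 1]."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"probabilities must lie in [0, 1], got {probabilities}")
    if np.any(p == 0):
        return 0.0
    return float(math.exp(np.mean(np.log(p))))


def classify(consensus: float, threshold: float = 0.5) -> str:
    """ACP iff consensus >= threshold (boundary inclusive)."""
    if not 0 <= consensus <= 1 or not 0 <= threshold <= 1:
        raise ValueError("consensus and threshold must lie in [0, 1]")
    return ACP if consensus >= threshold else NON_ACP


def score_consensus(
    table: ScoreTable, threshold: float = 0.5
) -> list[ConsensusResult]:
    """Consensus + call for every complete peptide in the table."""
    complete = table.complete_cases()
    k = len(complete.predictor_names)
    out = []
    for pid, row in complete.probabilities.iterrows():
        c = consensus_score(row.to_numpy())
        out.append(ConsensusResult(str(pid), c, classify(c, threshold), k))
    return out


def round3(value: float) -> float:
    """Half-up rounding to 3 decimals, the report display convention."""
    return float(Decimal(repr(value)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def consensus_frame(
    table: ScoreTable, results: Iterable[ConsensusResult]
) -> pd.DataFrame:
    """Export table: per-predictor probabilities, consensus (3 dp), call."""
    res = list(results)
    df = table.probabilities.loc[[r.peptide_id for r in res]].copy()
    df["consensus"] = [round3(r.consensus) for r in res]
    df["call"] = [r.call for r in res]
    return df.rename_axis("peptide_id").reset_index()
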