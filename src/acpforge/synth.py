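"""Seeded generators for every input the pipeline consumes.

Each generator derives its own independent random substream from a
single integer seed plus a fixed label, so adding a generator never
perturbs the output of another, and identical (params, seed) pairs are
bit-reproducible.

What the generators emulate, and what they do not:

* ``gen_protein`` draws residues i.i.d. from a composition (uniform or
  average vertebrate frequencies); real proteins have local sequence
  structure that this ignores.
* ``gen_score_table`` plants a hidden true-ACP label per peptide and
  draws per-predictor probabilities from a high Beta (true) or low Beta
  (false) distribution with logit-normal predictor noise — a bimodal
  spread like real ensemble predictors, without their sequence
  dependence.
* ``gen_proteome`` produces a two-group log-normal intensity matrix
  with biological and technical variance components, a configurable
  fraction of planted fold-changes, and missing-at-random dropouts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .libgen import PeptideLibrary, ProteinRecord
from .proteomics_de import TREATED, UNTREATED, IntensityMatrix
from .scores import ScoreTable
from .structure import StructureAnnotation, parse_label

#: Average vertebrate amino-acid frequencies (approximate, normalized).
VERTEBRATE_FREQS: dict[str, float] = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.042,
    "S": 0.081, "T": 0.062, "V": 0.073, "W": 0.013, "Y": 0.033,
}

_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for (seed, label); stable across versions."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class SynthScoreParams:
    base_rate: float = 0.05
    acp_alpha: float = 8.0
    acp_beta: float = 2.0
    non_alpha: float = 2.0
    non_beta: float = 8.0
    logit_noise_sd: float = 0.5
    predictor_names: tuple[str, ...] = ("pred_a", "pred_b", "pred_c")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.base_rate <= 1:
            raise ValueError("base_rate must lie in [0, 1]")
        if min(self.acp_alpha, self.acp_beta, self.non_alpha, self.non_beta) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.logit_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class SynthProteomeParams:
    n_proteins: int = 286
    de_fraction: float = 38 / 286
    log2_effect: float = 1.0
    between_bio_sd: float = 0.3
    within_tech_sd: float = 0.2
    missing_rate: float = 0.05
    n_bio: int = 3
    n_tech: int = 3
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.between_bio_sd, self.within_tech_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.de_fraction <= 1 and 0 <= self.missing_rate <= 1):
            raise ValueError("fractions must lie in [0, 1]")


def gen_protein(
    length: int,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    record_id: str | None = None,
) -> ProteinRecord:
    """Random protein with i.i.d. residues from ``composition``.

    ``composition`` defaults to uniform over the 20 standard letters;
    :data:`VERTEBRATE_FREQS` is shipped as a realistic alternative.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if composition is None:
        probs = np.full(len(_LETTERS), 1.0 / len(_LETTERS))
    else:
        weights = np.array([composition.get(l, 0.0) for l in _LETTERS], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("degenerate composition (all weights zero)")
        probs = weights / weights.sum()
    rng = substream(seed, "protein")
    seq = "".join(rng.choice(list(_LETTERS), size=length, p=probs))
    return ProteinRecord(
        id=record_id or f"synth{seed}", description="synthetic protein", sequence=seq
    )


def gen_score_table(
    library: PeptideLibrary, params: SynthScoreParams = SynthScoreParams()
) -> tuple[ScoreTable, pd.Series]:
    """Predictor probabilities with planted truth labels.

    Returns the score table and a boolean Series (index peptide_id) of
    the hidden true-ACP labels for downstream evaluation.
    """
    ids = [w.peptide_id for w in library]
    if not ids:
        raise ValueError("empty library")
    rng = substream(params.seed, "scores")
    labels = rng.random(len(ids)) < params.base_rate
    eps = 1e-9
    cols = {}
    for name in params.predictor_names:
        a = np.where(labels, params.acp_alpha, params.non_alpha)
        b = np.where(labels, params.acp_beta, params.non_beta)
        p = rng.beta(a, b)
        if params.logit_noise_sd > 0:
            logit = np.log(np.clip(p, eps, 1 - eps) / (1 - np.clip(p, eps, 1 - eps)))
            logit += rng.normal(0.0, params.logit_noise_sd, size=len(ids))
            p = 1.0 / (1.0 + np.exp(-logit))
        cols[name] = np.clip(p, 0.0, 1.0)
    table = ScoreTable(pd.DataFrame(cols, index=pd.Index(ids, name="peptide_id")))
    return table, pd.Series(labels, index=table.probabilities.index, name="true_acp")


_HELIX_LABELS = ("helix", "helix–coil", "coil–helix", "coil–helix–coil–helix")
_NON_HELIX_LABELS = ("coil", "sheet", "coil–sheet", "sheet–coil")


def gen_structure_annotations(
    library: PeptideLibrary, helix_fraction: float = 0.5, seed: int = 0
) -> list[StructureAnnotation]:
    """Random segment labels; ``helix_fraction`` of peptides contain helix."""
    if not 0 <= helix_fraction <= 1:
        raise ValueError("helix_fraction must lie in [0, 1]")
    rng = substream(seed, "structures")
    out = []
    for w in library:
        if rng.random() < helix_fraction:
            label = _HELIX_LABELS[rng.integers(len(_HELIX_LABELS))]
        else:
            label = _NON_HELIX_LABELS[rng.integers(len(_NON_HELIX_LABELS))]
        out.append(parse_label(w.peptide_id, label))
    return out


def gen_viability_plate(
    true_viability: dict[str, float],
    n_replicates: int = 3,
    noise_sd: float = 0.02,
    a570_media: float = 0.05,
    a570_untreated: float = 1.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format MTT plate with known ground-truth viabilities.

    Rows: conditions ``media``, ``untreated`` and each key of
    ``true_viability`` (percent), replicated, with Gaussian read noise on
    every well.  Columns (well, condition, value).
    """
    rng = substream(seed, "viability_plate")
    rows = []
    span = a570_untreated - a570_media
    conditions = {"media": a570_media, "untreated": a570_untreated}
    conditions.update(
        {cond: a570_media + pct / 100.0 * span for cond, pct in true_viability.items()}
    )
    well = 1
    for cond, value in conditions.items():
        for _ in range(n_replicates):
            rows.append(
                {"well": f"W{well:03d}", "condition": cond,
                 "value": value + rng.normal(0.0, noise_sd)}
            )
            well += 1
    return pd.DataFrame(rows)


def gen_hemolysis_plate(
    true_hemolysis: dict[str, float],
    n_replicates: int = 3,
    noise_sd: float = 0.02,
    a415_blank: float = 0.10,
    a415_positive: float = 2.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format hemolysis plate with known ground-truth percentages."""
    rng = substream(seed, "hemolysis_plate")
    rows = []
    span = a415_positive - a415_blank
    conditions = {"blank": a415_blank, "positive": a415_positive}
    conditions.update(
        {cond: a415_blank + pct / 100.0 * span for cond, pct in true_hemolysis.items()}
    )
    well = 1
    for cond, value in conditions.items():
        for _ in range(n_replicates):
            rows.append(
                {"well": f"W{well:03d}", "condition": cond,
                 "value": value + rng.normal(0.0, noise_sd)}
            )
            well += 1
    return pd.DataFrame(rows)


def gen_proteome(
    params: SynthProteomeParams = SynthProteomeParams(),
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Two-group log-normal intensity matrix with planted effects.

    log2 intensity = protein baseline + group effect (DE proteins only,
    sign randomized) + biological-replicate effect + technical noise,
    exponentiated to the linear scale and masked missing-at-random.
    Returns the matrix and a truth table (protein_id, true_log2fc).
    """
    rng = substream(params.seed, "proteome")
    n = params.n_proteins
    protein_ids = [f"P{i:04d}" for i in range(1, n + 1)]
    is_de = rng.random(n) < params.de_fraction
    signs = rng.choice([-1.0, 1.0], size=n)
    true_log2fc = np.where(is_de, signs * params.log2_effect, 0.0)
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n)

    run_ids, groups, bios, techs = [], [], [], []
    for group in (TREATED, UNTREATED):
        for bio in range(1, params.n_bio + 1):
            for tech in range(1, params.n_tech + 1):
                run_ids.append(f"{group}_b{bio}_t{tech}")
                groups.append(group)
                bios.append(bio)
                techs.append(tech)

    log2 = np.empty((n, len(run_ids)))
    col = 0
    for group in (TREATED, UNTREATED):
        effect = true_log2fc if group == TREATED else 0.0
        for bio in range(params.n_bio):
            bio_effect = rng.normal(0.0, params.between_bio_sd, size=n)
            for tech in range(params.n_tech):
                noise = rng.normal(0.0, params.within_tech_sd, size=n)
                log2[:, col] = baseline + effect + bio_effect + noise
                col += 1

    intensities = np.power(2.0, log2)
    if params.missing_rate > 0:
        mask = rng.random(intensities.shape) < params.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    values = pd.DataFrame(intensities, index=protein_ids, columns=run_ids)
    annotations = pd.DataFrame(
        {"group": groups, "bio_rep": bios, "tech_rep": techs},
        index=pd.Index(run_ids, name="run_id"),
    )
    truth = pd.DataFrame({"protein_id": protein_ids, "true_log2fc": true_log2fc})
    return IntensityMatrix(values, annotations), truth
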