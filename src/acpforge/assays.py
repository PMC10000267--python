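"""Quantification formulas for the wet-lab validation assays.

Cell viability (MTT, absorbance at 570 nm):

    % viability = 100 * (A570_treated - A570_media)
                        / (A570_untreated - A570_media)

Hemolysis (hemoglobin release, absorbance at 415 nm, detergent lysis as
the positive control):

    % hemolysis = 100 * (A415_sample - A415_blank)
                        / (A415_positive - A415_blank)

Autophagy activity: the autophagosome/autophagolysosome fluorescence
normalized to the nuclear stain, expressed as fold over untreated.

IC50 is read from the mean dose-response curve by piecewise-linear
interpolation at the first 50% crossing; when the curve never crosses
50% inside the tested range the estimate is censored ("greater than" the
top dose or "less than" the bottom dose) rather than extrapolated.

Values outside [0, 100]% are preserved and logged, never clipped, so QC
problems stay visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViabilityReading:
    a570_treated: float
    a570_untreated: float
    a570_media: float


@dataclass(frozen=True)
class HemolysisReading:
    a415_sample: float
    a415_blank: float
    a415_positive: float


@dataclass(frozen=True)
class AutophagySignal:
    autophagosome_signal: float  # ex480/em530
    nuclear_signal: float  # ex340/em480

    def __post_init__(self) -> None:
        if self.nuclear_signal <= 0:
            raise ValueError("nuclear signal must be positive")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Doses in uM (strictly increasing) with matched mean viabilities.

    ``viabilities`` may be per-dose scalars or per-dose replicate lists;
    replicates are averaged before interpolation.
    """

    doses: tuple[float, ...]
    viabilities: tuple  # floats or tuples of replicate floats

    def __post_init__(self) -> None:
        if len(self.doses) < 2:
            raise ValueError("need at least two dose points")
        if len(self.doses) != len(self.viabilities):
            raise ValueError("doses and viabilities must have equal length")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")

    def mean_viabilities(self) -> np.ndarray:
        return np.array(
            [np.mean(v) if np.ndim(v) else float(v) for v in self.viabilities]
        )


@dataclass(frozen=True)
class IC50Estimate:
    """Interpolated IC50 in uM, or a censored bound when 50% is not crossed."""

    value: float | None
    censored: str | None = None  # e.g. "greater than 400 uM"
    method: str = "interpolation"

    def __str__(self) -> str:
        return self.censored if self.censored else f"{self.value:g} uM"


def _flag(percent: float, what: str) -> float:
    if not 0 <= percent <= 100:
        logger.warning("%s outside [0, 100]%%: %.2f", what, percent)
    return percent


def percent_viability(reading: ViabilityReading) -> float:
    """MTT viability in percent; may exceed 100 or fall below 0 (flagged)."""
    denom = reading.a570_untreated - reading.a570_media
    if denom == 0:
        raise ValueError("untreated and media absorbances are equal (zero denominator)")
    value = 100.0 * (reading.a570_treated - reading.a570_media) / denom
    return _flag(value, "viability")


def percent_hemolysis(reading: HemolysisReading) -> float:
    """Hemolysis in percent of the detergent positive control."""
    denom = reading.a415_positive - reading.a415_blank
    if denom == 0:
        raise ValueError("positive control and blank absorbances are equal (zero denominator)")
    value = 100.0 * (reading.a415_sample - reading.a415_blank) / denom
    return _flag(value, "hemolysis")


def autophagy_activity(treated: AutophagySignal, untreated: AutophagySignal) -> float:
    """Nuclear-normalized autophagosome signal as fold over untreated."""
    baseline = untreated.autophagosome_signal / untreated.nuclear_signal
    if baseline == 0:
        raise ValueError("untreated autophagosome signal is zero; fold undefined")
    return (treated.autophagosome_signal / treated.nuclear_signal) / baseline


def estimate_ic50(curve: DoseResponseCurve) -> IC50Estimate:
    """Dose at the first 50%-viability crossing of the mean curve.

    Linear interpolation between the bracketing doses; censored when all
    means stay on one side of 50%.
    """
    means = curve.mean_viabilities()
    doses = curve.doses
    for i, (dose, mean) in enumerate(zip(doses, means)):
        if mean == 50.0:
            return IC50Estimate(value=float(dose))
        if i + 1 < len(means) and (means[i] - 50.0) * (means[i + 1] - 50.0) < 0:
            frac = (means[i] - 50.0) / (means[i] - means[i + 1])
            return IC50Estimate(value=float(doses[i] + frac * (doses[i + 1] - doses[i])))
    if np.all(means > 50.0):
        return IC50Estimate(value=None, censored=f"greater than {doses[-1]:g} uM")
    if np.all(means < 50.0):
        return IC50Estimate(value=None, censored=f"less than {doses[0]:g} uM")
    # Mixed sides without an adjacent sign change can only happen with an
    # exact-50 point, handled above; defensive fallback.
    raise RuntimeError("unreachable crossing state")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Long-format plate file: columns (well, condition, value)."""
    df = pd.read_csv(path)
    required = {"well", "condition", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate file must have columns {sorted(required)}")
    return df


def summarize_conditions(df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Per-condition mean, SD (ddof=1) and n, the reporting convention."""
    g = df.groupby("condition")[value_col]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out
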