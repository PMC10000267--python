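"""Shared fixtures: the published candidate table and small helpers."""

from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from acpforge.libgen import PeptideLibrary, PeptideWindow

DATA_DIR = Path(__file__).parent / "data"

# The five synthesized candidates with their published annotations:
# sequence, source coordinates (1-based in the alpha-lactalbumin
# precursor), net charge, structure label, per-predictor probabilities.
CANDIDATES = {
    "ALA-A1": dict(
        sequence="RFFVPLFLVGILFPAILAKQFTK", start=2, end=24, charge=3,
        structure="coil–helix–coil–helix", probs=(0.980, 0.620, 0.964),
        consensus_3dp=0.836, call="ACP",
    ),
    "ALA-A2": dict(
        sequence="KLWCKSSQVPQSR", start=77, end=89, charge=3,
        structure="helix–coil", probs=(0.992, 0.480, 0.798),
        consensus_3dp=0.724, call="ACP",
    ),
    "ALA-A3": dict(
        sequence="RFFVPLFLVGILFPAILAKQFTKC", start=2, end=25, charge=3,
        structure="helix–coil–helix", probs=(0.980, 0.590, 0.977),
        consensus_3dp=0.826, call="ACP",
    ),
    "ALA-A4": dict(
        sequence="LFQISNKLWCKSSQVPQSRN", start=71, end=90, charge=3,
        structure="coil", probs=(0.944, 0.460, 0.075),
        consensus_3dp=0.319, call="non-ACP",
    ),
    "BMP-S6": dict(
        sequence="FKCRRWQWRMKKLGAPSITCVR", start=1, end=22, charge=7,
        structure="coil–helix", probs=(0.606, 1.000, 0.9848),
        consensus_3dp=0.842, call="ACP",
    ),
}


@pytest.fixture(scope="session")
def candidates():
    return CANDIDATES


@pytest.fixture(scope="session")
def candidate_library():
    """The four alpha-lactalbumin candidates as a coordinate-true library
    (the bovine positive control lives on its own source)."""
    windows = []
    for name, info in CANDIDATES.items():
        source = "P00709" if name.startswith("ALA") else "BMP"
        windows.append(
            PeptideWindow(source_id=source, start=info["start"],
                          end=info["end"], sequence=info["sequence"])
        )
    return PeptideLibrary(windows, 13, 24, 1)


@pytest.fixture(scope="session")
def candidate_ids(candidate_library):
    return {
        name: w.peptide_id
        for name, w in zip(CANDIDATES, candidate_library.windows)
    }


@pytest.fixture(scope="session")
def de_fixture_table():
    """Published (fold-change, p-value) pairs of the significant proteins."""
    return pd.read_csv(DATA_DIR / "table2_de.tsv", sep="\t")
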