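"""Label-free (DIA/SWATH-style) differential protein expression.

The stage starts from an extracted protein x run intensity matrix with a
two-group design (treated vs untreated; by default 3 biological x 3
technical replicates per group, 18 runs).  The recipe is:

1. log2 transform (positive intensities required);
2. per-run normalization — default median-centering on the log2 scale
   (each run's median is subtracted and the grand median restored), with
   a glog variance-stabilizing surrogate as an alternative;
3. missing-value imputation by the protein's median over observed runs;
   proteins missing in *all* runs of a group are flagged and left
   unimputed;
4. per-protein two-sample t-test (Welch by default) on log2 values,
   log2 fold-change = mean(treated) - mean(untreated), linear
   fold-change = 2**log2fc;
5. significance gate: fold-change >= 2 or <= 0.5 (inclusive) AND
   p < 0.05 (strict).  Benjamini-Hochberg q-values are exported for
   transparency but do not enter the gate.

Technical replicates enter the test as samples by default (n = 9 per
group); ``collapse_mean`` averages them within biological replicates
first, which is the statistically conservative choice when technical
replicates are correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TREATED = "treated"
UNTREATED = "untreated"

UP = "up"
DOWN = "down"
NS = "ns"


@dataclass
class IntensityMatrix:
    """Protein x run abundances plus run annotations.

    ``values``: DataFrame, rows protein_ids, columns run_ids, NaN for
    missing.  ``annotations``: DataFrame indexed by run_id with columns
    (group, bio_rep, tech_rep).  ``log_scale`` records whether values
    have been log2-transformed.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    log_scale: bool = False
    flagged_proteins: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        required = {"group", "bio_rep", "tech_rep"}
        if not required.issubset(self.annotations.columns):
            raise ValueError(f"run annotations need columns {sorted(required)}")
        missing_runs = set(self.values.columns) - set(self.annotations.index)
        if missing_runs:
            raise ValueError(f"runs without annotation: {sorted(missing_runs)}")
        groups = set(self.annotations.loc[list(self.values.columns), "group"])
        if groups != {TREATED, UNTREATED}:
            raise ValueError(
                f"expected groups {{'treated', 'untreated'}}, got {sorted(groups)}"
            )

    def runs_in(self, group: str) -> list[str]:
        ann = self.annotations.loc[list(self.values.columns)]
        return list(ann.index[ann["group"] == group])


@dataclass(frozen=True)
class DEConfig:
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    normalization: str = "median_center"  # median_center | glog_vsn_surrogate | none
    imputation: str = "protein_median"  # protein_median | none
    tech_rep_policy: str = "as_samples"  # as_samples | collapse_mean
    test: str = "welch_t"  # welch_t | student_t

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for name, allowed in (
            ("normalization", ("median_center", "glog_vsn_surrogate", "none")),
            ("imputation", ("protein_median", "none")),
            ("tech_rep_policy", ("as_samples", "collapse_mean")),
            ("test", ("welch_t", "student_t")),
        ):
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")


def read_intensity_matrix(
    matrix_path: str | Path, annotations_path: str | Path
) -> IntensityMatrix:
    """Wide TSV/CSV (rows proteins, columns runs) + run-annotation TSV."""
    sep_m = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(matrix_path, sep=sep_m, index_col=0)
    sep_a = "\t" if str(annotations_path).endswith((".tsv", ".txt")) else ","
    ann = pd.read_csv(annotations_path, sep=sep_a).set_index("run_id")
    return IntensityMatrix(values.astype(float), ann)


def _check_positive(values: pd.DataFrame) -> None:
    arr = values.to_numpy(dtype=float)
    bad = (arr <= 0) & ~np.isnan(arr)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive intensity at protein {values.index[i]!r}, "
            f"run {values.columns[j]!r}"
        )


def preprocess(matrix: IntensityMatrix, config: DEConfig = DEConfig()) -> IntensityMatrix:
    """log2 transform -> per-run normalization -> median imputation.

    Returns a new matrix on the log2 scale.  Proteins observed in no run
    of one group are listed in ``flagged_proteins`` and left unimputed
    (their test is reported as missing downstream).
    """
    if matrix.log_scale:
        raise ValueError("matrix is already on the log scale")
    _check_positive(matrix.values)
    log2 = np.log2(matrix.values)

    if config.normalization == "median_center":
        run_medians = log2.median(axis=0)
        log2 = log2.sub(run_medians, axis=1) + run_medians.median()
    elif config.normalization == "glog_vsn_surrogate":
        # arsinh-style generalized log with a robust scale, expressed in
        # log2 units, then median-centered per run.
        c = float(np.nanmedian(matrix.values.to_numpy()))
        glog = np.log2(matrix.values + np.sqrt(matrix.values**2 + c**2)) - 1.0
        run_medians = glog.median(axis=0)
        log2 = glog.sub(run_medians, axis=1) + run_medians.median()

    flagged = []
    for group in (TREATED, UNTREATED):
        runs = matrix.runs_in(group)
        all_missing = log2[runs].isna().all(axis=1)
        flagged.extend(log2.index[all_missing])
    flagged = sorted(set(map(str, flagged)))
    if flagged:
        logger.warning(
            "%d proteins missing in all runs of a group; left unimputed", len(flagged)
        )

    if config.imputation == "protein_median":
        medians = log2.median(axis=1)
        to_impute = log2.index[~log2.index.isin(flagged)]
        log2.loc[to_impute] = log2.loc[to_impute].T.fillna(medians[to_impute]).T

    return IntensityMatrix(
        log2, matrix.annotations, log_scale=True, flagged_proteins=tuple(flagged)
    )


def _collapse_tech_reps(matrix: IntensityMatrix) -> tuple[pd.DataFrame, dict[str, str]]:
    """Average technical replicates within (group, bio_rep).

    Returns collapsed values keyed by synthetic run ids plus a run -> group map.
    """
    ann = matrix.annotations.loc[list(matrix.values.columns)]
    grouped = {}
    meta = {}
    for (group, bio), runs in ann.groupby(["group", "bio_rep"]).groups.items():
        rid = f"{group}_bio{bio}"
        grouped[rid] = matrix.values[list(runs)].mean(axis=1)
        meta[rid] = group
    values = pd.DataFrame(grouped)
    return values, meta


def differential_expression(
    matrix: IntensityMatrix, config: DEConfig = DEConfig()
) -> pd.DataFrame:
    """Per-protein fold-change and p-value on the preprocessed matrix.

    Returns a DataFrame sorted by protein_id with columns (protein_id,
    log2fc, fold_change, p_value, q_value, n_treated, n_untreated,
    flagged).  Proteins with fewer than two observations in either group
    get a missing p-value.
    """
    if not matrix.log_scale:
        raise ValueError("run preprocess() first (matrix must be on the log2 scale)")
    if config.tech_rep_policy == "collapse_mean":
        values, meta = _collapse_tech_reps(matrix)
        treated_runs = [r for r, g in meta.items() if g == TREATED]
        untreated_runs = [r for r, g in meta.items() if g == UNTREATED]
    else:
        values = matrix.values
        treated_runs = matrix.runs_in(TREATED)
        untreated_runs = matrix.runs_in(UNTREATED)
    if min(len(treated_runs), len(untreated_runs)) < 2:
        raise ValueError("need at least two runs per group")

    equal_var = config.test == "student_t"
    rows = []
    for pid in values.index:
        t_obs = values.loc[pid, treated_runs].dropna().to_numpy()
        u_obs = values.loc[pid, untreated_runs].dropna().to_numpy()
        log2fc = float(np.mean(t_obs) - np.mean(u_obs)) if len(t_obs) and len(u_obs) else np.nan
        if len(t_obs) < 2 or len(u_obs) < 2:
            p = np.nan
        else:
            p = float(stats.ttest_ind(t_obs, u_obs, equal_var=equal_var).pvalue)
        rows.append(
            {
                "protein_id": str(pid),
                "log2fc": log2fc,
                "fold_change": float(2**log2fc) if np.isfinite(log2fc) else np.nan,
                "p_value": p,
                "n_treated": len(t_obs),
                "n_untreated": len(u_obs),
                "flagged": str(pid) in matrix.flagged_proteins,
            }
        )
    out = pd.DataFrame(rows).sort_values("protein_id").reset_index(drop=True)
    out["q_value"] = np.nan
    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return out


@dataclass(frozen=True)
class DESummary:
    n_up: int
    n_down: int

    @property
    def n_total_de(self) -> int:
        return self.n_up + self.n_down


def filter_de(
    results: pd.DataFrame, config: DEConfig = DEConfig()
) -> tuple[pd.DataFrame, DESummary]:
    """Attach up/down/ns status under the fold-change and p-value gate.

    Fold-change boundaries are inclusive, the p-value cut is strict.
    Missing p-values are ns.
    """
    out = results.copy()
    fc = out["fold_change"]
    p = out["p_value"]
    sig = p.notna() & (p < config.p_threshold)
    up = sig & (fc >= config.fc_threshold)
    down = sig & (fc <= 1.0 / config.fc_threshold)
    out["status"] = NS
    out.loc[up, "status"] = UP
    out.loc[down, "status"] = DOWN
    return out, DESummary(n_up=int(up.sum()), n_down=int(down.sum()))


def export_volcano(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano table (protein_id, log2fc, neg_log10_p, status).

    Proteins without a p-value are excluded and logged.
    """
    tested = results[results["p_value"].notna()].copy()
    dropped = len(results) - len(tested)
    if dropped:
        logger.warning("excluding %d proteins without p-values from volcano", dropped)
    with np.errstate(divide="ignore"):
        tested["neg_log10_p"] = -np.log10(tested["p_value"])
    cols = ["protein_id", "log2fc", "neg_log10_p"]
    if "status" in tested.columns:
        cols.append("status")
    return tested[cols].reset_index(drop=True)


def export_heatmap_matrix(
    matrix: IntensityMatrix, protein_ids: list[str]
) -> pd.DataFrame:
    """Row-wise z-scored submatrix of the given proteins over all runs.

    Constant rows get z-scores of zero.
    """
    sub = matrix.values.loc[protein_ids]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z
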