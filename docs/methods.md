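# Methods

This note documents the models, defaults and numerical choices behind
`acpforge`, and what its synthetic-data tests do and do not demonstrate.

## Peptide library

A library is the exhaustive set of contiguous windows of the source
protein, lengths `Lmin..Lmax` (default 5–25), step 1. Coordinates are
1-based and inclusive at both ends, and exports state this. For step 1
the count obeys the closed form Σ (N − L + 1), which doubles as an
independent oracle in the tests. Duplicate sequences from internal
repeats are **kept** as separate windows — the library count is the
window count — and `distinct_sequences` makes any collapse visible
instead of silently deduplicating. Non-standard residues (B, J, O, U,
X, Z) are rejected by default because the charge model is defined only
on the 20 standard letters; an opt-in flag drops offending records with
a warning.

The human alpha-lactalbumin precursor (UniProt P00709, 142 aa) is
shipped as reference data so library-wide computations run without
network access. Its first 25 residues and the 69–92 region are pinned
exactly by the validated candidate peptides it must contain.

## Net charge

Default model: K/R +1, D/E −1, H 0, termini ignored — the convention
that reproduces all five published candidate charges. Because predictor
servers differ in convention, the model is configurable: per-residue
overrides (e.g. H +0.5), terminal charges, and a Henderson–Hasselbalch
mode computing fractional charge at a given pH from standard side-chain
pKa values (K 10.5, R 12.5, H 6.0, D 3.9, E 4.1, C 8.3, Y 10.1; termini
9.0/2.0). Charges are stored as signed numbers; "3+" style display is a
report-layer concern.

On the shipped precursor the library's charges span −6..+3. Under the
default model (and under every alternative convention we examined:
H +1, Henderson–Hasselbalch at pH 7 with or without termini and C/Y)
the library contains **40** windows at +3, clustered in exactly the two
regions the validated candidates come from. Reported counts of ~25
+3-charged peptides for this protein are therefore
convention-dependent and could not be reproduced; the span and the
cluster locations could.

## Structure annotations

Structure labels are dash-joined segment strings over {helix, coil,
sheet}; hyphen, en dash and em dash all parse, case-insensitively. The
screening filter is *contains at least one helix segment* — validated
candidates carry mixed labels such as `coil–helix–coil–helix`.

The surrogate annotator exists only so synthetic pipelines need no
external server: it slides a 4-residue window, computes the mean
Chou–Fasman-style helix propensity (table shipped as CSV), marks
windows with mean > 1.0 as helix, and merges adjacent labels. It is
deterministic and is deliberately excluded from every comparison with
published structure calls.

## Consensus scoring

The consensus is the geometric mean of the k predictor probabilities;
zeros are legal and annihilate the product (no epsilon flooring).
Peptides missing from any predictor are excluded rather than averaged
over fewer predictors — a k−1 geometric mean is not comparable across
peptides. The ACP call threshold is 0.5, inclusive, chosen as the
simplest cutoff consistent with the published calls (the observed gap
between the highest non-ACP consensus, 0.319, and the lowest ACP
consensus, 0.724, leaves the choice unconstrained inside that
interval); it is configurable.

Values are stored at full precision and rounded half-up to 3 decimals
only at the report layer. Recomputing the published consensus values
from the *printed* probability triples reproduces them to within one
unit of the third decimal; exact equality at 3 dp is not attainable for
every row because the printed probabilities are themselves rounded from
higher-precision server outputs (e.g. (0.980, 0.620, 0.964) has
geometric mean 0.83669, which displays as 0.837 against a printed
0.836).

## Screening

Filters run charge → structure → consensus, so the expensive external
structure annotation need only cover charge-passing peptides. Survivors
are ranked by consensus descending; ties break by higher net charge,
then shorter length, then lexicographic sequence — an arbitrary but
documented and deterministic order. Redundancy default is substring
containment in either direction; an alternative source-coordinate
overlap rule (overlap ≥ 0.8 × shorter length) is available. Collapse is
greedy from the best rank, so the kept set is pairwise non-redundant
and re-ranked 1..m. Control peptides bypass filters and are excluded
from the shortlist.

## Assays

The viability and hemolysis formulas are ratios of background-corrected
absorbances, hence invariant under affine rescaling of the plate reader
(a property test). Out-of-range percentages are flagged, never clipped.
IC50 uses piecewise-linear interpolation of the replicate-averaged
curve at its first 50% crossing — assumption-free and reproducible — and
censors ("greater than <max dose>" / "less than <min dose>") instead of
extrapolating beyond the tested range. Four-parameter logistic fitting
was deliberately not used: with 8 dose points and a crossing inside the
range it adds model assumptions without changing the headline read-out.

## Differential expression

Input is a protein × run intensity matrix with run annotations (group,
biological replicate, technical replicate); the reference design is 2
groups × 3 bio × 3 tech = 18 runs. Order of operations: log2 →
normalization → imputation, fixed and documented.

- **Normalization** default is per-run median-centering on the log2
  scale with the grand median restored — a deliberately simple,
  parameter-free stand-in for variance-stabilizing normalization. A
  `glog_vsn_surrogate` option (generalized log with a robust scale,
  then median-centering) is provided; both sit behind config so a full
  VSN fit can be swapped in externally.
- **Imputation** is the protein's median over observed runs, applied
  across all runs (per-protein, not per-group, as the least
  group-biased reading). Proteins observed in no run of a group are
  flagged and left unimputed; they surface downstream with a missing
  p-value. Median imputation pulls imputed cells toward the protein's
  overall level and therefore *attenuates* fold-changes slightly: with
  5% missing-at-random cells the recovered log2 fold-change at a
  planted effect of 1 averages ≈0.94. Tests quantify this rather than
  hide it.
- **Test** default is Welch's two-sided t on log2 values
  (`student_t` available); fold-change is 2^(Δ mean log2), consistent
  with the log-scale pipeline, not a ratio of raw means.
- **Gate**: up iff fold-change ≥ 2 and p < 0.05; down iff fold-change
  ≤ 0.5 and p < 0.05; fold-change boundaries inclusive, p strict. No
  multiple-testing correction enters the gate (matching the published
  thresholds), but BH q-values are always exported.
- **Technical replicates** enter as samples by default (n = 9 per
  group), mirroring the reference design's stated n. This treats
  correlated technical replicates as independent; on a hierarchical
  null with between-bio variance it inflates the empirical p < 0.05
  rate several-fold (≈0.23 in our simulations at bio sd 0.3, tech sd
  0.2). This is a known limitation of the convention, stated here
  deliberately; the `collapse_mean` policy averages technical
  replicates first and restores calibration (≈0.03–0.05). Type-I
  control is therefore verified in the two designs where the t-test's
  assumptions hold: an i.i.d. null (technical noise only) under
  `as_samples`, and a hierarchical null under `collapse_mean`.

## Synthetic data

All generators draw from independent substreams derived from (seed,
generator label) via CRC-salted `numpy` SeedSequences, so outputs are
bit-reproducible and adding a generator never perturbs another.

- Proteins: i.i.d. residues, uniform or average vertebrate composition.
  No local sequence structure is emulated.
- Score tables: hidden true-ACP labels at a base rate of 0.05 (the
  order of magnitude of plausible hits in a sliding-window library,
  set high enough that small test libraries contain positives); true
  ACPs draw probabilities from Beta(8, 2), others from Beta(2, 8), with
  logit-normal predictor noise (sd 0.5). This mimics the bimodal spread
  of real ensemble predictors but carries no sequence signal — passing
  recovery tests shows the ranking machinery works, not that real
  predictors are accurate.
- Proteomes: log2 intensity = protein baseline N(20, 2) + group effect
  (planted |log2fc|, sign randomized, on a configurable fraction;
  defaults 286 proteins with 38/286 affected, matching the reference
  design's scale) + per-bio-replicate effect N(0, 0.3) + technical
  noise N(0, 0.2), exponentiated, with missing-at-random dropouts (5%).
  Real DIA data have intensity-dependent missingness and heavier tails;
  conclusions about those regimes are out of scope.
- Assay plates: anchor wells (media/untreated; blank/positive) plus
  condition wells placed at the true percentage between the anchors,
  all with Gaussian read noise, so the quantification formulas can be
  verified by noiseless round-trip and by sampling-error bounds.

## Problem sizes used in the test suite

Property and calibration tests run at desk scale chosen for tight
Monte-Carlo error at interactive runtimes: 2,000 proteins for type-I
calibration (binomial se ≈ 0.005), 200 proteins for effect recovery
(se ≈ 0.02), 150-residue proteins for screening recovery. All seeds are
fixed in the tests.

## Known limitations

- The surrogate helix annotator is not a structure predictor; published
  helix/coil splits from external servers are not reproducible here.
- The geometric-mean consensus assumes predictors are calibrated
  probabilities; no recalibration is attempted.
- Median imputation biases fold-changes toward zero (quantified above);
  group-aware or censored-likelihood imputation is not implemented.
- The `as_samples` replicate policy inflates significance under
  between-replicate correlation; use `collapse_mean` when technical
  replicates are not independent.
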