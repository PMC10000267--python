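# acpforge

An in silico screening toolkit for **anticancer peptide (ACP) discovery**
from a single source protein. It implements the complete computational
arm of a library-to-candidate workflow:

1. **Library generation** — enumerate every contiguous peptide window of
   a protein sequence in a length range (default 5–25 residues, step 1).
   For an *N*-residue protein the library size is
   Σ<sub>L=Lmin</sub><sup>min(Lmax,N)</sup> (N − L + 1); a 142-residue
   protein such as the human alpha-lactalbumin precursor yields 2688
   peptides.
2. **Physicochemistry** — integer net charge per peptide,
   *z* = (#K + #R) − (#D + #E) by default (configurable, including a
   Henderson–Hasselbalch pH mode), and library-wide charge
   distributions.
3. **Consensus scoring** — external ML predictors each supply an ACP
   probability *p<sub>i</sub>* ∈ [0, 1] per peptide; the ranking
   statistic is the geometric mean (Π *p<sub>i</sub>*)<sup>1/k</sup>,
   with an ACP call at consensus ≥ 0.5.
4. **Screening** — filter (net charge ≥ +3, contains a helix segment,
   consensus call), rank by consensus, greedily collapse
   sequence-redundant candidates (substring containment by default), and
   emit a top-*k* shortlist. Positive-control peptides ride along
   without competing for the shortlist.
5. **Assay quantification** — % viability (MTT, A570), % hemolysis
   (A415 vs detergent lysis), nuclear-normalized autophagy fold-change,
   and IC50 by linear interpolation of the mean dose–response curve with
   censoring outside the tested range.
6. **Label-free differential expression** — from a protein × run
   intensity matrix (two groups × biological × technical replicates):
   log2 transform, per-run median-centering normalization, protein-median
   imputation, Welch's t-test per protein, and the 2× fold-change /
   p < 0.05 gate with BH q-values exported alongside.
7. **Synthetic data** — seeded generators for proteins, predictor score
   tables with planted truth, structure annotations, assay plates, and
   log-normal proteome matrices, so every stage is testable offline.

External structure and probability predictors are *inputs* (TSV files);
this package does not reimplement them. A deterministic
propensity-based helix annotator is included purely as a surrogate for
synthetic end-to-end runs.

## Worked example

```python
from acpforge import (bundled_alpha_lactalbumin, enumerate_windows,
                      annotate_charges, charge_distribution,
                      consensus_score, classify, net_charge)

protein = bundled_alpha_lactalbumin()          # 142-aa precursor, shipped
library = enumerate_windows(protein, 5, 25)
print(len(library))                            # 2688

dist = charge_distribution(annotate_charges(library))
print(dist.iloc[[0, -1]].to_dict("records"))
# [{'charge': -6, 'count': 20}, {'charge': 3, 'count': 40}]

print(net_charge("KLWCKSSQVPQSR"))             # 3
c = consensus_score((0.992, 0.480, 0.798))
print(round(c, 3), classify(c))                # 0.724 ACP
```

The library spans net charges −6 to +3; the most positively charged
windows (+3) are the screening pool. The consensus shown is the
geometric mean of three predictor probabilities for one experimentally
validated candidate, called ACP at the 0.5 threshold.

The same pipeline is available from a shell:

```bash
acp-forge libgen --fasta protein.fasta --lmin 5 --lmax 25 --out library.tsv
acp-forge charges --library library.tsv --out charges.tsv
acp-forge consensus --scores a.tsv --scores b.tsv --scores c.tsv --out consensus.tsv
acp-forge screen --library library.tsv --charges charges.tsv \
    --structures structures.tsv --consensus consensus.tsv --out report.tsv
acp-forge de --matrix intensities.tsv --annotations runs.tsv --out-prefix de
```

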