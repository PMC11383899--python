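# chemoscreen

Statistical pipeline for secretome-to-migration screening in
tumor-microenvironment (TME) studies, built around the analysis design used
to identify stroma-derived chemokines that attract dendritic cells toward
head-and-neck cancer secretomes.

## Who this is for

Groups running transwell chemotaxis assays against conditioned media
(cell lines or dissociated-tumor cultures), profiling the same media with
targeted proteomics panels (Olink-style NPX values with per-protein limits
of detection), and relating the findings to gene-expression cohorts. The
package covers the quantification, quality control, screening and scoring
statistics for that workflow; it does not touch raw flow-cytometry gating
or proteomics normalization.

## What it computes

**Migration calling.** Per-well immune-subset event counts are converted to
absolute migrated-cell counts with counting-bead arithmetic
(`count = events x beads_added / bead_events`). Donors whose
positive/negative control ratio falls below 2.5 are excluded per subset.
Migration toward an attractant is *induced* when the mean count exceeds
`mean(negative control) + 2 x SD(negative control)`; percentages are
normalized to the positive-control chemokine mix (= 100 %).

**Nonparametric statistics.** Exact two-sided Fisher 2x2
(hypergeometric enumeration), Mann-Whitney U and Wilcoxon signed-rank
(full enumeration for small samples, tie-corrected Edgeworth-refined
normal approximation otherwise), Kruskal-Wallis and Friedman omnibus tests
with Dunn post-hoc comparisons, Pearson correlation, and Benjamini-Hochberg
step-up FDR — all implemented directly with explicit tie and
degenerate-input handling.

**Secretome screening.** NPX profiles carry limit-of-detection (LOD) flags.
The *presence contrast* marks proteins below LOD in **all** cell-line
secretomes yet above LOD in a strict majority of TME secretomes —
the signature of stromal or immune origin. The *correlation screen*
relates per-sample migration counts to NPX per protein (Pearson, BH
within subset); candidate chemokines for an anchor subset (default cDC1)
are its significant positive correlates that also pass the presence
contrast.

**Signature scoring.** Gene-set scores are per-sample means of cohort
z-scored genes; composite sets (e.g. overall DC = cDC1 ∪ cDC2) resolve to
de-duplicated gene unions. Response groups (major pathologic response vs
none) are compared with an exact rank-sum test.

**Synthetic studies.** `chemoscreen.simulate` generates all three data
layers with recorded ground truth — planted stroma-only chemokines, known
migration multipliers, planted signature shifts — at the default design
scale of 28 TME media, 11 cell lines (3 HPV-positive), two PBMC donors,
a 92-protein panel and a 16-patient cohort.

## Worked example

```
chemoscreen simulate --seed 1 --out-dir data/
chemoscreen run --data-dir data/ --out-dir results/
```

The run writes migration calls, presence contrasts, association records,
candidates and signature tests as TSV. With seed 1 the candidate table is

```
protein  candidate
CCL13    True
CCL7     True
CCL8     True
CXCL5    True
```

exactly the four planted stroma-only chemokines, with cDC1 association
records (`results/associations.tsv`)

```
protein        r            p            q
   CCL7 0.878018 8.360459e-10 4.403999e-08
  CCL13 0.873278 1.334545e-09 4.403999e-08
  CXCL5 0.826030 6.195790e-08 1.363074e-06
   CCL8 0.759247 2.810585e-06 4.637465e-05
```

— strong positive correlations between each planted chemokine's NPX and
cDC1 migration counts across the 28 TME samples, all significant after BH
correction. The signature comparison (`results/signature_tests.tsv`) finds
the shifted chemokine/DC/myCAF/iCAF signatures at the exact rank-sum
minimum p = 0.0036 (3 responders vs 13 non-responders) while the unshifted
eCAF and pericyte signatures stay at p > 0.5.

Every stage is also callable as a library function
(`chemoscreen.migration.summarize_experiment`,
`chemoscreen.association.screen`, ...) on in-memory objects.

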